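# ccweight

Clone–censor–weight emulation of dynamic treatment-initiation strategies in
longitudinal person-month data, with a confounded synthetic cohort generator
for end-to-end validation.

The pipeline compares strategies of the form *"initiate oral anticoagulation
the first month the CHA₂DS₂-VASc score reaches k"* (k configurable, default
1, 2, 4, 6) against *"never initiate"*:

1. **simulate / load** a long person-month panel (one row per patient-month
   with baseline flags, time-varying score components, treatment status and
   outcome indicators);
2. **score** — recompute CHA₂DS₂-VASc and a claims-adapted HAS-BLED monthly;
3. **eligibility** — sequential baseline inclusion/exclusion with a
   flowchart-style attrition log;
4. **clone / censor** — copy every eligible patient into each strategy arm,
   delete baseline-noncompliant replicates, artificially censor replicates at
   the first protocol deviation (with a configurable grace period for
   initiation after threshold crossing);
5. **weight** — pooled logistic models for initiation and loss to follow-up,
   converted to unstabilized cumulative inverse-probability weights with
   percentile truncation (default 99th);
6. **estimate** — weighted pooled logistic discrete-time hazard models with
   patient-clustered robust variance, summary hazard ratios with 95% CIs,
   standardized survival curves, per-arm events / person-years / incidence
   rates.

Because treatment initiation in the generator is a logistic function of the
current score (confounding by indication), while `counterfactual_truth`
replays the same generative model with treatment *forced* to follow a
regimen, the package can check itself: the weighted estimator must recover
the forced-regimen ground truth that the naive person-month association
misses (see `ccweight.validation` and `tests/test_acceptance.py`).

## CLI

```sh
# generate a synthetic panel
ccweight simulate --config examples/sim.yaml --out panel.csv

# full emulation (writes CSV tables + manifest.json to the output directory)
ccweight emulate --config examples/run.yaml --out-dir results/run1

# the four sensitivity variants (36-month follow-up, no metastatic disease,
# no thrombocytopenia, 95th-percentile truncation)
ccweight sensitivity --config examples/run.yaml --out-dir results/sens

# pretty-print a finished run
ccweight report --out-dir results/run1
```

A run config YAML mirrors `ccweight.RunConfig`; minimal example:

```yaml
simulation: {n_patients: 10000, seed: 1}
seed: 1
thresholds: [1, 2, 4, 6]
grace_months: 1
follow_up_months: 12
truncation_percentile: 99
```

Alternatively set `input_panel: path/to/panel.csv` to analyse an existing
person-month table (column order documented in
`ccweight.simulate.PANEL_COLUMNS`); missing values fail fast — the pipeline
does not impute.

## Layout

| module                  | role |
|-------------------------|------|
| `ccweight.simulate`     | synthetic cohort generator + forced-regimen truth oracle |
| `ccweight.scores`       | CHA₂DS₂-VASc / HAS-BLED scoring |
| `ccweight.eligibility`  | baseline criteria + attrition log |
| `ccweight.cloning`      | clone expansion, baseline exclusion, artificial censoring |
| `ccweight.weights`      | initiation/dropout models, cumulative IP weights, truncation |
| `ccweight.estimation`   | weighted hazard models, HRs, survival curves, person-time |
| `ccweight.pipeline`     | orchestration, sensitivity suite, manifest I/O |
| `ccweight.validation`   | canonical parameter-recovery scenarios |
| `ccweight.cli`          | `ccweight` command-line entry point |
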