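# chronact

Analytics for chronic active white-matter lesions on longitudinal MRI:

* **SEL detection** — classify slowly expanding lesions from the Jacobian
  determinant of a baseline-to-final displacement field, with per-patient
  follow-up-time normalisation (annualised mean log-Jacobian, z-scored) and
  possible/definite sub-categories.
* **PRL detection** — a deterministic, rule-based surrogate of visual
  paramagnetic-rim reading on a susceptibility-weighted channel: shell/core/
  ring contrast scoring, a consecutive-axial-slice rule, and a tubularity
  filter that rejects veins.
* **Cohort statistics** — SEL-by-PRL cross-tabs with Yates-corrected
  chi-square, patient stratification (SEL+PRL+ / SEL+PRL− / SEL−),
  confirmed-disability-progression flags, Spearman and partial Spearman
  correlations, mixed-effects EDSS models with metric-by-time interactions,
  Poisson count models, log-volume OLS and logistic progression models.
* **Synthetic cohort generator** — fully ground-truthed phantoms: ellipsoid
  lesions, analytic compact-support expansion fields (exact Jacobians),
  implanted susceptibility rims and vein confounders on an anisotropic
  lattice, and EDSS trajectories whose slopes depend on the lesion stratum.

## Command line

```bash
chronact config --dump                      # print all defaults as YAML
chronact simulate --out cohort/ --seed 1    # write a synthetic cohort
chronact detect-sels --labels L.nii.gz --field F.nii.gz --years 3.2 \
    --out lesions.csv
chronact detect-prls --swi S.nii.gz --labels L.nii.gz --out rims.csv
chronact analyze --lesions lesions.csv --clinical clinical.csv \
    --visits visits.csv --out report/
chronact run-all --out report/ --seed 1     # end to end, in memory
```

A single YAML file with `simulate:` / `sel:` / `prl:` sections configures
everything; CLI flags point at it via `--config`. Every pipeline output
directory contains one `manifest.json` recording the command, config hash,
seed and outputs; reruns with the same seed are byte-identical.

## Layout

```
src/chronact/
  image_core.py        volumes, NIfTI I/O, components, morphology, Jacobians
  sel_pipeline.py      lesion expansion summaries and SEL classification
  prl_pipeline.py      rim scoring, vein filter, PRL classification
  cohort_stats.py      cross-tabs, stratification, CDP, correlations, models
  synthetic_cohort.py  ground-truthed cohort generator
  config.py            YAML configuration
  workbench.py         run-all orchestration and manifests
  cli.py               click CLI
tests/                 pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py  acceptance report
```
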