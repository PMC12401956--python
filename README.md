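# bloodml

Case-control classification of routine blood panels with binary Grey Wolf
Optimization (GWO) wrapper feature selection.

The package provides an end-to-end, fully reproducible pipeline:

1. **`bloodml.synthetic_cohort`** — generate case/control cohorts whose
   marginal distributions match per-group summary statistics (mean/SD per
   analyte), with configurable missingness (MCAR), a shared-latent-factor
   correlation knob, and a builtin 45-analyte reference spec set
   (192 controls / 203 cases, age and sex demographics included).
2. **`bloodml.preprocessing`** — missingness-threshold feature elimination
   (default: drop features > 50% missing), fold-safe median/mode imputation,
   binary sex encoding (female → 0, male → 1), and z-score standardization
   fit on training folds only.
3. **`bloodml.gwo_select`** — a from-scratch binary Grey Wolf Optimizer.
   Wolves are continuous positions in [0, 1]^d binarized via a stochastic
   sigmoid (or deterministic threshold) transfer function; fitness is the
   stratified cross-validated accuracy of a wrapper classifier on the masked
   features, optionally penalized by subset size. Defaults: 10 wolves,
   20 iterations, linearly decaying exploration coefficient 2 → 0.
4. **`bloodml.classifiers`** — five models behind one train/score interface:
   random forest, logistic regression (L2, C=1), RBF SVM (C=1,
   gamma="scale"), KNN (k=5, Euclidean), and gradient-boosted trees
   (100 rounds, learning rate 0.3, depth 6). Tree ensembles expose
   normalized feature importances.
5. **`bloodml.evaluation`** — repeated stratified k-fold cross-validation
   (default 10×5), confusion-matrix metrics (accuracy, sensitivity,
   specificity, precision, F1), ROC/AUC with Mann-Whitney-consistent tie
   handling, and the before/after-selection comparative experiment.
6. **`bloodml.stats_compare`** — per-feature Welch t-tests (pooled Student
   optional), a Pearson 2×2 chi-square for sex, and a p-sorted
   group-comparison table.
7. **`bloodml.cli` / `bloodml.cohort_io`** — CSV/YAML I/O and a `bloodml`
   command-line tool. A single global seed fans out deterministically to
   every stage.

## Test

```sh
python -m pytest -q
```

The suite covers every module plus an acceptance suite
(`tests/test_acceptance.py`) with independent oracles: exhaustive subset
enumeration against the GWO, exact-arithmetic metric checks, the
AUC = normalized Mann-Whitney U identity, null calibration, signal
recovery, and leakage-safety checks.

## CLI

All subcommands take `--config` (YAML or JSON), `--seed` (overrides the
config's global seed) and `--out` (output directory):

```sh
bloodml simulate   --config config.yaml --out out/   # cohort.csv + manifest
bloodml preprocess --config config.yaml --out out/
bloodml select     --config config.yaml --out out/   # selected features + trace
bloodml compare    --config config.yaml --out out/   # comparison.csv
bloodml evaluate   --config config.yaml --out out/
bloodml run-all    --config config.yaml --out out/   # full pipeline
```

Minimal config:

```yaml
seed: 1
simulate:            # or cohort_path: my_cohort.csv
  n_control: 192
  n_case: 203
  feature_specs: builtin
gwo:
  pop_size: 10
  n_iter: 20
  fitness: {classifier: random_forest, cv_folds: 5}
evaluation:
  k: 10
  repeats: 5
```

`run-all` writes `cohort.csv`, `metrics.csv`, `roc.csv`, `convergence.csv`,
`selected_features.txt`, `comparison.csv`, `importances.csv`, and
`run_log.json` (all seeds + config hash).

## Cohort file format

CSV, UTF-8, header `subject_id,group,sex,age,<analyte...>`; `group` ∈
{case, control}, `sex` ∈ {male, female}, missing lab values as empty cells.
Feature-spec files use the header
`name,unit,control_mean,control_sd,case_mean,case_sd,lower_bound,missing_rate`.
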