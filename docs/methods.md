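# Methods

This note documents the models, generators, and numerical conventions
behind `cvbias`, and what the package's tests do and do not establish about
real data.

## The leakage-bias experiment

The quantity of interest is the *empirical leakage bias* of a resampling
method: the difference, per evaluation metric, between a model trained with
the resampler misapplied to all data before splitting ("incorrect") and a
model trained with the resampler applied inside the cross-validation to
training folds only ("correct"). Both arms run repeated stratified k-fold
cross-validation (default 5 folds × 30 repeats; repeat *r* uses seed
`base_seed + r` for the fold shuffle, the resampler, and stochastic model
components, identically in both arms, so the design is paired). In each
repeat the best model is the grid configuration — feature scorer × number
of selected features × classifier × classifier hyperparameters × the
resampling method's own hyperparameters (k for the SMOTE family, topology
for polynomial-fit SMOTE) — maximizing fold-mean AUC; the other four
metrics are read off that same argmax model. Ties in the argmax go to the
first configuration in the deterministic enumeration order.

Incorrect-arm stratification operates on the post-resampling labels (that
is what "splitting after resampling" means in practice). The leakage audit
is structural, not statistical: every synthetic row records the input-row
indices it was generated from, and a test-fold synthetic row with a parent
in the training fold counts as leaked. The correct arm must audit clean by
construction; the tests assert it does for every method.

Upfront preprocessing (column-mean imputation, then z-scoring with the
population SD; constant columns map to zeros because real radiomic exports
contain constant features) is applied to *all* data before any split. That
is itself a mild, deliberate form of leakage: it replicates the pipeline
under study, affects both arms identically, and therefore cancels in the
bias. Do not move it inside the CV.

## Resamplers

Seven methods share one contract: kept original rows are bit-identical,
synthetic rows are flagged with nonempty parent sets, and identical
(input, spec, seed) gives identical output. Euclidean distance on the
(z-scored) features throughout; neighbor ties break toward the lowest row
index.

- **Random over/undersampling** — duplicate minority rows (with
  replacement) / subsample majority rows (without) to equal counts.
  Duplicates are flagged synthetic so audits treat them like generated
  samples.
- **SMOTE** — `x_new = x_i + t·(x_nn − x_i)`, `t ~ U(0,1)`, `x_nn` one of
  the k nearest minority neighbors of minority row `x_i` (k ∈ {3,5,7} in
  the benchmark grid, default 5). Base rows are cycled evenly over the
  minority class and the excess trimmed by a seeded permutation, so output
  counts are exactly equal. If k ≥ minority count, k is clamped to
  minority−1 with a warning rather than erroring, so small, highly
  imbalanced folds still run.
- **Tomek links** — remove the majority member of every cross-class
  mutual-nearest-neighbor pair, found on the input in one pass (no
  cascade). On exactly balanced classes the per-pair tie removes the
  label-0 member: deterministic, documented, immaterial to the bias
  conclusions.
- **SMOTE + Tomek links** — SMOTE to balance, then Tomek cleaning of the
  balanced result (majority resolved by the post-SMOTE counts).
- **Polynomial-fit SMOTE** — deterministic interpolation along a geometric
  template of the minority class: *star* (segments to the minority
  centroid), *bus* (segments through consecutive minority rows in dataset
  order), *poly* (per-feature polynomial of degree min(5, m−1) over the
  minority index, sampled at evenly spaced fractional indices). Star and
  bus always emit at least one synthetic point per minority sample, even
  on balanced data — the always-generate behavior that makes these
  topologies biased even at balance 1 — so they can overshoot exact
  balance when fewer than m samples are needed.
- **MWMOTE** — the published procedure with its original default
  hyperparameters (k1=5, k2=3, k3=⌈m/2⌉, closeness threshold 5, CMAX=2,
  cluster cut at 3× the mean minority nearest-neighbor distance):
  noise-filter the minority, find the borderline majority set, weight the
  informative minority by closeness×density to that set, cluster the
  filtered minority by average linkage, and interpolate within clusters.
  An informative sample that was filtered as noise gets a singleton
  cluster (its synthetic copies collapse onto itself); an empty
  informative set falls back to uniform weights with a warning.

## Models and metrics

Feature scorers: one-way ANOVA F (infinite F capped at 1e12 so ranking
stays defined), per-feature Bhattacharyya distance between class-
conditional Gaussians (variances floored at 1e-12), extra-trees impurity
importances (100 trees), and |coefficients| of an L1 logistic regression
(C=1.0) — the LASSO is a scorer only, never the final classifier.
Classifiers: logistic regression and RBF-SVM with C ∈ {2⁻¹⁰..2¹⁰}
(γ = 1/d), Gaussian naive Bayes, random forest (250 trees), and optionally
k-NN (present in the hyperparameter table but off by default, matching the
four classifiers actually used). SVM probabilities come from Platt scaling
(sklearn's internal CV) because the Brier score needs probabilities; AUC
uses the same outputs for consistency — on the simulation they are
rank-identical to the decision scores (checked during development).

Metrics: AUC as the midrank statistic (macro-averaged AUC coincides with
it for binary outcomes), sensitivity and specificity at probability
threshold 0.5 (the conventional default on calibrated probabilities; no
threshold is inherent to the protocol), balanced accuracy as their mean,
and the Brier score mean((p − y)²).

## Synthetic data

`generate_radiomics_like` emulates the statistical shape of tabular
radiomic exports: n samples with minority count round(n/(1+balance))
(minority = positive class), d features of which `n_informative` get a
class-mean shift of `effect_size` SD and the rest are equicorrelated
Gaussian noise (one shared factor, correlation default 0.5 — radiomic
feature sets are heavily redundant), optional uniformly missing cells.
Defaults (n=200, d=500, 10 informative features at 0.8 SD, balance 2) are
a modeling choice of a plausible mid-sized cohort, not an empirical claim
about any particular dataset. What the generator does **not** emulate:
non-Gaussian marginals, block rather than global correlation, batch
effects, and label noise. Tests passing on this generator therefore show
protocol-level properties (leakage, bias ordering, balance association),
not performance claims about real radiomic cohorts.

`generate_sim_data` draws N negatives plus round(N·B/100) positives i.i.d.
uniform on [−1,1]²; labels are independent of the coordinates, so 0.5 is
the true AUC of every classifier and any excess is leakage.

## The simulation study

Each grid point (B, N) runs 100 repeats. A repeat draws a fresh dataset,
then: correct arm — stratified 80–20 split, SMOTE (k=5) on the 80% only,
RBF-SVM (C=50, γ=500 — deliberately overfitting-prone so memorized
synthetic test points are rewarded), AUC on the untouched 20%; incorrect
arm — SMOTE on all data, then the split. Both arms reuse the repeat's
dataset and split seed. The default grid spans B ∈ {100, 50, 33.3, 25, 20}
(imbalance 1–5) × N ∈ {50, 100, 200}; the bias-vs-imbalance slope is an
OLS fit over the pre-saturation range (imbalance ≤ 4). These grid bounds
and the 100-repeat depth keep the full sweep under a minute on one CPU
while giving per-point standard errors near 0.01 AUC.

Measured behavior at these settings: the correct arm stays at 0.50
everywhere; the incorrect arm's mean AUC grows at ~0.08 per unit of
imbalance before flattening near 0.78. The growth rate is consistent with
the ~0.1-per-imbalance rule of thumb, but the saturation level is a
genuine property of this geometry: even an oracle ranking test points by
distance to the nearest positive training point tops out near 0.83 at
imbalance 5, because mid-segment synthetic test points are far (on the
kernel's length scale of 1/√500 ≈ 0.045) from every positive training
point. Pushing imbalance to 20 or N to 2000 moves the plateau only within
0.75–0.82. Higher peaks would require the leak detector to exploit the
segment structure itself rather than point proximity.

## Design choices and limitations

- Best-model selection maximizes over the method's own hyperparameters as
  well as the model grid, so one bias number is reported per method.
- Best-of-grid selection noise inflates *both* arms' absolute AUC on null
  data (the larger the grid, the larger the lift — ~+0.1 for the reduced
  grid's ~72 argmax cells); the paired bias subtracts it out.
- The reduced grid (2 scorers × {1,4,16} features × LR/NB × coarse C) is
  the default for interactive runs; the full grid is available by config
  and is substantially more expensive.
- Single-cell bias estimates at few repeats carry a Monte-Carlo noise
  floor of a few hundredths of AUC; claims about small biases (e.g.,
  undersampling's) should pool several datasets.
- Binary outcomes only; no nested tuning beyond the printed grids; no
  attempt to reproduce results on any external cohort — generic CSV
  ingestion is provided for users who have one.
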