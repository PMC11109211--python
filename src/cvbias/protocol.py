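"""The paired correct / incorrect resampling experiment.

The experiment runs repeated stratified k-fold cross-validation twice on the
same data with the same seeds:

* **correct** — folds are drawn from the original data; the resampler is
  applied *inside* the loop, to each training part only.  Test folds never
  contain a synthetic row.
* **incorrect** — the resampler is applied *once to all data* before
  splitting; folds are drawn from the resampled data, so test folds can
  contain synthetic rows whose parents sit in the training fold.  This is
  the data-leakage misuse whose cost the package quantifies.

In both arms, for every repeat, the configuration (feature scorer x number
of features x classifier x classifier hyperparameters x resampler
hyperparameters) with the highest fold-mean AUC is the repeat's best model;
its full metric set is recorded.  The empirical leakage bias of a metric is
(incorrect - correct) of those best models, per repeat, averaged over
repeats.  Because both arms consume identical repeat seeds, the comparison
is matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .datasets import LabeledTable
from .modeling import MetricSet, ModelGrid, evaluate, score_features, select_top_k, train_predict
from .resamplers import ResamplerSpec, resample, resampler_variants

__all__ = [
    "CVScheme",
    "FoldAudit",
    "ScenarioResult",
    "BiasRecord",
    "AssociationResult",
    "run_correct",
    "run_incorrect",
    "compute_bias",
    "summarize_bias",
    "associate_with_balance",
]


@dataclass(frozen=True)
class CVScheme:
    """Repeated stratified k-fold cross-validation; repeat r uses seed
    base_seed + r for the fold shuffle, the resampler, and any stochastic
    model component — in both arms, so the design is paired."""

    n_folds: int = 5
    n_repeats: int = 30
    base_seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")


@dataclass(frozen=True)
class FoldAudit:
    """Leakage audit of one test fold: how many of its rows are synthetic,
    and how many of those have a parent in the corresponding training fold
    (i.e., genuinely leak training information)."""

    repeat: int
    fold: int
    n_test: int
    n_test_synthetic: int
    n_test_leaky: int


@dataclass
class ScenarioResult:
    """Per-repeat best-model metrics of one (dataset, method, arm) run."""

    method: str
    arm: str  # "correct" | "incorrect"
    per_repeat: list  # list[MetricSet]
    best_configs: list  # list[tuple] parallel to per_repeat
    audits: list = field(default_factory=list)  # list[FoldAudit]

    def mean_metrics(self) -> MetricSet:
        return MetricSet.mean(self.per_repeat)

    def total_synthetic_in_test(self) -> int:
        return sum(a.n_test_synthetic for a in self.audits)

    def total_leaky_in_test(self) -> int:
        return sum(a.n_test_leaky for a in self.audits)


@dataclass(frozen=True)
class BiasRecord:
    """One paired repeat: best-model metrics under both protocols and their
    difference (incorrect - correct, per metric)."""

    dataset_id: str
    resampler: str
    repeat: int
    correct: MetricSet
    incorrect: MetricSet

    @property
    def bias(self) -> MetricSet:
        return self.incorrect - self.correct


@dataclass(frozen=True)
class AssociationResult:
    """OLS of mean bias on class balance: slope (bias units per unit
    balance), intercept, Pearson r, and the two-sided slope t-test p-value."""

    slope: float
    intercept: float
    r: float
    p_value: float


def _evaluate_grid_on_fold(train_tab, test_X, test_y, grid, seed, sink):
    """Score every grid configuration on one fold; append MetricSets into
    ``sink[config_key]``.  Feature scores are computed once per scorer."""
    score_cache = {
        s: score_features(train_tab, s, seed=seed, lasso_C=grid.lasso_C)
        for s in grid.scorers
    }
    sel_cache = {}
    for scorer, k, clf, hp in grid.configs():
        key = (scorer, k, clf, tuple(sorted(hp.items())))
        sel_key = (scorer, k)
        if sel_key not in sel_cache:
            sel_cache[sel_key] = select_top_k(score_cache[scorer], k)
        idx = sel_cache[sel_key]
        sub_train = LabeledTable(
            train_tab.features[:, idx],
            train_tab.labels,
            train_tab.provenance,
            train_tab.parent_ids,
        )
        probs = train_predict(sub_train, test_X[:, idx], clf, hp, seed=seed)
        sink.setdefault(key, []).append(evaluate(probs, test_y))


def _run_scenario(
    table: LabeledTable,
    method: str,
    grid: ModelGrid,
    cv: CVScheme,
    leak: bool,
    variants: list | None = None,
) -> ScenarioResult:
    if np.isnan(table.features).any():
        raise ValueError("table contains missing values; run preprocess() first")
    variants = list(variants) if variants is not None else resampler_variants(method)
    per_repeat, best_configs, audits = [], [], []
    for r in range(cv.n_repeats):
        seed = cv.base_seed + r
        best_auc, best_metrics, best_cfg = -np.inf, None, None
        for v in variants:
            data = resample(table, v, seed) if leak else table
            skf = StratifiedKFold(cv.n_folds, shuffle=True, random_state=seed)
            fold_sets: dict = {}
            for f, (tr, te) in enumerate(skf.split(data.features, data.labels)):
                if leak:
                    train_tab = data.subset(tr)
                    syn_mask = data.synthetic_mask[te]
                    tr_set = set(int(i) for i in tr)
                    leaky = sum(
                        1
                        for i in te[syn_mask]
                        if any(p in tr_set for p in data.parent_ids[int(i)])
                    )
                    audits.append(
                        FoldAudit(r, f, len(te), int(syn_mask.sum()), int(leaky))
                    )
                else:
                    train_tab = resample(table.subset(tr), v, seed)
                    # test fold comes straight from the original table
                    n_syn = int(data.synthetic_mask[te].sum())
                    audits.append(FoldAudit(r, f, len(te), n_syn, 0))
                _evaluate_grid_on_fold(
                    train_tab, data.features[te], data.labels[te], grid, seed, fold_sets
                )
            for key, sets in fold_sets.items():
                mean_set = MetricSet.mean(sets)
                if mean_set.auc > best_auc:  # strict >: first config in order wins ties
                    best_auc, best_metrics, best_cfg = mean_set.auc, mean_set, (v.label, *key)
        per_repeat.append(best_metrics)
        best_configs.append(best_cfg)
    return ScenarioResult(
        method=method,
        arm="incorrect" if leak else "correct",
        per_repeat=per_repeat,
        best_configs=best_configs,
        audits=audits,
    )


def run_correct(table, method, grid=None, cv=None, variants=None) -> ScenarioResult:
    """Resampling applied inside the CV, to each training fold only."""
    return _run_scenario(table, method, grid or ModelGrid.reduced(), cv or CVScheme(), leak=False, variants=variants)


def run_incorrect(table, method, grid=None, cv=None, variants=None) -> ScenarioResult:
    """Resampling misapplied once to all data before the CV (the leakage
    scenario): folds are drawn from the resampled data."""
    return _run_scenario(table, method, grid or ModelGrid.reduced(), cv or CVScheme(), leak=True, variants=variants)


def compute_bias(dataset_id: str, correct: ScenarioResult, incorrect: ScenarioResult) -> list:
    """Pair the two arms repeat-by-repeat into BiasRecords.

    Sign convention: a positive AUC bias is inflation from leakage; a
    negative Brier bias is an apparent (spurious) calibration improvement.
    """
    if correct.method != incorrect.method:
        raise ValueError("arms ran different resampling methods")
    if len(correct.per_repeat) != len(incorrect.per_repeat):
        raise ValueError("arms ran different repeat counts")
    return [
        BiasRecord(dataset_id, correct.method, r, c, i)
        for r, (c, i) in enumerate(zip(correct.per_repeat, incorrect.per_repeat))
    ]


def summarize_bias(records) -> pd.DataFrame:
    """Mean bias per (dataset, resampler): one row per cell, the per-metric
    repeat-mean of (incorrect - correct) plus the mean metrics of each arm."""
    rows = []
    for rec in records:
        b = rec.bias
        rows.append(
            {
                "dataset_id": rec.dataset_id,
                "resampler": rec.resampler,
                "repeat": rec.repeat,
                **{f"bias_{k}": v for k, v in b.as_dict().items()},
                **{f"correct_{k}": v for k, v in rec.correct.as_dict().items()},
                **{f"incorrect_{k}": v for k, v in rec.incorrect.as_dict().items()},
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["dataset_id", "resampler"], sort=True)
        .mean(numeric_only=True)
        .drop(columns=["repeat"])
        .reset_index()
    )


def associate_with_balance(mean_biases, balances) -> AssociationResult:
    """OLS of mean bias on class balance across datasets (needs >= 3
    points): slope, intercept, Pearson r, two-sided slope t-test p-value."""
    y = np.asarray(mean_biases, dtype=float)
    x = np.asarray(balances, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("association needs >= 3 (balance, bias) points")
    res = stats.linregress(x, y)
    return AssociationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
    )
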