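"""Labeled tabular data: container, synthetic generators, preprocessing, CSV I/O.

The central container is :class:`LabeledTable`, a numeric feature matrix with
binary labels and per-row provenance.  Provenance distinguishes original
samples from synthetic ones created by oversampling, which is what makes the
leakage audits in the protocol module possible: a test fold is "clean" exactly
when every row in it is original.

Two generators are provided:

* :func:`generate_radiomics_like` emulates the statistical shape of tabular
  radiomics exports — many z-scorable features, heavy feature redundancy,
  a small informative subset, class imbalance, optional missing cells.
* :func:`generate_sim_data` draws two-dimensional points uniformly from
  [-1, 1]^2 with labels assigned independently of the coordinates, the
  null configuration used by the random-label simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ORIGINAL = "original"
SYNTHETIC = "synthetic"

__all__ = [
    "LabeledTable",
    "SyntheticSpec",
    "SimSpec",
    "generate_radiomics_like",
    "generate_sim_data",
    "preprocess",
    "compute_balance",
    "read_labeled_csv",
    "write_labeled_csv",
]


class InvalidSpecError(ValueError):
    """A generator spec violates its invariants."""


@dataclass(frozen=True)
class LabeledTable:
    """An n x d feature matrix with binary labels and row provenance.

    Parameters
    ----------
    features
        Real-valued matrix, shape (n, d).  May contain NaN before
        :func:`preprocess`.
    labels
        Length-n integer vector with values in {0, 1}.  By convention 1 is
        the positive (and, for generated data, minority) class.
    provenance
        Length-n vector of ``"original"`` / ``"synthetic"`` flags.
    parent_ids
        Length-n tuple; for synthetic rows, the input-table row indices the
        row was generated from (nonempty), for original rows the empty tuple.
    feature_names
        Optional column names, carried through CSV round trips.
    """

    features: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray = None  # type: ignore[assignment]
    parent_ids: tuple = ()
    feature_names: tuple = ()

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if y.shape != (X.shape[0],):
            raise ValueError("labels must be a length-n vector")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")
        prov = self.provenance
        if prov is None:
            prov = np.full(len(y), ORIGINAL, dtype=object)
        prov = np.asarray(prov, dtype=object)
        parents = self.parent_ids or tuple(() for _ in range(len(y)))
        parents = tuple(tuple(p) for p in parents)
        if len(parents) != len(y) or len(prov) != len(y):
            raise ValueError("provenance/parent_ids length mismatch")
        for flag, par in zip(prov, parents):
            if flag not in (ORIGINAL, SYNTHETIC):
                raise ValueError(f"unknown provenance flag {flag!r}")
            if (flag == SYNTHETIC) != (len(par) > 0):
                raise ValueError("parent_ids must be nonempty iff synthetic")
        names = tuple(self.feature_names) or tuple(
            f"f{j}" for j in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise ValueError("feature_names length mismatch")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "provenance", prov)
        object.__setattr__(self, "parent_ids", parents)
        object.__setattr__(self, "feature_names", names)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def synthetic_mask(self) -> np.ndarray:
        return self.provenance == SYNTHETIC

    def class_counts(self) -> dict:
        return {int(v): int(c) for v, c in zip(*np.unique(self.labels, return_counts=True))}

    def minority_label(self) -> int:
        counts = self.class_counts()
        if len(counts) < 2:
            raise ValueError("both classes must be present")
        # ties resolved toward label 1 (the positive-class convention)
        return 1 if counts.get(1, 0) <= counts.get(0, 0) else 0

    def subset(self, idx) -> "LabeledTable":
        """Row subset; provenance and parents travel with the rows.

        Parent ids still refer to the *parent table's* row numbering — keep
        subsets of resampled tables only for evaluation, not re-resampling.
        """
        idx = np.asarray(idx)
        return LabeledTable(
            self.features[idx],
            self.labels[idx],
            self.provenance[idx],
            tuple(self.parent_ids[i] for i in idx),
            self.feature_names,
        )

    def with_rows_appended(self, X_new, y_new, parents) -> "LabeledTable":
        """Append synthetic rows; existing rows are untouched (bit-identical)."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        y_new = np.asarray(y_new, dtype=int)
        return LabeledTable(
            np.vstack([self.features, X_new]),
            np.concatenate([self.labels, y_new]),
            np.concatenate([self.provenance, np.full(len(y_new), SYNTHETIC, dtype=object)]),
            self.parent_ids + tuple(tuple(p) for p in parents),
            self.feature_names,
        )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a radiomics-like table.

    ``effect_size`` is the class-mean shift of the informative features in SD
    units (before z-scoring); ``balance`` is majority/minority count ratio;
    ``correlation`` is the equicorrelation among nuisance features.
    """

    n_samples: int = 200
    n_features: int = 500
    n_informative: int = 10
    effect_size: float = 0.8
    balance: float = 2.0
    missing_rate: float = 0.0
    correlation: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.n_features < 1:
            raise InvalidSpecError("need n_samples >= 2 and n_features >= 1")
        if not (0 <= self.n_informative <= self.n_features):
            raise InvalidSpecError("n_informative must be in [0, n_features]")
        if self.effect_size < 0 or self.balance < 1:
            raise InvalidSpecError("effect_size >= 0 and balance >= 1 required")
        if not (0 <= self.missing_rate < 1) or not (0 <= self.correlation < 1):
            raise InvalidSpecError("missing_rate and correlation must be in [0, 1)")
        if self.minority_count < 2:
            raise InvalidSpecError(
                f"minority count {self.minority_count} < 2; "
                "increase n_samples or decrease balance"
            )

    @property
    def minority_count(self) -> int:
        return int(round(self.n_samples / (1 + self.balance)))

    @property
    def majority_count(self) -> int:
        return self.n_samples - self.minority_count


@dataclass(frozen=True)
class SimSpec:
    """Configuration of one random-label simulation point.

    ``B`` is the balance in percent: the positive class has round(N*B/100)
    samples against ``N`` negatives, so B=100 is balanced and B=20 is a
    1:5 imbalance.  The classifier is a deliberately overfitting-prone
    RBF-SVM (large C and gamma) so that memorized synthetic test points are
    rewarded.
    """

    B: float = 50.0
    N: int = 100
    n_repeats: int = 100
    test_fraction: float = 0.2
    smote_k: int = 5
    svm_C: float = 50.0
    svm_gamma: float = 500.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.B <= 100):
            raise InvalidSpecError("B must be in (0, 100]")
        if self.N < 2 or self.n_repeats < 1:
            raise InvalidSpecError("N >= 2 and n_repeats >= 1 required")
        if not (0 < self.test_fraction < 1):
            raise InvalidSpecError("test_fraction must be in (0, 1)")
        if self.positive_count < 2:
            raise InvalidSpecError("N*B/100 must round to at least 2 positives")
        if self.smote_k < 1 or self.svm_C <= 0 or self.svm_gamma <= 0:
            raise InvalidSpecError("smote_k, svm_C, svm_gamma must be positive")

    @property
    def positive_count(self) -> int:
        return int(round(self.N * self.B / 100.0))

    @property
    def imbalance(self) -> float:
        return 100.0 / self.B


def generate_radiomics_like(spec: SyntheticSpec) -> LabeledTable:
    """Generate a radiomics-like table with exact class counts.

    The minority (positive, label 1) class has round(n/(1+balance)) samples.
    The first ``n_informative`` columns get a mean shift of ``effect_size``
    SD in the positive class; the remaining columns are equicorrelated
    Gaussian noise independent of the label (one shared factor per dataset),
    mimicking the heavy feature redundancy of radiomic exports.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    n_min = spec.minority_count
    y = np.zeros(n, dtype=int)
    y[:n_min] = 1
    rng.shuffle(y)

    X = np.empty((n, d))
    k = spec.n_informative
    if k:
        X[:, :k] = rng.standard_normal((n, k)) + spec.effect_size * y[:, None]
    n_noise = d - k
    if n_noise:
        rho = spec.correlation
        shared = rng.standard_normal((n, 1))
        X[:, k:] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(
            (n, n_noise)
        )
    if spec.missing_rate > 0:
        mask = rng.random((n, d)) < spec.missing_rate
        X[mask] = np.nan
    return LabeledTable(X, y)


def generate_sim_data(B: float, N: int, seed: int) -> LabeledTable:
    """Draw the random-label 2-D dataset: N negatives plus round(N*B/100)
    positives, all coordinates i.i.d. uniform on [-1, 1], labels carrying no
    information about the coordinates by construction."""
    n_pos = int(round(N * B / 100.0))
    if n_pos < 2:
        raise InvalidSpecError("need at least 2 positive samples (N*B/100 >= 2)")
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, size=(N + n_pos, 2))
    y = np.concatenate([np.zeros(N, dtype=int), np.ones(n_pos, dtype=int)])
    return LabeledTable(X, y)


def preprocess(table: LabeledTable) -> LabeledTable:
    """Mean-impute missing cells, then z-score every column.

    Uses the population SD (divide by n); columns with zero spread map to
    all-zeros rather than erroring, since real radiomic exports routinely
    contain constant features.  Labels and provenance are unchanged.

    Note this runs on *all* data before any train/test split.  That is a
    deliberate replication of the upstream pipeline being studied (a known,
    mild form of leakage that affects both protocol arms identically); do
    not move it inside the cross-validation.
    """
    X = table.features.copy()
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [table.feature_names[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"column(s) entirely missing: {', '.join(bad)}")
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD (ddof=0)
    nonconst = sd > 0
    X[:, nonconst] = (X[:, nonconst] - mu[nonconst]) / sd[nonconst]
    X[:, ~nonconst] = 0.0
    return replace(table, features=X)


def compute_balance(table: LabeledTable) -> float:
    """Majority-class count divided by minority-class count (>= 1)."""
    counts = table.class_counts()
    if len(counts) < 2:
        raise ValueError("balance undefined: only one class present")
    c0, c1 = counts[0], counts[1]
    return max(c0, c1) / min(c0, c1)


def read_labeled_csv(path, label_column: str = "Target", positive_label=None) -> LabeledTable:
    """Read a LabeledTable from CSV (header row, numeric features, one label
    column; empty cells or "NA" are missing).  ``positive_label`` selects
    which raw label value maps to 1; by default values must already be 0/1.
    """
    df = pd.read_csv(path, na_values=["NA"])
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    raw = df[label_column]
    if positive_label is not None:
        y = (raw == positive_label).astype(int).to_numpy()
    else:
        y = raw.to_numpy()
    feats = df.drop(columns=[label_column])
    return LabeledTable(
        feats.to_numpy(dtype=float), y, feature_names=tuple(feats.columns)
    )


def write_labeled_csv(table: LabeledTable, path, label_column: str = "Target") -> None:
    """Write features + label column; provenance/parents are appended as two
    extra columns only when synthetic rows are present."""
    df = pd.DataFrame(table.features, columns=list(table.feature_names))
    df[label_column] = table.labels
    if table.synthetic_mask.any():
        df["provenance"] = table.provenance
        df["parent_ids"] = [";".join(map(str, p)) for p in table.parent_ids]
    df.to_csv(path, index=False)
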