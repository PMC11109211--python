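"""Class-rebalancing resamplers with synthetic-sample provenance.

All seven methods share one contract::

    resample(table, spec, seed) -> LabeledTable

Kept original rows are bit-identical to their inputs; every synthetic row is
flagged ``synthetic`` and records the input-table row indices it was
generated from.  That provenance is what the leakage audit downstream relies
on, so the resamplers never launder a synthetic row back to "original".

Methods
-------
- random undersampling, Tomek links (undersampling)
- random oversampling, SMOTE, polynomial-fit SMOTE, MWMOTE (oversampling)
- SMOTE + Tomek links (combined)

SMOTE follows Chawla et al. (2002): linear interpolation between a minority
point and one of its k nearest minority neighbors.  Tomek links (Tomek 1976)
removes the majority member of every cross-class mutual-nearest-neighbor
pair.  Polynomial-fit SMOTE (Gazzah & Amara 2008) interpolates along
geometric structures (star / bus / polynomial curve).  MWMOTE (Barua et al.
2014) weights hard-to-learn borderline minority samples and generates inside
hierarchical minority clusters; the original publication's default
hyperparameters are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from .datasets import LabeledTable

__all__ = [
    "ResamplerSpec",
    "METHODS",
    "resampler_variants",
    "resample",
    "random_oversample",
    "random_undersample",
    "smote",
    "tomek_links",
    "smote_tomek",
    "polyfit_smote",
    "mwmote",
]

#: canonical method names -> (display spelling, type tag)
METHODS = {
    "random_undersampling": ("Random undersampling", "undersampling"),
    "tomek_links": ("Tomek links", "undersampling"),
    "random_oversampling": ("Random oversampling", "oversampling"),
    "smote": ("SMOTE", "oversampling"),
    "polyfit_smote": ("Polynomial-fit SMOTE", "oversampling"),
    "mwmote": ("MWMOTE", "oversampling"),
    "smote_tomek": ("SMOTE + Tomek links", "combined"),
    "none": ("None", "identity"),
}

_ALIASES = {display.lower(): name for name, (display, _) in METHODS.items()}

_SMOTE_K_GRID = (3, 5, 7)
_TOPOLOGIES = ("star", "bus", "poly")


def canonical_method(name: str) -> str:
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    if key in METHODS:
        return key
    if name.strip().lower() in _ALIASES:
        return _ALIASES[name.strip().lower()]
    raise ValueError(
        f"unknown resampling method {name!r}; known methods: "
        + ", ".join(display for display, _ in METHODS.values())
    )


@dataclass(frozen=True)
class ResamplerSpec:
    """A method plus its hyperparameters.

    ``k`` applies to smote and smote_tomek (neighborhood size, default 5);
    ``topology`` applies to polyfit_smote only.
    """

    method: str
    k: int | None = None
    topology: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "method", canonical_method(self.method))
        if self.method in ("smote", "smote_tomek"):
            if self.k is None:
                object.__setattr__(self, "k", 5)
        elif self.k is not None:
            raise ValueError(f"k applies only to smote/smote_tomek, not {self.method}")
        if self.method == "polyfit_smote":
            if self.topology is None:
                object.__setattr__(self, "topology", "star")
            if self.topology not in _TOPOLOGIES:
                raise ValueError(f"topology must be one of {_TOPOLOGIES}")
        elif self.topology is not None:
            raise ValueError("topology applies only to polyfit_smote")

    @property
    def type_tag(self) -> str:
        return METHODS[self.method][1]

    @property
    def label(self) -> str:
        extra = ""
        if self.method in ("smote", "smote_tomek"):
            extra = f" (k={self.k})"
        elif self.method == "polyfit_smote":
            extra = f" ({self.topology})"
        return METHODS[self.method][0] + extra


def resampler_variants(method: str) -> list[ResamplerSpec]:
    """The hyperparameter grid of one method: k in {3,5,7} for the SMOTE
    family, the three topologies for polynomial-fit SMOTE, a single variant
    otherwise.  Best-model selection maximizes over these variants."""
    method = canonical_method(method)
    if method in ("smote", "smote_tomek"):
        return [ResamplerSpec(method, k=k) for k in _SMOTE_K_GRID]
    if method == "polyfit_smote":
        return [ResamplerSpec(method, topology=t) for t in _TOPOLOGIES]
    return [ResamplerSpec(method)]


def resample(table: LabeledTable, spec: ResamplerSpec | str, seed: int = 0) -> LabeledTable:
    """Dispatch to the requested method under one shared contract."""
    if isinstance(spec, str):
        spec = ResamplerSpec(spec)
    m = spec.method
    if m == "none":
        return table
    if m == "random_undersampling":
        return random_undersample(table, seed)
    if m == "tomek_links":
        return tomek_links(table)
    if m == "random_oversampling":
        return random_oversample(table, seed)
    if m == "smote":
        return smote(table, k=spec.k, seed=seed)
    if m == "smote_tomek":
        return smote_tomek(table, k=spec.k, seed=seed)
    if m == "polyfit_smote":
        return polyfit_smote(table, topology=spec.topology, seed=seed)
    if m == "mwmote":
        return mwmote(table, seed=seed)
    raise AssertionError(m)


# ---------------------------------------------------------------- helpers

def _class_split(table: LabeledTable):
    counts = table.class_counts()
    if len(counts) < 2:
        raise ValueError("resampling requires both classes to be present")
    min_label = table.minority_label()
    min_idx = np.flatnonzero(table.labels == min_label)
    maj_idx = np.flatnonzero(table.labels != min_label)
    return min_label, min_idx, maj_idx


def _pairwise(X, Y=None):
    return cdist(X, X if Y is None else Y)


def _nearest_neighbor(X) -> np.ndarray:
    """Index of each row's single nearest neighbor (ties -> lowest index)."""
    D = _pairwise(X)
    np.fill_diagonal(D, np.inf)
    return D.argmin(axis=1)  # argmin returns the first (lowest-index) minimum


def _knn_indices(X_query, X_ref, k, exclude_self=False) -> np.ndarray:
    """k nearest rows of X_ref per query row, ties broken by lowest index."""
    D = _pairwise(X_query, X_ref)
    if exclude_self:
        np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def _clamped_k(k: int, m: int, method: str) -> int:
    # k must stay below the minority count so every point has k neighbors
    if k >= m:
        warnings.warn(
            f"{method}: k={k} >= minority count {m}; clamping to {m - 1}",
            stacklevel=3,
        )
        return m - 1
    return k


def _even_counts(total: int, bins: int) -> np.ndarray:
    base, extra = divmod(total, bins)
    out = np.full(bins, base, dtype=int)
    out[:extra] += 1
    return out


# ---------------------------------------------------------------- methods

def random_oversample(table: LabeledTable, seed: int = 0) -> LabeledTable:
    """Duplicate minority rows (with replacement) until class counts match.

    Duplicates are flagged synthetic with the duplicated row as sole parent,
    so downstream leakage audits treat them like any generated sample.
    """
    min_label, min_idx, maj_idx = _class_split(table)
    need = len(maj_idx) - len(min_idx)
    if need == 0:
        return table
    rng = np.random.default_rng(seed)
    picks = rng.choice(min_idx, size=need, replace=True)
    return table.with_rows_appended(
        table.features[picks],
        np.full(need, min_label),
        [(int(p),) for p in picks],
    )


def random_undersample(table: LabeledTable, seed: int = 0) -> LabeledTable:
    """Subsample majority rows (without replacement) down to the minority
    count; never creates rows."""
    _, min_idx, maj_idx = _class_split(table)
    if len(maj_idx) == len(min_idx):
        return table
    rng = np.random.default_rng(seed)
    keep_maj = rng.choice(maj_idx, size=len(min_idx), replace=False)
    keep = np.sort(np.concatenate([min_idx, keep_maj]))
    return table.subset(keep)


def smote(table: LabeledTable, k: int = 5, seed: int = 0) -> LabeledTable:
    """SMOTE: x_new = x_i + t (x_nn - x_i) with t ~ U(0,1) and x_nn one of
    the k nearest minority neighbors of minority point x_i.

    Base points are cycled evenly over the minority class and the excess
    trimmed by a seeded permutation, so exactly enough samples are created
    to equalize the classes.  Parents recorded as {i, nn}.
    """
    min_label, min_idx, maj_idx = _class_split(table)
    m = len(min_idx)
    need = len(maj_idx) - m
    if need == 0:
        return table
    if m < 2:
        raise ValueError("SMOTE requires at least 2 minority samples")
    k = _clamped_k(k, m, "smote")
    rng = np.random.default_rng(seed)
    X_min = table.features[min_idx]
    nn = _knn_indices(X_min, X_min, k, exclude_self=True)  # (m, k) minority-local

    base_local = np.tile(np.arange(m), int(np.ceil(need / m)))
    base_local = rng.permutation(base_local)[:need]
    which_nn = rng.integers(0, k, size=need)
    t = rng.random(need)
    nn_local = nn[base_local, which_nn]
    X_new = X_min[base_local] + t[:, None] * (X_min[nn_local] - X_min[base_local])
    parents = [
        (int(min_idx[b]), int(min_idx[q])) for b, q in zip(base_local, nn_local)
    ]
    return table.with_rows_appended(X_new, np.full(need, min_label), parents)


def _tomek_pairs(table: LabeledTable) -> list[tuple[int, int]]:
    """All cross-class mutual-nearest-neighbor pairs (a < b)."""
    nn = _nearest_neighbor(table.features)
    y = table.labels
    pairs = []
    for a in range(table.n):
        b = int(nn[a])
        if a < b and nn[b] == a and y[a] != y[b]:
            pairs.append((a, b))
    return pairs


def tomek_links(table: LabeledTable) -> LabeledTable:
    """Remove the majority-class member of every Tomek link.

    Links are found on the input data in one pass (removals do not cascade).
    When the classes are exactly balanced the tie is resolved by removing
    the label-0 member — a documented, deterministic convention.
    """
    counts = {0: 0, 1: 0}
    counts.update(table.class_counts())
    if min(counts.values()) == 0:
        raise ValueError("Tomek links require both classes to be present")
    maj_label = 0 if counts[0] >= counts[1] else 1  # tie -> remove label 0
    drop = set()
    for a, b in _tomek_pairs(table):
        drop.add(a if table.labels[a] == maj_label else b)
    if not drop:
        return table
    keep = np.array([i for i in range(table.n) if i not in drop])
    return table.subset(keep)


def smote_tomek(table: LabeledTable, k: int = 5, seed: int = 0) -> LabeledTable:
    """SMOTE to balance, then Tomek-link cleaning of the balanced result."""
    return tomek_links(smote(table, k=k, seed=seed))


def polyfit_smote(table: LabeledTable, topology: str = "star", seed: int = 0) -> LabeledTable:
    """Polynomial-fit SMOTE: deterministic interpolation along a geometric
    template of the minority class.

    star
        evenly spaced points on the segments joining each minority point to
        the minority centroid.
    bus
        evenly spaced points on the segments joining consecutive minority
        points in dataset order.
    poly
        per-feature polynomial of degree min(5, m-1) fitted over the
        minority sample index 0..m-1, sampled at evenly spaced fractional
        indices.

    star and bus always emit at least one synthetic point per minority
    sample — even on balanced data — so these topologies can overshoot the
    balance slightly; that always-generate behavior is integral to the
    method and is the source of its balanced-data leakage bias.
    """
    if topology not in _TOPOLOGIES:
        raise ValueError(f"topology must be one of {_TOPOLOGIES}")
    min_label, min_idx, maj_idx = _class_split(table)
    m = len(min_idx)
    need = len(maj_idx) - m
    if m < 2 or (topology == "poly" and m < 3):
        raise ValueError(
            f"polyfit_smote ({topology}) requires at least "
            f"{3 if topology == 'poly' else 2} minority samples"
        )
    X_min = table.features[min_idx]

    if topology == "star":
        n_gen = max(need, m)
        centroid = X_min.mean(axis=0)
        counts = _even_counts(n_gen, m)
        rows, parents = [], []
        all_parents = tuple(int(i) for i in min_idx)
        for i, g in enumerate(counts):
            for j in range(1, g + 1):
                t = j / (g + 1)
                rows.append(X_min[i] + t * (centroid - X_min[i]))
                parents.append(all_parents)  # centroid involves every minority row
    elif topology == "bus":
        n_gen = max(need, m)
        counts = _even_counts(n_gen, m - 1)
        rows, parents = [], []
        for s, g in enumerate(counts):
            a, b = X_min[s], X_min[s + 1]
            for j in range(1, g + 1):
                t = j / (g + 1)
                rows.append(a + t * (b - a))
                parents.append((int(min_idx[s]), int(min_idx[s + 1])))
    else:  # poly
        if need == 0:
            return table
        deg = min(5, m - 1)
        idx = np.arange(m, dtype=float)
        ts = np.linspace(0.0, m - 1.0, need + 2)[1:-1]
        rows = np.empty((need, table.d))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            for f in range(table.d):
                coef = np.polyfit(idx, X_min[:, f], deg)
                rows[:, f] = np.polyval(coef, ts)
        parents = [tuple(int(i) for i in min_idx)] * need
        rows = list(rows)

    if not rows:
        return table
    return table.with_rows_appended(
        np.array(rows), np.full(len(rows), min_label), parents
    )


def mwmote(
    table: LabeledTable,
    seed: int = 0,
    k1: int = 5,
    k2: int = 3,
    k3: int | None = None,
    cf_th: float = 5.0,
    cmax: float = 2.0,
    cp: float = 3.0,
) -> LabeledTable:
    """Majority Weighted Minority Oversampling (MWMOTE).

    Steps, with the original publication's default hyperparameters:

    1. drop noisy minority samples — those whose ``k1`` nearest neighbors
       (over all samples) contain no minority sample;
    2. borderline majority set = union of the ``k2`` nearest majority
       neighbors of the filtered minority set; informative minority set =
       union of the ``k3`` (default ceil(m/2)) nearest minority neighbors of
       that majority set;
    3. each informative minority sample x gets a selection weight summing
       closeness x density factors over the borderline majority set;
    4. the filtered minority set is clustered by average-linkage
       agglomeration cut at ``cp`` x (mean minority nearest-neighbor
       distance);
    5. x_new = x + t (y - x), t ~ U(0,1), x drawn by selection weight and y
       uniform over x's cluster, until classes are equal.

    If the informative set comes out empty the weights fall back to uniform
    over the minority class (with a warning).
    """
    min_label, min_idx, maj_idx = _class_split(table)
    m = len(min_idx)
    need = len(maj_idx) - m
    if need == 0:
        return table
    if m < 2:
        raise ValueError("MWMOTE requires at least 2 minority samples")
    if k3 is None:
        k3 = int(np.ceil(m / 2))
    rng = np.random.default_rng(seed)
    X = table.features
    X_min, X_maj = X[min_idx], X[maj_idx]

    # (1) filter noisy minority samples
    k1_eff = min(k1, table.n - 1)
    nn_all = _knn_indices(X_min, X, k1_eff, exclude_self=False)
    is_min = np.isin(nn_all, min_idx)
    # a sample is its own neighbor; require another minority point among k1
    self_pos = nn_all == min_idx[:, None]
    has_min_neighbor = (is_min & ~self_pos).any(axis=1)
    filtered_local = np.flatnonzero(has_min_neighbor)  # indices into min_idx

    weights = None
    informative_local = np.arange(m)
    if len(filtered_local) > 0:
        # (2) borderline majority and informative minority sets
        k2_eff = min(k2, len(maj_idx))
        bmaj_local = np.unique(
            _knn_indices(X_min[filtered_local], X_maj, k2_eff)
        )  # indices into maj_idx
        k3_eff = min(k3, m)
        informative_local = np.unique(
            _knn_indices(X_maj[bmaj_local], X_min, k3_eff)
        )
        # (3) selection weights: closeness * density w.r.t. borderline majority
        D = _pairwise(X_maj[bmaj_local], X_min[informative_local]) / table.d
        with np.errstate(divide="ignore"):
            closeness = np.where(D > 0, 1.0 / D, np.inf)
        closeness = np.minimum(closeness, cf_th) / cf_th * cmax
        row_sum = closeness.sum(axis=1, keepdims=True)
        density = np.where(row_sum > 0, closeness / row_sum, 0.0)
        weights = (closeness * density).sum(axis=0)
        if weights.sum() <= 0:
            weights = None

    if weights is None:
        warnings.warn(
            "mwmote: empty/degenerate informative set; falling back to "
            "uniform selection weights over the minority class",
            stacklevel=2,
        )
        informative_local = np.arange(m)
        weights = np.ones(m)
        filtered_local = np.arange(m)
    probs = weights / weights.sum()

    # (4) cluster the filtered minority set
    cluster_of = {}  # minority-local index -> array of minority-local members
    if len(filtered_local) >= 2:
        Xf = X_min[filtered_local]
        Df = _pairwise(Xf)
        np.fill_diagonal(Df, np.inf)
        d_avg = Df.min(axis=1).mean()
        Z = linkage(Xf, method="average")
        labels = fcluster(Z, t=max(cp * d_avg, 1e-12), criterion="distance")
        for lab in np.unique(labels):
            members = filtered_local[labels == lab]
            for loc in members:
                cluster_of[int(loc)] = members
    elif len(filtered_local) == 1:
        cluster_of[int(filtered_local[0])] = filtered_local

    # (5) generate
    picks = rng.choice(len(informative_local), size=need, p=probs)
    t = rng.random(need)
    rows, parents = [], []
    for i, ti in zip(picks, t):
        x_loc = int(informative_local[i])
        members = cluster_of.get(x_loc, np.array([x_loc]))
        y_loc = int(members[rng.integers(len(members))])
        x, yv = X_min[x_loc], X_min[y_loc]
        rows.append(x + ti * (yv - x))
        parents.append((int(min_idx[x_loc]), int(min_idx[y_loc])))
    return table.with_rows_appended(
        np.array(rows), np.full(need, min_label), parents
    )
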