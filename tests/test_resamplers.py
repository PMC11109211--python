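"""Resampler contracts: balance, provenance, geometry, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvbias.datasets import LabeledTable
from cvbias.resamplers import (
    ResamplerSpec,
    mwmote,
    polyfit_smote,
    random_oversample,
    random_undersample,
    resample,
    resampler_variants,
    smote,
    smote_tomek,
    tomek_links,
)

from conftest import make_table

ALL_SPECS = [
    ResamplerSpec("random_undersampling"),
    ResamplerSpec("tomek_links"),
    ResamplerSpec("random_oversampling"),
    ResamplerSpec("smote", k=5),
    ResamplerSpec("polyfit_smote", topology="star"),
    ResamplerSpec("polyfit_smote", topology="bus"),
    ResamplerSpec("polyfit_smote", topology="poly"),
    ResamplerSpec("mwmote"),
    ResamplerSpec("smote_tomek", k=5),
]
OVERSAMPLERS = ["random_oversampling", "smote", "polyfit_smote", "mwmote"]


def _ids(spec):
    return spec.label


@pytest.mark.parametrize("spec", ALL_SPECS, ids=_ids)
class TestSharedContract:
    def test_kept_originals_bit_identical(self, imbalanced_table, spec):
        out = resample(imbalanced_table, spec, seed=0)
        orig_rows = {r.tobytes() for r in imbalanced_table.features}
        kept = out.features[~out.synthetic_mask]
        assert all(r.tobytes() in orig_rows for r in kept)

    def test_synthetic_rows_have_parents(self, imbalanced_table, spec):
        out = resample(imbalanced_table, spec, seed=0)
        for syn, parents in zip(out.synthetic_mask, out.parent_ids):
            assert syn == (len(parents) > 0)

    def test_deterministic_under_seed(self, imbalanced_table, spec):
        a = resample(imbalanced_table, spec, seed=123)
        b = resample(imbalanced_table, spec, seed=123)
        np.testing.assert_array_equal(a.features, b.features)
        assert (a.labels == b.labels).all()

    def test_single_class_rejected(self, spec):
        t = make_table(np.random.default_rng(0).normal(size=(10, 3)), [1] * 10)
        with pytest.raises(ValueError):
            resample(t, spec, seed=0)

    def test_provenance_completeness(self, imbalanced_table, spec):
        out = resample(imbalanced_table, spec, seed=0)
        n_kept = sum(~out.synthetic_mask)
        assert int(out.synthetic_mask.sum()) == out.n - n_kept
        assert n_kept <= imbalanced_table.n


@pytest.mark.parametrize("method", OVERSAMPLERS)
def test_oversamplers_equalize_classes_exactly(imbalanced_table, method):
    # 80/20 input: needed (60) exceeds the minority count (20), so even the
    # star/bus always-generate floor coincides with exact equalization
    for spec in resampler_variants(method):
        out = resample(imbalanced_table, spec, seed=1)
        counts = out.class_counts()
        assert counts[0] == counts[1] == 80
        assert int(out.synthetic_mask.sum()) == 60
        assert out.n == imbalanced_table.n + 60  # never deletes rows


@pytest.mark.parametrize("method", ["random_undersampling", "tomek_links"])
def test_undersamplers_never_synthesize(imbalanced_table, method):
    out = resample(imbalanced_table, method, seed=1)
    assert not out.synthetic_mask.any()
    assert out.n <= imbalanced_table.n


class TestRandomOverUnder:
    def test_oversample_duplicates_equal_some_minority_row(self, imbalanced_table):
        out = random_oversample(imbalanced_table, seed=2)
        minority_rows = {r.tobytes() for r in imbalanced_table.features[imbalanced_table.labels == 1]}
        for i in np.flatnonzero(out.synthetic_mask):
            assert out.features[i].tobytes() in minority_rows
            (parent,) = out.parent_ids[i]
            np.testing.assert_array_equal(out.features[i], imbalanced_table.features[parent])

    def test_balanced_input_returned_unchanged(self, balanced_table):
        assert random_oversample(balanced_table, seed=0) is balanced_table
        assert random_undersample(balanced_table, seed=0) is balanced_table

    def test_undersample_keeps_subset_of_majority(self, imbalanced_table):
        out = random_undersample(imbalanced_table, seed=3)
        assert out.class_counts() == {0: 20, 1: 20}
        orig = {r.tobytes() for r in imbalanced_table.features}
        assert all(r.tobytes() in orig for r in out.features)


class TestSmoteGeometry:
    def test_synthetic_on_segment_between_parents(self, imbalanced_table):
        out = smote(imbalanced_table, k=5, seed=4)
        for i in np.flatnonzero(out.synthetic_mask):
            a, b = (imbalanced_table.features[p] for p in out.parent_ids[i])
            z = out.features[i]
            # z = a + t (b - a) for a single t in [0, 1], across all coordinates
            seg = b - a
            denom = float(seg @ seg)
            t = float((z - a) @ seg) / denom if denom > 0 else 0.0
            assert -1e-8 <= t <= 1 + 1e-8
            np.testing.assert_allclose(z, a + t * seg, atol=1e-8)

    def test_identical_minority_points_degenerate(self):
        X = np.vstack([np.zeros((3, 2)) + 7.0, np.random.default_rng(1).normal(size=(9, 2))])
        t = make_table(X, [1] * 3 + [0] * 9)
        out = smote(t, k=3, seed=0)
        syn = out.features[out.synthetic_mask]
        np.testing.assert_allclose(syn, 7.0)

    def test_k_clamped_with_warning(self):
        X = np.vstack([[[0, 0]], [[1, 1]], np.random.default_rng(2).normal(size=(8, 2))])
        t = make_table(X, [1, 1] + [0] * 8)
        with pytest.warns(UserWarning, match="clamping"):
            out = smote(t, k=5, seed=0)
        assert out.class_counts() == {0: 8, 1: 8}

    def test_too_few_minority_rejected(self):
        t = make_table(np.random.default_rng(3).normal(size=(9, 2)), [1] + [0] * 8)
        with pytest.raises(ValueError):
            smote(t, k=5, seed=0)


def _brute_force_tomek_pairs(X, y):
    """Independent oracle: enumerate all cross-class mutual-NN pairs."""
    n = len(y)
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    np.fill_diagonal(D, np.inf)
    pairs = []
    for a in range(n):
        for b in range(a + 1, n):
            if y[a] != y[b] and D[a].argmin() == b and D[b].argmin() == a:
                pairs.append((a, b))
    return pairs


class TestTomekLinks:
    def test_one_dimensional_toy(self):
        # majority (0) at {0.0, 0.9}, minority (1) at {1.0}: (0.9, 1.0) is a
        # cross-class mutual-NN pair; the majority member 0.9 is removed
        t = make_table([[0.0], [0.9], [1.0]], [0, 0, 1])
        out = tomek_links(t)
        assert sorted(out.features[:, 0].tolist()) == [0.0, 1.0]

    def test_well_separated_clusters_untouched(self):
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(10, 0.1, (5, 2))])
        t = make_table(X, [0] * 10 + [1] * 5)
        assert tomek_links(t).n == 15

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        X = rng.normal(size=(n, 2))
        y = np.array([0] * (n - n // 3) + [1] * (n // 3))
        t = make_table(X, y)
        counts = t.class_counts()
        maj = 0 if counts[0] >= counts[1] else 1
        drop = {a if y[a] == maj else b for a, b in _brute_force_tomek_pairs(X, y)}
        expected = np.delete(np.arange(n), sorted(drop))
        out = tomek_links(t)
        np.testing.assert_array_equal(out.features, X[expected])

    def test_balanced_tie_removes_label_zero_member(self):
        t = make_table([[0.0], [0.1], [5.0], [9.0]], [0, 1, 1, 0])
        out = tomek_links(t)  # (0.0, 0.1) is the only link; classes tied 2:2
        assert 0.0 not in out.features[:, 0]
        assert 0.1 in out.features[:, 0]


class TestSmoteTomek:
    def test_no_links_after_smote_identical_to_smote(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.2, (12, 2)), rng.normal(8, 0.2, (4, 2))])
        t = make_table(X, [0] * 12 + [1] * 4)
        a, b = smote_tomek(t, k=3, seed=7), smote(t, k=3, seed=7)
        np.testing.assert_array_equal(a.features, b.features)

    def test_imbalanced_input_runs_and_stays_near_balanced(self, imbalanced_table):
        out = smote_tomek(imbalanced_table, k=5, seed=8)
        counts = out.class_counts()
        removed = 160 - out.n
        assert removed >= 0 and abs(counts[0] - counts[1]) <= removed


class TestPolyfitSmote:
    def test_star_points_lie_on_spokes(self):
        # two minority points at (-1,0), (1,0): centroid (0,0); every
        # synthetic point sits on the x-axis within [-1, 1]
        rng = np.random.default_rng(9)
        X = np.vstack([[[-1.0, 0.0]], [[1.0, 0.0]], rng.normal(5, 1, (8, 2))])
        t = make_table(X, [1, 1] + [0] * 8)
        out = polyfit_smote(t, topology="star", seed=0)
        syn = out.features[out.synthetic_mask]
        np.testing.assert_allclose(syn[:, 1], 0.0, atol=1e-12)
        assert (np.abs(syn[:, 0]) <= 1).all()

    def test_star_generates_even_on_balanced_data(self, balanced_table):
        for topology in ("star", "bus"):
            out = polyfit_smote(balanced_table, topology=topology, seed=0)
            assert out.n > balanced_table.n
            assert out.synthetic_mask.sum() >= (balanced_table.labels == 1).sum()

    def test_bus_collinear_minority_stays_collinear(self):
        X = np.vstack([[[i, 2.0 * i] for i in range(4)], np.random.default_rng(10).normal(9, 1, (12, 2))])
        t = make_table(X, [1] * 4 + [0] * 12)
        out = polyfit_smote(t, topology="bus", seed=0)
        syn = out.features[out.synthetic_mask]
        np.testing.assert_allclose(syn[:, 1], 2.0 * syn[:, 0], atol=1e-10)

    def test_poly_needs_three_minority(self):
        t = make_table(np.random.default_rng(11).normal(size=(10, 2)), [1, 1] + [0] * 8)
        with pytest.raises(ValueError):
            polyfit_smote(t, topology="poly", seed=0)


class TestMwmote:
    def test_counts_and_parent_geometry(self, imbalanced_table):
        out = mwmote(imbalanced_table, seed=12)
        assert out.class_counts() == {0: 80, 1: 80}
        for i in np.flatnonzero(out.synthetic_mask):
            a, b = (imbalanced_table.features[p] for p in out.parent_ids[i])
            z, seg = out.features[i], b - a
            denom = float(seg @ seg)
            t = float((z - a) @ seg) / denom if denom > 0 else 0.0
            assert -1e-8 <= t <= 1 + 1e-8
            np.testing.assert_allclose(z, a + t * seg, atol=1e-8)

    def test_tight_minority_cluster_keeps_hull(self):
        rng = np.random.default_rng(13)
        minority = rng.normal(0, 0.05, (8, 2))
        majority = rng.normal(4, 0.5, (24, 2))
        t = make_table(np.vstack([minority, majority]), [1] * 8 + [0] * 24)
        out = mwmote(t, seed=14)
        syn = out.features[out.synthetic_mask]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert (syn >= lo - 1e-9).all() and (syn <= hi + 1e-9).all()

    def test_isolated_minority_falls_back_with_warning(self):
        # each minority point's k1-neighborhood is all-majority -> noisy set
        # filter empties and uniform weights take over
        rng = np.random.default_rng(15)
        minority = np.array([[0.0, 0.0], [50.0, 50.0]])
        majority = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(50, 0.5, (10, 2))])
        t = make_table(np.vstack([minority, majority]), [1] * 2 + [0] * 20)
        with pytest.warns(UserWarning, match="uniform"):
            out = mwmote(t, seed=16)
        assert out.class_counts() == {0: 20, 1: 20}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n_min=st.integers(3, 8),
    n_maj=st.integers(8, 20),
    d=st.integers(1, 4),
    seed=st.integers(0, 2**16),
)
def test_smote_property_balance_and_geometry(n_min, n_maj, d, seed):
    """For any small table: SMOTE equalizes counts exactly and every
    synthetic point is a convex combination of its recorded parents."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_min + n_maj, d))
    t = make_table(X, [1] * n_min + [0] * n_maj)
    out = smote(t, k=min(3, n_min - 1), seed=seed)
    counts = out.class_counts()
    assert counts[0] == counts[1] == n_maj
    for i in np.flatnonzero(out.synthetic_mask):
        a, b = (t.features[p] for p in out.parent_ids[i])
        z, seg = out.features[i], b - a
        denom = float(seg @ seg)
        tt = float((z - a) @ seg) / denom if denom > 0 else 0.0
        assert -1e-8 <= tt <= 1 + 1e-8
        np.testing.assert_allclose(z, a + tt * seg, atol=1e-8)
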