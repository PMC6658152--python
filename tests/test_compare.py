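"""Histograms, Jensen-Shannon divergence, IsoMap embedding, group tests."""

import numpy as np
import pytest
from scipy import stats

from fundusgraph.compare import (
    DivergenceMatrix,
    HistogramSet,
    common_bin_edges,
    divergence_matrix,
    group_separation,
    isomap_2d,
    js_divergence,
    to_histogram,
    ttest2,
)


class TestBinning:
    def test_uniform_pooled_samples(self, rng):
        samples = [rng.uniform(0, 10, 4000) for _ in range(5)]
        edges = common_bin_edges(samples, n_bins=10)
        assert len(edges) == 11
        assert np.allclose(edges, np.linspace(edges[0], edges[-1], 11))
        assert edges[0] == pytest.approx(0.0, abs=0.1)
        assert edges[-1] == pytest.approx(10.0, abs=0.1)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            common_bin_edges([[5.0, 5.0], [5.0]], n_bins=8)

    def test_all_samples_inside_after_clipping(self, rng):
        samples = [rng.normal(size=500) for _ in range(3)]
        edges = common_bin_edges(samples, n_bins=16)
        for s in samples:
            h = to_histogram(s, edges)
            assert h.sum() == pytest.approx(1.0, abs=1e-9)

    def test_histogram_examples(self):
        edges = np.array([0.0, 1.0, 2.0])
        assert to_histogram([0.5, 0.6, 0.2], edges).tolist() == [1.0, 0.0]
        assert to_histogram([0.5, 0.5, 1.5, 1.5], edges).tolist() == [0.5, 0.5]

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            to_histogram([], np.array([0.0, 1.0]))


class TestJsDivergence:
    def test_identical_is_zero(self):
        assert js_divergence([0.25, 0.75], [0.25, 0.75]) == 0.0

    def test_disjoint_supports_reach_ln2(self):
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(np.log(2), abs=1e-12)

    def test_half_vs_delta(self):
        # direct evaluation: H((0.75,0.25)) - H((0.5,0.5))/2 = 0.21576...
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25)) - 0.5 * np.log(2)
        assert js_divergence([0.5, 0.5], [1, 0]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.2158, abs=1e-4)

    def test_not_probability_rejected(self):
        with pytest.raises(ValueError):
            js_divergence([0.5, 0.4], [0.5, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_bounds_and_identity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(16))
        q = rng.dirichlet(np.ones(16))
        d = js_divergence(p, q)
        assert d == pytest.approx(js_divergence(q, p), abs=1e-14)
        assert 0.0 < d <= np.log(2)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.floats(0.01, 10.0), min_size=2, max_size=24),
        st.lists(st.floats(0.01, 10.0), min_size=2, max_size=24),
    )
    def test_js_divergence_properties_hypothesis(wa, wb):
        """JS is symmetric, bounded by ln 2, and zero only for equal inputs."""
        n = min(len(wa), len(wb))
        p = np.asarray(wa[:n]) / np.sum(wa[:n])
        q = np.asarray(wb[:n]) / np.sum(wb[:n])
        d = js_divergence(p, q)
        assert 0.0 <= d <= np.log(2) + 1e-12
        assert d == pytest.approx(js_divergence(q, p), abs=1e-13)
        if np.allclose(p, q, atol=1e-15):
            assert d <= 1e-12

except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


class TestDivergenceMatrix:
    def _hset(self, probs):
        return HistogramSet(edges=np.arange(probs.shape[1] + 1.0), probabilities=probs,
                            ids=list(range(len(probs))))

    def test_identical_histograms_zero_matrix(self):
        probs = np.tile([0.2, 0.3, 0.5], (3, 1))
        m = divergence_matrix(self._hset(probs))
        assert np.allclose(m.values, 0.0)

    def test_symmetric_zero_diagonal_consistent(self, rng):
        probs = rng.dirichlet(np.ones(8), size=5)
        m = divergence_matrix(self._hset(probs))
        assert np.array_equal(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)
        assert m.values[1, 3] == pytest.approx(js_divergence(probs[1], probs[3]))

    def test_too_few_images_rejected(self, rng):
        with pytest.raises(ValueError):
            divergence_matrix(self._hset(rng.dirichlet(np.ones(4), size=2)))


class TestIsomap:
    def test_collinear_points_recovered(self):
        x = np.arange(10.0)
        d = np.abs(x[:, None] - x[None, :])
        emb = isomap_2d(DivergenceMatrix(d, list(range(10))), k_neighbors=3)
        de = np.abs(emb.coords[:, 0][:, None] - emb.coords[:, 0][None, :])
        assert np.abs(de - d).max() < 1e-6

    def test_three_equidistant_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        emb = isomap_2d(DivergenceMatrix(d, [0, 1, 2]), k_neighbors=2)
        pd = np.hypot(*(emb.coords[:, None, :] - emb.coords[None, :, :]).transpose(2, 0, 1))
        off = pd[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0], atol=1e-6)

    def test_duplicate_images_embed_identically(self, rng):
        pts = rng.random((6, 3))
        pts[3] = pts[0]  # twin
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = isomap_2d(DivergenceMatrix(d, list(range(6))), k_neighbors=3)
        assert np.allclose(emb.coords[0], emb.coords[3], atol=1e-9)

    def test_full_knn_equals_classical_mds(self, rng):
        """With k = N-1 the geodesics are the input distances, so the
        embedding must coincide with classical MDS of the matrix itself."""
        pts = rng.random((12, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = isomap_2d(DivergenceMatrix(d, list(range(12))), k_neighbors=11)
        # independent classical MDS oracle
        n = len(d)
        j = np.eye(n) - 1.0 / n
        b = -0.5 * j @ (d**2) @ j
        vals, vecs = np.linalg.eigh(b)
        idx = np.argsort(vals)[::-1][:2]
        oracle = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))
        pd_emb = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=-1)
        pd_oracle = np.linalg.norm(oracle[:, None] - oracle[None, :], axis=-1)
        assert np.abs(pd_emb - pd_oracle).max() < 1e-8

    def test_matches_sklearn_isomap(self, rng):
        """Cross-check against the reference IsoMap on a precomputed matrix."""
        sklearn_manifold = pytest.importorskip("sklearn.manifold")
        pts = rng.random((15, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = isomap_2d(DivergenceMatrix(d, list(range(15))), k_neighbors=5)
        ref = sklearn_manifold.Isomap(
            n_neighbors=5, n_components=2, metric="precomputed"
        ).fit_transform(d)
        pd_emb = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=-1)
        pd_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        assert np.abs(pd_emb - pd_ref).max() < 1e-6

    def test_disconnected_knn_auto_increments_k(self):
        # two tight clusters far apart: k=1 cannot connect them
        d = np.array(
            [
                [0, 1, 9, 9.5],
                [1, 0, 9.5, 9],
                [9, 9.5, 0, 1],
                [9.5, 9, 1, 0],
            ],
            dtype=float,
        )
        with pytest.warns(UserWarning, match="increased k"):
            emb = isomap_2d(DivergenceMatrix(d, [0, 1, 2, 3]), k_neighbors=1)
        assert emb.k_used > 1


class TestTtest2:
    def test_identical_samples(self):
        gt = ttest2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert gt.t == 0.0 and gt.p == 1.0

    def test_against_hand_computed_pooled_formula(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([2.0, 3, 4, 5])
        gt = ttest2(a, b)
        df = 6
        sp2 = ((3 * a.var(ddof=1)) + (3 * b.var(ddof=1))) / df
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (0.25 + 0.25))
        p_expected = 2 * stats.t.sf(abs(t_expected), df)
        assert gt.t == pytest.approx(t_expected, abs=1e-12)
        assert gt.p == pytest.approx(p_expected, abs=1e-12)

    def test_group_swap_flips_sign(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        g1, g2 = ttest2(a, b), ttest2(b, a)
        assert g1.t == pytest.approx(-g2.t)
        assert g1.p == pytest.approx(g2.p)

    def test_zero_variance_unequal_means(self):
        gt = ttest2([1.0, 1.0], [2.0, 2.0])
        assert gt.p == 0.0 and "zero variance" in gt.note

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            ttest2([1.0], [1.0, 2.0])


class TestGroupSeparation:
    def test_separated_groups_reject(self, rng):
        x0 = rng.normal([-1.5, 0], 0.5, size=(15, 2))
        x1 = rng.normal([+1.5, 0], 0.5, size=(15, 2))
        gt = group_separation(np.vstack([x0, x1]), np.array([0] * 15 + [1] * 15))
        assert gt.p < 1e-6

    def test_rotation_invariance(self, rng):
        pts = rng.normal(size=(24, 2))
        pts[12:, 0] += 1.0
        labels = np.array([0] * 12 + [1] * 12)
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        p0 = group_separation(pts, labels).p
        p1 = group_separation(pts @ rot.T, labels).p
        assert p0 == pytest.approx(p1, rel=1e-9)

    def test_null_p_values_uniform(self, rng):
        """Identical groups: the calibrated p must be uniform (the naive
        projected-t p is biased low, which is why it is not the default)."""
        ps, naive = [], []
        for _ in range(200):
            x = rng.standard_normal((16, 2))
            labels = np.array([0] * 8 + [1] * 8)
            gt = group_separation(x, labels)
            ps.append(gt.p)
            naive.append(gt.p_projected)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
        assert stats.kstest(naive, "uniform").pvalue < 0.01  # bias is real

    def test_first_coordinate_mode(self, rng):
        x = rng.standard_normal((20, 2))
        x[10:, 0] += 3.0
        labels = np.array([0] * 10 + [1] * 10)
        gt = group_separation(x, labels, use_first_coordinate=True)
        oracle = ttest2(x[:10, 0], x[10:, 0])
        assert gt.t == pytest.approx(oracle.t)
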