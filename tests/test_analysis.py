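"""Variance-separability statistics: oracles, invariants, model object."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comascope.analysis import (
    EmbeddingVarianceModel,
    brown_forsythe,
    cluster_center,
    distances_to_center,
    dunn_posthoc,
    group_variances,
    pca_view,
    pearson_gcs,
)


class TestClusterCenter:
    def test_single_point_is_its_own_center(self):
        p = np.arange(32.0)[None]
        np.testing.assert_array_equal(cluster_center(p), p[0])

    def test_midpoint_of_two_points(self):
        pts = np.vstack([np.zeros(32), np.full(32, 2.0)])
        np.testing.assert_array_equal(cluster_center(pts), np.ones(32))

    def test_mean_minimizes_sum_of_squared_distances(self, rng):
        pts = rng.standard_normal((40, 8))
        center = cluster_center(pts)
        best = (distances_to_center(pts, center) ** 2).sum()
        for _ in range(100):
            candidate = center + rng.standard_normal(8) * 0.5
            assert (distances_to_center(pts, candidate) ** 2).sum() >= best

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cluster_center(np.empty((0, 32)))


class TestDistances:
    def test_zero_for_point_at_center(self):
        c = np.ones(5)
        assert distances_to_center(c[None], c)[0] == 0.0

    def test_unit_offset(self):
        c = np.zeros(5)
        p = np.zeros(5)
        p[2] = 1.0
        assert distances_to_center(p[None], c)[0] == pytest.approx(1.0)

    def test_rotation_invariance(self, rng):
        """Euclidean distances are invariant under a common rotation."""
        pts = rng.standard_normal((30, 8))
        center = pts.mean(axis=0)
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        d0 = distances_to_center(pts, center)
        d1 = distances_to_center(pts @ q, center @ q)
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            distances_to_center(np.zeros((3, 4)), np.zeros(5))


class TestGroupVariances:
    def test_constant_group_has_zero_variance(self):
        t = group_variances(np.array([1.0, 1.0, 1.0]), np.array([7, 7, 7]))
        assert t.loc[0, "variance"] == 0.0

    def test_sample_variance_divisor_n_minus_1(self):
        t = group_variances(np.array([0.0, 2.0]), np.array([5, 5]))
        assert t.loc[0, "variance"] == pytest.approx(2.0)

    def test_counts_conserved_and_small_groups_flagged(self, rng):
        d = rng.standard_normal(20)
        labels = np.array([5] * 10 + [8] * 9 + [11])
        t = group_variances(d, labels)
        assert t["n_ex"].sum() == 20
        singleton = t[t.gcs_value == 11].iloc[0]
        assert singleton["degenerate"] and np.isnan(singleton["variance"])


class TestBrownForsythe:
    def test_identical_groups_give_zero_statistic(self):
        f, p = brown_forsythe([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """Transformed groups {1,1,0} and {2,2,0} give F = 0.8."""
        f, p = brown_forsythe([np.array([1.0, 3, 2]), np.array([0.0, 4, 2])])
        assert f == pytest.approx(0.8, abs=1e-12)
        assert p == pytest.approx(float(stats.f.sf(0.8, 1, 4)))

    def test_matches_independent_levene_on_random_data(self, rng):
        """Identity with scipy's mean-centered Levene over 50 datasets."""
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = [rng.standard_normal(int(rng.integers(3, 12))) * rng.uniform(0.5, 3) for _ in range(k)]
            f_ours, p_ours = brown_forsythe(groups)
            f_ref, p_ref = stats.levene(*groups, center="mean")
            assert f_ours == pytest.approx(f_ref, rel=1e-10)
            assert p_ours == pytest.approx(p_ref, rel=1e-10)

    def test_median_center_matches_classical_brown_forsythe(self, rng):
        groups = [rng.standard_normal(15), rng.standard_normal(12) * 2]
        f_ours, p_ours = brown_forsythe(groups, center="median")
        f_ref, p_ref = stats.levene(*groups, center="median")
        assert f_ours == pytest.approx(f_ref, rel=1e-10)

    def test_transform_mean_equals_mean_absolute_deviation(self, rng):
        from comascope.analysis import _transform

        g = rng.standard_normal(50)
        (z,) = _transform([g], "mean")
        assert z.mean() == pytest.approx(np.abs(g - g.mean()).mean())

    def test_degenerate_constant_groups(self):
        f, p = brown_forsythe([np.array([3.0, 3.0]), np.array([5.0, 5.0])])
        assert (f, p) == (0.0, 1.0)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            brown_forsythe([np.array([1.0]), np.array([1.0, 2.0])])


class TestDunnPosthoc:
    def test_identical_groups_maximal_p(self):
        g = np.array([1.0, 2, 3])
        pmat = dunn_posthoc([g, g.copy()])
        assert pmat[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        groups = [rng.standard_normal(10) * s for s in (1, 3, 9)]
        pmat = dunn_posthoc(groups)
        np.testing.assert_array_equal(pmat, pmat.T)
        np.testing.assert_array_equal(np.diag(pmat), np.ones(3))
        assert np.all((pmat >= 0) & (pmat <= 1))

    def test_power_on_extreme_spread_difference(self):
        """sd 1 vs sd 100 (n=50): detected at p < 0.001 almost always."""
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            pmat = dunn_posthoc([r.standard_normal(50), r.standard_normal(50) * 100])
            hits += pmat[0, 1] < 0.001
        assert hits >= 95

    def test_holm_adjustment_monotone(self, rng):
        groups = [rng.standard_normal(20) * s for s in (1, 2, 6)]
        raw = dunn_posthoc(groups)
        holm = dunn_posthoc(groups, adjust="holm")
        off = ~np.eye(3, dtype=bool)
        assert np.all(holm[off] >= raw[off] - 1e-15)


class TestPCAView:
    def test_centered_2d_input_recovered_up_to_rotation(self, rng):
        pts = rng.standard_normal((50, 2)) @ np.diag([3.0, 1.0])
        pts -= pts.mean(axis=0)
        coords, fig = pca_view(pts)
        d_orig = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d_proj = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        np.testing.assert_allclose(d_proj, d_orig, atol=1e-8)

    def test_projected_variance_bounded_by_total(self, rng):
        pts = rng.standard_normal((40, 10))
        coords, _ = pca_view(pts)
        assert coords.var(axis=0).sum() <= pts.var(axis=0).sum() + 1e-9

    def test_two_separated_clusters_remain_separated(self, rng):
        """Headset clusters far apart in 32-d stay apart in the plane."""
        from sklearn.metrics import silhouette_score

        a = rng.standard_normal((60, 32))
        b = rng.standard_normal((60, 32)) + 8.0
        coords, _ = pca_view(np.vstack([a, b]))
        labels = np.array([0] * 60 + [1] * 60)
        assert silhouette_score(coords, labels) > 0.5

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_view(rng.standard_normal((2, 5)))


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_gcs(2 * x + 1, x) == pytest.approx(1.0)
        assert pearson_gcs(-x, x) == pytest.approx(-1.0)

    def test_matches_definitional_formula(self, rng):
        x = rng.standard_normal(50)
        y = 0.3 * x + rng.standard_normal(50)
        r = pearson_gcs(y, x)
        brute = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
        assert r == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_gcs(np.ones(5), np.arange(5.0))


class TestVarianceModel:
    @staticmethod
    def _frame(rng, spread_by_gcs):
        rows = []
        for gcs, (spread, n) in spread_by_gcs.items():
            z = rng.standard_normal((n, 6)) * spread
            for i in range(n):
                rows.append(
                    {"participant_id": f"P{gcs}", "headset": 5, "gcs_sum": gcs,
                     **{f"e{j + 1}": z[i, j] for j in range(6)}}
                )
        return pd.DataFrame(rows)

    def test_fit_detects_planted_variance_heterogeneity(self, rng):
        frame = self._frame(rng, {5: (1.0, 40), 8: (1.0, 40), 11: (6.0, 40)})
        results = EmbeddingVarianceModel.from_frame(frame).fit(components=("sum",))
        t = results.tests[(5, "sum")]
        assert t.bf_p < 0.001
        table = results.variance_table.set_index("gcs_value")
        assert table.loc[11, "variance"] > table.loc[5, "variance"]
        assert t.pairwise_p.loc[5, 11] < 0.01
        assert "Brown-Forsythe" in results.summary()

    def test_fit_on_homogeneous_groups_usually_accepts(self, rng):
        frame = self._frame(rng, {5: (1.0, 40), 8: (1.0, 40), 11: (1.0, 40)})
        results = EmbeddingVarianceModel.from_frame(frame).fit(components=("sum",))
        assert results.tests[(5, "sum")].bf_p > 0.01

    def test_summary_flags_insignificant_cells(self, rng):
        frame = self._frame(rng, {5: (1.0, 30), 8: (1.0, 30)})
        results = EmbeddingVarianceModel.from_frame(frame).fit(components=("sum",))
        assert "(ns)" in results.summary()

    def test_labels_must_align(self, rng):
        with pytest.raises(ValueError, match="align"):
            EmbeddingVarianceModel(rng.standard_normal((5, 3)), pd.DataFrame({"headset": [5]}))
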