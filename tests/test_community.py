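import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova

from teaterroir import (
    DistanceMatrix,
    bray_curtis,
    dbrda_pair_test,
    dispersion_test,
    pcoa,
    permanova_pair_test,
    permanova_pseudo_r2,
    procrustes_m2,
    procrustes_pair_test,
)
from teaterroir.community import _dispersion_f
from teaterroir.tables import MatchedDesign

from conftest import toy_table


def _euclid_dm(x, ids=None):
    ids = ids or [f"s{i}" for i in range(len(x))]
    return DistanceMatrix(tuple(ids), squareform(pdist(np.asarray(x, float))), "euclidean")


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = toy_table([[3, 3], [1, 1]], ["a", "b"], ["s1", "s2"], kind="genus_counts")
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = toy_table([[3, 0], [0, 9]], ["a", "b"], ["s1", "s2"], kind="genus_counts")
        assert bray_curtis(t).values[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        t = toy_table([[6, 2], [4, 0], [0, 8]], ["a", "b", "c"], ["s1", "s2"],
                      kind="genus_counts")
        assert bray_curtis(t).values[0, 1] == pytest.approx(0.8)

    def test_scale_stability_after_relative_abundance(self, cohort):
        t = cohort.bacteria
        scaled = t.data.copy()
        scaled.iloc[:, 0] *= 10
        t2 = toy_table(scaled.to_numpy(), t.feature_ids, t.sample_ids, "genus_counts")
        d1 = bray_curtis(t.relative_abundance())
        d2 = bray_curtis(t2.relative_abundance())
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_all_zero_sample_error(self):
        t = toy_table([[0, 1], [0, 2]], ["a", "b"], ["dead", "s2"], kind="genus_counts")
        with pytest.raises(ValueError, match="dead"):
            bray_curtis(t)


class TestPcoa:
    def test_points_on_a_line_give_one_axis(self):
        x = np.array([[0.0], [1.0], [3.0], [6.0]])
        ord_ = pcoa(_euclid_dm(x))
        assert ord_.coordinates.shape[1] == 1
        got = squareform(pdist(ord_.coordinates))
        np.testing.assert_allclose(got, squareform(pdist(x)), atol=1e-9)

    def test_two_samples_coordinates_half_distance(self):
        d = DistanceMatrix(("a", "b"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        ord_ = pcoa(d)
        np.testing.assert_allclose(np.abs(ord_.coordinates[:, 0]), 1.0, atol=1e-12)

    def test_euclidean_self_consistency(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 3))
        ord_ = pcoa(_euclid_dm(x))
        got = squareform(pdist(ord_.coordinates))
        np.testing.assert_allclose(got, squareform(pdist(x)), atol=1e-9)

    def test_axes_ordered_and_centered(self, cohort):
        ord_ = pcoa(bray_curtis(cohort.bacteria.relative_abundance()))
        assert (np.diff(ord_.eigenvalues) <= 1e-12).all()
        np.testing.assert_allclose(ord_.coordinates.mean(axis=0), 0, atol=1e-9)
        assert 0 <= ord_.negative_inertia < 1


class TestPermanova:
    def test_perfect_separation_gives_one(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        dm = DistanceMatrix(("a", "b", "c", "d"), d)
        r2 = permanova_pseudo_r2(dm, ["g1", "g1", "g2", "g2"])
        assert r2 == pytest.approx(1.0)

    def test_toy_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 2))
        dm = _euclid_dm(x)
        labels = np.array(["u", "u", "v", "v"])
        r2 = permanova_pseudo_r2(dm, labels)
        # independent SS computation straight from the definition
        d2 = dm.values ** 2
        n = 4
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = (d2[0, 1] / 2) + (d2[2, 3] / 2)
        assert r2 == pytest.approx((ss_total - ss_within) / ss_total)

    def test_matches_skbio_f_statistic(self):
        """Pseudo-R² converts exactly to skbio's PERMANOVA F on the same data."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(8, 3))
        ids = [f"s{i}" for i in range(8)]
        labels = ["a"] * 4 + ["b"] * 4
        r2 = permanova_pseudo_r2(_euclid_dm(x, ids), labels)
        f_ref = skbio_permanova(
            SkbioDM(squareform(pdist(x)), ids), grouping=labels, permutations=0
        )["test statistic"]
        n, k = 8, 2
        f_from_r2 = (r2 / (k - 1)) / ((1 - r2) / (n - k))
        assert f_from_r2 == pytest.approx(f_ref, rel=1e-10)

    def test_label_name_and_order_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 2))
        dm = _euclid_dm(x)
        labels = np.array(["a", "b", "a", "b", "a", "b"])
        renamed = np.where(labels == "a", "zzz", "qqq")
        assert permanova_pseudo_r2(dm, labels) == pytest.approx(
            permanova_pseudo_r2(dm, renamed)
        )

    def test_pair_restricted_p_floor_on_separable_data(self, design4):
        # region effect much larger than noise: observed R2 strictly maximal
        rng = np.random.default_rng(5)
        x = np.zeros((8, 2))
        for i in range(4):
            x[2 * i] = [10, 0]
            x[2 * i + 1] = [0, 10]
        x += rng.normal(scale=0.01, size=x.shape)
        dm = _euclid_dm(x, design4.sample_ids)
        res = permanova_pair_test(dm, design4, n_unrestricted=None)
        assert res.p_pair == pytest.approx(2 / 16)  # identity and full swap tie
        assert res.value > 0.9


class TestDispersion:
    def test_symmetric_spread_gives_small_f(self, design4):
        coords = np.array(
            [[1, 0], [-1, 0], [2, 0], [-2, 0], [0, 1], [0, -1], [0, 2], [0, -2]],
            dtype=float,
        )
        labels = np.array(["a", "a", "a", "a", "b", "b", "b", "b"])
        assert _dispersion_f(coords, labels) == pytest.approx(0.0, abs=1e-12)

    def test_unequal_spread_gives_large_f(self):
        coords = np.r_[np.zeros((4, 2)), np.array([[3, 0], [-3, 0], [0, 3], [0, -3]])]
        labels = np.array(["tight"] * 4 + ["wide"] * 4)
        assert _dispersion_f(coords, labels) > 50

    def test_hand_centroid_arithmetic(self):
        coords = np.array([[0.0], [2.0], [7.0], [0.0], [4.0]])
        labels = np.array(["a", "a", "a", "b", "b"])
        # centroids: a at 3 → dists (3,1,4); b at 2 → dists (2,2)
        # within-SS = 42/9, between-SS = 8/15, F = (8/15) / (42/9 / 3)
        f = _dispersion_f(coords, labels)
        assert f == pytest.approx((8 / 15) / ((42 / 9) / 3), abs=1e-12)

    def test_pair_test_runs(self, cohort):
        dm = bray_curtis(cohort.bacteria.relative_abundance())
        res = dispersion_test(dm, cohort.design, n_unrestricted=None)
        assert 1 / 256 <= res.p_pair <= 1.0


class TestProcrustes:
    def test_rigid_motion_and_scaling_give_zero(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(8, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        b = 3.1 * (a @ rot) + np.array([5.0, -2.0])
        b[:, 0] *= -1  # reflection allowed too
        assert procrustes_m2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance_of_m2(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(8, 2))
        b = rng.normal(size=(8, 2))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert procrustes_m2(a, b) == pytest.approx(procrustes_m2(a @ rot, b @ rot))

    def test_independent_coordinates_m2_near_one(self):
        rng = np.random.default_rng(9)
        vals = [procrustes_m2(rng.normal(size=(30, 2)), rng.normal(size=(30, 2)))
                for _ in range(30)]
        assert np.mean(vals) > 0.75

    def test_pair_test_on_concordant_ordinations(self, cohort):
        dmb = bray_curtis(cohort.bacteria.relative_abundance())
        dmf = bray_curtis(cohort.fungi.relative_abundance())
        res = procrustes_pair_test(pcoa(dmb), pcoa(dmf), cohort.design,
                                   n_unrestricted=None)
        assert 0.0 <= res.value <= 1.0
        assert res.permutation.null[0] == pytest.approx(1 - res.value)


class TestDbRda:
    def test_constant_covariate_error(self, design4):
        rng = np.random.default_rng(10)
        dm = _euclid_dm(rng.normal(size=(8, 3)), design4.sample_ids)
        cov = pd.DataFrame({"flat": np.ones(8)}, index=design4.sample_ids)
        with pytest.raises(ValueError, match="flat"):
            dbrda_pair_test(dm, cov, design4, n_unrestricted=None)

    def test_perfectly_explained_response(self, design4):
        rng = np.random.default_rng(11)
        z = rng.normal(size=8)
        x = np.c_[z, np.zeros(8)]  # 1-D configuration, linear in z
        dm = _euclid_dm(x, design4.sample_ids)
        cov = pd.DataFrame({"z": z}, index=design4.sample_ids)
        res = dbrda_pair_test(dm, cov, design4, n_unrestricted=None)
        assert res.extra["R2"] == pytest.approx(1.0, abs=1e-9)
        assert res.value == pytest.approx(1.0, abs=1e-9)

    def test_single_covariate_matches_least_squares_oracle(self):
        pairs = tuple((f"p{i}", f"p{i}_A", f"p{i}_B") for i in range(3))
        design = MatchedDesign(pairs, ("A", "B"))
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(6, 2))
        dm = _euclid_dm(pts, design.sample_ids)
        z = rng.normal(size=6)
        cov = pd.DataFrame({"z": z}, index=design.sample_ids)
        res = dbrda_pair_test(dm, cov, design, n_unrestricted=None)
        # oracle: regress each centered PCoA axis on standardized z by hand
        from teaterroir import pcoa as _pcoa

        y = _pcoa(dm).coordinates
        y = y - y.mean(axis=0)
        zs = (z - z.mean()) / z.std(ddof=1)
        beta = (zs @ y) / (zs @ zs)
        fitted = np.outer(zs, beta)
        r2 = (fitted**2).sum() / (y**2).sum()
        adj = 1 - (1 - r2) * (6 - 1) / (6 - 1 - 1)
        assert res.extra["R2"] == pytest.approx(r2, abs=1e-10)
        assert res.value == pytest.approx(adj, abs=1e-10)

    def test_adjusted_not_above_unadjusted(self, cohort):
        dm = bray_curtis(cohort.bacteria.relative_abundance())
        cov = pd.DataFrame(
            {
                "OM": cohort.soil.values_for("OM"),
                "TN": cohort.soil.values_for("TN"),
            }
        ).loc[list(dm.sample_ids)]
        res = dbrda_pair_test(dm, cov, cohort.design, n_unrestricted=None)
        assert res.value <= res.extra["R2"] + 1e-12
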