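import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from modhet import dispersion as disp
from conftest import make_matrix


def _coords_df(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(points.shape[0])]
    return make_matrix(points.T, genes=[f"g{i}" for i in range(points.shape[1])],
                       samples=ids)


class TestEuclideanDistances:
    def test_three_four_five(self):
        m = make_matrix([[0.0, 3.0], [0.0, 4.0]])
        d = disp.euclidean_distances(m)
        assert d.iloc[0, 1] == pytest.approx(5.0)

    def test_identical_samples_distance_zero(self):
        m = make_matrix([[1.0, 1.0], [2.0, 2.0]])
        assert disp.euclidean_distances(m).iloc[0, 1] == 0.0

    def test_brute_force_three_by_three(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(size=(3, 3)))
        d = disp.euclidean_distances(m).to_numpy()
        x = m.to_numpy()
        for s in range(3):
            for t in range(3):
                expected = np.sqrt(sum((x[g, s] - x[g, t]) ** 2 for g in range(3)))
                assert d[s, t] == pytest.approx(expected, abs=1e-12)


class TestPcoaEmbed:
    def test_euclidean_input_reproduces_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 4))
        d = disp.euclidean_distances(_coords_df(pts))
        emb = disp.pcoa_embed(d)
        assert emb.imag.shape[1] == 0
        from scipy.spatial.distance import pdist, squareform
        dd = squareform(pdist(emb.real))
        np.testing.assert_allclose(dd, d.to_numpy(), atol=1e-8)

    def test_two_points_single_axis(self):
        d = pd.DataFrame([[0.0, 3.0], [3.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        emb = disp.pcoa_embed(d)
        assert emb.real.shape[1] == 1
        np.testing.assert_allclose(np.sort(emb.real[:, 0]), [-1.5, 1.5], atol=1e-10)

    def test_non_euclidean_input_has_negative_eigenvalue(self):
        # 4th point claims distance 1.05 to all vertices of a side-2 triangle;
        # the circumradius is 2/sqrt(3) > 1.05, so no embedding exists
        d = np.full((4, 4), 2.0)
        d[3, :3] = d[:3, 3] = 1.05
        np.fill_diagonal(d, 0.0)
        emb = disp.pcoa_embed(pd.DataFrame(d))
        assert emb.eigenvalues.min() < -1e-8 * emb.eigenvalues.max()
        assert emb.imag.shape[1] >= 1


class TestGroupCenter:
    def test_symmetric_point_set_median_equals_centroid(self):
        square = np.array([[0.0, 0.0], [0.0, 2.0], [2.0, 0.0], [2.0, 2.0]])
        members = np.arange(4)
        c = disp.group_center(square, members, "centroid")
        m = disp.group_center(square, members, "spatial_median")
        np.testing.assert_allclose(c, [1.0, 1.0], atol=1e-10)
        np.testing.assert_allclose(m, [1.0, 1.0], atol=1e-8)

    def test_single_member_is_its_own_center(self):
        pts = np.array([[3.0, 4.0]])
        np.testing.assert_allclose(
            disp.group_center(pts, np.array([0]), "spatial_median"), [3.0, 4.0]
        )

    def test_collinear_points_median_is_middle_point(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        members = np.arange(3)
        med = disp.group_center(pts, members, "spatial_median")
        cen = disp.group_center(pts, members, "centroid")
        # direct minimization over a grid confirms the 1-d median
        grid = np.linspace(-1, 11, 12001)
        sums = np.abs(grid[:, None] - pts[:, 0][None, :]).sum(axis=1)
        assert abs(med[0] - grid[np.argmin(sums)]) < 1e-3
        assert med[0] == pytest.approx(1.0, abs=1e-8)
        assert cen[0] == pytest.approx(11.0 / 3.0)

    def test_median_minimizes_summed_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        members = np.arange(12)
        med = disp.group_center(pts, members, "spatial_median")
        cen = disp.group_center(pts, members, "centroid")
        sum_med = np.linalg.norm(pts - med, axis=1).sum()
        sum_cen = np.linalg.norm(pts - cen, axis=1).sum()
        assert sum_med <= sum_cen + 1e-10
        # cross-check against a general-purpose optimizer
        res = minimize(lambda c: np.linalg.norm(pts - c, axis=1).sum(), cen,
                       method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        assert sum_med <= res.fun + 1e-8


class TestDistancesToCenter:
    def test_two_point_group_midpoint(self):
        pts = np.array([[0.0], [2.0]])
        d = disp.euclidean_distances(_coords_df(pts))
        emb = disp.pcoa_embed(d)
        groups = pd.Series(["g", "g"], index=d.index)
        z = disp.distances_to_center(emb, groups, "centroid", bias_adjust=False)
        np.testing.assert_allclose(z.to_numpy(), [1.0, 1.0], atol=1e-10)
        assert disp.beta_diversity(z, groups)["g"] == pytest.approx(1.0)

    def test_equilateral_triangle_circumradius(self):
        s = 2.0
        pts = np.array([[0.0, 0.0], [s, 0.0], [s / 2, s * np.sqrt(3) / 2]])
        d = disp.euclidean_distances(_coords_df(pts))
        emb = disp.pcoa_embed(d)
        groups = pd.Series(["g"] * 3, index=d.index)
        z = disp.distances_to_center(emb, groups, "centroid", bias_adjust=False)
        np.testing.assert_allclose(z.to_numpy(), s / np.sqrt(3), atol=1e-8)

    def test_single_member_group_zero(self):
        pts = np.array([[0.0], [5.0], [6.0]])
        d = disp.euclidean_distances(_coords_df(pts))
        emb = disp.pcoa_embed(d)
        groups = pd.Series(["lone", "g", "g"], index=d.index)
        z = disp.distances_to_center(emb, groups, bias_adjust=False)
        assert z.iloc[0] == 0.0

    def test_bias_adjustment_scales_by_group_size(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        d = disp.euclidean_distances(_coords_df(pts))
        emb = disp.pcoa_embed(d)
        groups = pd.Series(["a"] * 5 + ["b"] * 3, index=d.index)
        raw = disp.distances_to_center(emb, groups, "centroid", bias_adjust=False)
        adj = disp.distances_to_center(emb, groups, "centroid", bias_adjust=True)
        np.testing.assert_allclose(
            adj[groups == "a"], raw[groups == "a"] * np.sqrt(5 / 4), atol=1e-10
        )
        np.testing.assert_allclose(
            adj[groups == "b"], raw[groups == "b"] * np.sqrt(3 / 2), atol=1e-10
        )

    def test_embedded_path_matches_gene_space_directly(self):
        # oracle equivalence for Euclidean input: distances to the group
        # centroid computed in the PCoA embedding equal those computed with
        # plain arithmetic in the original standardized gene space
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(20, 15)))
        groups = pd.Series(["a"] * 7 + ["b"] * 8, index=m.columns)
        emb = disp.pcoa_embed(disp.euclidean_distances(m))
        z = disp.distances_to_center(emb, groups, "centroid", bias_adjust=False)
        x = m.to_numpy()
        expected = np.empty(15)
        for g in ("a", "b"):
            cols = np.flatnonzero((groups == g).to_numpy())
            center = x[:, cols].mean(axis=1)
            expected[cols] = np.sqrt(((x[:, cols] - center[:, None]) ** 2).sum(axis=0))
        np.testing.assert_allclose(z.to_numpy(), expected, atol=1e-8)


class TestPermdisp:
    @staticmethod
    def _z_case(rng, n_a=10, n_b=10, scale_b=1.0):
        pts = np.vstack([rng.normal(0, 1, (n_a, 5)), rng.normal(0, scale_b, (n_b, 5))])
        d = disp.euclidean_distances(_coords_df(pts))
        emb = disp.pcoa_embed(d)
        groups = pd.Series(["a"] * n_a + ["b"] * n_b, index=d.index)
        z = disp.distances_to_center(emb, groups)
        return z, groups

    def test_seeded_runs_are_bit_reproducible(self):
        z, groups = self._z_case(np.random.default_rng(0))
        r1 = disp.permdisp_test(z, groups, 199, seed=7)
        r2 = disp.permdisp_test(z, groups, 199, seed=7)
        assert r1.p_value == r2.p_value
        assert r1.f_statistic == r2.f_statistic

    def test_p_value_floor_is_one_over_permutations_plus_one(self):
        rng = np.random.default_rng(1)
        z, groups = self._z_case(rng, n_a=25, n_b=25, scale_b=8.0)
        res = disp.permdisp_test(z, groups, 100, seed=0)
        assert res.p_value >= 1.0 / 101.0
        assert res.p_value == pytest.approx(1.0 / 101.0)

    def test_strong_dispersion_difference_detected(self):
        rng = np.random.default_rng(2)
        z, groups = self._z_case(rng, n_a=30, n_b=30, scale_b=4.0)
        res = disp.permdisp_test(z, groups, 999, seed=0)
        assert res.p_value < 0.01
        assert res.beta_div_b > res.beta_div_a

    def test_label_scheme_agrees_with_residual_scheme_under_null(self):
        rng = np.random.default_rng(3)
        z, groups = self._z_case(rng, n_a=20, n_b=20)
        pr = disp.permdisp_test(z, groups, 999, seed=0, scheme="residuals")
        pl = disp.permdisp_test(z, groups, 999, seed=0, scheme="labels")
        assert abs(pr.p_value - pl.p_value) < 0.1

    def test_tiny_group_rejected(self):
        z = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        groups = pd.Series(["g1", "g1", "g2"], index=z.index)
        with pytest.raises(ValueError, match=">= 2 members"):
            disp.permdisp_test(z, groups, 99)

    def test_matches_vegan_betadisper_oracle(self, tmp_path):
        # vegan::betadisper + anova as the independent reference on a small
        # fixture: distances to group centroids and the observed F statistic
        rscript = shutil.which("Rscript")
        assert rscript, "Rscript is part of the supported environment"
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(6, 12)))
        groups = pd.Series(["a"] * 5 + ["b"] * 7, index=m.columns)
        d = disp.euclidean_distances(m)
        emb = disp.pcoa_embed(d)
        z = disp.distances_to_center(emb, groups, "centroid", bias_adjust=False)
        gidx = (groups == "b").to_numpy().astype(int)
        f_obs = disp._anova_f(z.to_numpy(), gidx, 2)

        d_path = tmp_path / "d.tsv"
        d.to_csv(d_path, sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(vegan))
            d <- as.matrix(read.table("{d_path}", sep="\\t", header=TRUE,
                                      row.names=1, check.names=FALSE))
            grp <- factor(c(rep("a", 5), rep("b", 7)))
            mod <- betadisper(as.dist(d), grp, type = "centroid")
            cat(paste(mod$distances, collapse=","), "\\n")
            cat(anova(mod)[1, "F value"], "\\n")
        """))
        out = subprocess.run([rscript, str(script)], capture_output=True, text=True,
                             check=True)
        lines = [l for l in out.stdout.strip().splitlines() if l.strip()]
        vegan_z = np.array([float(v) for v in lines[0].split(",")])
        vegan_f = float(lines[1])
        np.testing.assert_allclose(z.to_numpy(), vegan_z, atol=1e-6)
        assert f_obs == pytest.approx(vegan_f, abs=1e-6)


class TestFdrAdjust:
    def test_hand_benjamini_hochberg_m4(self):
        np.testing.assert_allclose(
            disp.fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_benjamini_hochberg_m2(self):
        np.testing.assert_allclose(disp.fdr_adjust([0.005, 0.5]), [0.01, 0.5])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(disp.fdr_adjust([0.3]), [0.3])

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = disp.fdr_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            disp.fdr_adjust([0.5, 1.2])


class TestInvariance:
    def test_beta_diversity_invariant_under_rotation_and_linear_in_scale(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(14, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        groups_arr = ["a"] * 7 + ["b"] * 7

        def bd(points):
            d = disp.euclidean_distances(_coords_df(points))
            emb = disp.pcoa_embed(d)
            groups = pd.Series(groups_arr, index=d.index)
            z = disp.distances_to_center(emb, groups, "centroid", bias_adjust=False)
            return disp.beta_diversity(z, groups)

        base = bd(pts)
        rotated = bd(pts @ q)
        scaled = bd(3.0 * pts)
        np.testing.assert_allclose(rotated.to_numpy(), base.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(scaled.to_numpy(), 3.0 * base.to_numpy(), atol=1e-8)

    def test_spatial_median_minimizes_group_distance_sum(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(15, 4))
        d = disp.euclidean_distances(_coords_df(pts))
        emb = disp.pcoa_embed(d)
        groups = pd.Series(["a"] * 8 + ["b"] * 7, index=d.index)
        z_med = disp.distances_to_center(emb, groups, "spatial_median", bias_adjust=False)
        z_cen = disp.distances_to_center(emb, groups, "centroid", bias_adjust=False)
        for g in ("a", "b"):
            assert z_med[groups == g].sum() <= z_cen[groups == g].sum() + 1e-8

    def test_comparison_seed_is_stable_and_context_sensitive(self):
        a = disp.comparison_seed(1, "m1", "x", "y")
        b = disp.comparison_seed(1, "m1", "x", "y")
        c = disp.comparison_seed(1, "m2", "x", "y")
        assert a.entropy == b.entropy
        assert a.entropy != c.entropy
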