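import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from nhkit.inference import (
    ClusterTable,
    StatMap,
    build_design,
    cluster_report,
    estimate_smoothness,
    extract_cluster_nh,
    grf_cluster_correct,
    voxelwise_glm,
)


def _two_group_table(n1=3, n2=3):
    return pd.DataFrame({
        "group": ["a"] * n1 + ["b"] * n2,
        "age": np.zeros(n1 + n2),
    })


class TestGLM:
    def test_pairwise_t_matches_pooled_two_sample_t(self, rng):
        y = rng.standard_normal((6, 40))
        design = build_design(_two_group_table(), covariates=())
        tmap, _ = voxelwise_glm(y, design, contrast=("a", "b"))
        for v in range(40):
            t_ref, _ = stats.ttest_ind(y[:3, v], y[3:, v])
            assert tmap.stat[v] == pytest.approx(t_ref, abs=1e-10)
        assert tmap.df == 4

    def test_omnibus_f_equals_t_squared_for_two_groups(self, rng):
        y = rng.standard_normal((8, 25))
        design = build_design(_two_group_table(4, 4), covariates=())
        tmap, _ = voxelwise_glm(y, design, contrast=("a", "b"))
        fmap, _ = voxelwise_glm(y, design)
        np.testing.assert_allclose(fmap.stat, tmap.stat**2, atol=1e-8)

    def test_collinear_covariate_pruned_with_warning(self, rng):
        table = _two_group_table(4, 4)
        table["dup"] = (table["group"] == "a").astype(float)  # collinear with group
        design = build_design(table, covariates=("dup",))
        y = rng.standard_normal((8, 10))
        with pytest.warns(UserWarning, match="collinear"):
            tmap, _ = voxelwise_glm(y, design, contrast=("a", "b"))
        assert np.isfinite(tmap.stat).all()

    def test_covariate_adjustment_removes_linear_confound(self, rng):
        n = 40
        cov = rng.standard_normal(n)
        table = pd.DataFrame({"group": ["a"] * (n // 2) + ["b"] * (n // 2), "age": cov})
        y = np.outer(cov, np.ones(15)) + 0.1 * rng.standard_normal((n, 15))
        design = build_design(table, covariates=("age",))
        tmap, _ = voxelwise_glm(y, design, contrast=("a", "b"))
        # after adjusting for the covariate, no group effect remains
        assert np.abs(tmap.stat).max() < 4.0

    def test_null_pvalues_uniform(self, rng):
        # under a global null the voxelwise p-values are uniform (KS check)
        y = rng.standard_normal((30, 2000))
        table = pd.DataFrame({"group": ["a", "b", "c"] * 10})
        design = build_design(table, covariates=())
        fmap, _ = voxelwise_glm(y, design)
        p = stats.f.sf(fmap.stat, *fmap.df)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_residual_dof(self, rng):
        y = rng.standard_normal((10, 5))
        design = build_design(_two_group_table(5, 5), covariates=())
        _, resid = voxelwise_glm(y, design, contrast=("a", "b"))
        assert resid.shape == y.shape
        np.testing.assert_allclose(resid.sum(axis=0), 0, atol=1e-10)


class TestSmoothness:
    GRID = (24, 28, 22)

    def _fields(self, rng, n, fwhm_vox=None):
        out = []
        for _ in range(n):
            f = rng.standard_normal(self.GRID)
            if fwhm_vox:
                f = gaussian_filter(f, fwhm_vox / 2.3548, mode="constant", truncate=6)
            out.append(f)
        return np.asarray(out)

    def test_white_noise_estimates_voxel_size(self, rng):
        mask = np.ones(self.GRID, bool)
        stack = self._fields(rng, 12)[:, mask]
        est = estimate_smoothness(stack, mask, (3.0, 3.0, 3.0))
        for f in est.fwhm_mm:
            assert f == pytest.approx(3.0, rel=0.15)

    def test_known_6mm_smoothness_recovered(self, rng):
        mask = np.ones(self.GRID, bool)
        stack = self._fields(rng, 12, fwhm_vox=2.0)[:, mask]
        est = estimate_smoothness(stack, mask, (3.0, 3.0, 3.0))
        for f in est.fwhm_mm:
            assert f == pytest.approx(6.0, rel=0.15)

    def test_resels_double_with_mask_volume(self, rng):
        mask1 = np.zeros(self.GRID, bool)
        mask1[:, :, :8] = True
        mask2 = np.zeros(self.GRID, bool)
        mask2[:, :, :16] = True
        fields = self._fields(rng, 10, fwhm_vox=2.0)
        e1 = estimate_smoothness(fields[:, mask1], mask1, (3, 3, 3))
        e2 = estimate_smoothness(fields[:, mask2], mask2, (3, 3, 3))
        assert e2.n_voxels == 2 * e1.n_voxels
        assert e2.resel_count / e1.resel_count == pytest.approx(2.0, rel=0.1)


class TestGRF:
    def _null_zmap(self, rng, grid=(24, 28, 22)):
        f = gaussian_filter(rng.standard_normal(grid), 0.85, mode="constant", truncate=6)
        return f / f.std()

    def test_subthreshold_map_gives_empty_table(self, rng):
        grid = (10, 10, 8)
        sm = StatMap(np.zeros(grid), 1.0, "z", np.ones(grid, bool), np.eye(4))
        est = estimate_smoothness(rng.standard_normal((5, 800)), np.ones(grid, bool))
        table = grf_cluster_correct(sm, est, 0.001, 0.05)
        assert len(table) == 0

    def test_invalid_thresholds_rejected(self, rng):
        grid = (6, 6, 4)
        sm = StatMap(np.zeros(grid), 1.0, "z", np.ones(grid, bool), np.eye(4))
        est = estimate_smoothness(rng.standard_normal((5, 144)), np.ones(grid, bool))
        with pytest.raises(ValueError):
            grf_cluster_correct(sm, est, 0.0, 0.05)

    def test_signed_tails_reported_separately(self, rng):
        grid = (20, 20, 12)
        mask = np.ones(grid, bool)
        vol = self._null_zmap(rng, grid) * 0.1
        vol[3:7, 3:7, 3:7] = 8.0
        vol[12:16, 12:16, 6:10] = -8.0
        est = estimate_smoothness(
            np.asarray([self._null_zmap(rng, grid)[mask] for _ in range(10)]), mask)
        sm = StatMap(vol, 40.0, "t", mask, np.eye(4))
        table = grf_cluster_correct(sm, est, 0.001, 0.05, mask)
        signs = sorted(r["sign"] for r in table.rows)
        assert signs == [-1, 1]
        assert all(r["p_corrected"] < 0.05 for r in table.rows)


class TestReporting:
    def _table(self):
        t = ClusterTable()
        t.rows.append({
            "comparison": "a vs b", "label": "", "peak_ijk": (2, 3, 4),
            "voxels": np.array([[2, 3, 4], [2, 3, 5]]), "n_voxels": 2,
            "peak_stat": 4.2, "sign": 1, "p_corrected": 0.01,
        })
        return t

    def test_identity_affine_maps_mm_to_indices(self):
        df = cluster_report(self._table(), np.eye(4))
        assert (df.loc[0, ["x_mm", "y_mm", "z_mm"]] == [2, 3, 4]).all()

    def test_offset_affine_matches_matrix_multiply(self):
        aff = np.array([[3, 0, 0, -36], [0, 3, 0, -42], [0, 0, 3, -33], [0, 0, 0, 1]], float)
        df = cluster_report(self._table(), aff)
        np.testing.assert_allclose(
            df.loc[0, ["x_mm", "y_mm", "z_mm"]].astype(float),
            aff[:3, :3] @ [2, 3, 4] + aff[:3, 3],
        )

    def test_empty_table_reports_empty_frame(self):
        df = cluster_report(ClusterTable(), np.eye(4))
        assert len(df) == 0

    def test_atlas_labels_attached(self):
        atlas = np.zeros((6, 6, 6), dtype=np.int16)
        atlas[2, 3, :] = 2
        df = cluster_report(self._table(), np.eye(4), atlas, {2: "region_two"})
        assert df.loc[0, "label"] == "region_two"


class TestExtractClusterNH:
    def test_single_voxel_cluster_is_that_column(self, rng):
        mask = np.zeros((4, 4, 2), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = mask[2, 2, 0] = True
        stack = rng.standard_normal((5, 3))
        vals = extract_cluster_nh(stack, mask, np.array([[1, 1, 1]]))
        np.testing.assert_array_equal(vals, stack[:, 1])

    def test_uniform_stack_returns_constant(self):
        mask = np.ones((3, 3, 1), bool)
        stack = np.full((4, 9), 0.7)
        vals = extract_cluster_nh(stack, mask, np.array([[0, 0, 0], [1, 1, 0]]))
        np.testing.assert_allclose(vals, 0.7)

    def test_matches_brute_force_mean(self, rng):
        mask = np.ones((4, 3, 2), bool)
        stack = rng.standard_normal((6, 24))
        cluster = np.array([[0, 0, 0], [1, 2, 1], [3, 0, 1]])
        flat = [np.ravel_multi_index(c, (4, 3, 2)) for c in cluster]
        expected = stack[:, flat].mean(axis=1)
        np.testing.assert_allclose(
            extract_cluster_nh(stack, mask, cluster), expected, atol=1e-12)

    def test_cluster_outside_mask_rejected(self, rng):
        mask = np.zeros((4, 3, 2), bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        stack = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="outside"):
            extract_cluster_nh(stack, mask, np.array([[3, 2, 1]]))
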