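"""Group inference: t/eta^2, bootstrap correlation, Shapiro gate,
Bonferroni, voxelwise GLM and permutation cluster FWE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ntpipe import (bonferroni_correct, cluster_fwe_perm, eta_squared_from_t,
                    normality_test, pearson_bootstrap, two_sample_t,
                    voxelwise_glm_t)
from ntpipe.core import AtlasGeometry, IntMap

GEOM = AtlasGeometry((10, 10, 8), (4.0, 4.0, 4.0), (-18.0, -18.0, -14.0))


def _maps_from_matrix(Y):
    """Wrap an (S, V) matrix as full-mask IntMaps on GEOM (values shifted
    to be nonnegative; shifts do not change t statistics)."""
    Y = Y - Y.min() + 1.0
    dims = GEOM.grid_dims
    maps = []
    for row in Y:
        vals = row.reshape(dims)
        maps.append(IntMap(values=vals, mask=np.ones(dims, dtype=bool),
                           geometry=GEOM, tr_s=2.2))
    return maps


class TestEtaSquared:
    @given(st.floats(-20, 20), st.integers(1, 1000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_identity(self, t, df):
        e = eta_squared_from_t(t, df)
        assert 0 <= e <= 1
        assert e == pytest.approx(t * t / (t * t + df))

    def test_zero_t(self):
        assert eta_squared_from_t(0.0, 100) == 0.0

    def test_df_below_one_rejected(self):
        with pytest.raises(ValueError):
            eta_squared_from_t(2.0, 0)


class TestTwoSampleT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        res = two_sample_t(a, a)
        assert res.t == 0.0 and res.p == pytest.approx(1.0) and res.eta2 == 0.0

    def test_hand_worked_example(self):
        # pooled-variance formula by hand: means 2 vs 5, s_p^2 = 1,
        # t = -3 / sqrt(2/3) = -3.6742, df = 4
        res = two_sample_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == 4

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(60)
        a, b = rng.standard_normal(20), rng.standard_normal(15) + 0.4
        res = two_sample_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_swapping_groups_flips_sign_only(self):
        rng = np.random.default_rng(61)
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 1
        r1, r2 = two_sample_t(a, b), two_sample_t(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t([1.0, 1.0], [1.0, 1.0])


class TestPearsonBootstrap:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = pearson_bootstrap(x, 2 * x, n_boot=500, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p_boot == pytest.approx(1 / 500)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0] )
        y = y - y.mean()
        y -= x * (x @ y) / (x @ x)
        res = pearson_bootstrap(x, y, n_boot=2000, seed=2)
        assert abs(res.r) < 1e-12
        assert res.p_boot > 0.5

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(62)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        a = pearson_bootstrap(x, y, n_boot=1000, seed=3)
        b = pearson_bootstrap(y, x, n_boot=1000, seed=3)
        assert a.r == pytest.approx(b.r) and a.p_boot == b.p_boot

    def test_sampling_distribution_recovers_rho(self):
        # large-sample expectation of sample r is the generating rho
        rho, rs = 0.6, []
        rng = np.random.default_rng(63)
        cov = [[1, rho], [rho, 1]]
        for _ in range(200):
            x, y = rng.multivariate_normal([0, 0], cov, size=100).T
            rs.append(sps.pearsonr(x, y).statistic)
        assert np.mean(rs) == pytest.approx(rho, abs=0.03)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_bootstrap(np.ones(10), np.arange(10.0), n_boot=100, seed=0)


class TestNormality:
    def test_nominal_level_on_gaussian(self):
        hits = sum(normality_test(np.random.default_rng(s).standard_normal(100))[1] > 0.05
                   for s in range(50))
        assert hits >= 45

    def test_power_against_lognormal(self):
        hits = sum(
            normality_test(np.exp(np.random.default_rng(s).standard_normal(100)))[1] < 0.05
            for s in range(50))
        assert hits >= 45

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0])


class TestBonferroni:
    def test_printed_pairs(self):
        assert bonferroni_correct(0.008, 2) == pytest.approx(0.016)
        assert bonferroni_correct(0.007, 5) == pytest.approx(0.035)

    def test_cap_at_one(self):
        assert bonferroni_correct(0.7, 2) == 1.0

    @given(st.floats(0, 1), st.integers(1, 50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_and_bounded(self, p, m):
        q = bonferroni_correct(p, m)
        assert p <= q <= 1.0


class TestVoxelwiseGlm:
    def test_reduces_to_two_sample_t_with_orthogonal_covariates(self):
        """With covariates balanced across groups and orthogonal to the
        data, the GLM group contrast reproduces the unadjusted two-sample
        t up to the exact df correction sqrt(df_glm / df_pooled)."""
        rng = np.random.default_rng(70)
        n = 24
        group = ["CN"] * 12 + ["AD"] * 12
        age = np.tile([60.0, 65.0, 70.0, 75.0], 6)
        sex = ["F", "M"] * 12
        C = np.column_stack([np.ones(n), age, [1.0 if s == "M" else 0.0 for s in sex]])
        Y = rng.standard_normal((n, np.prod(GEOM.grid_dims)))
        # voxel 0: orthogonalize against the covariates, then add the group gap
        y0 = Y[:, 0] - C @ np.linalg.lstsq(C, Y[:, 0], rcond=None)[0]
        Y[:, 0] = y0 + np.repeat([0.0, 2.0], 12)
        maps = _maps_from_matrix(Y)
        t_map, mask, df = voxelwise_glm_t(maps, group, age, sex)
        vals = np.stack([m.values[mask] for m in maps])
        ref = two_sample_t(vals[12:, 0], vals[:12, 0])  # AD - CN contrast
        assert t_map[mask][0] == pytest.approx(ref.t * np.sqrt(df / ref.df), abs=1e-6)

    def test_null_calibration_across_voxels(self):
        rng = np.random.default_rng(71)
        n = 40
        group = rng.permutation(["CN"] * 20 + ["AD"] * 20)
        age = rng.normal(70, 5, n)
        sex = rng.choice(["F", "M"], n)
        maps = _maps_from_matrix(rng.standard_normal((n, np.prod(GEOM.grid_dims))))
        t_map, mask, df = voxelwise_glm_t(maps, group, age, sex)
        crit = sps.t.isf(0.025, df)
        frac = np.mean(np.abs(t_map[mask]) > crit)
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_undefined_voxels_excluded(self):
        rng = np.random.default_rng(72)
        Y = rng.standard_normal((12, np.prod(GEOM.grid_dims)))
        maps = _maps_from_matrix(Y)
        # knock one voxel out of one subject
        m0 = maps[0]
        m0.mask[0, 0, 0] = False
        m0.values[0, 0, 0] = np.nan
        t_map, mask, _ = voxelwise_glm_t(maps, ["CN"] * 6 + ["AD"] * 6,
                                         np.arange(12.0), ["F", "M"] * 6)
        assert not mask[0, 0, 0] and np.isnan(t_map[0, 0, 0])

    def test_too_few_subjects_rejected(self):
        maps = _maps_from_matrix(np.random.default_rng(73).standard_normal((4, np.prod(GEOM.grid_dims))))
        with pytest.raises(ValueError, match="3 subjects"):
            voxelwise_glm_t(maps, ["CN", "CN", "AD", "AD"], [70, 71, 72, 73], ["F", "M", "F", "M"])


class TestClusterFwe:
    def _cohort(self, rng, n_per_group=12, effect=0.0, block=None):
        n = 2 * n_per_group
        Y = rng.standard_normal((n, np.prod(GEOM.grid_dims)))
        if effect:
            vol = np.zeros(GEOM.grid_dims)
            vol[block] = effect
            Y[n_per_group:] += vol.ravel()
        group = ["CN"] * n_per_group + ["AD"] * n_per_group
        age = rng.normal(70, 5, n)
        sex = rng.choice(["F", "M"], n)
        return _maps_from_matrix(Y), group, age, sex

    def test_pure_noise_rarely_yields_clusters(self):
        rng = np.random.default_rng(80)
        maps, group, age, sex = self._cohort(rng)
        clusters = cluster_fwe_perm(maps, group, age, sex, GEOM, n_perm=150, seed=5)
        assert all(c.p_fwe > 0.0 for c in clusters)  # p never exactly zero
        sig = [c for c in clusters if c.p_fwe < 0.05]
        assert len(sig) == 0

    def test_planted_block_detected(self):
        rng = np.random.default_rng(81)
        block = (slice(3, 6), slice(3, 6), slice(3, 6))
        maps, group, age, sex = self._cohort(rng, effect=5.0, block=block)
        clusters = cluster_fwe_perm(maps, group, age, sex, GEOM, n_perm=200, seed=6)
        assert clusters, "planted 3x3x3 block not detected"
        top = clusters[0]
        assert top.cluster_size_voxels == 27
        assert top.p_fwe <= 1 / 200 + 0.01
        peak_vox = GEOM.mm_to_voxel(top.peak_coord_mm)
        assert all(3 <= v < 6 for v in peak_vox)

    def test_face_connectivity_splits_diagonal_blocks(self):
        rng = np.random.default_rng(82)
        # two blocks touching only at a corner must be separate clusters
        b1 = (slice(2, 4), slice(2, 4), slice(2, 4))
        b2 = (slice(4, 6), slice(4, 6), slice(4, 6))
        n = 24
        Y = rng.standard_normal((n, np.prod(GEOM.grid_dims)))
        vol = np.zeros(GEOM.grid_dims)
        vol[b1] = 6.0
        vol[b2] = 6.0
        Y[12:] += vol.ravel()
        maps = _maps_from_matrix(Y)
        clusters = cluster_fwe_perm(maps, ["CN"] * 12 + ["AD"] * 12,
                                    rng.normal(70, 5, n), rng.choice(["F", "M"], n),
                                    GEOM, n_perm=150, seed=7)
        assert len([c for c in clusters if c.cluster_size_voxels == 8]) == 2

    def test_permutation_count_floor(self):
        rng = np.random.default_rng(83)
        maps, group, age, sex = self._cohort(rng, n_per_group=6)
        with pytest.raises(ValueError, match="n_perm"):
            cluster_fwe_perm(maps, group, age, sex, GEOM, n_perm=50, seed=1)
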