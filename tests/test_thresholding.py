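"""The four thresholding methods, smoothness estimation and the
Monte-Carlo cluster-extent calibration."""

import numpy as np
import pytest
from scipy import integrate, ndimage, special
from scipy.stats import norm
from scipy.stats import t as t_dist

import boldrepro as br
from boldrepro.glm import StatMap
from boldrepro.thresholding import (
    ample_threshold,
    cluster_size_threshold,
    cluster_threshold,
    fdr_threshold,
)


def make_stat(tmap, dof=60, mask=None, residuals=None):
    tmap = np.asarray(tmap, dtype=float)
    if mask is None:
        mask = np.ones(tmap.shape, dtype=bool)
    return StatMap(tmap=tmap, dof=dof, beta=tmap.copy(),
                   residuals=residuals if residuals is not None
                   else np.zeros(tmap.shape + (12,)),
                   mask=mask, condition="task",
                   affine=br.centered_affine(tmap.shape, 4.0))


class TestPFromT:
    def test_symmetry_and_monotonicity(self):
        assert br.p_from_t(0.0, 30) == pytest.approx(0.5)
        ts = np.linspace(-3, 6, 50)
        ps = br.p_from_t(ts, 30)
        assert np.all(np.diff(ps) < 0)
        assert br.p_from_t(50.0, 30) < 1e-10

    def test_matches_quadrature_of_t_density(self):
        # independent oracle: numerically integrate the t density
        dof = 60

        def density(x):
            c = special.gamma((dof + 1) / 2) / (
                np.sqrt(dof * np.pi) * special.gamma(dof / 2)
            )
            return c * (1 + x ** 2 / dof) ** (-(dof + 1) / 2)

        tail, _ = integrate.quad(density, 2.0, np.inf)
        assert br.p_from_t(2.0, dof) == pytest.approx(tail, abs=1e-10)


class TestBonferroni:
    def test_strict_inequality_boundary(self):
        # corrected p exactly at alpha is NOT active; just below is
        shape = (10, 10, 10)  # 1000-voxel mask
        t0 = 4.0
        p0 = float(t_dist.sf(t0, 60))
        stat = make_stat(np.full(shape, t0))
        at_boundary = br.bonferroni_threshold(stat, alpha=p0 * 1000)
        assert not at_boundary.active.any()
        just_above = br.bonferroni_threshold(stat, alpha=p0 * 1000 * 1.001)
        assert just_above.active.all()

    def test_single_voxel_mask_reduces_to_uncorrected(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        t0 = float(t_dist.isf(0.005, 60))
        stat = make_stat(np.full((3, 3, 3), t0), mask=mask)
        act = br.bonferroni_threshold(stat, alpha=0.01)
        assert act.active[1, 1, 1]
        assert act.active.sum() == 1


class TestFdr:
    def test_all_equal_pvalues(self):
        q = br.fdr_adjust(np.full(7, 0.03))
        assert np.allclose(q, 0.03)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        q = br.fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_matches_step_up_oracle(self):
        p = np.array([0.001, 0.008, 0.039, 0.041])
        # exhaustive Benjamini-Hochberg step-up on 4 values
        m = len(p)
        raw = p * m / (np.arange(m) + 1)
        expected = np.minimum.accumulate(raw[::-1])[::-1]
        assert np.allclose(br.fdr_adjust(p), expected, atol=1e-12)

    def test_bonferroni_active_subset_of_bh_active(self):
        rng = np.random.default_rng(8)
        tmap = rng.normal(1.0, 2.0, size=(8, 8, 8))
        stat = make_stat(tmap)
        alpha = 0.01
        bon = br.bonferroni_threshold(stat, alpha=alpha)
        fdr = fdr_threshold(stat, q=alpha)
        assert not np.any(bon.active & ~fdr.active)


class TestSmoothness:
    def test_white_noise_below_1p5_voxels(self, rng):
        res = rng.normal(size=(16, 16, 12, 30))
        mask = np.ones((16, 16, 12), dtype=bool)
        est = br.estimate_smoothness(res, mask, 4.0)
        assert np.all(est.fwhm_mm < 1.5 * 4.0)

    def test_recovers_applied_kernel(self, rng):
        res = rng.normal(size=(24, 24, 18, 30))
        sigma = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 4.0
        res = ndimage.gaussian_filter(res, sigma=(sigma, sigma, sigma, 0))
        mask = np.ones((24, 24, 18), dtype=bool)
        est = br.estimate_smoothness(res, mask, 4.0)
        assert est.geometric_mean == pytest.approx(8.0, abs=1.6)

    def test_monotone_in_kernel(self, rng):
        mask = np.ones((20, 20, 16), dtype=bool)
        base = rng.normal(size=(20, 20, 16, 20))
        prev = -1.0
        for fwhm in (0.0, 4.0, 8.0, 12.0):
            sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / 4.0
            res = (ndimage.gaussian_filter(base, sigma=(sigma,) * 3 + (0,))
                   if sigma > 0 else base)
            est = br.estimate_smoothness(res, mask, 4.0)
            assert est.geometric_mean > prev
            prev = est.geometric_mean

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            br.estimate_smoothness(np.zeros((4, 4, 4, 5)),
                                   np.ones((4, 4, 4), bool), 4.0)


class TestClusterSizeThreshold:
    def test_alpha_one_gives_k_one(self):
        mask = br.make_brain_mask((12, 12, 10), 4.0)
        table = br.cluster_size_threshold(mask, 6.0, 4.0, alphas=(1.0,),
                                          n_iter=20, seed=1)
        assert table.k(1.0) == 1

    def test_deterministic_under_fixed_seed(self):
        mask = br.make_brain_mask((12, 12, 10), 4.0)
        t1 = br.cluster_size_threshold(mask, 6.0, 4.0, n_iter=100, seed=7)
        t2 = br.cluster_size_threshold(mask, 6.0, 4.0, n_iter=100, seed=7)
        assert t1.k_by_alpha == t2.k_by_alpha

    def test_k_nonincreasing_in_alpha(self):
        mask = br.make_brain_mask((14, 14, 10), 4.0)
        table = br.cluster_size_threshold(
            mask, 8.0, 4.0, alphas=(0.01, 0.05, 0.2), n_iter=200, seed=3
        )
        ks = [table.k(a) for a in (0.01, 0.05, 0.2)]
        assert ks[0] >= ks[1] >= ks[2]


class TestAmple:
    def _atlas(self, shape):
        mask = np.ones(shape, dtype=bool)
        atlas = np.ones(shape, dtype=np.int8)  # single "frontal" sector
        return mask, atlas

    def test_percent_of_regional_max(self):
        mask, atlas = self._atlas((4, 4, 2))
        tmap = np.zeros((4, 4, 2))
        tmap[0, 0, 0] = 10.0
        tmap[1, 0, 0] = 6.5
        tmap[2, 0, 0] = 6.0
        stat = make_stat(tmap, mask=mask)
        vals = br.ample_map(stat, atlas)
        assert vals[0, 0, 0] == pytest.approx(100.0)
        assert vals[1, 0, 0] == pytest.approx(65.0)
        act = ample_threshold(stat, atlas)
        assert act.active[1, 0, 0]       # 65 > 60
        assert not act.active[2, 0, 0]   # 60 is not > 60 (strict)

    def test_scale_invariance(self, rng):
        mask = br.make_brain_mask((10, 10, 8), 4.0)
        atlas = br.make_region_atlas(mask, br.centered_affine((10, 10, 8), 4.0))
        tmap = np.abs(rng.normal(size=(10, 10, 8))) + 0.1
        a1 = ample_threshold(make_stat(tmap, mask=mask), atlas)
        a2 = ample_threshold(make_stat(3.7 * tmap, mask=mask), atlas)
        assert np.array_equal(a1.active, a2.active)

    def test_nonpositive_region_flagged(self):
        mask, atlas = self._atlas((3, 3, 2))
        stat = make_stat(np.full((3, 3, 2), -1.0), mask=mask)
        with pytest.warns(RuntimeWarning):
            act = ample_threshold(stat, atlas)
        assert not act.active.any()


class TestApplyThreshold:
    def test_all_zero_tmap_empty_under_every_method(self):
        mask = br.make_brain_mask((10, 10, 8), 4.0)
        atlas = br.make_region_atlas(mask, br.centered_affine((10, 10, 8), 4.0))
        stat = make_stat(np.zeros((10, 10, 8)), mask=mask)
        table = br.ClusterSizeTable(k_by_alpha={0.01: 5}, voxel_p=1e-4,
                                    n_iterations=1, seed=0)
        ctx = br.ThresholdContext(atlas=atlas, cluster_table=table)
        for method in ("Bon", "FDR", "Clst"):
            act = br.apply_threshold(stat, method, ctx)
            assert not act.active.any(), method
        with pytest.warns(RuntimeWarning):
            # every region's max t is 0 -> AMPLE undefined, no activation
            act = br.apply_threshold(stat, "AMPLE", ctx)
        assert not act.active.any()

    def test_missing_context_rejected(self):
        stat = make_stat(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            br.apply_threshold(stat, "AMPLE")
        with pytest.raises(ValueError):
            br.apply_threshold(stat, "Clst")

    def test_cluster_threshold_removes_small_clusters(self):
        shape = (12, 12, 8)
        tmap = np.zeros(shape)
        tthr = float(t_dist.isf(1e-4, 60))
        tmap[2:5, 2:5, 2:4] = tthr + 1      # 18-voxel blob
        tmap[9, 9, 6] = tthr + 1            # single voxel
        stat = make_stat(tmap)
        table = br.ClusterSizeTable(k_by_alpha={0.01: 5}, voxel_p=1e-4,
                                    n_iterations=1, seed=0)
        act = cluster_threshold(stat, table)
        assert act.active[3, 3, 3]
        assert not act.active[9, 9, 6]

    def test_strong_sphere_recovered_by_all_methods(self, noiseless_run1):
        cfg, bold, truths = noiseless_run1
        cfg_noisy = br.SimulationConfig(n_subjects=1, seed=21)
        noisy, _, _ = br.simulate_session(cfg_noisy, 1, 1, "run1", truths)
        run_mc, _ = br.motion_correct_run(noisy, "NoMoCo")
        sm = br.smooth_in_mask(run_mc.data, 6.0, run_mc.mask, 4.0)
        bold_sm = br.Bold4D(data=sm, affine=noisy.affine, tr_seconds=5.0,
                            mask=noisy.mask)
        design = br.build_design(br.build_paradigm("run1"), "Std")
        stat = br.fit_ols(bold_sm, design)["word_repetition"]
        atlas = br.make_region_atlas(noisy.mask, noisy.affine)
        smooth = br.estimate_smoothness(stat.residuals, noisy.mask, 4.0)
        table = br.cluster_size_threshold(noisy.mask, smooth, 4.0,
                                          n_iter=200, seed=5)
        ctx = br.ThresholdContext(atlas=atlas, cluster_table=table)
        from boldrepro.core import mm_to_voxel

        center = tuple(np.round(
            mm_to_voxel(noisy.affine, np.asarray(truths[0].center_mm))
        ).astype(int))
        for method in ("Bon", "FDR", "Clst", "AMPLE"):
            act = br.apply_threshold(stat, method, ctx)
            assert act.active[center], method
            assert np.all(~act.active[~noisy.mask])
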