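"""GLM design, voxelwise fit, cluster rule, region series, refinement."""

import numpy as np
import pytest

from oisbold.glm_mapping import (build_design, fit_glm, fold_trials,
                                 interpolate_series, refine_design,
                                 region_timeseries, threshold_clusters)
from oisbold.synthetic_data import make_paradigm


def ols_oracle(X, y):
    """Independent normal-equations least squares."""
    return np.linalg.solve(X.T @ X, X.T @ y)


class TestDesign:
    def test_structure(self, paradigm):
        d = build_design(paradigm, 1.0)
        assert d.columns.shape == (2160, 3)
        assert np.all(d.columns[:60, 0] == 0.0)          # pre-stimulus baseline
        assert d.columns[:, 2].sum() == d.n_frames       # DC column of ones
        assert np.all(np.diff(d.columns[:, 1]) > 0)      # strict ramp

    def test_boxcar_active_frames(self, paradigm):
        d = build_design(paradigm, 1.0)
        per_trial = d.columns[60:130, 0].sum()
        assert per_trial == 16.0                          # 16 s at 1 Hz

    def test_kernel_convolution(self, paradigm):
        k = np.array([0.5, 0.3, 0.2])
        d = build_design(paradigm, 1.0, kernel=k)
        assert d.columns[60, 0] == pytest.approx(0.5)
        assert d.columns[61, 0] == pytest.approx(0.8)

    def test_invalid_rate(self, paradigm):
        with pytest.raises(ValueError):
            build_design(paradigm, 0.0)


class TestFit:
    def test_exact_linear_input_flags_zero_residual(self, paradigm):
        d = build_design(paradigm, 1.0)
        series = 2.0 * d.columns[:, 1] + 3.0
        res = fit_glm(series, d)
        assert res.betas[:, 0, 0] == pytest.approx([0.0, 2.0, 3.0], abs=1e-9)
        assert res.zero_residual[0, 0]
        assert np.isfinite(res.z).all()

    def test_betas_match_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        p = make_paradigm(n_trials=2, baseline_s=5, isi_s=10,
                          stim_duration_s=4, ois_prestim_s=1,
                          ois_trial_window_s=10)
        for _ in range(100):
            nf = rng.integers(10, 31)
            d = build_design(p, 1.0, n_frames=nf)
            y = rng.normal(size=nf)
            res = fit_glm(y, d)
            expect = ols_oracle(d.columns, y)
            assert np.allclose(res.betas[:, 0, 0], expect, rtol=1e-10,
                               atol=1e-12)

    def test_z_grows_with_sqrt_frames(self):
        rng = np.random.default_rng(3)
        p1 = make_paradigm(n_trials=15)
        p2 = make_paradigm(n_trials=30)
        zs = []
        for p in (p1, p2):
            d = build_design(p, 1.0)
            y = d.columns[:, 0] + rng.normal(size=d.n_frames)
            zs.append(fit_glm(y, d).z[0, 0])
        assert zs[1] / zs[0] == pytest.approx(np.sqrt(2.0), rel=0.2)

    def test_rank_deficient_design_rejected(self, paradigm):
        d = build_design(paradigm, 1.0)
        d.columns[:, 0] = d.columns[:, 2]
        with pytest.raises(ValueError, match="rank"):
            fit_glm(np.zeros(d.n_frames), d)


class TestClusters:
    def test_empty_map(self):
        pos, neg = threshold_clusters(np.zeros((8, 8)), 4.0, -2.0)
        assert not pos.any() and not neg.any()

    def test_four_voxel_component_excluded(self):
        z = np.zeros((8, 8))
        z[2:4, 2:4] = 10.0                     # 4 voxels, below the size rule
        pos, _ = threshold_clusters(z, 4.0, -2.0)
        assert not pos.any()

    def test_six_voxel_negative_component_retained(self):
        z = np.zeros((8, 8))
        z[1, 1:4] = -3.0
        z[2, 1:4] = -3.0
        _, neg = threshold_clusters(z, 4.0, -2.0)
        assert neg.sum() == 6

    def test_connectivity_choice(self):
        z = np.zeros((8, 8))                   # 6 voxels joined only diagonally
        z[[0, 1, 2, 3, 4, 5], [0, 1, 2, 3, 4, 5]] = 9.0
        pos4, _ = threshold_clusters(z, 4.0, -2.0, connectivity=4)
        pos8, _ = threshold_clusters(z, 4.0, -2.0, connectivity=8)
        assert not pos4.any()
        assert pos8.sum() == 6

    def test_size_rule_exhaustive_on_random_maps(self):
        from scipy import ndimage
        rng = np.random.default_rng(7)
        for _ in range(20):
            z = rng.normal(scale=3.0, size=(24, 24))
            pos, neg = threshold_clusters(z, 4.0, -2.0, min_cluster=6)
            assert not np.any(pos & neg)
            for mask, cond in ((pos, z > 4.0), (neg, z < -2.0)):
                assert np.all(cond[mask])
                lab, n = ndimage.label(mask)
                for i in range(1, n + 1):
                    assert (lab == i).sum() >= 6


class TestRegionSeries:
    def test_single_voxel_identity(self):
        series = np.arange(24.0).reshape(6, 2, 2)
        mask = np.zeros((2, 2), bool)
        mask[1, 0] = True
        assert np.array_equal(region_timeseries(series, mask), series[:, 1, 0])

    def test_constant_series(self):
        series = np.full((5, 3, 3), 2.5)
        mask = np.ones((3, 3), bool)
        assert np.all(region_timeseries(series, mask) == 2.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            region_timeseries(np.zeros((5, 2, 2)), np.zeros((2, 2), bool))

    def test_fold_window_length(self, paradigm):
        ts = np.zeros(2160)
        folded = fold_trials(ts, paradigm, 1.0)
        assert len(folded) == 70               # one ISI at the series rate

    def test_fold_and_mean_commute(self, paradigm):
        rng = np.random.default_rng(5)
        series = rng.normal(size=(2160, 3, 3))
        mask = np.ones((3, 3), bool)
        a = fold_trials(region_timeseries(series, mask), paradigm, 1.0)
        folded_stack = np.stack([fold_trials(series[:, i, j], paradigm, 1.0)
                                 for i in range(3) for j in range(3)])
        b = folded_stack.mean(axis=0)
        assert np.allclose(a, b, atol=1e-12)

    def test_interpolation_rate(self):
        ts = np.sin(np.linspace(0, 4 * np.pi, 71))
        up = interpolate_series(ts, 1.0, 8.0)
        assert len(up) == 561
        assert np.allclose(up[::8], ts, atol=1e-12)


class TestRefine:
    def test_boxcar_fixed_point_up_to_scale(self, paradigm):
        d = build_design(paradigm, 1.0)
        refined = refine_design(d, d.columns[:, 0].copy())
        r = refined.columns[:, 0]
        b = d.columns[:, 0]
        corr = np.corrcoef(r, b)[0, 1]
        assert corr > 0.999
        assert np.max(np.abs(r)) == pytest.approx(1.0)

    def test_refined_z_not_worse_on_refining_series(self, paradigm):
        rng = np.random.default_rng(2)
        d = build_design(paradigm, 1.0)
        kernel = np.exp(-np.arange(8) / 2.0)
        resp = np.convolve(d.columns[:, 0], kernel / kernel.sum())[:d.n_frames]
        y = resp + 0.5 * rng.normal(size=d.n_frames)
        z0 = fit_glm(y, d).z[0, 0]
        refined = refine_design(d, y)
        z1 = fit_glm(y, refined).z[0, 0]
        assert z1 >= z0

    def test_constant_series_rejected(self, paradigm):
        d = build_design(paradigm, 1.0)
        with pytest.raises(ValueError):
            refine_design(d, np.ones(d.n_frames))
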