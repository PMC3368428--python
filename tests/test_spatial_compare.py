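"""Smoothing, subsampling, template correlation, projective warping."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.transform import SimilarityTransform, resize, warp

from oisbold.spatial_compare import (AffineMatch, fit_projective_transform,
                                     match_template, projective_residuals,
                                     smooth_map, subsample_map, warp_image)


class TestSmooth:
    def test_constant_preserved(self):
        m = np.full((16, 16), 3.7)
        out = smooth_map(m, 489.0, 468.75)
        assert np.allclose(out, 3.7, atol=1e-12)

    def test_impulse_matches_closed_form(self):
        # EPI voxel 468.75 um, sigma 489 um -> ~1.04 px
        sigma = 489.0 / 468.75
        m = np.zeros((33, 33))
        m[16, 16] = 1.0
        out = smooth_map(m, 489.0, 468.75)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)   # kernel normalised
        r = int(4 * sigma + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        expected = np.outer(k1, k1)
        got = out[16 - r:16 + r + 1, 16 - r:16 + r + 1]
        assert np.allclose(got, expected, atol=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_map(np.zeros((4, 4)), -1.0, 80.0)


class TestSubsample:
    def test_identity_at_unit_scale(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(20, 20))
        assert np.allclose(subsample_map(m, 1.0), m, atol=1e-12)

    def test_dimension_contract(self):
        m = np.zeros((200, 200))
        assert subsample_map(m, 0.15).shape == (30, 30)

    def test_cubic_beats_bilinear_on_smooth_surface(self):
        y, x = np.mgrid[0:40, 0:40] / 40.0
        surface = np.sin(2 * np.pi * x) * np.cos(2 * np.pi * y)
        small_c = subsample_map(surface, 0.5)
        small_l = resize(surface, (20, 20), order=1, mode="reflect",
                         anti_aliasing=False)
        yy, xx = np.mgrid[0:20, 0:20]
        truth = np.sin(2 * np.pi * (xx * 39 / 19) / 40.0) \
            * np.cos(2 * np.pi * (yy * 39 / 19) / 40.0)
        err_c = np.abs(small_c - truth)[2:-2, 2:-2].max()
        err_l = np.abs(small_l - truth)[2:-2, 2:-2].max()
        assert err_c < err_l

    def test_too_small_output_rejected(self):
        with pytest.raises(ValueError):
            subsample_map(np.zeros((10, 10)), 0.1)


@pytest.fixture(scope="module")
def pattern():
    rng = np.random.default_rng(4)
    return ndimage.gaussian_filter(rng.normal(size=(64, 64)), 2.0)


class TestMatchTemplate:
    def test_exact_crop_self_match(self, pattern):
        tmpl = pattern[20:36, 24:40]
        m = match_template(tmpl, pattern, scale_grid=[1.0], angle_grid=[0.0])
        assert m.correlation == pytest.approx(1.0, abs=1e-9)
        assert (m.tx_px, m.ty_px) == (24.0, 20.0)

    def test_anticorrelated_crop(self, pattern):
        tmpl = -pattern[20:36, 24:40]
        m = match_template(tmpl, pattern, scale_grid=[1.0], angle_grid=[0.0])
        # the best positive correlation elsewhere is weak; the known
        # offset carries correlation -1
        from skimage.feature import match_template as zncc
        cc = zncc(pattern, tmpl)
        assert cc[20, 24] == pytest.approx(-1.0, abs=1e-9)
        assert m.correlation < 1.0

    def test_recovers_known_scale_and_rotation(self):
        rng = np.random.default_rng(9)
        template = ndimage.gaussian_filter(rng.normal(size=(80, 80)), 3.0)
        # target: template scaled 0.5, rotated 10 deg, embedded + noise SNR 10
        scaled = resize(template, (40, 40), order=3, mode="reflect",
                        anti_aliasing=True)
        c = (np.array(scaled.shape[::-1]) - 1) / 2.0
        tf = (SimilarityTransform(translation=-c)
              + SimilarityTransform(rotation=np.deg2rad(10.0))
              + SimilarityTransform(translation=c))
        rotated = warp(scaled, tf.inverse, order=3, mode="reflect")
        target = np.zeros((96, 96))
        target[30:70, 25:65] = rotated
        target += rng.normal(scale=rotated.std() / 10, size=target.shape)
        m = match_template(template, target,
                           scale_grid=np.arange(0.40, 0.61, 0.05),
                           angle_grid=np.arange(-20.0, 21.0, 5.0))
        assert m.scale == pytest.approx(0.5, abs=0.05)
        assert m.angle_deg == pytest.approx(10.0, abs=5.0)

    def test_intensity_invariance(self, pattern):
        tmpl = pattern[10:30, 10:30]
        m1 = match_template(tmpl, pattern, scale_grid=[1.0], angle_grid=[0.0])
        m2 = match_template(3.0 * tmpl + 7.0, 0.5 * pattern - 2.0,
                            scale_grid=[1.0], angle_grid=[0.0])
        assert m1.correlation == pytest.approx(m2.correlation, abs=1e-9)
        assert (m1.tx_px, m1.ty_px) == (m2.tx_px, m2.ty_px)

    def test_zero_variance_template_rejected(self):
        with pytest.raises(ValueError):
            match_template(np.ones((8, 8)), np.zeros((16, 16)))


class TestProjective:
    def test_identity_from_identity_pairs(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        H = fit_projective_transform(pts, pts)
        assert np.allclose(H, np.eye(3), atol=1e-9)
        assert projective_residuals(H, pts, pts).max() < 1e-9

    def test_four_generic_exact_pairs(self):
        rng = np.random.default_rng(1)
        src = np.array([[0, 0], [20, 1], [2, 18], [19, 21]], float)
        H_true = np.array([[1.1, 0.05, 2.0],
                           [-0.03, 0.95, -1.0],
                           [1e-3, -5e-4, 1.0]])
        ones = np.ones((4, 1))
        mapped = np.hstack([src, ones]) @ H_true.T
        dst = mapped[:, :2] / mapped[:, 2:3]
        H = fit_projective_transform(src, dst)
        assert projective_residuals(H, src, dst).max() < 1e-9

    def test_overdetermined_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        src = rng.uniform(0, 50, size=(8, 2))
        dst = src @ np.array([[0.9, 0.1], [-0.1, 1.05]]).T + [3.0, -2.0]
        dst += rng.normal(scale=0.1, size=dst.shape)
        H = fit_projective_transform(src, dst)
        # oracle: smallest eigenvector of A^T A from the DLT system
        n = len(src)
        A = np.zeros((2 * n, 9))
        x, y = src[:, 0], src[:, 1]
        xp, yp = dst[:, 0], dst[:, 1]
        A[0::2, 0], A[0::2, 1], A[0::2, 2] = x, y, 1.0
        A[0::2, 6], A[0::2, 7], A[0::2, 8] = -xp * x, -xp * y, -xp
        A[1::2, 3], A[1::2, 4], A[1::2, 5] = x, y, 1.0
        A[1::2, 6], A[1::2, 7], A[1::2, 8] = -yp * x, -yp * y, -yp
        w, v = np.linalg.eigh(A.T @ A)
        h = v[:, 0].reshape(3, 3)
        h /= h[2, 2]
        assert np.allclose(H, h, atol=1e-8)

    def test_too_few_or_degenerate_pairs(self):
        pts3 = np.zeros((3, 2))
        with pytest.raises(ValueError):
            fit_projective_transform(pts3, pts3)
        collinear = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.raises(ValueError):
            fit_projective_transform(collinear, collinear)

    def test_composition_chain(self):
        rng = np.random.default_rng(8)
        src = rng.uniform(0, 40, size=(6, 2))
        H1 = np.array([[1.05, 0.02, 1.0], [0.01, 0.98, -2.0], [1e-4, 2e-4, 1.0]])
        H2 = np.array([[0.97, -0.03, 0.5], [0.02, 1.02, 1.5], [-2e-4, 1e-4, 1.0]])

        def apply(H, p):
            q = np.hstack([p, np.ones((len(p), 1))]) @ H.T
            return q[:, :2] / q[:, 2:3]

        mid = apply(H1, src)
        dst = apply(H2, mid)
        Ha = fit_projective_transform(src, mid)
        Hb = fit_projective_transform(mid, dst)
        Hc = fit_projective_transform(src, dst)
        chained = apply(Hb, apply(Ha, src))
        direct = apply(Hc, src)
        assert np.allclose(chained, direct, atol=1e-6)


class TestWarp:
    def test_identity(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(12, 12))
        out = warp_image(img, np.eye(3), sentinel=0.0)
        assert np.allclose(out, img, atol=1e-9)

    def test_integer_translation_exact(self):
        rng = np.random.default_rng(3)
        img = rng.normal(size=(16, 16))
        H = np.eye(3)
        H[0, 2], H[1, 2] = 3.0, 5.0        # +3 px in x, +5 px in y
        out = warp_image(img, H, sentinel=np.nan)
        assert np.allclose(out[5:, 3:], img[:-5, :-3], atol=1e-9)
        assert np.isnan(out[:5]).all()

    def test_round_trip_bounded_interpolation_loss(self):
        y, x = np.mgrid[0:32, 0:32] / 32.0
        img = np.sin(3 * x) + np.cos(2 * y) + x * y
        H = np.array([[1.02, 0.03, 1.2], [-0.02, 0.99, -0.7],
                      [1e-4, -1e-4, 1.0]])
        fwd = warp_image(img, H, sentinel=np.nan)
        fwd_f = np.nan_to_num(fwd, nan=img.mean())
        back = warp_image(fwd_f, np.linalg.inv(H), sentinel=np.nan)
        inner = np.s_[4:-4, 4:-4]
        err = np.abs(back - img)[inner]
        err = err[np.isfinite(err)]
        assert err.max() < 0.02 * np.ptp(img)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            warp_image(np.zeros((4, 4)), np.zeros((3, 3)))


def test_affine_match_validation():
    with pytest.raises(ValueError):
        AffineMatch(scale=-1.0, angle_deg=0, tx_px=0, ty_px=0, correlation=0.5)
    with pytest.raises(ValueError):
        AffineMatch(scale=1.0, angle_deg=0, tx_px=0, ty_px=0, correlation=1.5)
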