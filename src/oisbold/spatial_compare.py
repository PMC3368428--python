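"""Spatial concordance between predicted and measured activation maps.

The predicted-BOLD parameter map (optical resolution) is smoothed,
cubically subsampled towards the EPI resolution and matched to the
measured fMRI parameter map by exhaustive search over uniform scale,
rotation and translation of the zero-mean normalised cross-correlation.
Histology-style registration from fiducial points is provided as a
least-squares projective (homography) fit and inverse-mapped warping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template as _zncc
from skimage.transform import (ProjectiveTransform, SimilarityTransform,
                               resize, warp)

__all__ = [
    "AffineMatch",
    "smooth_map",
    "subsample_map",
    "match_template",
    "fit_projective_transform",
    "warp_image",
    "save_match_json",
]


@dataclass
class AffineMatch:
    scale: float
    angle_deg: float
    tx_px: float
    ty_px: float
    correlation: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not -1.0 - 1e-9 <= self.correlation <= 1.0 + 1e-9:
            raise ValueError("correlation must lie in [-1, 1]")

    def to_dict(self):
        return {"scale": self.scale, "angle_deg": self.angle_deg,
                "tx_px": self.tx_px, "ty_px": self.ty_px,
                "correlation": self.correlation}


def smooth_map(m: np.ndarray, sigma_um: float, pixel_um: float) -> np.ndarray:
    """2-D Gaussian smoothing, sigma given in micrometres."""
    if sigma_um < 0:
        raise ValueError("sigma_um must be non-negative")
    if sigma_um == 0:
        return np.asarray(m, dtype=float).copy()
    return ndimage.gaussian_filter(np.asarray(m, dtype=float),
                                   sigma_um / pixel_um, mode="reflect")


def subsample_map(m: np.ndarray, scale: float) -> np.ndarray:
    """Cubic-interpolated resampling to round(dim * scale)."""
    if not 0 < scale <= 1:
        raise ValueError("scale must lie in (0, 1]")
    m = np.asarray(m, dtype=float)
    out_shape = tuple(int(round(d * scale)) for d in m.shape)
    if min(out_shape) < 2:
        raise ValueError("output dimension below 2")
    if out_shape == m.shape:
        return m.copy()
    return resize(m, out_shape, order=3, mode="reflect", anti_aliasing=False)


def _transform_template(template: np.ndarray, scale: float,
                        angle_deg: float) -> np.ndarray:
    """Scale then rotate the template about its centre; crop to the
    central region that stays clear of rotation fill-in."""
    scaled = template if scale == 1.0 else resize(
        template, tuple(max(2, int(round(d * scale))) for d in template.shape),
        order=3, mode="reflect", anti_aliasing=scale < 1)
    if angle_deg != 0.0:
        c = (np.array(scaled.shape[::-1]) - 1) / 2.0
        tf = (SimilarityTransform(translation=-c)
              + SimilarityTransform(rotation=np.deg2rad(angle_deg))
              + SimilarityTransform(translation=c))
        scaled = warp(scaled, tf.inverse, order=1, mode="constant",
                      cval=np.nan, preserve_range=True)
    # central crop: valid for rotations up to ~20 degrees
    my = int(np.ceil(scaled.shape[0] * 0.15)) if angle_deg else 0
    mx = int(np.ceil(scaled.shape[1] * 0.15)) if angle_deg else 0
    out = scaled[my:scaled.shape[0] - my or None, mx:scaled.shape[1] - mx or None]
    return np.nan_to_num(out, nan=float(np.nanmean(out)))


def match_template(template: np.ndarray, target: np.ndarray,
                   scale_grid=None, angle_grid=None, step_px: int = 1,
                   min_size_px: int = 6) -> AffineMatch:
    """Exhaustive affine template matching by normalised correlation.

    For every (scale, angle) on the grids the template is rescaled and
    rotated about its centre, and the zero-mean normalised
    cross-correlation against the target is maximised exhaustively over
    integer translations; the overall argmax is returned.  Default
    grids bracket the expected optics-to-EPI scale (0.10-0.25 step
    0.01, angles -15..15 degrees step 1).
    """
    template = np.asarray(template, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.ptp(template) == 0:
        raise ValueError("template has zero variance")
    scale_grid = (np.round(np.arange(0.10, 0.2501, 0.01), 4)
                  if scale_grid is None else np.asarray(scale_grid, float))
    angle_grid = (np.arange(-15.0, 15.1, 1.0)
                  if angle_grid is None else np.asarray(angle_grid, float))
    best = None
    for s in scale_grid:
        for a in angle_grid:
            cand = _transform_template(template, float(s), float(a))
            if np.ptp(cand) == 0:
                continue
            if cand.shape[0] > target.shape[0] or cand.shape[1] > target.shape[1]:
                continue
            if min(cand.shape) < min_size_px:
                continue    # too small to carry discriminating structure
            cc = _zncc(target, cand)
            if step_px > 1:
                cc = cc[::step_px, ::step_px]
            ij = np.unravel_index(int(np.argmax(cc)), cc.shape)
            val = float(cc[ij])
            if best is None or val > best.correlation:
                best = AffineMatch(float(s), float(a),
                                   float(ij[1] * step_px), float(ij[0] * step_px),
                                   val)
    if best is None:
        raise ValueError("template larger than target at every searched scale")
    return best


def fit_projective_transform(src_points, dst_points) -> np.ndarray:
    """Least-squares homography (3x3, normalised h33 = 1) from point pairs.

    Four exact pairs define the projection exactly (zero residual); more
    pairs give the best fit in the least-squares sense.  Residuals are
    available via :func:`projective_residuals`.
    """
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("point sets must both be (n, 2)")
    if len(src) < 4:
        raise ValueError("at least 4 point pairs are required")
    # direct linear transform: rows of the homogeneous system A h = 0
    n = len(src)
    A = np.zeros((2 * n, 9))
    x, y = src[:, 0], src[:, 1]
    xp, yp = dst[:, 0], dst[:, 1]
    A[0::2, 0] = x
    A[0::2, 1] = y
    A[0::2, 2] = 1.0
    A[0::2, 6] = -xp * x
    A[0::2, 7] = -xp * y
    A[0::2, 8] = -xp
    A[1::2, 3] = x
    A[1::2, 4] = y
    A[1::2, 5] = 1.0
    A[1::2, 6] = -yp * x
    A[1::2, 7] = -yp * y
    A[1::2, 8] = -yp
    _, s, vt = np.linalg.svd(A)
    if s[-2] < 1e-9 * max(s[0], 1.0):     # solution space not 1-D
        raise ValueError("degenerate point configuration")
    H = vt[-1].reshape(3, 3)
    if not np.all(np.isfinite(H)) or abs(np.linalg.det(H)) < 1e-12 \
            or abs(H[2, 2]) < 1e-12:
        raise ValueError("degenerate point configuration")
    return H / H[2, 2]


def projective_residuals(H: np.ndarray, src_points, dst_points) -> np.ndarray:
    src = np.asarray(src_points, dtype=float)
    dst = np.asarray(dst_points, dtype=float)
    ones = np.ones((len(src), 1))
    mapped = (np.hstack([src, ones]) @ H.T)
    mapped = mapped[:, :2] / mapped[:, 2:3]
    return np.linalg.norm(mapped - dst, axis=1)


def warp_image(image: np.ndarray, h: np.ndarray, output_shape=None,
               sentinel: float = np.nan) -> np.ndarray:
    """Inverse-mapped bilinear warping; out-of-domain pixels = sentinel."""
    h = np.asarray(h, dtype=float)
    if h.shape != (3, 3) or abs(np.linalg.det(h)) < 1e-12:
        raise ValueError("homography must be an invertible 3x3 matrix")
    tf = ProjectiveTransform(matrix=h)
    return warp(np.asarray(image, dtype=float), tf.inverse,
                output_shape=output_shape, order=1, mode="constant",
                cval=sentinel, preserve_range=True)


def save_match_json(path, match: AffineMatch) -> None:
    with open(path, "w") as f:
        json.dump(match.to_dict(), f, indent=2)
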