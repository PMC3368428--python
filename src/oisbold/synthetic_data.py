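"""Synthetic study data: paradigm, haemodynamics, optical stacks, fMRI.

Emulates a whisker-stimulation imaging session: a 60 s baseline then 30
electrical stimulation trials (16 s at 5 Hz) separated by 70 s, imaged
optically at 8 Hz per wavelength over a ~6 mm window at 80 um pixels,
with concurrent 64x64 EPI BOLD at TR 1 s / TE 12 ms over a 30 mm FOV.

Ground truth is a pair of disc regions: the activated barrel region
(total haemoglobin up, deoxyhaemoglobin down, with an early deoxy dip
and a post-stimulus lobe) and a surround region with the reversed sign
structure, which is what generates a negative BOLD signal.  The
haemodynamic field is the deterministic trial-locked response over one
inter-stimulus window; measurement noise enters downstream, in the
rendered attenuation stack and the fMRI series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
import yaml

from .containers import FMRISeries, HaemodynamicField, MultiWavelengthStack
from .mr_attenuation import BoldLUT, MRSimConfig
from .photon_transport import OpticalConstants, PathLengthLUT, TissueModel
from .spectroscopy import BaselineState, baseline_concentrations, _layer_weights

__all__ = [
    "StimulusParadigm",
    "RegionSpec",
    "make_paradigm",
    "default_regions",
    "generate_haemodynamics",
    "render_wavelength_stack",
    "generate_fmri",
    "default_light_mua_grid",
    "save_paradigm_yaml",
    "load_paradigm_yaml",
    "export_stack_tiff",
]


@dataclass(frozen=True)
class StimulusParadigm:
    """Timing of the stimulation session (all durations seconds)."""

    baseline_s: float = 60.0
    n_trials: int = 30
    stim_duration_s: float = 16.0
    isi_s: float = 70.0
    ois_trial_window_s: float = 70.0
    ois_prestim_s: float = 10.0
    ois_rate_hz: float = 8.0
    fmri_tr_s: float = 1.0

    def __post_init__(self):
        for name in ("baseline_s", "stim_duration_s", "isi_s",
                     "ois_trial_window_s", "ois_prestim_s", "ois_rate_hz",
                     "fmri_tr_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"paradigm field {name} must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.ois_trial_window_s < self.stim_duration_s + self.ois_prestim_s:
            raise ValueError("trial window must cover prestim + stimulation")

    @property
    def onsets_s(self) -> np.ndarray:
        """Stimulus onset times: baseline + k * ISI."""
        return self.baseline_s + self.isi_s * np.arange(self.n_trials)

    @property
    def total_duration_s(self) -> float:
        return self.baseline_s + self.n_trials * self.isi_s

    @property
    def n_fmri_frames(self) -> int:
        return int(round(self.total_duration_s / self.fmri_tr_s))


def make_paradigm(**overrides) -> StimulusParadigm:
    """Build a paradigm from the study defaults plus keyword overrides."""
    valid = set(StimulusParadigm.__dataclass_fields__)
    for k, v in overrides.items():
        if k not in valid:
            raise ValueError(f"unknown paradigm field {k!r}")
        if not (isinstance(v, (int, float)) and v > 0):
            raise ValueError(f"paradigm field {k!r} must be a positive number")
    return StimulusParadigm(**overrides)


@dataclass(frozen=True)
class RegionSpec:
    """A disc-shaped response region and its haemodynamic shape."""

    center_px: tuple[float, float]        # (y, x)
    radius_px: float
    polarity: str                         # "positive" | "negative"
    hbt_peak_uM: float
    hbr_peak_uM: float
    peak_time_s: float = 4.0
    plateau_fraction: float = 0.5
    dip_amplitude_uM: float = 0.0
    overshoot_amplitude_uM: float = 0.0

    def __post_init__(self):
        if self.polarity == "positive":
            if not (self.hbt_peak_uM > 0 and self.hbr_peak_uM < 0):
                raise ValueError("positive region needs hbt_peak > 0 > hbr_peak")
        elif self.polarity == "negative":
            if not (self.hbt_peak_uM < 0 and self.hbr_peak_uM > 0):
                raise ValueError("negative region needs hbt_peak < 0 < hbr_peak")
        else:
            raise ValueError("polarity must be 'positive' or 'negative'")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")


def default_regions(grid: int = 72) -> tuple[RegionSpec, RegionSpec]:
    """Activated barrel disc plus an anterior/medial surround disc."""
    c = grid / 2.0
    pos = RegionSpec((c + grid * 0.10, c + grid * 0.10), grid * 0.12,
                     "positive", hbt_peak_uM=10.0, hbr_peak_uM=-5.0,
                     peak_time_s=4.0, plateau_fraction=0.5,
                     dip_amplitude_uM=0.5, overshoot_amplitude_uM=1.0)
    neg = RegionSpec((c - grid * 0.22, c - grid * 0.22), grid * 0.10,
                     "negative", hbt_peak_uM=-5.0, hbr_peak_uM=2.5,
                     peak_time_s=8.0, plateau_fraction=0.7,
                     dip_amplitude_uM=0.0, overshoot_amplitude_uM=0.5)
    return pos, neg


# ---------------------------------------------------------------------------
# response kernels
# ---------------------------------------------------------------------------

def _gamma_variate(t, peak_s, shape=3.0):
    """Unit-peak gamma-variate lobe, zero for t <= 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_s
    out[pos] = x ** shape * np.exp(shape * (1.0 - x))
    return out


def _response_curve(t, stim_s, peak_time_s, plateau_fraction):
    """Peak-then-plateau stimulus response, unit peak.

    A transient gamma lobe at ``peak_time_s`` rides on a sustained
    component (boxcar convolved with a fast gamma kernel) that holds
    ``plateau_fraction`` of the peak until stimulus offset.
    """
    dt = t[1] - t[0] if len(t) > 1 else 0.125
    box = ((t >= 0) & (t < stim_s)).astype(float)
    kt = np.arange(0, 8.0, dt)
    kern = _gamma_variate(kt, peak_s=1.5)
    kern /= kern.sum()
    sustained = np.convolve(box, kern)[:len(t)]
    if sustained.max() > 0:
        sustained = sustained / sustained.max()
    transient = _gamma_variate(t, peak_time_s)
    r = plateau_fraction * sustained + (1.0 - plateau_fraction) * transient
    m = r.max()
    return r / m if m > 0 else r


def region_timecourses(region: RegionSpec, t: np.ndarray, stim_s: float):
    """(d_hbt(t), d_hbr(t)) for one region, uM."""
    main = _response_curve(t, stim_s, region.peak_time_s,
                           region.plateau_fraction)
    hbt = region.hbt_peak_uM * main
    hbr = region.hbr_peak_uM * main
    if region.dip_amplitude_uM:
        # early deoxy transient of the opposite sign to the main deflection
        hbr = hbr - np.sign(region.hbr_peak_uM) \
            * region.dip_amplitude_uM * _gamma_variate(t, 1.2, shape=4.0)
    if region.overshoot_amplitude_uM:
        # post-stimulus lobe: extra deoxy washout after offset
        hbr = hbr - region.overshoot_amplitude_uM \
            * _gamma_variate(t - stim_s, 4.0, shape=3.0)
    return hbt, hbr


def _disc_amplitude(shape, center, radius, taper_px=1.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    d = np.hypot(yy - center[0], xx - center[1])
    out = np.where(d <= radius, 1.0,
                   np.exp(-0.5 * ((d - radius) / taper_px) ** 2))
    out[d > radius + 4 * taper_px] = 0.0
    return out


def generate_haemodynamics(paradigm: StimulusParadigm,
                           regions, grid: int = 72,
                           seed: int = 0, pixel_um: float = 80.0
                           ) -> HaemodynamicField:
    """Trial-locked ground-truth haemodynamic field over one ISI window.

    Time runs over ``ois_trial_window_s`` at ``ois_rate_hz`` with the
    stimulus onset at ``ois_prestim_s``.  Regions must be disjoint discs
    inside the grid; the output is exactly zero outside them and is a
    pure function of its inputs (the generator itself is noise free).
    """
    shape = (grid, grid) if np.isscalar(grid) else tuple(grid)
    nt = int(round(paradigm.ois_trial_window_s * paradigm.ois_rate_hz))
    t = np.arange(nt) / paradigm.ois_rate_hz - paradigm.ois_prestim_s
    d_hbt = np.zeros((nt, *shape))
    d_hbr = np.zeros((nt, *shape))
    cover = np.zeros(shape, dtype=int)
    for reg in regions:
        cy, cx = reg.center_px
        if (cy - reg.radius_px < 0 or cy + reg.radius_px > shape[0] - 1
                or cx - reg.radius_px < 0 or cx + reg.radius_px > shape[1] - 1):
            raise ValueError("region extends beyond the grid")
        amp = _disc_amplitude(shape, reg.center_px, reg.radius_px)
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        cover += (np.hypot(yy - reg.center_px[0], xx - reg.center_px[1])
                  <= reg.radius_px).astype(int)
        if np.any(cover > 1):
            raise ValueError("regions overlap")
        hbt_t, hbr_t = region_timecourses(reg, t, paradigm.stim_duration_s)
        d_hbt += hbt_t[:, None, None] * amp[None]
        d_hbr += hbr_t[:, None, None] * amp[None]
    return HaemodynamicField.from_components(d_hbt - d_hbr, d_hbr,
                                             rate_hz=paradigm.ois_rate_hz,
                                             pixel_um=pixel_um)


# ---------------------------------------------------------------------------
# forward optical rendering
# ---------------------------------------------------------------------------

def default_light_mua_grid() -> np.ndarray:
    """mu_a grid (mm^-1) covering the four bands at Y0 from 30 to 90%."""
    return np.linspace(0.3, 1.6, 14)


def render_wavelength_stack(field: HaemodynamicField, tissue: TissueModel,
                            lut: PathLengthLUT, optics: OpticalConstants,
                            noise_sd: float = 0.0, seed: int = 0,
                            baseline: BaselineState | None = None,
                            layer_profile=None) -> MultiWavelengthStack:
    """Forward Beer-Lambert rendering of a field into attenuation.

    A(band) = sum_l L_l(band, mu_a,l) * dmu_a,l with the concentration
    change distributed over layers by ``layer_profile`` (default: the
    partial-path-proportional weights the inversion also uses).
    Gaussian noise of ``noise_sd`` (attenuation units) is added in the
    log domain, matching where the inversion operates.
    """
    if baseline is None:
        baseline = baseline_concentrations(tissue, optics)
    w = (_layer_weights(lut, baseline) if layer_profile is None
         else np.asarray(layer_profile, dtype=float))
    if w.shape != (lut.n_layers,) or not np.isclose(w.sum(), 1.0):
        raise ValueError("layer_profile must have one weight per layer, sum 1")
    eps = optics.band_extinctions()
    nb = optics.n_bands
    A = np.empty((nb, *field.shape))
    dmu_flat = lambda b: (eps[b, 0] * field.d_hbo2 + eps[b, 1] * field.d_hbr)
    for b in range(nb):
        dmu = dmu_flat(b)
        Ab = np.zeros(field.shape)
        for l in range(lut.n_layers):
            mua_l = baseline.mua0[b, l] + w[l] * dmu
            if mua_l.min() < lut.mua_grid[0] or mua_l.max() > lut.mua_grid[-1]:
                bad = np.unravel_index(
                    int(np.argmax((mua_l < lut.mua_grid[0])
                                  | (mua_l > lut.mua_grid[-1]))), mua_l.shape)
                raise ValueError(
                    f"mu_a outside LUT range at band {optics.bands_nm[b][0]:.0f}"
                    f" nm, pixel {bad}")
            L = np.interp(mua_l, lut.mua_grid, lut.pathlength[b, :, l])
            Ab += L * w[l] * dmu
        A[b] = Ab
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    return MultiWavelengthStack(A, tuple(optics.bands_nm),
                                rate_hz=field.rate_hz, pixel_um=field.pixel_um)


# ---------------------------------------------------------------------------
# synthetic fMRI measurement arm
# ---------------------------------------------------------------------------

def generate_fmri(field: HaemodynamicField, baseline: BaselineState,
                  mr: MRSimConfig, bold_lut: BoldLUT,
                  noise_sd: float = 0.003, seed: int = 0,
                  paradigm: StimulusParadigm | None = None,
                  embed_offset: tuple[int, int] = (24, 26),
                  baseline_signal: float = 100.0,
                  drift_fraction: float = 0.0) -> FMRISeries:
    """Synthesise the EPI measurement from the ground-truth field.

    The field's BOLD forward prediction (mid-range vessel radius) is
    resampled to the EPI pixel size, embedded into the 30 mm FOV at
    ``embed_offset``, tiled over the thirty trials on top of the 60 s
    baseline, decimated to TR, scaled onto a constant baseline signal
    and corrupted with i.i.d. Gaussian noise (optionally plus a linear
    drift, since the analysis design matrix carries a ramp).
    """
    from skimage.transform import resize

    from .mr_attenuation import predict_bold

    paradigm = paradigm or make_paradigm()
    pred = predict_bold(field, baseline, bold_lut, mr)
    bold8 = pred.central                                   # (nt, gy, gx)
    # spatial: optical pixels -> EPI pixels
    epi_px_um = 30.0 * 1000 / 64
    m = max(2, int(round(field.shape[1] * field.pixel_um / epi_px_um)))
    small = resize(bold8, (bold8.shape[0], m, m), order=3,
                   anti_aliasing=True, mode="reflect")
    # temporal: tile the trial-locked window across the paradigm at 8 Hz
    rate = paradigm.ois_rate_hz
    n8 = int(round(paradigm.total_duration_s * rate))
    full = np.zeros((n8, m, m))
    win = small.shape[0]
    for onset in paradigm.onsets_s:
        i0 = int(round((onset - paradigm.ois_prestim_s) * rate))
        j0 = max(i0, 0)
        full[j0:min(i0 + win, n8)] += small[j0 - i0:min(i0 + win, n8) - i0]
    # decimate to TR by block averaging
    per_tr = int(round(paradigm.fmri_tr_s * rate))
    n_tr = paradigm.n_fmri_frames
    full = full[:n_tr * per_tr].reshape(n_tr, per_tr, m, m).mean(axis=1)
    data = np.full((n_tr, 64, 64), baseline_signal)
    oy, ox = embed_offset
    data[:, oy:oy + m, ox:ox + m] *= (1.0 + full)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd * baseline_signal, size=data.shape)
    if drift_fraction:
        ramp = np.linspace(0.0, drift_fraction * baseline_signal, n_tr)
        data = data + ramp[:, None, None]
    return FMRISeries(data, tr_s=paradigm.fmri_tr_s, fov_mm=30.0, te_s=mr.te_s)


# ---------------------------------------------------------------------------
# persistence helpers
# ---------------------------------------------------------------------------

def save_paradigm_yaml(path, p: StimulusParadigm) -> None:
    with open(path, "w") as f:
        yaml.safe_dump({k: getattr(p, k)
                        for k in StimulusParadigm.__dataclass_fields__}, f)


def load_paradigm_yaml(path) -> StimulusParadigm:
    with open(path) as f:
        return make_paradigm(**yaml.safe_load(f))


def export_stack_tiff(prefix, stack: MultiWavelengthStack) -> list:
    """One multi-page TIFF per wavelength band; returns written paths."""
    paths = []
    for b, (c, _) in enumerate(stack.bands_nm):
        p = f"{prefix}_{int(round(c))}nm.tif"
        tifffile.imwrite(p, stack.attenuation[b].astype(np.float32))
        paths.append(p)
    return paths
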