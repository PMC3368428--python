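"""End-to-end orchestration: generate -> LUTs -> invert -> predict -> map.

A run generates ground-truth haemodynamics (positive barrel region +
negative surround), renders the four-wavelength stack through the
layered tissue (positive changes superficial, negative changes deep),
synthesises the concurrent EPI measurement from the same truth, then
analyses the stack twice - once with the homogeneous and once with the
heterogeneous tissue model - predicts BOLD from each analysis, maps
activations with the two-pass GLM and compares predicted and measured
time series and maps.  The summary numbers are the Pearson
correlation and regression gradient of prediction on measurement per
region, plus the affine template match of the spatial maps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import glm_mapping as glm
from . import spatial_compare as spatial
from .containers import FMRISeries, HaemodynamicField
from .mr_attenuation import MRSimConfig, build_bold_lut, predict_bold
from .photon_transport import OpticalConstants, TissueModel, build_lut
from .spectroscopy import baseline_concentrations, plsa_invert
from .synthetic_data import (StimulusParadigm, default_light_mua_grid,
                             default_regions, generate_fmri,
                             generate_haemodynamics, make_paradigm,
                             render_wavelength_stack)

__all__ = ["GLMConfig", "CompareConfig", "RunConfig", "ComparisonReport",
           "compare_timeseries", "run_pipeline"]

log = logging.getLogger("oisbold")


@dataclass(frozen=True)
class GLMConfig:
    z_pos: float = 4.0
    z_neg: float = -2.0
    min_cluster: int = 6
    connectivity: int = 4

    def __post_init__(self):
        if not (self.z_pos > 0 > self.z_neg):
            raise ValueError("GLM thresholds need z_pos > 0 > z_neg")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be >= 1")


@dataclass(frozen=True)
class CompareConfig:
    sigma_um: float = 489.0
    scale_lo: float = 0.10
    scale_hi: float = 0.25
    scale_step: float = 0.01
    angle_lo: float = -15.0
    angle_hi: float = 15.0
    angle_step: float = 1.0

    def scale_grid(self):
        return np.round(np.arange(self.scale_lo, self.scale_hi + 1e-9,
                                  self.scale_step), 6)

    def angle_grid(self):
        return np.arange(self.angle_lo, self.angle_hi + 1e-9, self.angle_step)


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible end-to-end run needs."""

    paradigm: StimulusParadigm = field(default_factory=make_paradigm)
    grid: int = 72
    seed: int = 0
    blood_hbt_uM: float = 104.0 / 0.06
    light_n_photons: int = 20_000
    mr: MRSimConfig = field(default_factory=lambda: MRSimConfig(n_protons=4000))
    glm: GLMConfig = field(default_factory=GLMConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    optical_noise_sd: float = 0.0
    fmri_noise_sd: float = 0.003
    outdir: str | None = None

    def content_hash(self) -> str:
        # the output directory is not part of the scientific content
        payload = repr(dataclasses.replace(self, outdir=None))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @staticmethod
    def reduced(seed: int = 0, **kw) -> "RunConfig":
        """Smaller numerical settings for quick runs; same study design."""
        defaults = dict(grid=48, seed=seed, light_n_photons=8000,
                        mr=MRSimConfig(n_protons=1500))
        defaults.update(kw)
        return RunConfig(**defaults)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as f:
            doc = yaml.safe_load(f) or {}
        kw = {}
        if "paradigm" in doc:
            kw["paradigm"] = make_paradigm(**doc.pop("paradigm"))
        if "mr" in doc:
            kw["mr"] = MRSimConfig(**doc.pop("mr"))
        if "glm" in doc:
            kw["glm"] = GLMConfig(**doc.pop("glm"))
        if "compare" in doc:
            kw["compare"] = CompareConfig(**doc.pop("compare"))
        kw.update(doc)
        return RunConfig(**kw)


@dataclass
class ComparisonReport:
    """Prediction-vs-measurement summary of one run."""

    timeseries: dict            # model -> region -> {correlation, gradient, coverage}
    spatial: dict               # model -> AffineMatch dict
    qc: dict
    config_hash: str

    def to_dict(self):
        return {"timeseries": self.timeseries, "spatial": self.spatial,
                "qc": self.qc, "config_hash": self.config_hash}

    def save(self, path):
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2, sort_keys=True)


def compare_timeseries(predicted, measured):
    """Pearson correlation and OLS gradient of prediction on measurement."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if len(p) < 3:
        raise ValueError("need at least 3 points")
    if np.var(p) == 0 or np.var(m) == 0:
        raise ValueError("zero-variance series")
    corr = float(np.corrcoef(p, m)[0, 1])
    mm = m - m.mean()
    gradient = float((mm @ (p - p.mean())) / (mm @ mm))
    return corr, gradient


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _depth_profile(tissue: TissueModel, z_lo: float, z_hi: float) -> np.ndarray:
    """Layer weights proportional to overlap with the depth band [z_lo, z_hi] mm."""
    w = np.array([max(0.0, min(l.z_bottom_mm, z_hi) - max(l.z_top_mm, z_lo))
                  for l in tissue.layers])
    if w.sum() == 0:
        raise ValueError("depth band does not intersect the tissue model")
    return w / w.sum()


def _trial_paradigm(p: StimulusParadigm) -> StimulusParadigm:
    """One-trial paradigm matching the trial-locked optical window."""
    return StimulusParadigm(
        baseline_s=p.ois_prestim_s, n_trials=1, stim_duration_s=p.stim_duration_s,
        isi_s=p.ois_trial_window_s - p.ois_prestim_s,
        ois_trial_window_s=p.ois_trial_window_s, ois_prestim_s=p.ois_prestim_s,
        ois_rate_hz=p.ois_rate_hz, fmri_tr_s=p.fmri_tr_s)


def _two_pass_glm(stack3d, design, cfg: GLMConfig):
    """Boxcar pass for region finding, refined pass for the maps."""
    first = glm.fit_glm(stack3d, design, cfg.z_pos, cfg.z_neg,
                        cfg.min_cluster, cfg.connectivity)
    mask = first.positive_mask | first.negative_mask
    if not mask.any():
        # fall back to the strongest |z| decile so refinement stays defined
        thr = np.quantile(np.abs(first.z), 0.9)
        mask = np.abs(first.z) >= thr
    series = glm.region_timeseries(stack3d, mask)
    refined = glm.refine_design(design, series)
    second = glm.fit_glm(stack3d, refined, cfg.z_pos, cfg.z_neg,
                         cfg.min_cluster, cfg.connectivity)
    return second, refined


def _fractional_bold(series: FMRISeries, mask, paradigm) -> np.ndarray:
    """Region series as fractional change over the initial baseline."""
    ts = series.data[:, mask].mean(axis=1)
    n0 = int(round(paradigm.baseline_s / series.tr_s))
    return ts / ts[:n0].mean() - 1.0


# ---------------------------------------------------------------------------
# the run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> ComparisonReport:
    """Execute all stages with both tissue models and build the report.

    Identical config (including seeds) reproduces the report bit for
    bit.  Stage failures raise with a stage tag; partial outputs are
    kept with a FAILED marker when an output directory is configured.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    stage = "validate"
    try:
        return _run(config, outdir, timings)
    except Exception as exc:
        stage = getattr(exc, "_stage", stage)
        if outdir:
            (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc


def _tag(stage):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s", stage)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, et, ev, tb):
            if ev is not None:
                ev._stage = stage
            return False
    return _Ctx()


def _run(config: RunConfig, outdir, timings) -> ComparisonReport:
    p = config.paradigm
    seed = config.seed
    optics = OpticalConstants()
    tis_hom = TissueModel.homogeneous()
    tis_het = TissueModel.heterogeneous()
    models = {"homogeneous": tis_hom, "heterogeneous": tis_het}
    qc = {}

    with _tag("simulate"):
        t0 = time.perf_counter()
        regions = default_regions(config.grid)
        truth = generate_haemodynamics(p, regions, grid=config.grid, seed=seed)
        timings["simulate"] = time.perf_counter() - t0

    with _tag("lut-light"):
        t0 = time.perf_counter()
        mua_grid = default_light_mua_grid()
        luts = {name: build_lut(t, optics, mua_grid,
                                n_photons=config.light_n_photons, seed=seed + 11)
                for name, t in models.items()}
        timings["lut-light"] = time.perf_counter() - t0

    with _tag("render"):
        t0 = time.perf_counter()
        baselines = {name: baseline_concentrations(t, optics, config.blood_hbt_uM)
                     for name, t in models.items()}
        # truth rendered through the heterogeneous tissue: the positive
        # region occupies the superficial 0-1 mm; the negative-region
        # response extends deeper (0-2 mm, thickness-proportional), which
        # is what makes its optical recovery depth-limited
        masks = {}
        stacks = []
        for reg, band in zip(regions, ((0.0, 1.0), (0.0, 2.0))):
            amp = np.zeros((config.grid, config.grid), bool)
            yy, xx = np.mgrid[0:config.grid, 0:config.grid]
            amp = np.hypot(yy - reg.center_px[0], xx - reg.center_px[1]) \
                <= reg.radius_px + 4
            masks[reg.polarity] = amp
            sub = HaemodynamicField.from_components(
                truth.d_hbo2 * amp, truth.d_hbr * amp,
                rate_hz=truth.rate_hz, pixel_um=truth.pixel_um)
            stacks.append(render_wavelength_stack(
                sub, tis_het, luts["heterogeneous"], optics, noise_sd=0.0,
                baseline=baselines["heterogeneous"],
                layer_profile=_depth_profile(tis_het, *band)))
        stack = stacks[0]
        stack.attenuation = stack.attenuation + stacks[1].attenuation
        if config.optical_noise_sd > 0:
            rng = np.random.default_rng(seed + 23)
            stack.attenuation = stack.attenuation + rng.normal(
                0.0, config.optical_noise_sd, size=stack.attenuation.shape)
        timings["render"] = time.perf_counter() - t0

    with _tag("lut-mr"):
        t0 = time.perf_counter()
        bold_lut = build_bold_lut(config.mr, seed=seed + 31)
        timings["lut-mr"] = time.perf_counter() - t0

    with _tag("measure-fmri"):
        t0 = time.perf_counter()
        fmri = generate_fmri(truth, baselines["homogeneous"], config.mr,
                             bold_lut, noise_sd=config.fmri_noise_sd,
                             seed=seed + 41, paradigm=p)
        timings["measure-fmri"] = time.perf_counter() - t0

    # --- analyses with both tissue models -------------------------------
    trial_p = _trial_paradigm(p)
    design8 = glm.build_design(trial_p, p.ois_rate_hz,
                               n_frames=truth.shape[0])
    design1 = glm.build_design(p, 1.0 / p.fmri_tr_s)
    cfg_glm = config.glm

    with _tag("glm-fmri"):
        t0 = time.perf_counter()
        fmri_glm, _ = _two_pass_glm(fmri.data, design1, cfg_glm)
        qc["fmri_pos_voxels"] = int(fmri_glm.positive_mask.sum())
        qc["fmri_neg_voxels"] = int(fmri_glm.negative_mask.sum())
        timings["glm-fmri"] = time.perf_counter() - t0

    ts_report = {}
    spatial_report = {}
    predictions = {}
    for name, tis in models.items():
        with _tag(f"invert-{name}"):
            t0 = time.perf_counter()
            res = plsa_invert(stack, luts[name], baselines[name], optics=optics)
            qc[f"plsa_nonconverged_{name}"] = int((~res.converged).sum())
            timings[f"invert-{name}"] = time.perf_counter() - t0
        with _tag(f"predict-{name}"):
            t0 = time.perf_counter()
            pred = predict_bold(res.field, baselines[name], bold_lut, config.mr)
            predictions[name] = pred
            qc[f"clipped_fraction_{name}"] = pred.clipped_fraction
            timings[f"predict-{name}"] = time.perf_counter() - t0
        with _tag(f"compare-{name}"):
            t0 = time.perf_counter()
            pred_glm, _ = _two_pass_glm(pred.central, design8, cfg_glm)
            entry = {}
            for region, tmask, fmask in (
                    ("positive", masks["positive"], fmri_glm.positive_mask),
                    ("negative", masks["negative"], fmri_glm.negative_mask)):
                if not fmask.any():
                    entry[region] = {"correlation": np.nan, "gradient": np.nan,
                                     "coverage": np.nan}
                    continue
                p_series = pred.central[:, tmask].mean(axis=1)
                lo_series = pred.lower[:, tmask].mean(axis=1)
                hi_series = pred.upper[:, tmask].mean(axis=1)
                m_full = _fractional_bold(fmri, fmask, p)
                m_fold = glm.fold_trials(m_full, p, 1.0 / p.fmri_tr_s)
                m8 = glm.interpolate_series(m_fold, 1.0 / p.fmri_tr_s,
                                            p.ois_rate_hz)
                n = min(len(m8), len(p_series))
                corr, grad = compare_timeseries(p_series[:n], m8[:n])
                cover = float(np.mean((m8[:n] >= lo_series[:n] - 1e-12)
                                      & (m8[:n] <= hi_series[:n] + 1e-12)))
                entry[region] = {"correlation": corr, "gradient": grad,
                                 "coverage": cover}
            ts_report[name] = entry
            # spatial template correlation of the refined beta maps
            meas_map = spatial.smooth_map(fmri_glm.betas[0],
                                          config.compare.sigma_um,
                                          fmri.pixel_um)
            sd = meas_map.std()
            if sd > 0:
                meas_map = (meas_map - meas_map.mean()) / sd
            pred_map = pred_glm.betas[0]
            act = masks["positive"] | masks["negative"]
            ys, xs = np.where(act)
            pad = 8
            crop = pred_map[max(ys.min() - pad, 0):ys.max() + pad,
                            max(xs.min() - pad, 0):xs.max() + pad]
            match = spatial.match_template(
                crop, meas_map, scale_grid=config.compare.scale_grid(),
                angle_grid=config.compare.angle_grid())
            spatial_report[name] = match.to_dict()
            timings[f"compare-{name}"] = time.perf_counter() - t0

    report = ComparisonReport(ts_report, spatial_report, qc,
                              config.content_hash())
    if outdir:
        report.save(outdir / "report.json")
        manifest = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "versions": {"numpy": np.__version__},
        }
        with open(outdir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
    return report
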