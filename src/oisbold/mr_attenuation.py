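"""Extravascular gradient-echo BOLD signal from vessel-scale dephasing.

Deoxyhaemoglobin makes blood paramagnetic; a vessel (modelled as an
infinite cylinder) perturbs the field around itself and water protons
diffusing through those perturbations accumulate phase, attenuating the
gradient-echo signal.  The simulation places randomly oriented
cylinders in a periodic cube at a target blood volume fraction, random
walks extravascular protons with the water diffusion coefficient, and
accrues phase from the standard inside/outside cylinder field offsets.
The signal is S(TE) = |<exp(i phi)>| and the quantity of interest is

    dR2* = -ln( S(V, Y) / S(V0, Y0) ) / TE

relative to the baseline volume fraction V0 and saturation Y0.  The
accrued phase is linear in the susceptibility offset, so one random
walk per (V, radius) geometry serves every saturation value.

The predicted BOLD fraction is exp(-dR2* * TE) - 1, evaluated at the
low/mid/high vessel radii of the 3-20 um range to give the prediction
envelope.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from numba import njit

from .containers import HaemodynamicField
from .spectroscopy import BaselineState, PLSAConfig, baseline_concentrations, plsa_invert

__all__ = [
    "MRSimConfig",
    "BoldLUT",
    "BOLDPrediction",
    "ev_delta_r2star",
    "ev_phases",
    "build_bold_lut",
    "predict_bold",
    "y0_sweep",
    "save_bold_lut",
    "load_bold_lut",
]


@dataclass(frozen=True)
class MRSimConfig:
    """Physical constants and numerical settings of the MR Monte Carlo."""

    b0_T: float = 7.0
    te_s: float = 0.012
    gamma_rad_per_s_per_T: float = 2.675e8
    d_water_m2_per_s: float = 1e-9
    dchi0_ppm_cgs: float = 0.18     # full deoxy-oxy susceptibility per unit Hct
    hct: float = 0.4
    radius_um_range: tuple[float, float] = (3.0, 20.0)
    radius_um_mid: float = 10.0
    v0: float = 0.06                # baseline blood volume fraction
    y0: float = 0.5                 # baseline saturation
    n_protons: int = 10_000
    n_geometries: int = 8           # vessel-configuration realisations averaged
    dt_s: float = 2e-4              # TE/60
    seed: int = 0
    reflect: bool = True            # elastic rejection at vessel walls

    def __post_init__(self):
        for name in ("b0_T", "te_s", "gamma_rad_per_s_per_T",
                     "d_water_m2_per_s", "dchi0_ppm_cgs", "hct", "dt_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.radius_um_range[0] >= self.radius_um_range[1]:
            raise ValueError("radius range must have low < high")
        n = self.te_s / self.dt_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("te_s must be an integral number of dt_s steps")

    @property
    def n_steps(self) -> int:
        return int(round(self.te_s / self.dt_s))

    def dchi(self, y) -> np.ndarray:
        """Absolute susceptibility offset (cgs, dimensionless) at saturation y."""
        return self.dchi0_ppm_cgs * 1e-6 * self.hct * (1.0 - np.asarray(y, float))

    def content_hash(self) -> str:
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# geometry + random walk
# ---------------------------------------------------------------------------

def _make_geometry(v_target: float, radius_um: float, box_um: float,
                   rng: np.random.Generator):
    """Random infinite cylinders in a periodic cube, added until the
    occupied volume reaches v_target.

    Returns (centers, axes, cumulative_fractions): the k-th cumulative
    fraction is the Monte Carlo volume estimate with the first k
    cylinders present, so nested subsets of one master geometry realise
    a whole family of blood volume fractions with perfectly correlated
    phase statistics.
    """
    max_cyl = max(50, int(20 * v_target * box_um ** 2 / (np.pi * radius_um ** 2)))
    pts = rng.uniform(0, box_um, size=(100_000, 3))
    inside = np.zeros(len(pts), dtype=bool)
    centers, axes, cum = [], [], []
    frac = 0.0
    while frac < v_target:
        if len(centers) >= max_cyl:
            raise RuntimeError(
                f"cannot reach blood volume {v_target} with radius {radius_um} um")
        p = rng.uniform(0, box_um, size=3)
        # uniform orientation on the sphere
        z = rng.uniform(-1, 1)
        phi = rng.uniform(0, 2 * np.pi)
        s = np.sqrt(1 - z * z)
        u = np.array([s * np.cos(phi), s * np.sin(phi), z])
        centers.append(p)
        axes.append(u)
        d = pts - p
        d -= box_um * np.round(d / box_um)
        proj = d @ u
        rho2 = (d * d).sum(axis=1) - proj ** 2
        inside |= rho2 <= radius_um ** 2
        frac = inside.mean()
        cum.append(frac)
    return np.array(centers), np.array(axes), np.array(cum)


@njit(cache=True)
def _walk_kernel(pc, u, e1, e2, coef_out, coef_in, radius, box,
                 n_protons, n_steps, sigma, dt, reflect, seed):
    """Random-walk protons; return per-cylinder reference phases
    (susceptibility offset = 1) accumulated to TE, shape (n_protons, nc)."""
    np.random.seed(seed)
    nc = pc.shape[0]
    r2 = radius * radius
    phases = np.zeros((n_protons, nc))
    for ip in range(n_protons):
        # rejection-sample an extravascular start
        while True:
            x = np.random.random() * box
            y = np.random.random() * box
            z = np.random.random() * box
            ok = True
            for c in range(nc):
                dx = x - pc[c, 0]
                dy = y - pc[c, 1]
                dz = z - pc[c, 2]
                dx -= box * np.round(dx / box)
                dy -= box * np.round(dy / box)
                dz -= box * np.round(dz / box)
                proj = dx * u[c, 0] + dy * u[c, 1] + dz * u[c, 2]
                rho2 = dx * dx + dy * dy + dz * dz - proj * proj
                if rho2 <= r2:
                    ok = False
                    break
            if ok:
                break
        for _ in range(n_steps):
            nx = x + sigma * np.random.standard_normal()
            ny = y + sigma * np.random.standard_normal()
            nz = z + sigma * np.random.standard_normal()
            nx -= box * np.floor(nx / box)
            ny -= box * np.floor(ny / box)
            nz -= box * np.floor(nz / box)
            if reflect:
                hit = False
                for c in range(nc):
                    dx = nx - pc[c, 0]
                    dy = ny - pc[c, 1]
                    dz = nz - pc[c, 2]
                    dx -= box * np.round(dx / box)
                    dy -= box * np.round(dy / box)
                    dz -= box * np.round(dz / box)
                    proj = dx * u[c, 0] + dy * u[c, 1] + dz * u[c, 2]
                    rho2 = dx * dx + dy * dy + dz * dz - proj * proj
                    if rho2 <= r2:
                        hit = True
                        break
                if hit:
                    nx, ny, nz = x, y, z   # elastic rejection at the wall
            x, y, z = nx, ny, nz
            # field offset (units of gamma*B0*dchi), per cylinder
            for c in range(nc):
                dx = x - pc[c, 0]
                dy = y - pc[c, 1]
                dz = z - pc[c, 2]
                dx -= box * np.round(dx / box)
                dy -= box * np.round(dy / box)
                dz -= box * np.round(dz / box)
                proj = dx * u[c, 0] + dy * u[c, 1] + dz * u[c, 2]
                px = dx - proj * u[c, 0]
                py = dy - proj * u[c, 1]
                pz = dz - proj * u[c, 2]
                rho2 = px * px + py * py + pz * pz
                if rho2 <= r2:
                    phases[ip, c] += coef_in[c] * dt
                else:
                    a1 = px * e1[c, 0] + py * e1[c, 1] + pz * e1[c, 2]
                    a2 = px * e2[c, 0] + py * e2[c, 1] + pz * e2[c, 2]
                    # cos(2*phi_azimuth) = (a1^2 - a2^2)/rho^2
                    phases[ip, c] += coef_out[c] * r2 / rho2 \
                        * (a1 * a1 - a2 * a2) / rho2 * dt
    return phases


def _cylinder_phases(v_max: float, radius_um: float, mr: MRSimConfig,
                     seed: int, n_protons: int):
    """Master geometry reaching v_max plus per-cylinder proton phases.

    Returns (phases (n_protons, K), cum_fracs (K,)): cumulative blood
    volume fractions of the nested cylinder subsets and the reference
    phase (unit susceptibility offset) each cylinder contributes to each
    proton by TE.  Subset sums give every volume fraction up to v_max
    with perfectly correlated statistics, which is what makes small
    volume excursions resolvable above the Monte Carlo noise.
    """
    if not 0.0 < v_max < 0.2:
        raise ValueError("blood volume fraction must lie in (0, 0.2)")
    if n_protons < 100:
        warnings.warn("fewer than 100 protons: noisy estimate", stacklevel=3)
    rng = np.random.default_rng(seed)
    box = 20.0 * radius_um
    pc, u, cum = _make_geometry(v_max, radius_um, box, rng)
    uz = u[:, 2]
    # local frame perpendicular to the axis, e1 along the projection of B0
    e1 = np.zeros_like(u)
    e2 = np.zeros_like(u)
    for c in range(len(u)):
        b = np.array([0.0, 0.0, 1.0]) - uz[c] * u[c]
        nb = np.linalg.norm(b)
        if nb < 1e-12:      # axis parallel to B0: no external perturbation
            b = np.array([1.0, 0.0, 0.0])
            nb = 1.0
        e1[c] = b / nb
        e2[c] = np.cross(u[c], e1[c])
    gb0 = mr.gamma_rad_per_s_per_T * mr.b0_T
    coef_out = 2.0 * np.pi * (1.0 - uz ** 2) * gb0
    coef_in = (2.0 * np.pi / 3.0) * (3.0 * uz ** 2 - 1.0) * gb0
    sigma = np.sqrt(2.0 * mr.d_water_m2_per_s * mr.dt_s) * 1e6   # um per axis
    phases = _walk_kernel(pc, u, e1, e2, coef_out, coef_in, radius_um, box,
                          int(n_protons), mr.n_steps, sigma, mr.dt_s,
                          mr.reflect, int(seed) & 0x7FFFFFFF)
    return phases, cum


def ev_phases(v: float, radius_um: float, mr: MRSimConfig,
              seed: int | None = None, n_protons: int | None = None) -> np.ndarray:
    """Per-proton reference phases at TE for blood volume fraction v.

    Phases are for a unit susceptibility offset; the physical phase at
    saturation Y is ``phases * mr.dchi(Y)``.
    """
    seed = mr.seed if seed is None else seed
    n_protons = mr.n_protons if n_protons is None else n_protons
    phases, cum = _cylinder_phases(v, radius_um, mr, seed, n_protons)
    k = int(np.searchsorted(cum, v - 1e-12)) + 1
    return phases[:, :k].sum(axis=1)


def _signal(phases: np.ndarray, dchi: float) -> float:
    return float(np.abs(np.exp(1j * phases * dchi).mean()))


def _r2star_curve(phases: np.ndarray, cum: np.ndarray, dchi: float,
                  te_s: float):
    """R2* (s^-1) versus cumulative blood volume, including (V=0, 0)."""
    csum = np.cumsum(phases, axis=1) * dchi
    s = np.abs(np.exp(1j * csum).mean(axis=0))
    s = np.maximum(s, 1e-300)
    vv = np.concatenate([[0.0], cum])
    r2 = np.concatenate([[0.0], -np.log(s) / te_s])
    return vv, r2


def ev_delta_r2star(v: float, y: float, radius_um: float, mr: MRSimConfig,
                    seed: int | None = None,
                    n_protons: int | None = None) -> float:
    """dR2* (s^-1) of state (V, Y) relative to baseline (V0, Y0).

    Both states are evaluated on nested subsets of one master cylinder
    geometry (linear interpolation between achieved volume fractions),
    so the baseline state maps to exactly zero and small excursions are
    fully paired.
    """
    if not 0.0 <= y <= 1.0:
        raise ValueError("saturation must lie in [0, 1]")
    if not 0.0 < v < 0.2:
        raise ValueError("blood volume fraction must lie in (0, 0.2)")
    seed = mr.seed if seed is None else seed
    n_protons = mr.n_protons if n_protons is None else n_protons
    if n_protons < 100:
        warnings.warn("fewer than 100 protons: noisy estimate", stacklevel=2)
    ng = max(1, mr.n_geometries)
    per = max(10, n_protons // ng)
    dy, dy0 = 0.0, 0.0
    for g in range(ng):
        phases, cum = _cylinder_phases(max(v, mr.v0), radius_um, mr,
                                       seed + 104729 * g, per)
        vv, r2_y = _r2star_curve(phases, cum, float(mr.dchi(y)), mr.te_s)
        _, r2_y0 = _r2star_curve(phases, cum, float(mr.dchi(mr.y0)), mr.te_s)
        dy += np.interp(v, vv, r2_y)
        dy0 += np.interp(mr.v0, vv, r2_y0)
    return float(dy - dy0) / ng


# ---------------------------------------------------------------------------
# lookup table + prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoldLUT:
    """Absolute R2* attenuation (s^-1) on a (V, Y, radius) grid.

    ``delta_r2star`` interpolates tri-linearly and subtracts the value
    at the baseline state, so the baseline anchors to exactly zero.
    """

    v_grid: np.ndarray
    y_grid: np.ndarray
    r_grid: np.ndarray
    r2star: np.ndarray          # (nv, ny, nr)
    mr: MRSimConfig
    config_hash: str = ""

    def __post_init__(self):
        for g in (self.v_grid, self.y_grid, self.r_grid):
            if np.any(np.diff(g) <= 0):
                raise ValueError("LUT grids must be strictly increasing")

    def _interp_vy(self, sl: np.ndarray, v, y):
        v = np.clip(v, self.v_grid[0], self.v_grid[-1])
        y = np.clip(y, self.y_grid[0], self.y_grid[-1])
        iv = np.clip(np.searchsorted(self.v_grid, v) - 1, 0, len(self.v_grid) - 2)
        iy = np.clip(np.searchsorted(self.y_grid, y) - 1, 0, len(self.y_grid) - 2)
        fv = (v - self.v_grid[iv]) / (self.v_grid[iv + 1] - self.v_grid[iv])
        fy = (y - self.y_grid[iy]) / (self.y_grid[iy + 1] - self.y_grid[iy])
        return ((1 - fv) * (1 - fy) * sl[iv, iy]
                + fv * (1 - fy) * sl[iv + 1, iy]
                + (1 - fv) * fy * sl[iv, iy + 1]
                + fv * fy * sl[iv + 1, iy + 1])

    def _interp(self, v, y, r):
        r = float(r)
        if r < self.r_grid[0] - 1e-9 or r > self.r_grid[-1] + 1e-9:
            raise ValueError("radius outside LUT grid")
        ir = int(np.clip(np.searchsorted(self.r_grid, r) - 1, 0,
                         len(self.r_grid) - 2)) if len(self.r_grid) > 1 else 0
        if len(self.r_grid) == 1:
            return self._interp_vy(self.r2star[:, :, 0], v, y)
        fr = (r - self.r_grid[ir]) / (self.r_grid[ir + 1] - self.r_grid[ir])
        lo = self._interp_vy(self.r2star[:, :, ir], v, y)
        hi = self._interp_vy(self.r2star[:, :, ir + 1], v, y)
        return (1 - fr) * lo + fr * hi

    def delta_r2star(self, v, y, r, v0: float | None = None,
                     y0: float | None = None):
        """dR2* of (v, y) relative to (v0, y0) (defaults: config baseline)."""
        v0 = self.mr.v0 if v0 is None else v0
        y0 = self.mr.y0 if y0 is None else y0
        return self._interp(v, y, r) - self._interp(v0, y0, r)


def build_bold_lut(mr: MRSimConfig, v_grid=None, y_grid=None, r_grid=None,
                   seed: int | None = None,
                   n_protons: int | None = None) -> BoldLUT:
    """Run the random walk on the (V, radius) grid product.

    The Y axis is free: phases are linear in the susceptibility offset,
    so each geometry's phases are re-used for every saturation node.
    """
    v_grid = np.linspace(0.02, 0.12, 11) if v_grid is None else np.asarray(v_grid, float)
    y_grid = np.linspace(0.2, 0.9, 15) if y_grid is None else np.asarray(y_grid, float)
    r_grid = (np.array([mr.radius_um_range[0], mr.radius_um_mid,
                        mr.radius_um_range[1]])
              if r_grid is None else np.asarray(r_grid, float))
    if not (v_grid[0] <= mr.v0 <= v_grid[-1]):
        raise ValueError("v_grid must cover the baseline volume fraction")
    if not (y_grid[0] <= mr.y0 <= y_grid[-1]):
        raise ValueError("y_grid must cover the baseline saturation")
    seed = mr.seed if seed is None else seed
    n_protons = mr.n_protons if n_protons is None else n_protons
    ng = max(1, mr.n_geometries)
    per = max(100, n_protons // ng)
    r2star = np.zeros((len(v_grid), len(y_grid), len(r_grid)))
    for ir, r in enumerate(r_grid):
        for g in range(ng):
            phases, cum = _cylinder_phases(float(v_grid[-1]), float(r), mr,
                                           seed + 7919 * ir + 104729 * g, per)
            for iy, y in enumerate(y_grid):
                vv, curve = _r2star_curve(phases, cum, float(mr.dchi(y)),
                                          mr.te_s)
                r2star[:, iy, ir] += np.interp(v_grid, vv, curve)
    r2star /= ng
    return BoldLUT(v_grid, y_grid, r_grid, r2star, mr, mr.content_hash())


@dataclass
class BOLDPrediction:
    """Fractional BOLD change with the vessel-radius envelope."""

    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    radius_low_um: float
    radius_high_um: float
    rate_hz: float = 8.0
    clipped_fraction: float = 0.0    # QC: saturation left [0, 1]

    def __post_init__(self):
        if np.any(self.lower > self.central + 1e-12) or \
           np.any(self.central > self.upper + 1e-12):
            raise ValueError("envelope must satisfy lower <= central <= upper")


def predict_bold(field: HaemodynamicField, baseline: BaselineState,
                 lut: BoldLUT, mr: MRSimConfig) -> BOLDPrediction:
    """Map a haemodynamic field to predicted extravascular BOLD fractions.

    The surface layer of the baseline supplies the reference
    concentrations; blood volume scales with total haemoglobin,
    saturation follows the oxygenated fraction:

        V(t) = V0 * (HbT0 + dHbT) / HbT0
        Y(t) = (HbO2_0 + dHbO2) / (HbT0 + dHbT)
    """
    hbt0 = baseline.hbt0_uM[0]
    hbo2_0 = baseline.hbo2_0_uM[0]
    hbt = hbt0 + field.d_hbt
    v = mr.v0 * hbt / hbt0
    with np.errstate(divide="ignore", invalid="ignore"):
        y = (hbo2_0 + field.d_hbo2) / hbt
    bad = ~np.isfinite(y) | (y < 0) | (y > 1)
    clipped = float(bad.mean())
    y = np.clip(np.nan_to_num(y, nan=1.0), 0.0, 1.0)
    radii = (mr.radius_um_range[0], mr.radius_um_mid, mr.radius_um_range[1])
    preds = [np.exp(-lut.delta_r2star(v, y, r) * mr.te_s) - 1.0 for r in radii]
    stackp = np.stack(preds)
    return BOLDPrediction(preds[1], stackp.min(axis=0), stackp.max(axis=0),
                          radii[0], radii[2], rate_hz=field.rate_hz,
                          clipped_fraction=clipped)


# ---------------------------------------------------------------------------
# Y0 sensitivity sweep
# ---------------------------------------------------------------------------

def y0_sweep(stack, light_lut, tissue, mr: MRSimConfig, y0_grid,
             optics=None, mask=None, bold_lut: BoldLUT | None = None,
             blood_hbt_uM: float | None = None,
             plsa_config: PLSAConfig = PLSAConfig(),
             seed: int | None = None, n_protons: int | None = None):
    """Peak |BOLD| of the region-mean prediction per analysis Y0.

    For each Y0 the baseline is rebuilt, the same stack re-inverted and
    the recovered haemodynamics passed through the MR forward model at
    the mid-range vessel radius; the table of peak magnitudes and the
    argmax Y0 are returned.
    """
    y0_grid = np.asarray(y0_grid, dtype=float)
    if y0_grid.size == 0:
        raise ValueError("empty Y0 grid")
    if np.any((y0_grid <= 0) | (y0_grid >= 1)):
        raise ValueError("Y0 values must lie in (0, 1)")
    if mask is None:
        # stack-driven active region: strongest quartile of the band-mean
        # peak attenuation magnitude
        amp = np.abs(stack.attenuation).mean(axis=0).max(axis=0)
        mask = amp >= 0.5 * amp.max()
    mask = np.asarray(mask, dtype=bool)
    if bold_lut is None:
        # the sweep compares nearby Y levels, so geometry-realisation
        # variance matters more than per-proton noise: average many
        # geometries at the same total proton budget
        import dataclasses
        mr_mid = dataclasses.replace(mr, n_geometries=max(24, mr.n_geometries))
        bold_lut = build_bold_lut(
            mr_mid, v_grid=np.linspace(0.03, 0.10, 8),
            y_grid=np.linspace(0.05, 1.0, 20),
            r_grid=np.array([mr.radius_um_mid]),
            seed=seed, n_protons=n_protons)
    kwargs = {} if blood_hbt_uM is None else {"blood_hbt_uM": blood_hbt_uM}
    peaks = []
    for y0 in y0_grid:
        t = tissue.with_y0(float(y0))
        base = baseline_concentrations(t, optics, **kwargs) if optics is not None \
            else baseline_concentrations(t, _default_optics(stack), **kwargs)
        res = plsa_invert(stack, light_lut, base, optics=optics, config=plsa_config)
        f = res.field
        region = HaemodynamicField.from_components(
            f.d_hbo2[:, mask].mean(axis=1)[:, None, None],
            f.d_hbr[:, mask].mean(axis=1)[:, None, None],
            rate_hz=f.rate_hz, pixel_um=f.pixel_um)
        hbt0 = base.hbt0_uM[0]
        v = mr.v0 * (hbt0 + region.d_hbt) / hbt0
        with np.errstate(divide="ignore", invalid="ignore"):
            yy = (base.hbo2_0_uM[0] + region.d_hbo2) / (hbt0 + region.d_hbt)
        yy = np.clip(np.nan_to_num(yy, nan=1.0), 0.0, 1.0)
        dr2 = bold_lut.delta_r2star(v, yy, mr.radius_um_mid,
                                    v0=mr.v0, y0=float(y0))
        bold = np.exp(-dr2 * mr.te_s) - 1.0
        peaks.append(float(np.max(np.abs(bold))))
    table = pd.DataFrame({"y0": y0_grid, "peak_abs_bold": peaks})
    argmax_y0 = float(y0_grid[int(np.argmax(peaks))])
    return table, argmax_y0


def _default_optics(stack):
    from .photon_transport import OpticalConstants
    return OpticalConstants(bands_nm=stack.bands_nm)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_bold_lut(path, lut: BoldLUT) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dr2star", data=lut.r2star)
        f.create_dataset("v_grid", data=lut.v_grid)
        f.create_dataset("y_grid", data=lut.y_grid)
        f.create_dataset("r_grid", data=lut.r_grid)
        f.attrs["config_hash"] = lut.config_hash
        f.attrs["config_repr"] = repr(lut.mr)
        f.attrs["v0"] = lut.mr.v0
        f.attrs["y0"] = lut.mr.y0


def load_bold_lut(path, mr: MRSimConfig) -> BoldLUT:
    with h5py.File(path, "r") as f:
        return BoldLUT(f["v_grid"][()], f["y_grid"][()], f["r_grid"][()],
                       f["dr2star"][()], mr, str(f.attrs["config_hash"]))
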