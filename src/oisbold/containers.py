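"""Core in-memory containers shared across the pipeline.

All image-like arrays are (time, y, x), row-major, 0-based pixel
centres.  Haemoglobin concentrations are uM changes from baseline;
attenuation is natural-log units, A = -ln(I/I0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import nibabel as nib
import numpy as np

__all__ = [
    "HaemodynamicField",
    "MultiWavelengthStack",
    "FMRISeries",
    "save_field",
    "load_field",
    "save_stack",
    "load_stack",
    "save_fmri_nifti",
    "load_fmri_nifti",
]


@dataclass
class HaemodynamicField:
    """Spatio-temporal haemoglobin concentration changes (uM).

    Closure d_hbt == d_hbo2 + d_hbr is enforced on construction.
    """

    d_hbo2: np.ndarray          # (T, Y, X) uM
    d_hbr: np.ndarray
    d_hbt: np.ndarray
    rate_hz: float = 8.0
    pixel_um: float = 80.0

    def __post_init__(self):
        for a in (self.d_hbo2, self.d_hbr, self.d_hbt):
            if a.shape != self.d_hbo2.shape or a.ndim != 3:
                raise ValueError("fields must share a (time, y, x) shape")
            if not np.all(np.isfinite(a)):
                raise ValueError("fields must be finite")
        if np.max(np.abs(self.d_hbt - (self.d_hbo2 + self.d_hbr))) != 0.0:
            raise ValueError("closure violated: d_hbt != d_hbo2 + d_hbr")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.d_hbo2.shape

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.shape[0]) / self.rate_hz

    @staticmethod
    def from_components(d_hbo2, d_hbr, rate_hz=8.0, pixel_um=80.0):
        d_hbo2 = np.asarray(d_hbo2, dtype=float)
        d_hbr = np.asarray(d_hbr, dtype=float)
        return HaemodynamicField(d_hbo2, d_hbr, d_hbo2 + d_hbr,
                                 rate_hz=rate_hz, pixel_um=pixel_um)


@dataclass
class MultiWavelengthStack:
    """Four-band attenuation movie A(band, t, y, x) = -ln(I/I0)."""

    attenuation: np.ndarray                 # (n_bands, T, Y, X)
    bands_nm: tuple[tuple[float, float], ...]
    rate_hz: float = 8.0
    pixel_um: float = 80.0

    def __post_init__(self):
        if self.attenuation.ndim != 4:
            raise ValueError("attenuation must be (band, time, y, x)")
        if self.attenuation.shape[0] != len(self.bands_nm):
            raise ValueError("band axis must match bands_nm")
        if not np.all(np.isfinite(self.attenuation)):
            raise ValueError("attenuation must be finite")

    @property
    def n_bands(self) -> int:
        return self.attenuation.shape[0]


@dataclass
class FMRISeries:
    """EPI-like BOLD series, fixed 64x64 in-plane matrix."""

    data: np.ndarray            # (T, 64, 64)
    tr_s: float = 1.0
    fov_mm: float = 30.0
    te_s: float = 0.012

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[1:] != (64, 64):
            raise ValueError("fMRI data must be (T, 64, 64)")

    @property
    def pixel_um(self) -> float:
        return self.fov_mm * 1000.0 / self.data.shape[1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_field(path, f: HaemodynamicField) -> None:
    with h5py.File(path, "w") as h:
        for name in ("d_hbo2", "d_hbr", "d_hbt"):
            h.create_dataset(name, data=getattr(f, name))
        h.attrs["rate_hz"] = f.rate_hz
        h.attrs["pixel_um"] = f.pixel_um


def load_field(path) -> HaemodynamicField:
    with h5py.File(path, "r") as h:
        return HaemodynamicField(h["d_hbo2"][()], h["d_hbr"][()], h["d_hbt"][()],
                                 float(h.attrs["rate_hz"]),
                                 float(h.attrs["pixel_um"]))


def save_stack(path, s: MultiWavelengthStack) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("attenuation", data=s.attenuation)
        h.create_dataset("wavelengths_nm", data=np.asarray(s.bands_nm))
        h.attrs["rate_hz"] = s.rate_hz
        h.attrs["pixel_um"] = s.pixel_um


def load_stack(path) -> MultiWavelengthStack:
    with h5py.File(path, "r") as h:
        bands = tuple(tuple(b) for b in h["wavelengths_nm"][()])
        return MultiWavelengthStack(h["attenuation"][()], bands,
                                    float(h.attrs["rate_hz"]),
                                    float(h.attrs["pixel_um"]))


def save_fmri_nifti(path, s: FMRISeries) -> None:
    # stored as X x Y x 1 x T with pixdim from the FOV
    vol = np.transpose(s.data, (2, 1, 0))[:, :, None, :]
    pix = s.fov_mm / s.data.shape[1]
    aff = np.diag([pix, pix, 2.0, 1.0])
    img = nib.Nifti1Image(np.ascontiguousarray(vol), aff)
    img.header.set_zooms((pix, pix, 2.0, s.tr_s))
    nib.save(img, str(path))


def load_fmri_nifti(path, te_s: float = 0.012) -> FMRISeries:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    data = np.transpose(vol[:, :, 0, :], (2, 1, 0))
    zooms = img.header.get_zooms()
    return FMRISeries(np.ascontiguousarray(data), tr_s=float(zooms[3]),
                      fov_mm=float(zooms[0]) * data.shape[1], te_s=te_s)
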