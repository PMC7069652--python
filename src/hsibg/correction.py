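"""Reflectance/absorbance normalisation and retrieved-background correction.

Reflectance and absorbance of a sample are computed against a per-pixel
illumination estimate ("background") B:

    R(x,y,l) = (I(x,y,l) - I_dark) / (B(x,y,l) - I_dark)
    A(x,y,l) = -log10 R(x,y,l)

Three backgrounds are distinguished. The ground truth (GT) is a white
reference measured under exactly the sample's illumination; the single
background (SB) is one white reference reused everywhere (the conventional,
error-prone choice); the retrieved background (RB) is estimated from the
sample data itself. RB exploits a reference wavelength where the sample
absorbs negligibly (default 800 nm, inside the NIR tissue optical window and
at a haemoglobin isosbestic point): the per-pixel intensity there, divided by
the normalised source profile's value there, scales the normalised source
spectrum into a per-pixel illumination estimate,

    RM(x,y,l) = (C_s(x,y) / C_b) * NS(l),

with C_s(x,y) the dark-subtracted intensity at the reference channel and
C_b = NS(ref). Scaling the background by a factor w rescales reflectance by
1/w and offsets absorbance by +log10(w); a wrong background therefore
corrupts reflectance scale and absorbance offset, which is what the RB
correction repairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import DarkFrame, Hypercube, WavelengthGrid

__all__ = [
    "NormalizedSourceProfile",
    "BackgroundField",
    "minmax_normalize",
    "reflectance",
    "absorbance",
    "reflectance_to_absorbance",
    "retrieve_background",
    "rb_correct",
]

#: reflectance ratios at or below zero are floored here before the log
ABSORBANCE_FLOOR = 1e-6


def minmax_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Affinely map a spectrum onto [0, 1] (min -> 0, max -> 1)."""
    s = np.asarray(spectrum, dtype=float)
    lo, hi = s.min(), s.max()
    if hi == lo:
        raise ValueError("cannot min-max normalise a constant spectrum")
    return (s - lo) / (hi - lo)


@dataclass(frozen=True)
class NormalizedSourceProfile:
    """Min-max normalised source spectrum NS(l) with its reference channel.

    ``ns`` spans [0, 1]; ``cb`` is NS at the reference wavelength. Channels
    where NS falls below ``ns_floor`` carry almost no source power, so the
    retrieval divisor is clamped there (``ns_clamped``) and the channels are
    flagged unreliable.
    """

    ns: np.ndarray
    grid: WavelengthGrid
    ref_wavelength: float = 800.0
    ns_floor: float = 0.01

    def __post_init__(self) -> None:
        ns = np.asarray(self.ns, dtype=float)
        object.__setattr__(self, "ns", ns)
        if ns.shape != (self.grid.count,):
            raise ValueError("profile must live on its wavelength grid")
        if not (np.isclose(ns.min(), 0.0) and np.isclose(ns.max(), 1.0)):
            raise ValueError("profile must be min-max normalised to [0, 1]")
        if self.cb <= 0:
            raise ValueError("NS at the reference wavelength must be positive")

    @classmethod
    def from_source(
        cls,
        source: np.ndarray,
        grid: WavelengthGrid,
        ref_wavelength: float = 800.0,
        ns_floor: float = 0.01,
    ) -> "NormalizedSourceProfile":
        return cls(minmax_normalize(source), grid, ref_wavelength, ns_floor)

    @property
    def ref_index(self) -> int:
        return self.grid.index_of(self.ref_wavelength)

    @property
    def cb(self) -> float:
        return float(self.ns[self.ref_index])

    @property
    def ns_clamped(self) -> np.ndarray:
        return np.maximum(self.ns, self.ns_floor)

    @property
    def reliable_channels(self) -> np.ndarray:
        """Boolean mask of channels where the retrieval divisor is unclamped."""
        return self.ns > self.ns_floor


@dataclass(frozen=True)
class BackgroundField:
    """Per-pixel, per-wavelength illumination estimate B(x,y,l) in counts."""

    field: np.ndarray
    grid: WavelengthGrid
    kind: Literal["GT", "SB", "RB"]

    def __post_init__(self) -> None:
        field = np.asarray(self.field, dtype=float)
        object.__setattr__(self, "field", field)
        if field.ndim != 3 or field.shape[2] != self.grid.count:
            raise ValueError("background field must be (x, y, n_channels)")
        if np.any(field < 0) or not np.all(np.isfinite(field)):
            raise ValueError("background field must be finite and non-negative")
        if self.kind not in ("GT", "SB", "RB"):
            raise ValueError(f"unknown background kind {self.kind!r}")


def _dark_value(dark: DarkFrame | None) -> np.ndarray:
    return np.float64(0.0) if dark is None else dark.data


def _check_counts(cube: Hypercube) -> None:
    if cube.kind != "counts":
        raise ValueError(f"expected a counts hypercube, got kind={cube.kind!r}")


def reflectance(
    I: Hypercube, I0: BackgroundField, Idark: DarkFrame | None = None
) -> Hypercube:
    """Reflectance R = (I - Idark) / (I0 - Idark), elementwise.

    Raises when the dark-corrected background is not strictly positive
    anywhere: a non-positive divisor means the background is invalid there.
    """
    _check_counts(I)
    if I.grid != I0.grid:
        raise ValueError("cube and background use different wavelength grids")
    dark = _dark_value(Idark)
    denom = I0.field - np.reshape(dark, np.shape(dark) + (1,) * (3 - np.ndim(dark)))
    if np.any(denom <= 0):
        raise ValueError(
            "background minus dark is non-positive somewhere; "
            "the background field is not valid for correction"
        )
    numer = np.maximum(
        I.data - np.reshape(dark, np.shape(dark) + (1,) * (3 - np.ndim(dark))), 0.0
    )
    return Hypercube(numer / denom, I.grid, kind="reflectance")


def reflectance_to_absorbance(
    R: Hypercube, floor: float = ABSORBANCE_FLOOR, return_mask: bool = False
):
    """Absorbance A = -log10(R); non-positive ratios are floored, not fatal.

    Shadowed or dead pixels would otherwise abort a whole-cube correction, so
    ratios <= 0 are replaced by ``floor`` and reported through a warning (and
    the mask, when requested). A is negative wherever R > 1.
    """
    if R.kind != "reflectance":
        raise ValueError("expected a reflectance hypercube")
    bad = R.data <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-positive reflectance values floored at {floor}",
            RuntimeWarning,
            stacklevel=2,
        )
    A = Hypercube(-np.log10(np.maximum(R.data, floor)), R.grid, kind="absorbance")
    return (A, bad) if return_mask else A


def absorbance(
    I: Hypercube, I0: BackgroundField, Idark: DarkFrame | None = None
) -> Hypercube:
    """Absorbance A = -log10((I - Idark) / (I0 - Idark))."""
    return reflectance_to_absorbance(reflectance(I, I0, Idark))


def retrieve_background(
    I: Hypercube,
    profile: NormalizedSourceProfile,
    band_halfwidth: int = 0,
    return_mask: bool = False,
):
    """Estimate the per-pixel illumination from the sample cube itself.

    ``I`` must already be dark-subtracted. C_s(x,y) is the cube value at the
    channel nearest the profile's reference wavelength (optionally averaged
    over ``band_halfwidth`` neighbouring channels to damp noise; off by
    default). The retrieved field is RM = (C_s / C_b) * NS. Pixels with
    C_s <= 0 carry no illumination information; they are flagged in the
    invalid-pixel mask and retrieve a zero field.
    """
    _check_counts(I)
    if I.grid != profile.grid:
        raise ValueError("cube and source profile use different wavelength grids")
    k = profile.ref_index
    if band_halfwidth < 0:
        raise ValueError("band_halfwidth must be >= 0")
    if band_halfwidth == 0:
        cs = I.data[:, :, k]
    else:
        lo, hi = max(0, k - band_halfwidth), min(I.grid.count, k + band_halfwidth + 1)
        cs = I.data[:, :, lo:hi].mean(axis=2)
    invalid = cs <= 0
    if invalid.any():
        warnings.warn(
            f"{int(invalid.sum())} pixels have no signal at the reference "
            "wavelength; their retrieved background is zero",
            RuntimeWarning,
            stacklevel=2,
        )
    rm = (cs / profile.cb)[:, :, None] * profile.ns_clamped[None, None, :]
    field = BackgroundField(np.maximum(rm, 0.0), I.grid, kind="RB")
    return (field, invalid) if return_mask else field


def rb_correct(
    I: Hypercube,
    profile: NormalizedSourceProfile,
    mode: Literal["reflectance", "absorbance"] = "reflectance",
    Idark: DarkFrame | None = None,
    band_halfwidth: int = 0,
) -> Hypercube:
    """Full retrieved-background correction of a counts hypercube.

    Divides the (dark-subtracted) cube by the retrieved field. Without
    band-averaging, the reflectance at the reference channel is exactly 1 for
    every pixel with signal there, since the retrieval is anchored at that
    channel. In ``absorbance`` mode the result is -log10 of that ratio.
    """
    _check_counts(I)
    dark = _dark_value(Idark)
    data = np.maximum(
        I.data - np.reshape(dark, np.shape(dark) + (1,) * (3 - np.ndim(dark))), 0.0
    )
    corrected = Hypercube(data, I.grid, kind="counts")
    rm, invalid = retrieve_background(
        corrected, profile, band_halfwidth=band_halfwidth, return_mask=True
    )
    denom = np.where(rm.field > 0, rm.field, 1.0)
    ratio = np.where(rm.field > 0, corrected.data / denom, 0.0)
    R = Hypercube(ratio, I.grid, kind="reflectance")
    if mode == "reflectance":
        return R
    if mode == "absorbance":
        return reflectance_to_absorbance(R)
    raise ValueError(f"unknown mode {mode!r}")
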