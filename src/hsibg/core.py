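"""Core data model for hyperspectral imaging.

A pushbroom (line-scan) instrument records one spatial line times the full
spectrum per frame; translating the sample builds the second spatial axis.
This module holds the shared containers (wavelength grid, line-scan frame,
hypercube, dark frame) plus the operations that turn a stack of line frames
into a hypercube and render it to a synthetic RGB image.

Conventions: 0-based indices, half-open intervals; the scan axis is the
first spatial axis of a hypercube, so ``cube.data[x, y, k]`` is scan
position x, in-line position y, spectral channel k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import rayleigh

__all__ = [
    "WavelengthGrid",
    "LineScanFrame",
    "Hypercube",
    "DarkFrame",
    "RGBFilterBank",
    "subtract_dark",
    "reconstruct_hypercube",
    "make_rgb_filters",
    "render_rgb",
]

CubeKind = Literal["counts", "reflectance", "absorbance"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength grid needs at least two values")
        if not np.all(np.isfinite(values)):
            raise ValueError("wavelengths must be finite")
        if np.any(values <= 0):
            raise ValueError("wavelengths must be positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def count(self) -> int:
        return int(self.values.size)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the channel nearest ``wavelength_nm``.

        Raises ``ValueError`` when the wavelength lies outside the grid range.
        """
        lo, hi = self.values[0], self.values[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside grid range [{lo}, {hi}] nm"
            )
        return int(np.argmin(np.abs(self.values - wavelength_nm)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.shape, self.values.tobytes()))

    @classmethod
    def linspace(cls, start_nm: float, stop_nm: float, count: int) -> "WavelengthGrid":
        return cls(np.linspace(start_nm, stop_nm, count))


@dataclass(frozen=True)
class DarkFrame:
    """Dark signal recorded without illumination (scalar or 2D, counts)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if np.any(data < 0) or not np.all(np.isfinite(data)):
            raise ValueError("dark frame must be finite and non-negative")

    @classmethod
    def zero(cls) -> "DarkFrame":
        return cls(np.float64(0.0))


@dataclass(frozen=True)
class LineScanFrame:
    """One recorded frame: spatial line pixels (rows) x spectral channels (cols)."""

    data: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("line-scan frame must be 2D (line pixel x channel)")
        if data.shape[1] != self.grid.count:
            raise ValueError(
                f"frame has {data.shape[1]} channels, grid has {self.grid.count}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("frame values must be finite")
        if np.any(data < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class Hypercube:
    """3D spectral image (scan x line x wavelength) with its wavelength grid."""

    data: np.ndarray
    grid: WavelengthGrid
    kind: CubeKind = "counts"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 3:
            raise ValueError("hypercube must be 3D (x, y, wavelength)")
        if data.shape[2] != self.grid.count:
            raise ValueError(
                f"cube has {data.shape[2]} channels, grid has {self.grid.count}"
            )
        if self.kind not in ("counts", "reflectance", "absorbance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if not np.all(np.isfinite(data)):
            raise ValueError("hypercube values must be finite")
        if self.kind in ("counts", "reflectance") and np.any(data < 0):
            raise ValueError(f"{self.kind} hypercube must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]


@dataclass(frozen=True)
class RGBFilterBank:
    """Three non-negative spectral responses with stated centre wavelengths."""

    responses: np.ndarray  # (3, n_channels)
    centres: tuple[float, float, float]
    amplitudes: tuple[float, float, float]
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        responses = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", responses)
        if responses.shape != (3, self.grid.count):
            raise ValueError("filter bank needs 3 responses on the shared grid")
        if np.any(responses < 0):
            raise ValueError("filter responses must be non-negative")


def subtract_dark(frame: LineScanFrame, dark: DarkFrame) -> LineScanFrame:
    """Subtract the dark signal from a line-scan frame, clamping at zero.

    Under-dark pixels are clamped to 0: downstream ratios and logarithms
    require non-negative counts.
    """
    try:
        corrected = frame.data - dark.data
    except ValueError as exc:
        raise ValueError(
            f"dark frame shape {np.shape(dark.data)} not broadcastable to "
            f"frame shape {frame.data.shape}"
        ) from exc
    if corrected.shape != frame.data.shape:
        raise ValueError("dark frame broadcast changed the frame shape")
    return LineScanFrame(np.maximum(corrected, 0.0), frame.grid)


def reconstruct_hypercube(
    frames: Sequence[LineScanFrame], step_pixels: int
) -> Hypercube:
    """Assemble ordered line-scan frames into a counts hypercube.

    Each frame's single scan line is duplicated ``step_pixels`` times along
    the scan axis (the physical slit-width fill), so frame i occupies scan
    rows ``[i*step, (i+1)*step)`` and the scan extent is
    ``len(frames) * step_pixels``. Adjacent frames tile without overlap.
    """
    if len(frames) == 0:
        raise ValueError("cannot reconstruct a hypercube from zero frames")
    if step_pixels < 1:
        raise ValueError("step_pixels must be >= 1")
    first = frames[0]
    for f in frames:
        if f.data.shape != first.data.shape or f.grid != first.grid:
            raise ValueError("all frames must share shape and wavelength grid")
    stack = np.stack([f.data for f in frames])  # (n_frames, line, channel)
    data = np.repeat(stack, step_pixels, axis=0)
    return Hypercube(data, first.grid, kind="counts")


# Rayleigh density x*exp(-x^2/2) (x in units of the scale) peaks at x=1 and
# crosses half maximum at these two roots; their spread converts FWHM to scale.
_RAYLEIGH_HALF_LO = brentq(lambda u: u * np.exp(-(u**2) / 2) - 0.5 * np.exp(-0.5), 1e-9, 1.0)
_RAYLEIGH_HALF_HI = brentq(lambda u: u * np.exp(-(u**2) / 2) - 0.5 * np.exp(-0.5), 1.0, 6.0)
_RAYLEIGH_FWHM_PER_SCALE = _RAYLEIGH_HALF_HI - _RAYLEIGH_HALF_LO


def make_rgb_filters(
    grid: WavelengthGrid,
    centres: Sequence[float] = (442.0, 518.0, 579.0),
    amplitudes: Sequence[float] = (1.0, 1.0, 1.0),
    fwhm_nm: float = 40.0,
) -> RGBFilterBank:
    """Build Rayleigh-density RGB filter responses.

    Each response is a shifted Rayleigh probability density whose mode sits
    at the requested centre wavelength (shift = centre - scale, so the density
    is zero below the shift origin), scaled by its amplitude. The scale is
    chosen from ``fwhm_nm`` (default 40 nm full width at half maximum).
    """
    centres = tuple(float(c) for c in centres)
    amplitudes = tuple(float(a) for a in amplitudes)
    if len(centres) != 3 or len(amplitudes) != 3:
        raise ValueError("exactly three centres and three amplitudes required")
    if any(a < 0 for a in amplitudes):
        raise ValueError("amplitudes must be non-negative")
    lo, hi = grid.values[0], grid.values[-1]
    for c in centres:
        if not (lo <= c <= hi):
            raise ValueError(f"filter centre {c} nm outside grid range")
    scale = fwhm_nm / _RAYLEIGH_FWHM_PER_SCALE
    responses = np.zeros((3, grid.count))
    for i, (c, a) in enumerate(zip(centres, amplitudes)):
        responses[i] = a * rayleigh.pdf(grid.values, loc=c - scale, scale=scale)
    return RGBFilterBank(responses, centres, amplitudes, grid)


def render_rgb(cube: Hypercube, filters: RGBFilterBank) -> np.ndarray:
    """Render a hypercube to an (x, y, 3) RGB image with values in [0, 1].

    Each channel is the trapezoidal area under (pixel spectrum x filter
    response). All three channels are then divided by the maximum channel
    value over the image, so saturation is avoided by construction, and the
    result is clipped to [0, 1].
    """
    if cube.grid != filters.grid:
        raise ValueError("cube and filter bank use different wavelength grids")
    lam = cube.grid.values
    # (x, y, 3): integrate spectrum * response over wavelength per filter
    filtered = cube.data[..., None, :] * filters.responses[None, None, :, :]
    image = np.trapezoid(filtered, lam, axis=-1)
    peak = image.max()
    if peak > 0:
        image = image / peak
    return np.clip(image, 0.0, 1.0)
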