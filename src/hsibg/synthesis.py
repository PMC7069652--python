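"""Synthetic hypercube generator.

Emulates the study conditions under which background correction is compared:
a halogen-like broadband source, a smooth 2D Gaussian illumination power
field M(x,y) in (0, 1], and a four-class phantom whose classes carry
stand-in reflectance spectra (muscle, oxygenated blood, methylene blue,
nigrosin; deoxygenated blood is in the library for the noise study). The
generator builds, per scene,

    BG(x,y,l) = M(x,y) * S_light(l)              (ground-truth illumination)
    GT(x,y,l) = rho_class(l) * (1 + a * N(l))    (true reflectance + noise)
    raw       = BG * GT                          (emulated measured counts)
    SB        = raw / S_light                    (single-background estimate)
    RB        = raw / RM                         (retrieved background)

with a ~ U(0, alpha_max) and N drawn from a pool of smooth "colour-chart"
spectra, independently per pixel. The noise enters relative to the class
spectrum so it stays below alpha_max of the signal at every wavelength.
SB and RB share the implementations in :mod:`hsibg.correction`, so the
generator and the correction tool cannot drift apart.

Stand-in spectra are sums of Gaussian absorption bands on neutral baselines,
converted to reflectance via 10**(-A). They are built from two shared band
templates (a haemoglobin-like 540/560 double band with a blue rise and a
small NIR tail, and a dye-like 664 nm band), which reproduces the strong
inter-correlation of measured reflectance spectra: after per-pixel centring
the class spectra span a two-dimensional space, so two principal components
carry essentially all the variance, as they do for the real measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Hypercube, WavelengthGrid
from .correction import (
    BackgroundField,
    NormalizedSourceProfile,
    rb_correct,
    reflectance,
    reflectance_to_absorbance,
)

__all__ = [
    "IlluminationField",
    "SpectrumLibrary",
    "PhantomLayout",
    "SynthConfig",
    "SyntheticScene",
    "HypercubeTriplet",
    "halogen_source",
    "gaussian_density",
    "sample_illumination",
    "make_background_cube",
    "make_phantom_layout",
    "synth_gt_cube",
    "synth_triplet",
    "make_triplet",
    "to_absorbance_triplet",
    "noise_robustness_sim",
]

#: phantom classes, in label order (label 0 is also the background region)
PHANTOM_CLASSES = ("muscle", "blood_oxy", "methylene_blue", "nigrosin")


def _gauss(lam: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-(((lam - centre) / width) ** 2))


def halogen_source(grid: WavelengthGrid, temperature_k: float = 3200.0) -> np.ndarray:
    """Halogen-like source spectrum: Planck curve times a blue-edge rolloff.

    The rolloff emulates the spectral throughput of a dispersive system,
    whose dark-subtracted counts fall towards zero at the blue band edge;
    the returned spectrum is scaled to unit maximum.
    """
    lam = grid.values
    hc_over_k = 1.43877e7  # nm*K
    planck = lam**-5.0 / np.expm1(hc_over_k / (lam * temperature_k))
    window = 1.0 - np.exp(-(((lam - (lam[0] - 5.0)) / 25.0) ** 2))
    s = planck * window
    return s / s.max()


# Absorbance band templates shared across the stand-in samples.
def _template_haem(lam: np.ndarray) -> np.ndarray:
    """Oxygenated-haemoglobin-like: 540/560 nm double band, blue rise, NIR tail."""
    return (
        _gauss(lam, 540.0, 8.0)
        + _gauss(lam, 560.0, 8.0)
        + 0.75 * _gauss(lam, 440.0, 30.0)
        + 0.035 * _gauss(lam, 760.0, 160.0)
    )


def _template_deoxy(lam: np.ndarray) -> np.ndarray:
    """Deoxygenated-haemoglobin-like: single 550 nm band, blue rise, 760 nm band."""
    return (
        _gauss(lam, 550.0, 10.0)
        + 0.75 * _gauss(lam, 440.0, 30.0)
        + 0.10 * _gauss(lam, 760.0, 30.0)
        + 0.035 * _gauss(lam, 800.0, 180.0)
    )


def _template_dye(lam: np.ndarray) -> np.ndarray:
    """Methylene-blue-like: 664 nm main band with a 610 nm shoulder."""
    return _gauss(lam, 664.0, 18.0) + 0.45 * _gauss(lam, 610.0, 16.0)


#: (flat baseline, haem coefficient, dye coefficient) per sample; deoxy uses
#: its own template. Amplitudes are calibrated so the stated spectral
#: features hold (peak positions, methylene blue A(800) < 0.01, nigrosin
#: small finite A(800) of ~30% of its peak).
_SAMPLE_RECIPES: Mapping[str, tuple[float, float, float]] = {
    "muscle": (0.09, 0.73, 0.42),
    "blood_oxy": (0.015, 1.40, 0.0),
    "methylene_blue": (0.005, 0.04, 1.19),
    "nigrosin": (0.38, 0.53, 0.77),
}


def _noise_pool(lam: np.ndarray) -> np.ndarray:
    """Smooth colour-chart-like spectra, values within (0, 1)."""
    return np.stack(
        [
            0.25 + 0.65 * _gauss(lam, 600.0, 120.0),
            0.20 + 0.70 * _gauss(lam, 500.0, 90.0),
            0.30 + 0.60 * _gauss(lam, 750.0, 130.0),
            0.25 + 0.40 * _gauss(lam, 550.0, 60.0) + 0.30 * _gauss(lam, 800.0, 80.0),
            0.85 - 0.50 * _gauss(lam, 650.0, 150.0),
            0.20 + 0.25 * _gauss(lam, 480.0, 50.0) + 0.45 * _gauss(lam, 700.0, 100.0),
        ]
    )


@dataclass(frozen=True)
class SpectrumLibrary:
    """Named 1D spectra on a shared wavelength grid.

    ``samples`` maps sample names to reflectance spectra in (0, 1];
    ``noise_pool`` holds smooth colour-chart spectra used as uncorrelated
    noise shapes; ``source`` is the light-source spectrum (unit maximum).
    """

    grid: WavelengthGrid
    source: np.ndarray
    samples: Mapping[str, np.ndarray]
    noise_pool: np.ndarray

    def __post_init__(self) -> None:
        if self.source.shape != (self.grid.count,) or np.any(self.source < 0):
            raise ValueError("source spectrum must be non-negative on the grid")
        for name, spec in self.samples.items():
            if spec.shape != (self.grid.count,):
                raise ValueError(f"sample {name!r} not on the shared grid")
            if np.any(spec <= 0) or np.any(spec > 1):
                raise ValueError(f"reflectance of {name!r} must lie in (0, 1]")
        if self.noise_pool.ndim != 2 or self.noise_pool.shape[0] < 4:
            raise ValueError("noise pool needs at least 4 spectra")
        if np.any(self.noise_pool < 0) or np.any(self.noise_pool > 1):
            raise ValueError("noise spectra must lie in [0, 1]")

    def absorbance(self, name: str) -> np.ndarray:
        return -np.log10(self.samples[name])

    def profile(
        self, ref_wavelength: float = 800.0, ns_floor: float = 0.01
    ) -> NormalizedSourceProfile:
        return NormalizedSourceProfile.from_source(
            self.source, self.grid, ref_wavelength, ns_floor
        )

    @classmethod
    def default(cls, grid: WavelengthGrid | None = None) -> "SpectrumLibrary":
        if grid is None:
            grid = WavelengthGrid.linspace(450.0, 900.0, 300)
        lam = grid.values
        haem, deoxy, dye = _template_haem(lam), _template_deoxy(lam), _template_dye(lam)
        samples = {
            name: 10.0 ** -(flat + ch * haem + cd * dye)
            for name, (flat, ch, cd) in _SAMPLE_RECIPES.items()
        }
        samples["blood_deoxy"] = 10.0 ** -(0.015 + 1.40 * deoxy)
        return cls(grid, halogen_source(grid), samples, _noise_pool(lam))


@dataclass(frozen=True)
class IlluminationField:
    """Spatial optical-power distribution M(x,y) in [floor, 1]."""

    m: np.ndarray
    centre: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        object.__setattr__(self, "m", m)
        if m.ndim != 2:
            raise ValueError("illumination field must be 2D")
        if not np.isclose(m.max(), 1.0):
            raise ValueError("illumination field must be scaled to unit maximum")
        if np.any(m <= 0):
            raise ValueError("illumination field must be strictly positive")


def gaussian_density(
    shape: tuple[int, int], centre: tuple[float, float], sigma: float
) -> np.ndarray:
    """Unnormalised isotropic bivariate Gaussian density on a pixel grid."""
    x = np.arange(shape[0], dtype=float)[:, None]
    y = np.arange(shape[1], dtype=float)[None, :]
    return np.exp(-(((x - centre[0]) ** 2 + (y - centre[1]) ** 2) / (2.0 * sigma**2)))


def sample_illumination(
    shape: tuple[int, int],
    seed: int,
    sigma_frac: float = 0.35,
    floor: float = 0.05,
) -> IlluminationField:
    """Random Gaussian optical-power field with a uniformly random centre.

    The density is scaled to unit maximum over the image and clipped below at
    ``floor`` so every pixel keeps some illumination (corrections stay
    well-posed); as sigma grows the field tends to the uniform limit M = 1.
    """
    rng = np.random.default_rng(seed)
    centre = (rng.uniform(0, shape[0]), rng.uniform(0, shape[1]))
    sigma = sigma_frac * min(shape)
    d = gaussian_density(shape, centre, sigma)
    m = np.maximum(d / d.max(), floor)
    return IlluminationField(m, centre, seed)


def make_background_cube(
    ill: IlluminationField, source: np.ndarray, grid: WavelengthGrid
) -> BackgroundField:
    """Separable ground-truth illumination BG(x,y,l) = M(x,y) * S_light(l)."""
    source = np.asarray(source, dtype=float)
    if source.shape != (grid.count,):
        raise ValueError("source spectrum must live on the grid")
    return BackgroundField(ill.m[:, :, None] * source[None, None, :], grid, kind="GT")


@dataclass(frozen=True)
class PhantomLayout:
    """Label image assigning each pixel one of four spectral classes."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        if labels.ndim != 2:
            raise ValueError("phantom layout must be 2D")
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(4)):
            raise ValueError("phantom layout must contain exactly labels 0..3")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


def make_phantom_layout(
    shape: tuple[int, int] = (256, 512), radius: int | None = None
) -> PhantomLayout:
    """Four-class phantom: per class, three circles in one horizontal row.

    The background region carries the muscle spectrum (label 0), giving
    exactly four classes for k = 4 clustering. The default circle radius of
    28 px on the 256x512 canvas shrinks proportionally with the image.
    """
    nx, ny = shape
    if radius is None:
        radius = max(2, round(28 * min(nx / 256, ny / 512)))
    labels = np.zeros(shape, dtype=np.int64)
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    for cls in range(4):
        cx = (cls + 0.5) * nx / 4.0
        for j in range(3):
            cy = (j + 0.5) * ny / 3.0
            labels[(x - cx) ** 2 + (y - cy) ** 2 <= radius**2] = cls
    return PhantomLayout(labels)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic dataset."""

    shape: tuple[int, int] = (256, 512)
    n_channels: int = 300
    n_train: int = 50
    n_test: int = 3
    alpha_max: float = 0.1
    seed: int = 0
    illum_sigma_frac: float = 0.35
    illum_floor: float = 0.05
    ref_wavelength: float = 800.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha_max < 1):
            raise ValueError("alpha_max must lie in (0, 1)")
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid.linspace(450.0, 900.0, self.n_channels)

    def scaled(self, factor: float) -> "SynthConfig":
        return replace(
            self,
            shape=(max(8, round(self.shape[0] * factor)), max(8, round(self.shape[1] * factor))),
            n_channels=max(10, round(self.n_channels * factor)),
        )


@dataclass(frozen=True)
class SyntheticScene:
    """A GT reflectance cube plus the exact noise draws that produced it."""

    gt: Hypercube
    labels: PhantomLayout
    alpha: np.ndarray
    noise_index: np.ndarray


@dataclass(frozen=True)
class HypercubeTriplet:
    """GT, SB and RB cubes of one scene, sharing grid, labels, illumination."""

    gt: Hypercube
    sb: Hypercube
    rb: Hypercube
    labels: PhantomLayout
    illumination: IlluminationField

    def __post_init__(self) -> None:
        if not (self.gt.shape == self.sb.shape == self.rb.shape):
            raise ValueError("triplet cubes must share shape")
        if not (self.gt.grid == self.sb.grid == self.rb.grid):
            raise ValueError("triplet cubes must share the wavelength grid")

    @property
    def kind(self) -> str:
        return self.gt.kind

    def cube(self, condition: str) -> Hypercube:
        return {"GT": self.gt, "SB": self.sb, "RB": self.rb}[condition]


def synth_gt_cube(
    layout: PhantomLayout,
    library: SpectrumLibrary,
    cfg: SynthConfig,
    seed: int,
    classes: Sequence[str] = PHANTOM_CLASSES,
) -> SyntheticScene:
    """Ground-truth reflectance cube: class spectrum plus colour-chart noise.

    Each pixel receives its class reflectance times (1 + a*N), with
    a ~ U(0, alpha_max) and N drawn uniformly from the noise pool,
    independently per pixel, so the perturbation stays below alpha_max of
    the signal at every wavelength. The exact (a, N) draws are recorded for
    replay.
    """
    if len(classes) <= int(layout.labels.max()):
        raise ValueError("layout labels exceed the class list")
    for name in classes:
        if name not in library.samples:
            raise KeyError(f"library has no sample {name!r}")
    rng = np.random.default_rng(seed)
    alpha = rng.uniform(0.0, cfg.alpha_max, size=layout.shape)
    noise_index = rng.integers(0, library.noise_pool.shape[0], size=layout.shape)
    base = np.stack([library.samples[name] for name in classes])[layout.labels]
    noise = library.noise_pool[noise_index]
    gt = base * (1.0 + alpha[:, :, None] * noise)
    gt = np.maximum(gt, 1e-12)
    return SyntheticScene(
        Hypercube(gt, library.grid, kind="reflectance"), layout, alpha, noise_index
    )


def synth_triplet(
    scene: SyntheticScene,
    ill: IlluminationField,
    library: SpectrumLibrary,
    profile: NormalizedSourceProfile | None = None,
) -> HypercubeTriplet:
    """SB and RB reflectance cubes for a scene under an illumination field.

    The emulated raw signal is BG * GT. The single-background correction
    divides by the unit-power source spectrum (so SB = M * GT), and the
    retrieved-background correction runs the actual retrieval on the raw
    signal; both go through :mod:`hsibg.correction`, so recomputing RB with
    ``rb_correct`` reproduces ``triplet.rb`` bit for bit.
    """
    if profile is None:
        profile = library.profile()
    grid = library.grid
    bg = make_background_cube(ill, library.source, grid)
    raw = Hypercube(bg.field * scene.gt.data, grid, kind="counts")
    sb_background = BackgroundField(
        np.broadcast_to(library.source, raw.shape).copy(), grid, kind="SB"
    )
    sb = reflectance(raw, sb_background)
    rb = rb_correct(raw, profile, mode="reflectance")
    return HypercubeTriplet(scene.gt, sb, rb, scene.labels, ill)


def make_triplet(
    cfg: SynthConfig,
    library: SpectrumLibrary,
    cube_seed: int,
    layout: PhantomLayout | None = None,
) -> HypercubeTriplet:
    """Generate one full reflectance triplet from a single cube seed."""
    if layout is None:
        layout = make_phantom_layout(cfg.shape)
    seq = np.random.SeedSequence(cube_seed).generate_state(2)
    ill = sample_illumination(
        cfg.shape, int(seq[0] % 2**31), cfg.illum_sigma_frac, cfg.illum_floor
    )
    scene = synth_gt_cube(layout, library, cfg, int(seq[1] % 2**31))
    return synth_triplet(scene, ill, library, library.profile(cfg.ref_wavelength))


def to_absorbance_triplet(triplet: HypercubeTriplet) -> HypercubeTriplet:
    """Log-transform a reflectance triplet to absorbance, elementwise."""
    if triplet.kind != "reflectance":
        raise ValueError("expected a reflectance triplet")
    return HypercubeTriplet(
        reflectance_to_absorbance(triplet.gt),
        reflectance_to_absorbance(triplet.sb),
        reflectance_to_absorbance(triplet.rb),
        triplet.labels,
        triplet.illumination,
    )


def noise_robustness_sim(
    spectrum: np.ndarray,
    profile: NormalizedSourceProfile,
    noise_levels: Sequence[float] = (0.01, 0.05, 0.10, 0.20),
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Sensitivity of the retrieved-background absorbance to spectral noise.

    Multiplicative zero-mean Gaussian noise of each stated relative level is
    added channel-wise to the raw spectrum; the RB absorbance of the noisy
    spectrum is compared with the noiseless RB absorbance. The percent error
    is the channel-mean absolute deviation over the channel-mean absolute
    noiseless absorbance, reported as mean and standard deviation over
    replicates. Because the retrieval is anchored at a single reference
    channel, the error grows with the noise level.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if np.any(spectrum <= 0):
        raise ValueError("raw spectrum must be strictly positive")

    def rb_absorbance(raw_1d: np.ndarray) -> np.ndarray:
        cube = Hypercube(raw_1d[None, None, :], profile.grid, kind="counts")
        return rb_correct(cube, profile, mode="absorbance").data[0, 0]

    a_ref = rb_absorbance(spectrum)
    keep = profile.reliable_channels
    denom = np.mean(np.abs(a_ref[keep]))
    rng = np.random.default_rng(seed)
    rows = []
    for level in noise_levels:
        errors = np.empty(n_reps)
        for rep in range(n_reps):
            noisy = spectrum * (1.0 + level * rng.standard_normal(spectrum.size))
            noisy = np.maximum(noisy, 1e-9)
            a = rb_absorbance(noisy)
            errors[rep] = 100.0 * np.mean(np.abs(a[keep] - a_ref[keep])) / denom
        rows.append(
            {
                "noise_level": level,
                "mean_pct_error": errors.mean(),
                "sd_pct_error": errors.std(ddof=1) if n_reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
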