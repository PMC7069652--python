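"""Pixel-wise PCA and spectral angle mapping of hypercubes.

Both tools probe how background errors distort spectra. A wrong background
rescales reflectance (per-pixel multiplicative factor) and offsets
absorbance (per-pixel additive constant). Per-pixel mean centring before
PCA removes additive offsets but not scalings, so PCA of absorbance is
insensitive to background errors while PCA of reflectance is not. The
spectral angle is invariant to per-pixel scaling but not to offsets, so the
sensitivities swap for SAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import Hypercube
from .synthesis import PhantomLayout

__all__ = ["PCAResult", "SAMResult", "pixelwise_pca", "sam_angle", "sam_map", "cluster_references"]


@dataclass(frozen=True)
class PCAResult:
    """Orthonormal spectral loadings, per-pixel score maps, variance shares."""

    components: np.ndarray  # (n_components, n_channels)
    scores: np.ndarray  # (x, y, n_components)
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        ratios = self.explained_variance_ratio
        if np.any(ratios < -1e-12) or np.any(np.diff(ratios) > 1e-12):
            raise ValueError("variance ratios must be non-negative and non-increasing")


def pixelwise_pca(
    cube: Hypercube, center: Literal["pixel", "channel"] = "pixel"
) -> PCAResult:
    """PCA of a hypercube vectorised to (pixels x channels).

    With ``center="pixel"`` (the default) each pixel's spectrum is centred by
    its own mean, which makes the decomposition blind to per-pixel additive
    offsets; ``center="channel"`` is the conventional column centring. The
    channel-by-channel covariance (1/(n-1) normalisation) is decomposed by
    SVD; each loading's largest-magnitude element is made positive so score
    maps are reproducible.
    """
    nx, ny, nch = cube.shape
    if nx * ny < 2:
        raise ValueError("pixel-wise PCA needs at least two pixels")
    X = cube.data.reshape(nx * ny, nch)
    if center == "pixel":
        X = X - X.mean(axis=1, keepdims=True)
    elif center == "channel":
        X = X - X.mean(axis=0, keepdims=True)
    else:
        raise ValueError(f"unknown centring {center!r}")
    cov = (X.T @ X) / (X.shape[0] - 1)
    U, s, _ = np.linalg.svd(cov, hermitian=True)
    components = U.T
    flip = np.sign(components[np.arange(nch), np.argmax(np.abs(components), axis=1)])
    components = components * flip[:, None]
    total = s.sum()
    ratios = s / total if total > 0 else np.zeros_like(s)
    scores = (X @ components.T).reshape(nx, ny, nch)
    return PCAResult(components, scores, ratios)


def sam_angle(t: np.ndarray, r: np.ndarray) -> float:
    """Spectral angle: arccos of the cosine similarity of two spectra.

    The argument is clamped to [-1, 1] against floating-point overshoot.
    Angles lie in [0, pi/2] for non-negative spectra; 0 means the target is
    proportional to the reference.
    """
    t = np.asarray(t, dtype=float)
    r = np.asarray(r, dtype=float)
    nt, nr = np.linalg.norm(t), np.linalg.norm(r)
    if nt == 0 or nr == 0:
        raise ValueError("spectral angle undefined for a zero spectrum")
    return float(np.arccos(np.clip(np.dot(t, r) / (nt * nr), -1.0, 1.0)))


@dataclass(frozen=True)
class SAMResult:
    """Per-pixel spectral angles (radians) against one reference spectrum."""

    angles: np.ndarray  # (x, y)
    reference: np.ndarray


def sam_map(cube: Hypercube, reference: np.ndarray) -> SAMResult:
    """Spectral angle of every pixel against a reference spectrum."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (cube.grid.count,):
        raise ValueError("reference spectrum must live on the cube's grid")
    nr = np.linalg.norm(reference)
    if nr == 0:
        raise ValueError("spectral angle undefined for a zero reference")
    X = cube.data
    norms = np.linalg.norm(X, axis=2)
    if np.any(norms == 0):
        raise ValueError("cube contains zero-spectrum pixels")
    cosine = (X @ reference) / (norms * nr)
    return SAMResult(np.arccos(np.clip(cosine, -1.0, 1.0)), reference)


def cluster_references(cube: Hypercube, layout: PhantomLayout) -> np.ndarray:
    """Average spectrum of each labelled cluster of the cube, in label order."""
    if layout.shape != cube.shape[:2]:
        raise ValueError("layout does not match the cube's spatial shape")
    labels = layout.labels
    return np.stack(
        [cube.data[labels == k].mean(axis=0) for k in range(labels.max() + 1)]
    )
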