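"""Machine-learning evaluation harness for background-correction quality.

Pixel spectra from synthetic GT/SB/RB hypercubes are classified by minibatch
k-means (k = 4, unsupervised), an incremental hinge-loss SVM, and a small
1D CNN, training on cubes from one background condition and testing on
every condition (the 3x3 grid). Accuracy differences across the grid expose
incomplete background correction.

Two scaling modes feed the classifiers. ``"spectrum"`` rescales each pixel
spectrum to [-1, 1]; this cancels any per-spectrum affine distortion
(offsets from wrong absorbance backgrounds, scalings from wrong reflectance
backgrounds), so under it the three conditions become indistinguishable.
``"cube"`` rescales each hypercube by one global min/max, which preserves
per-pixel distortions, and is the mode under which the single-background
condition genuinely degrades k-means and cross-condition accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import MiniBatchKMeans
from sklearn.linear_model import SGDClassifier

from .core import Hypercube
from .nn import SpectralCNN
from .synthesis import (
    HypercubeTriplet,
    PhantomLayout,
    SpectrumLibrary,
    SynthConfig,
    make_phantom_layout,
    make_triplet,
    to_absorbance_triplet,
)

__all__ = [
    "LabeledSpectra",
    "ClassifierSpec",
    "TrainedModel",
    "minmax_scale_pm1",
    "minmax_scale_cube_pm1",
    "vectorize_cube",
    "train",
    "evaluate",
    "background_grid_experiment",
]

CONDITIONS = ("GT", "SB", "RB")


@dataclass(frozen=True)
class LabeledSpectra:
    """Pixel spectra as a (n_pixels x n_channels) matrix with class labels."""

    spectra: np.ndarray
    labels: np.ndarray
    spatial_shape: tuple[int, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2D matrix")
        if self.labels.shape != (self.spectra.shape[0],):
            raise ValueError("one label per spectrum required")
        if self.spectra.shape[0] != self.spatial_shape[0] * self.spatial_shape[1]:
            raise ValueError("row count must equal the product of spatial dims")


def minmax_scale_pm1(spectra: np.ndarray) -> np.ndarray:
    """Map each row affinely so its (min, max) land on (-1, 1).

    This removes any per-row additive offset or positive scaling. Constant
    rows have no range and map to 0.
    """
    spectra = np.asarray(spectra, dtype=float)
    lo = spectra.min(axis=-1, keepdims=True)
    hi = spectra.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(spectra)
    np.divide(spectra - lo, span, out=out, where=span > 0)
    return np.where(span > 0, 2.0 * out - 1.0, 0.0)


def minmax_scale_cube_pm1(spectra: np.ndarray) -> np.ndarray:
    """Map a whole spectra matrix affinely so its global (min, max) land on
    (-1, 1); per-row offsets and scalings survive relative to the cube."""
    spectra = np.asarray(spectra, dtype=float)
    lo, hi = spectra.min(), spectra.max()
    if hi == lo:
        return np.zeros_like(spectra)
    return 2.0 * (spectra - lo) / (hi - lo) - 1.0


def _scale(spectra: np.ndarray, mode: str) -> np.ndarray:
    if mode == "spectrum":
        return minmax_scale_pm1(spectra)
    if mode == "cube":
        return minmax_scale_cube_pm1(spectra)
    if mode == "none":
        return np.asarray(spectra, dtype=float)
    raise ValueError(f"unknown scaling mode {mode!r}")


def vectorize_cube(
    cube: Hypercube, layout: PhantomLayout | None = None, provenance: str = ""
) -> LabeledSpectra:
    """Row-major flatten of a hypercube to (x*y) pixel spectra."""
    nx, ny, nch = cube.shape
    labels = (
        layout.labels.reshape(-1)
        if layout is not None
        else np.zeros(nx * ny, dtype=np.int64)
    )
    if layout is not None and layout.shape != (nx, ny):
        raise ValueError("layout does not match the cube's spatial shape")
    return LabeledSpectra(
        cube.data.reshape(nx * ny, nch), labels, (nx, ny), provenance
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """Configuration of one classifier in the harness."""

    kind: Literal["kmeans", "svm", "cnn"]
    n_classes: int = 4
    scaling: Literal["spectrum", "cube", "none"] = "spectrum"
    # k-means: epochs without inertia improvement before stopping
    early_stop_epochs: int = 21
    max_epochs: int = 100
    # svm
    svm_alpha: float = 1e-4
    svm_epochs: int = 5
    # cnn
    cnn_batch: int = 200
    cnn_lr: float = 0.01
    cnn_max_epochs: int = 20
    cnn_folds: int = 5

    def __post_init__(self) -> None:
        if self.kind not in ("kmeans", "svm", "cnn"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    model: object
    fold_accuracies: list[float] = field(default_factory=list)

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        X = _scale(spectra, self.spec.scaling)
        return np.asarray(self.model.predict(X))


def _train_kmeans(
    spec: ClassifierSpec, cubes: Sequence[LabeledSpectra], seed: int
) -> MiniBatchKMeans:
    """Incremental minibatch k-means over whole-cube batches.

    One epoch passes every training cube through ``partial_fit``; training
    stops after ``early_stop_epochs`` epochs without improvement of the
    inertia on a fixed evaluation sample.
    """
    km = MiniBatchKMeans(
        n_clusters=spec.n_classes, random_state=seed, n_init=1, batch_size=4096
    )
    rng = np.random.default_rng(seed)
    scaled = [_scale(c.spectra, spec.scaling) for c in cubes]
    eval_pool = np.concatenate(scaled)
    eval_idx = rng.choice(len(eval_pool), size=min(8192, len(eval_pool)), replace=False)
    eval_sample = eval_pool[eval_idx]
    best, since_best = np.inf, 0
    for _ in range(spec.max_epochs):
        for X in scaled:
            km.partial_fit(X)
        inertia = -km.score(eval_sample)
        if inertia < best - 1e-12:
            best, since_best = inertia, 0
        else:
            since_best += 1
            if since_best >= spec.early_stop_epochs:
                break
    return km


def _train_svm(
    spec: ClassifierSpec, cubes: Sequence[LabeledSpectra], seed: int
) -> SGDClassifier:
    """Incremental one-vs-all hinge-loss SVM, consuming one cube per batch."""
    clf = SGDClassifier(
        loss="hinge", penalty="l2", alpha=spec.svm_alpha, random_state=seed
    )
    classes = np.arange(spec.n_classes)
    rng = np.random.default_rng(seed)
    for _ in range(spec.svm_epochs):
        for c in cubes:
            X = _scale(c.spectra, spec.scaling)
            order = rng.permutation(len(X))
            clf.partial_fit(X[order], c.labels[order], classes=classes)
    return clf


def _train_cnn(
    spec: ClassifierSpec,
    cubes: Sequence[LabeledSpectra],
    seed: int,
    cross_validate: bool = False,
) -> tuple[SpectralCNN, list[float]]:
    X = np.concatenate([_scale(c.spectra, spec.scaling) for c in cubes])
    y = np.concatenate([c.labels for c in cubes])
    fold_acc: list[float] = []
    if cross_validate:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(X))
        folds = np.array_split(order, spec.cnn_folds)
        for i, val_idx in enumerate(folds):
            tr_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
            net = SpectralCNN(X.shape[1], spec.n_classes, seed=seed + 1 + i)
            net.fit(
                X[tr_idx], y[tr_idx], lr=spec.cnn_lr, batch_size=spec.cnn_batch,
                max_epochs=spec.cnn_max_epochs, seed=seed + 1 + i,
            )
            fold_acc.append(float((net.predict(X[val_idx]) == y[val_idx]).mean()))
    net = SpectralCNN(X.shape[1], spec.n_classes, seed=seed)
    net.fit(
        X, y, lr=spec.cnn_lr, batch_size=spec.cnn_batch,
        max_epochs=spec.cnn_max_epochs, seed=seed,
    )
    return net, fold_acc


def train(
    spec: ClassifierSpec,
    train_cubes: Sequence[LabeledSpectra],
    seed: int,
    cross_validate: bool = False,
) -> TrainedModel:
    """Train one classifier on a sequence of labelled spectra cubes.

    Supervised kinds (svm, cnn) require every class present in the training
    data; k-means ignores the labels. Deterministic given the seed.
    """
    if len(train_cubes) == 0:
        raise ValueError("at least one training cube required")
    if spec.kind in ("svm", "cnn"):
        present = np.unique(np.concatenate([c.labels for c in train_cubes]))
        missing = set(range(spec.n_classes)) - set(present.tolist())
        if missing:
            raise ValueError(f"classes missing from training data: {sorted(missing)}")
    if spec.kind == "kmeans":
        return TrainedModel(spec, _train_kmeans(spec, train_cubes, seed))
    if spec.kind == "svm":
        return TrainedModel(spec, _train_svm(spec, train_cubes, seed))
    net, folds = _train_cnn(spec, train_cubes, seed, cross_validate)
    return TrainedModel(spec, net, folds)


def match_clusters(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> np.ndarray:
    """Optimal one-to-one cluster-to-class assignment.

    Maximises accuracy over all n_classes! permutations (exhaustive for the
    4 classes used here) and returns the relabelled predictions.
    """
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (pred, truth), 1)
    best_perm, best_correct = None, -1
    for perm in permutations(range(n_classes)):
        correct = sum(confusion[c, perm[c]] for c in range(n_classes))
        if correct > best_correct:
            best_perm, best_correct = perm, correct
    mapping = np.array(best_perm)
    return mapping[pred]


def evaluate(
    model: TrainedModel, test_cube: LabeledSpectra
) -> tuple[float, np.ndarray]:
    """Pixel accuracy (percent) and predicted label map on one test cube.

    k-means clusters are mapped to classes by exhaustive optimal matching
    before scoring.
    """
    pred = model.predict(test_cube.spectra)
    if model.spec.kind == "kmeans":
        pred = match_clusters(pred, test_cube.labels, model.spec.n_classes)
    accuracy = 100.0 * float((pred == test_cube.labels).mean())
    return accuracy, pred.reshape(test_cube.spatial_shape)


def _triplet_to_cubes(
    triplet: HypercubeTriplet, cube_id: str
) -> dict[str, LabeledSpectra]:
    return {
        cond: vectorize_cube(
            triplet.cube(cond), triplet.labels, provenance=f"{cube_id}:{cond}"
        )
        for cond in CONDITIONS
    }


def generate_condition_cubes(
    cfg: SynthConfig,
    library: SpectrumLibrary,
    kind: Literal["reflectance", "absorbance"],
    role: Literal["train", "test"],
) -> dict[str, list[LabeledSpectra]]:
    """Labelled spectra for every background condition of a dataset split.

    Train and test cubes draw their noise and illumination from disjoint
    seed streams spawned from the config seed, so no (alpha, N) draw is
    shared between the splits.
    """
    n = cfg.n_train if role == "train" else cfg.n_test
    root = np.random.SeedSequence(cfg.seed)
    train_seq, test_seq = root.spawn(2)
    seq = train_seq if role == "train" else test_seq
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in seq.spawn(n)]
    layout = make_phantom_layout(cfg.shape)
    out: dict[str, list[LabeledSpectra]] = {cond: [] for cond in CONDITIONS}
    for i, cube_seed in enumerate(seeds):
        triplet = make_triplet(cfg, library, cube_seed, layout)
        if kind == "absorbance":
            triplet = to_absorbance_triplet(triplet)
        for cond, cube in _triplet_to_cubes(triplet, f"{role}{i}").items():
            out[cond].append(cube)
    return out


def background_grid_experiment(
    cfg: SynthConfig,
    library: SpectrumLibrary,
    clf_kind: Literal["kmeans", "svm", "cnn"],
    kind: Literal["reflectance", "absorbance"],
    seed: int,
    scaling: Literal["spectrum", "cube"] = "spectrum",
    conditions: Iterable[str] = CONDITIONS,
) -> pd.DataFrame:
    """The 3x3 background-condition accuracy grid for one classifier.

    Trains one classifier per training condition on ``cfg.n_train`` cubes and
    reports pixel accuracy on the concatenated ``cfg.n_test`` test cubes of
    every test condition, in percent. Rows: training condition; columns:
    test condition.
    """
    conditions = tuple(conditions)
    spec = ClassifierSpec(kind=clf_kind, scaling=scaling)
    train_cubes = generate_condition_cubes(cfg, library, kind, "train")
    test_cubes = generate_condition_cubes(cfg, library, kind, "test")
    grid = pd.DataFrame(
        np.zeros((len(conditions), len(conditions))),
        index=pd.Index(conditions, name="train"),
        columns=pd.Index(conditions, name="test"),
    )
    for train_cond in conditions:
        model = train(spec, train_cubes[train_cond], seed)
        for test_cond in conditions:
            merged = LabeledSpectra(
                np.concatenate([c.spectra for c in test_cubes[test_cond]]),
                np.concatenate([c.labels for c in test_cubes[test_cond]]),
                (len(test_cubes[test_cond]) * cfg.shape[0], cfg.shape[1]),
                provenance=f"test:{test_cond}",
            )
            accuracy, _ = evaluate(model, merged)
            grid.loc[train_cond, test_cond] = accuracy
    return grid
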