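"""Patch-based classifier: balanced patch sampling, dihedral augmentation,
deterministic training, dense probability maps, and peak detection.

The classifier is a small multilayer perceptron over downsampled RGB
patches. It is trained exclusively on clean (uncompressed) scenes and then
evaluated on compressed copies — the train-on-clean / test-on-compressed
protocol that isolates the effect of compression artifacts. Dense inference
scores a strided grid of patch centers and bilinearly upsamples the
resulting probability grid to full resolution, a documented approximation
to true stride-1 sliding-window inference chosen for CPU tractability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from skimage.transform import resize
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

from .errors import (DimensionError, EmptyClassError, ParameterError,
                     TrainingError)
from .synth import Scene

__all__ = [
    "TrainConfig", "ProbabilityMap", "CenterSet", "PatchClassifier",
    "extract_patches", "augment_patch", "apply_dihedral", "train_classifier",
    "predict_probability_map", "detect_centers", "binarize_map",
]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for patch sampling and classifier training.

    ``balance`` is the positive:negative sampling ratio (1.0 = balanced;
    0 = background-only sampling). ``downsample`` subsamples each patch by
    that factor before flattening into the feature vector.
    """

    patch_size: int = 16
    stride: int = 2
    epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    balance: float = 1.0
    seed: int = 0
    architecture: str = "mlp"
    hidden_widths: tuple[int, ...] = (96, 48)
    patches_per_scene: int = 400
    downsample: int = 1
    augment: bool = True

    def __post_init__(self) -> None:
        if self.patch_size % 2 != 0 or self.patch_size < 4:
            raise ParameterError("patch_size must be an even integer >= 4")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.stride < 1 or self.batch_size < 1 or self.patches_per_scene < 1:
            raise ParameterError("stride, batch_size, patches_per_scene must be >= 1")
        if self.balance < 0:
            raise ParameterError("balance must be >= 0")
        if self.architecture != "mlp":
            raise ParameterError(f"unknown architecture {self.architecture!r}")


@dataclass
class ProbabilityMap:
    """Per-pixel class probability raster in [0, 1] for one task."""

    values: np.ndarray  # H x W float64 in [0, 1]
    task: str


@dataclass
class CenterSet:
    """Detected centers sorted by descending score."""

    coords: np.ndarray  # (n, 2) float (row, col)
    scores: np.ndarray  # (n,) float

    def __len__(self) -> int:
        return len(self.coords)


def _positive_mask(scene: Scene) -> np.ndarray:
    """Per-pixel positive class for the scene's task."""
    task = scene.params.task
    if task == "nuclei":
        return scene.label_mask > 0
    if task == "region":
        if scene.region_mask is None:
            raise ParameterError("region scene lacks a region mask")
        return np.asarray(scene.region_mask, bool)
    # lymphocyte: positive within r px of a target center
    h, w = scene.label_mask.shape
    mask = np.zeros((h, w), bool)
    r = scene.params.nucleus_radius_mean
    tgt = scene.centers[scene.centers["class"] == "target"]
    if len(tgt):
        yy, xx = np.mgrid[:h, :w]
        for _, row in tgt.iterrows():
            mask |= (yy - row["row"]) ** 2 + (xx - row["col"]) ** 2 <= r * r
    return mask


def extract_patches(scene: Scene, config: TrainConfig,
                    rng: np.random.Generator | None = None):
    """Sample labeled square patches from a scene.

    A patch's label is the ground-truth class at its center pixel; the image
    is reflection-padded so every pixel is a valid center. Sampling honours
    ``config.balance`` (positive:negative); requesting positives from a
    scene with none raises :class:`EmptyClassError`.

    Returns ``(patches, labels)`` with patches ``(n, ps, ps, 3)`` uint8.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ps = config.patch_size
    pos = _positive_mask(scene)
    n = config.patches_per_scene
    n_pos = int(round(n * config.balance / (1.0 + config.balance)))
    n_neg = n - n_pos
    pos_idx = np.flatnonzero(pos.ravel())
    neg_idx = np.flatnonzero(~pos.ravel())
    if n_pos > 0 and len(pos_idx) == 0:
        raise EmptyClassError("scene has no positive pixels for this task")
    if n_neg > 0 and len(neg_idx) == 0:
        raise EmptyClassError("scene has no negative pixels for this task")

    chosen, labels = [], []
    for idx_pool, count, lab in ((pos_idx, n_pos, 1), (neg_idx, n_neg, 0)):
        if count == 0:
            continue
        take = rng.choice(idx_pool, size=count, replace=len(idx_pool) < count)
        chosen.append(take)
        labels.append(np.full(count, lab, dtype=np.int64))
    flat = np.concatenate(chosen)
    labels = np.concatenate(labels)
    rows, cols = np.unravel_index(flat, pos.shape)

    half = ps // 2
    padded = np.pad(scene.image, ((half, half), (half, half), (0, 0)), mode="reflect")
    patches = np.empty((len(flat), ps, ps, 3), dtype=np.uint8)
    for i, (r, c) in enumerate(zip(rows, cols)):
        patches[i] = padded[r:r + ps, c:c + ps]
    return patches, labels


def apply_dihedral(patch: np.ndarray, rot: int, mirror: bool) -> np.ndarray:
    """One named element of the dihedral group D4: rotate by rot*90 degrees
    counterclockwise, then flip left-right if mirror."""
    patch = np.asarray(patch)
    if patch.shape[0] != patch.shape[1]:
        raise DimensionError(f"patch must be square, got shape {patch.shape}")
    out = np.rot90(patch, k=rot % 4, axes=(0, 1))
    if mirror:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def augment_patch(patch: np.ndarray, seed) -> np.ndarray:
    """Apply one of the 8 dihedral transforms chosen uniformly.

    *seed* may be an integer or a ``numpy.random.Generator``. The pixel
    multiset is preserved exactly (rotations/mirrors only).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rot = int(rng.integers(0, 4))
    mirror = bool(rng.integers(0, 2))
    return apply_dihedral(patch, rot, mirror)


def _featurize(patches: np.ndarray, downsample: int) -> np.ndarray:
    x = patches[:, ::downsample, ::downsample, :]
    return (x.reshape(len(patches), -1).astype(np.float32) / np.float32(255.0))


class PatchClassifier:
    """A trained patch model: predicts P(positive) for square RGB patches.

    Serializable to a single checkpoint file with a versioned header.
    """

    def __init__(self, mlp: MLPClassifier, config: TrainConfig):
        self.mlp = mlp
        self.config = config

    @property
    def loss_curve(self) -> list[float]:
        return list(self.mlp.loss_curve_)

    @property
    def final_loss(self) -> float:
        return float(self.mlp.loss_curve_[-1])

    def predict_proba_patches(self, patches: np.ndarray) -> np.ndarray:
        x = _featurize(patches, self.config.downsample)
        proba = self.mlp.predict_proba(x)
        return proba[:, list(self.mlp.classes_).index(1)]

    def save(self, path) -> Path:
        path = Path(path)
        joblib.dump({"format": "histocompress-patch-model",
                     "version": _CHECKPOINT_VERSION,
                     "config": self.config, "mlp": self.mlp}, path)
        return path

    @classmethod
    def load(cls, path) -> "PatchClassifier":
        blob = joblib.load(path)
        if not (isinstance(blob, dict)
                and blob.get("format") == "histocompress-patch-model"):
            raise ParameterError(f"{path} is not a patch-model checkpoint")
        if blob.get("version") != _CHECKPOINT_VERSION:
            raise ParameterError(f"unsupported checkpoint version {blob.get('version')}")
        return cls(blob["mlp"], blob["config"])


def train_classifier(patches: np.ndarray, labels: np.ndarray,
                     config: TrainConfig) -> PatchClassifier:
    """Fit the patch classifier; deterministic given ``config.seed``.

    When ``config.augment`` is set, the training set is doubled with one
    random dihedral transform per patch (rotations in {0, 90, 180, 270}
    plus mirroring) — augmentation that leaves class frequencies unchanged.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise TrainingError("training requires at least 2 classes")
    rng = np.random.default_rng(config.seed)
    if config.augment:
        aug = np.stack([augment_patch(p, rng) for p in patches])
        patches = np.concatenate([patches, aug])
        labels = np.concatenate([labels, labels])
    x = _featurize(patches, config.downsample)
    mlp = MLPClassifier(
        hidden_layer_sizes=config.hidden_widths,
        batch_size=min(config.batch_size, len(x)),
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        solver="adam",
        shuffle=True,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_iter_no_change=max(10, config.epochs),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(x, labels)
    return PatchClassifier(mlp, config)


def predict_probability_map(model: PatchClassifier, image: np.ndarray,
                            task: str = "nuclei") -> ProbabilityMap:
    """Dense per-pixel probability map for an RGB image.

    Patch centers on a stride-``config.stride`` grid are scored (borders
    handled by reflection padding) and the grid is bilinearly upsampled to
    the full image resolution.
    """
    image = np.asarray(image)
    ps = model.config.patch_size
    if image.ndim != 3 or image.shape[0] < ps or image.shape[1] < ps:
        raise DimensionError(
            f"image shape {image.shape} smaller than patch size {ps}")
    h, w = image.shape[:2]
    half = ps // 2
    stride = model.config.stride
    padded = np.pad(image, ((half, half), (half, half), (0, 0)), mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (ps, ps, 3))[..., 0, :, :, :]
    rows = np.arange(0, h, stride)
    cols = np.arange(0, w, stride)
    grid = windows[np.ix_(rows, cols)]
    flat = grid.reshape(-1, ps, ps, 3)
    proba = model.predict_proba_patches(flat).reshape(len(rows), len(cols))
    if stride == 1:
        values = proba
    else:
        values = resize(proba, (h, w), order=1, mode="edge", anti_aliasing=False)
    return ProbabilityMap(values=np.clip(values, 0.0, 1.0), task=task)


def detect_centers(pmap: ProbabilityMap, threshold: float = 0.5,
                   min_distance: float = 6.0) -> CenterSet:
    """Local maxima of the map at or above *threshold*, greedily suppressed
    so no two returned centers are closer than *min_distance* px, sorted by
    descending score."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must lie strictly in (0, 1)")
    if min_distance <= 0:
        raise ParameterError("min_distance must be positive")
    v = pmap.values
    is_max = (v == ndimage.maximum_filter(v, size=3, mode="nearest")) & (v >= threshold)
    coords = np.argwhere(is_max)
    if len(coords) == 0:
        return CenterSet(coords=np.empty((0, 2)), scores=np.empty(0))
    scores = v[coords[:, 0], coords[:, 1]]
    # stable ordering: score desc, then row, col for ties
    order = np.lexsort((coords[:, 1], coords[:, 0], -scores))
    coords, scores = coords[order].astype(float), scores[order]
    kept_idx: list[int] = []
    for i in range(len(coords)):
        c = coords[i]
        if all(np.hypot(*(c - coords[j])) >= min_distance for j in kept_idx):
            kept_idx.append(i)
    return CenterSet(coords=coords[kept_idx], scores=scores[kept_idx])


def binarize_map(pmap: ProbabilityMap, threshold: float = 0.5) -> np.ndarray:
    """Boolean mask: probability >= threshold."""
    return np.asarray(pmap.values) >= threshold
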