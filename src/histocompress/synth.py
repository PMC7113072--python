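"""Seeded synthetic histology-like scenes with exact ground truth.

Scenes emulate three routine digital-pathology tasks at desk scale:

``nuclei``
    H&E-like field of textured elliptical nuclei on a pink background, with
    a per-pixel instance label mask (0 = background, k > 0 = nucleus id).
``lymphocyte``
    Small, dark, near-circular target cells (lymphocyte analog) mixed with
    larger, paler, elliptical distractor cells; ground truth is the list of
    annotated cell centers with a target/distractor class.
``region``
    A single spatially coherent "tumor" region occupying a controllable
    area fraction, with cells rendered differently inside vs outside; ground
    truth is the binary region mask.

All randomness flows from ``SceneParams.seed`` through a single
``numpy.random.Generator``, so a given parameter set reproduces the scene
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import OvercrowdingError, ParameterError, SceneFormatError

__all__ = ["SceneParams", "Scene", "generate_scene", "write_scene", "read_scene"]

TASKS = ("nuclei", "lymphocyte", "region")

#: hematoxylin-like purple used for nuclear chromatin
DEFAULT_STAIN_FG = (90, 60, 140)
#: eosin-like pink background (cytoplasm / stroma)
DEFAULT_STAIN_BG = (230, 180, 200)
#: paler purple for distractor cells / cells outside the tumor region
DEFAULT_STAIN_DISTRACTOR = (185, 150, 190)

MANIFEST_NAME = "scene.json"
_MANIFEST_VERSION = 1


@dataclass(frozen=True)
class SceneParams:
    """Generation parameters for one synthetic scene.

    ``cell_density`` is the expected number of cells per 10^4 px^2. The
    defaults emulate carcinoma tissue at roughly 10x magnification
    (~1 um/px): nuclei of ~8 px diameter at ~2,500-3,000 nuclei/mm^2, i.e.
    density 20 gives ~130 cells on a 256x256 field. Radii are
    semi-major axis lengths in pixels; eccentricity is drawn uniformly from
    ``eccentricity_range``. ``texture_sd`` is the within-nucleus Gaussian
    chromatin texture, ``noise_sd`` the additive background noise, both in
    8-bit intensity units.
    """

    width: int = 256
    height: int = 256
    task: str = "nuclei"
    cell_density: float = 20.0
    nucleus_radius_mean: float = 4.0
    nucleus_radius_sd: float = 1.0
    eccentricity_range: tuple[float, float] = (0.0, 0.7)
    stain_fg: tuple[int, int, int] = DEFAULT_STAIN_FG
    stain_bg: tuple[int, int, int] = DEFAULT_STAIN_BG
    stain_distractor: tuple[int, int, int] = DEFAULT_STAIN_DISTRACTOR
    texture_sd: float = 10.0
    noise_sd: float = 5.0
    region_fraction: float = 0.3
    distractor_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ParameterError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.width < 64 or self.height < 64:
            raise ParameterError("width and height must be >= 64 px")
        if self.cell_density < 0:
            raise ParameterError("cell_density must be >= 0")
        if self.nucleus_radius_mean <= 0 or self.nucleus_radius_sd < 0:
            raise ParameterError("nucleus radii must be positive")
        lo, hi = self.eccentricity_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ParameterError("eccentricity_range must satisfy 0 <= lo <= hi < 1")
        if not (0.0 < self.region_fraction < 1.0) and self.task == "region":
            raise ParameterError("region_fraction must lie in (0, 1)")
        if self.distractor_ratio < 0:
            raise ParameterError("distractor_ratio must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eccentricity_range"] = list(self.eccentricity_range)
        for k in ("stain_fg", "stain_bg", "stain_distractor"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        d["eccentricity_range"] = tuple(d["eccentricity_range"])
        for k in ("stain_fg", "stain_bg", "stain_distractor"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class Scene:
    """An RGB raster plus its exact ground truth.

    ``centers`` rows are ``(row, col, class)`` with class in
    {"target", "distractor"}; for the nuclei task each target center is the
    area centroid of exactly one label id (ids contiguous 1..K).
    """

    image: np.ndarray                       # H x W x 3, uint8
    label_mask: np.ndarray                  # H x W, int32, 0 = background
    region_mask: np.ndarray | None          # H x W, bool (region task only)
    centers: pd.DataFrame                   # columns: row, col, class
    params: SceneParams

    @property
    def n_objects(self) -> int:
        return int(self.label_mask.max())


def _draw_ellipse(label_mask, obj_id, cy, cx, a, b, theta):
    """Rasterize a filled rotated ellipse into *label_mask* (later id wins)."""
    h, w = label_mask.shape
    r = math.ceil(max(a, b)) + 1
    r0, r1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    c0, c1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    label_mask[r0:r1, c0:c1][inside] = obj_id


def _place_centers(rng, n, h, w, radii, existing=None, max_retries=50):
    """Uniform placement with rejection to limit overlap.

    A candidate is rejected while its center is within 0.8 * (r_i + r_j) of
    any already placed center; after *max_retries* draws the last candidate
    is accepted anyway so the Poisson object count is preserved.
    """
    if existing:
        py = np.array([p[0] for p in existing])
        px = np.array([p[1] for p in existing])
        pr = np.array([p[2] for p in existing])
    else:
        py = px = pr = np.empty(0)
    out = []
    for i in range(n):
        ri = radii[i]
        for _ in range(max_retries):
            cy = rng.uniform(0, h)
            cx = rng.uniform(0, w)
            lim = 0.8 * (ri + pr)
            if not np.any((cy - py) ** 2 + (cx - px) ** 2 < lim * lim):
                break
        py = np.append(py, cy)
        px = np.append(px, cx)
        pr = np.append(pr, ri)
        out.append((cy, cx, ri))
    return out


def _region_mask(rng, h, w, fraction):
    """Single smoothed connected region with area fraction ~ *fraction*.

    A low-frequency Gaussian random field is biased by a radial bump at a
    random anchor; the threshold is bisected until the largest connected
    component of the superlevel set hits the target fraction (within 10%,
    well inside the documented +-20% contract).
    """
    field_ = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=min(h, w) / 8.0)
    field_ /= max(field_.std(), 1e-9)
    ay = rng.uniform(0.25 * h, 0.75 * h)
    ax = rng.uniform(0.25 * w, 0.75 * w)
    yy, xx = np.mgrid[:h, :w]
    rr = math.sqrt(fraction * h * w / math.pi)
    field_ = field_ + 2.0 * np.exp(-(((yy - ay) ** 2 + (xx - ax) ** 2) / (2 * rr * rr)))

    def largest_cc(thresh):
        lab, n = ndimage.label(field_ >= thresh)
        if n == 0:
            return np.zeros((h, w), bool)
        sizes = ndimage.sum_labels(np.ones((h, w)), lab, index=np.arange(1, n + 1))
        return lab == (1 + int(np.argmax(sizes)))

    lo, hi = float(field_.min()), float(field_.max())
    mask = None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        mask = largest_cc(mid)
        frac = mask.mean()
        if abs(frac - fraction) <= 0.10 * fraction:
            break
        if frac > fraction:
            lo = mid
        else:
            hi = mid
    mask = ndimage.binary_closing(mask, iterations=2)
    return mask


def generate_scene(params: SceneParams) -> Scene:
    """Render one scene deterministically from its parameters.

    The object count is a Poisson draw with mean
    ``cell_density * H * W / 1e4``; each object is a filled rotated ellipse
    with per-object stain jitter and within-object Gaussian texture, drawn
    over a noisy background. Overlaps are resolved later-id-wins, then ids
    are compacted to 1..K and centroids recomputed, so the label mask is
    always a partition consistent with the center list.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.height, p.width
    lam = p.cell_density * h * w / 1e4
    max_count = 0.25 * h * w / (math.pi * p.nucleus_radius_mean**2)
    if lam > max_count:
        raise OvercrowdingError(
            f"expected {lam:.0f} objects exceeds the overcrowding limit {max_count:.0f} "
            f"for radius {p.nucleus_radius_mean}"
        )

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = p.stain_bg
    label_mask = np.zeros((h, w), dtype=np.int32)
    region = _region_mask(rng, h, w, p.region_fraction) if p.task == "region" else None

    n_targets = int(rng.poisson(lam))
    ecc_lo, ecc_hi = p.eccentricity_range

    def draw_radii(n, mean, sd):
        return np.clip(rng.normal(mean, sd, size=n), 1.5, None)

    specs = []  # (cy, cx, a, b, theta, color, cls)
    if p.task == "lymphocyte":
        # targets: small, dark, near-circular; distractors: larger, paler,
        # elliptical — mirrors the visual contrast of lymphocytes vs other cells
        n_distr = int(round(p.distractor_ratio * n_targets))
        t_rad = draw_radii(n_targets, 0.6 * p.nucleus_radius_mean, 0.5 * p.nucleus_radius_sd)
        d_rad = draw_radii(n_distr, 1.4 * p.nucleus_radius_mean, p.nucleus_radius_sd)
        target_fg = tuple(max(0, c - 40) for c in p.stain_fg)
        order = _place_centers(rng, n_targets + n_distr, h, w, np.concatenate([t_rad, d_rad]))
        for i, (cy, cx, a) in enumerate(order):
            if i < n_targets:
                ecc = rng.uniform(0.0, 0.25)
                base, cls = target_fg, "target"
            else:
                ecc = rng.uniform(max(ecc_lo, 0.4), max(ecc_hi, 0.5))
                base, cls = p.stain_distractor, "distractor"
            b = a * math.sqrt(1 - ecc * ecc)
            theta = rng.uniform(0, math.pi)
            color = np.array(base) + rng.normal(0, 8, size=3)
            specs.append((cy, cx, a, b, theta, color, cls))
    else:
        rad = draw_radii(n_targets, p.nucleus_radius_mean, p.nucleus_radius_sd)
        for cy, cx, a in _place_centers(rng, n_targets, h, w, rad):
            ecc = rng.uniform(ecc_lo, ecc_hi)
            b = a * math.sqrt(1 - ecc * ecc)
            theta = rng.uniform(0, math.pi)
            if p.task == "region" and not region[min(int(cy), h - 1), min(int(cx), w - 1)]:
                base = p.stain_distractor
            else:
                base = p.stain_fg
            color = np.array(base) + rng.normal(0, 8, size=3)
            specs.append((cy, cx, a, b, theta, color, "target"))

    for obj_id, (cy, cx, a, b, theta, _, _) in enumerate(specs, start=1):
        _draw_ellipse(label_mask, obj_id, cy, cx, a, b, theta)

    # paint surviving pixels of each object (later id already won in the mask)
    for obj_id, (_, _, _, _, _, color, _) in enumerate(specs, start=1):
        m = label_mask == obj_id
        npx = int(m.sum())
        if npx:
            image[m] = color + rng.normal(0, p.texture_sd, size=(npx, 3))

    bg = label_mask == 0
    image[bg] += rng.normal(0, p.noise_sd, size=(int(bg.sum()), 3))
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    # compact ids (overlap can erase early objects entirely)
    old_ids = np.unique(label_mask)
    old_ids = old_ids[old_ids > 0]
    remap = np.zeros(int(label_mask.max()) + 1, dtype=np.int32)
    remap[old_ids] = np.arange(1, len(old_ids) + 1, dtype=np.int32)
    label_mask = remap[label_mask]

    if p.task == "lymphocyte":
        rows = [
            {"row": cy, "col": cx, "class": cls}
            for (cy, cx, _, _, _, _, cls), old in zip(specs, np.arange(1, len(specs) + 1))
            if remap[old] > 0
        ]
        centers = pd.DataFrame(rows, columns=["row", "col", "class"])
    else:
        k = len(old_ids)
        if k:
            com = ndimage.center_of_mass(label_mask > 0, label_mask, index=np.arange(1, k + 1))
            centers = pd.DataFrame(
                [{"row": cy, "col": cx, "class": "target"} for cy, cx in com],
                columns=["row", "col", "class"],
            )
        else:
            centers = pd.DataFrame(columns=["row", "col", "class"])

    return Scene(image=image, label_mask=label_mask, region_mask=region,
                 centers=centers, params=p)


# ---------------------------------------------------------------------------
# persistence: PNG rasters + CSV centers + JSON manifest

def write_scene(scene: Scene, directory) -> Path:
    """Write a scene losslessly; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {"image": "image.png", "label_mask": "label_mask.png", "centers": "centers.csv"}
    Image.fromarray(scene.image).save(directory / files["image"])
    if scene.label_mask.max() > np.iinfo(np.uint16).max:
        raise ParameterError("more than 65535 objects cannot round-trip through 16-bit PNG")
    Image.fromarray(scene.label_mask.astype(np.uint16)).save(directory / files["label_mask"])
    if scene.region_mask is not None:
        files["region_mask"] = "region_mask.png"
        Image.fromarray(scene.region_mask.astype(np.uint16) * 65535).save(
            directory / files["region_mask"])
    scene.centers.to_csv(directory / files["centers"], index=False)
    manifest = {
        "format_version": _MANIFEST_VERSION,
        "files": files,
        "params": scene.params.to_dict(),
    }
    path = directory / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_scene(directory) -> Scene:
    """Inverse of :func:`write_scene`; raises SceneFormatError naming any
    missing or unreadable component."""
    directory = Path(directory)
    mpath = directory / MANIFEST_NAME
    if not mpath.is_file():
        raise SceneFormatError(f"missing manifest {mpath}")
    try:
        manifest = json.loads(mpath.read_text())
        files = manifest["files"]
        params = SceneParams.from_dict(manifest["params"])
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise SceneFormatError(f"corrupt manifest {mpath}: {exc}") from exc

    def load(key, loader):
        fname = files.get(key)
        if fname is None or not (directory / fname).is_file():
            raise SceneFormatError(f"missing component file for '{key}' in {directory}")
        try:
            return loader(directory / fname)
        except Exception as exc:  # noqa: BLE001 — reported as a format error
            raise SceneFormatError(f"unreadable component '{fname}': {exc}") from exc

    image = load("image", lambda f: np.asarray(Image.open(f).convert("RGB")))
    label = load("label_mask", lambda f: np.asarray(Image.open(f)).astype(np.int32))
    region = None
    if params.task == "region":
        region = load("region_mask", lambda f: np.asarray(Image.open(f)) > 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty CSV is legal for 0-object scenes
        centers = load("centers", lambda f: pd.read_csv(
            f, dtype={"row": float, "col": float, "class": str}))
    if list(centers.columns) != ["row", "col", "class"]:
        centers = pd.DataFrame(columns=["row", "col", "class"])
    return Scene(image=image, label_mask=label, region_mask=region,
                 centers=centers, params=params)
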