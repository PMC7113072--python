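"""End-to-end compression-robustness sweep.

One config drives the full experiment: generate synthetic scenes, split
into train/test, train the patch classifier on clean images only, then for
each test image and each compression level — encode, decode, infer, score.
For the nuclei task the predicted segmentations additionally feed the
nuclear-architecture feature tables and the level x feature stability
matrix. Everything is deterministic given the master seed (training is
single-threaded scikit-learn, reproducible on a fixed machine).

The protocol invariant — no lossy-compressed image ever enters training —
is structural here (training happens before any encoder runs) and is also
recorded in the output manifest for audit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from . import codec, metrics
from .errors import ConvergenceError, ParameterError, PipelineStageError
from .features import (StabilityMatrix, compute_feature_table, label_objects,
                       stability_matrix)
from .model import (PatchClassifier, TrainConfig, binarize_map,
                    detect_centers, extract_patches, predict_probability_map,
                    train_classifier)
from .synth import Scene, SceneParams, generate_scene

__all__ = ["SweepConfig", "SweepResult", "run_sweep", "summarize_curves",
           "plot_stability_heatmap"]

#: nominal PSNR assigned to the lossless level on degradation curves
LOSSLESS_LEVEL = 100.0


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one compression sweep.

    The scene template's ``seed`` is ignored: per-scene seeds are derived
    from ``seed`` (the master seed). ``psnr_targets`` is the JPEG2000
    ladder; ``jpeg_qualities`` optionally adds a JPEG quality ladder.
    """

    task: str = "nuclei"
    n_train: int = 8
    n_test: int = 3
    scene: SceneParams = field(default_factory=SceneParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    psnr_targets: tuple[float, ...] = (18, 20, 22, 25, 30, 35, 40)
    jpeg_qualities: tuple[int, ...] = ()
    include_lossless: bool = True
    psnr_tol: float = 0.5
    threshold: float = 0.5
    min_area: int = 5
    link_radius_factor: float = 5.0
    match_radius: float | None = None
    compute_features: bool | None = None  # None -> only for the nuclei task
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ParameterError("n_train and n_test must be >= 1")
        if not (self.psnr_targets or self.jpeg_qualities or self.include_lossless):
            raise ParameterError("at least one compression level is required")

    @property
    def features_enabled(self) -> bool:
        if self.compute_features is None:
            return self.task == "nuclei"
        return self.compute_features

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "scene" in raw:
            raw["scene"] = SceneParams.from_dict(raw["scene"])
        if "train" in raw:
            t = dict(raw["train"])
            if "hidden_widths" in t:
                t["hidden_widths"] = tuple(t["hidden_widths"])
            raw["train"] = TrainConfig(**t)
        for k in ("psnr_targets", "jpeg_qualities"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scene"] = self.scene.to_dict()
        d["train"] = dataclasses.asdict(self.train)
        d["train"]["hidden_widths"] = list(self.train.hidden_widths)
        d["psnr_targets"] = list(self.psnr_targets)
        d["jpeg_qualities"] = list(self.jpeg_qualities)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class SweepResult:
    """Long-format results plus the stability matrix (nuclei task)."""

    table: pd.DataFrame            # image, codec, level, achieved_psnr, ratio, metric, value
    stability: StabilityMatrix | None
    model: PatchClassifier
    manifest: dict


def _derive_seeds(master: int, n: int) -> np.ndarray:
    return np.random.default_rng(master).integers(0, 2**31 - 1, size=n)


def _levels(config: SweepConfig):
    levels = []
    if config.include_lossless:
        levels.append(("jpeg2000-lossless", LOSSLESS_LEVEL))
    levels += [("jpeg2000", float(t)) for t in config.psnr_targets]
    levels += [("jpeg", int(q)) for q in config.jpeg_qualities]
    return levels


def _encode_level(image, cdc, control, tol):
    """Returns (decoded, record, converged) for one (codec, control) level."""
    if cdc == "jpeg2000-lossless":
        data, rec = codec.encode_jpeg2000_lossless(image)
        return codec.decode_image(data), rec, True
    if cdc == "jpeg2000":
        try:
            data, rec = codec.compress_to_target_psnr(image, control, tol=tol)
            return codec.decode_image(data), rec, True
        except ConvergenceError as exc:
            if exc.best is None:
                raise
            data, rec = exc.best
            return codec.decode_image(data), rec, False
    data, rec = codec.encode_jpeg(image, control)
    return codec.decode_image(data), rec, True


def _score(config: SweepConfig, scene: Scene, pmap) -> dict[str, float]:
    out = {}
    if config.task == "nuclei":
        out["pixel_f1"] = metrics.pixel_f1(binarize_map(pmap, config.threshold),
                                           scene.label_mask > 0)
    elif config.task == "region":
        gt = np.asarray(scene.region_mask, bool)
        out["pixel_f1"] = metrics.pixel_f1(binarize_map(pmap, config.threshold), gt)
        out["pixel_auc"] = metrics.pixel_auc(pmap.values, gt)
    else:  # lymphocyte
        radius = config.match_radius or scene.params.nucleus_radius_mean
        det = detect_centers(pmap, threshold=config.threshold, min_distance=radius)
        tgt = scene.centers[scene.centers["class"] == "target"]
        match = metrics.match_detections(det.coords, tgt[["row", "col"]].to_numpy(),
                                         radius=radius)
        out["detection_f1"] = metrics.detection_f1(match)
    return out


def run_sweep(config: SweepConfig, out_dir=None) -> SweepResult:
    """Execute the full experiment; see the module docstring.

    Artifacts (metrics.csv, features.csv, stability_rel.csv,
    stability.json, stability.png, manifest.json) are written under
    *out_dir* when given. A failing stage raises
    :class:`PipelineStageError` naming the stage; files written by earlier
    stages are left in place.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    stage = "generate"
    try:
        seeds = _derive_seeds(config.seed, config.n_train + config.n_test + 2)
        mk = lambda i: generate_scene(dataclasses.replace(  # noqa: E731
            config.scene, task=config.task, seed=int(seeds[i])))
        train_scenes = [mk(i) for i in range(config.n_train)]
        test_scenes = [mk(config.n_train + i) for i in range(config.n_test)]
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "train"
    try:
        patch_rng = np.random.default_rng(int(seeds[-2]))
        xs, ys = [], []
        for sc in train_scenes:
            p, l = extract_patches(sc, config.train, rng=patch_rng)
            xs.append(p)
            ys.append(l)
        tcfg = dataclasses.replace(config.train, seed=int(seeds[-1]))
        model = train_classifier(np.concatenate(xs), np.concatenate(ys), tcfg)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "evaluate"
    radius = config.match_radius or config.scene.nucleus_radius_mean
    link_radius = config.link_radius_factor * config.scene.nucleus_radius_mean
    rows = []
    feat_rows = []
    tables: dict[float, list] = {}
    try:
        for (cdc, control) in _levels(config):
            if cdc != "jpeg":
                tables.setdefault(float(control), [])
        for img_idx, sc in enumerate(test_scenes):
            for (cdc, control) in _levels(config):
                decoded, rec, converged = _encode_level(sc.image, cdc, control,
                                                        config.psnr_tol)
                pmap = predict_probability_map(model, decoded, task=config.task)
                for metric, value in _score(config, sc, pmap).items():
                    rows.append({
                        "image": img_idx, "codec": cdc, "level": control,
                        "achieved_psnr": rec.achieved_psnr, "ratio": rec.ratio,
                        "compressed_bytes": rec.compressed_bytes,
                        "converged": converged, "metric": metric, "value": value,
                    })
                if config.features_enabled and cdc != "jpeg":
                    mask = binarize_map(pmap, config.threshold)
                    labels, cents = label_objects(mask, min_area=config.min_area)
                    table = compute_feature_table(labels, cents, link_radius)
                    tables[float(control)].append(table)
                    feat_rows.append({"image": img_idx, "codec": cdc,
                                      "level": control,
                                      **dict(zip(table.names, table.values))})
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    table = pd.DataFrame(rows)
    stab = None
    if config.features_enabled and config.include_lossless and len(config.psnr_targets):
        stage = "stability"
        try:
            stab = stability_matrix({lv: ts for lv, ts in tables.items() if ts},
                                    lossless_level=LOSSLESS_LEVEL)
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

    manifest = {
        "config": config.to_dict(),
        "scene_seeds": {"train": [int(s) for s in seeds[:config.n_train]],
                        "test": [int(s) for s in seeds[config.n_train:-2]]},
        "training_inputs": [
            {"index": i, "compressed": False} for i in range(config.n_train)],
        "levels": [{"codec": c, "level": l} for c, l in _levels(config)],
    }

    if out is not None:
        stage = "write"
        try:
            table.to_csv(out / "metrics.csv", index=False)
            manifest["artifacts"] = ["metrics.csv"]
            if feat_rows:
                pd.DataFrame(feat_rows).to_csv(out / "features.csv", index=False)
                manifest["artifacts"].append("features.csv")
            if stab is not None:
                stab.to_dataframe("rel").to_csv(out / "stability_rel.csv")
                (out / "stability.json").write_text(json.dumps({
                    "levels": stab.levels.tolist(),
                    "names": list(stab.names),
                    "families": list(stab.families),
                    "rel_diff": stab.rel_diff.tolist(),
                    "raw_diff": stab.raw_diff.tolist(),
                }, indent=1))
                plot_stability_heatmap(stab, out / "stability.png")
                manifest["artifacts"] += ["stability_rel.csv", "stability.json",
                                          "stability.png"]
            manifest["artifacts"].append("manifest.json")
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

    return SweepResult(table=table, stability=stab, model=model, manifest=manifest)


def summarize_curves(result: SweepResult) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-level aggregate curves and the PSNR-ratio rank correlation.

    Returns a table with mean +- sd of every metric, mean ratio and mean
    achieved PSNR per (codec, level), plus the Spearman correlation between
    achieved PSNR and compression ratio for each lossy codec ladder.
    """
    t = result.table
    if t["level"].nunique() < 2:
        raise ParameterError("need >= 2 compression levels to summarize curves")
    grouped = t.groupby(["codec", "level", "metric"]).agg(
        mean_value=("value", "mean"), sd_value=("value", "std"),
        mean_ratio=("ratio", "mean"), mean_psnr=("achieved_psnr", "mean"),
        n=("value", "size"),
    ).reset_index()
    rho: dict[str, float] = {}
    for cdc in t["codec"].unique():
        sub = t[t["codec"] == cdc].drop_duplicates(["image", "level"])
        if sub["level"].nunique() >= 2:
            rho[cdc] = float(spearmanr(sub["achieved_psnr"], sub["ratio"]).statistic)
    return grouped, rho


def plot_stability_heatmap(stab: StabilityMatrix, path) -> None:
    """Render the level x feature relative-difference heat map to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(14, 3 + 0.25 * len(stab.levels)))
    im = ax.imshow(stab.rel_diff, aspect="auto", cmap="viridis",
                   vmin=0.0, vmax=1.0, interpolation="nearest")
    ax.set_yticks(range(len(stab.levels)),
                  [f"{lv:.1f}" for lv in stab.levels])
    ax.set_ylabel("compression level (PSNR dB)")
    # family boundaries on the x axis
    fams = list(stab.families)
    ticks, labels_ = [], []
    start = 0
    for i in range(1, len(fams) + 1):
        if i == len(fams) or fams[i] != fams[start]:
            ticks.append((start + i - 1) / 2)
            labels_.append(fams[start])
            if i < len(fams):
                ax.axvline(i - 0.5, color="w", lw=1)
            start = i
    ax.set_xticks(ticks, labels_)
    ax.set_xlabel("feature family")
    fig.colorbar(im, ax=ax, label="relative difference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
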