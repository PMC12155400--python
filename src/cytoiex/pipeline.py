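"""End-to-end orchestration: generate, segment, measure, train, classify,
evaluate, report — with deterministic seeding, persisted intermediates and a
run manifest.

The demo pipeline exercises the whole chain on synthetic scenes: ground-truth
labels are transferred to segmented masks by best-IoU matching, features are
normalized with training statistics only, and held-out cells are scored with
the trained container model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import evalreport, features, iextreme, stainseg, synthgen

logger = logging.getLogger("cytoiex")

MODEL_SCHEMA_VERSION = iextreme.SCHEMA_VERSION

#: Generator presets are named after the tissue state; the recognition-class
#: alphabet and the metrics use the diagnostic labels.
LABEL_MAP = {"pathological": "malignant", "normal": "normal"}


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All stage parameters with their documented defaults."""

    seed: int = 7
    canvas: tuple[int, int] = (1024, 1024)
    nuclei_per_scene: int = 20
    n_train_scenes: int = 6
    n_test_scenes: int = 4
    n_train_cells: int = 100
    n_test_cells: int = 76
    min_area: int = 500
    solidity_min: float = 0.6
    ecc_max: float = 0.98
    active_contours: bool = False
    tissue_only: bool = False
    alpha: float = 0.05
    r: int = 2
    bits_per_feature: int = 1
    iou_match_threshold: float = 0.5
    unclassified_policy: str = "as-normal"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "canvas" in d:
            d = {**d, "canvas": tuple(d["canvas"])}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canvas"] = list(self.canvas)
        return d


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: list[str] = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def save_model(model: dict, path: str | Path) -> None:
    """Write a trained model dict as deterministic JSON."""
    Path(path).write_text(json.dumps(model, indent=2, sort_keys=True))


def load_model(path: str | Path) -> dict:
    """Read and schema-check a model JSON file."""
    model = json.loads(Path(path).read_text())
    version = model.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(f"model schema version {version!r} != {MODEL_SCHEMA_VERSION}")
    return model


def match_masks_to_truth(
    predicted: list[np.ndarray], truth: list[np.ndarray], iou_threshold: float = 0.5
) -> list[tuple[int, int, float]]:
    """Greedy best-IoU matching: (predicted index, truth index, IoU) triples."""
    matches = []
    used = set()
    for i, p in enumerate(predicted):
        p = np.asarray(p, dtype=bool)
        best_j, best_iou = -1, 0.0
        for j, t in enumerate(truth):
            if j in used:
                continue
            t = np.asarray(t, dtype=bool)
            inter = np.logical_and(p, t).sum()
            if inter == 0:
                continue
            iou = inter / np.logical_or(p, t).sum()
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_threshold:
            matches.append((i, best_j, float(best_iou)))
            used.add(best_j)
    return matches


def scene_feature_table(
    scene: synthgen.SyntheticScene, config: PipelineConfig
) -> pd.DataFrame:
    """Segment one scene and extract labeled features for matched nuclei."""
    params = stainseg.SegmentationParams(
        solidity_min=config.solidity_min,
        ecc_max=config.ecc_max,
        active_contours=config.active_contours,
    )
    stain, _, nuclei = stainseg.segment_image(
        scene.image, min_area=config.min_area, params=params, tissue_only=config.tissue_only
    )
    gray = features.gray_from_hematoxylin(stain.hema)
    matches = match_masks_to_truth(
        [n.mask for n in nuclei], scene.nucleus_masks, config.iou_match_threshold
    )
    masks = [nuclei[i].mask for i, _, _ in matches]
    labels = [LABEL_MAP.get(scene.labels[j], scene.labels[j]) for _, j, _ in matches]
    if not masks:
        return pd.DataFrame()
    table = features.extract_features(masks, gray, labels=labels)
    table["iou"] = [iou for _, _, iou in matches]
    return table


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Full synthetic demo: generate -> segment -> features -> train ->
    classify -> evaluate -> report.  Deterministic for a fixed config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)

    def stage(name):
        manifest.stages.append(name)
        logger.info("stage: %s", name)
        return time.perf_counter()

    t0 = stage("generate")
    rng = np.random.default_rng(config.seed)
    scenes = [
        synthgen.generate_scene(
            "mixed", config.nuclei_per_scene, config.canvas, int(rng.integers(0, 2**31 - 1))
        )
        for _ in range(config.n_train_scenes + config.n_test_scenes)
    ]
    manifest.timings["generate"] = time.perf_counter() - t0

    t0 = stage("segment+features")
    tables = [scene_feature_table(s, config) for s in scenes]
    table = pd.concat([t for t in tables if not t.empty], ignore_index=True)
    manifest.timings["segment+features"] = time.perf_counter() - t0

    t0 = stage("split+normalize")
    order = rng.permutation(len(table))
    n_train = min(config.n_train_cells, len(table) - 1)
    train_tab = table.iloc[order[:n_train]].reset_index(drop=True)
    test_tab = table.iloc[order[n_train : n_train + config.n_test_cells]].reset_index(drop=True)
    norm = features.fit_normalization(train_tab, alpha=config.alpha)
    train_n = features.apply_normalization(norm, train_tab)
    test_n = features.apply_normalization(norm, test_tab)
    manifest.timings["split+normalize"] = time.perf_counter() - t0

    t0 = stage("train")
    clf, model = iextreme.train(
        train_n, label_col="class",
        feature_cols=[c for c in features.FEATURE_COLUMNS],
        r=config.r, bits_per_feature=config.bits_per_feature,
    )
    model["normalization"] = norm.normalizer.to_dict()
    model_path = outdir / "model.json"
    save_model(model, model_path)
    manifest.timings["train"] = time.perf_counter() - t0

    t0 = stage("classify+evaluate")
    X_test = test_n[list(features.FEATURE_COLUMNS)].to_numpy(dtype=float)
    preds = clf.predict(X_test)
    report = evalreport.evaluate(
        test_tab["class"], preds, unclassified_policy=config.unclassified_policy
    )
    metrics_path = outdir / "metrics.json"
    metrics_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    pred_path = outdir / "predictions.csv"
    pd.DataFrame({"cell_id": test_tab["cell_id"], "truth": test_tab["class"], "pred": preds}).to_csv(
        pred_path, index=False
    )
    manifest.timings["classify+evaluate"] = time.perf_counter() - t0

    t0 = stage("report")
    demo_scene = scenes[-1]
    stain, _, nuclei = stainseg.segment_image(demo_scene.image, min_area=config.min_area)
    gray = features.gray_from_hematoxylin(stain.hema)
    if nuclei:
        tab = features.extract_features([n.mask for n in nuclei], gray)
        tab_n = features.apply_normalization(norm, tab)
        X = tab_n[list(features.FEATURE_COLUMNS)].to_numpy(dtype=float)
        scene_preds = clf.predict(X)
        mu = clf.decision_function(X)
        frac = stainseg.lesion_fraction(nuclei, demo_scene.image.shape[:2])
        overlay, cell_report = evalreport.annotate(
            demo_scene.image, [n.mask for n in nuclei], scene_preds,
            memberships=mu, class_order=list(clf.classes_), lesion_fraction=frac,
        )
        Image.fromarray(overlay).save(outdir / "overlay.png")
        (outdir / "report.json").write_text(json.dumps(cell_report, indent=2, sort_keys=True))
    manifest.timings["report"] = time.perf_counter() - t0

    manifest.outputs = {
        "model": str(model_path),
        "metrics": str(metrics_path),
        "predictions": str(pred_path),
        "n_cells_total": int(len(table)),
        "n_train": int(len(train_tab)),
        "n_test": int(len(test_tab)),
        "accuracy": report.accuracy,
        "precision": report.precision,
        "recall": report.recall,
        "f1": report.f1,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    return manifest
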