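"""End-to-end orchestration: enhance → segment → extract → fuse → select →
split/train → evaluate → compare, from one config with a single global seed.

Every stage writes its artifacts under the run directory and is recorded in
a manifest (paths, sha256 hashes, per-stage seeds, timings). A rerun with
``resume=True`` skips stages whose artifacts already exist, so deleting a
downstream artifact recomputes only downstream work. Per-stage seeds are
derived deterministically from the global seed and the stage name, so each
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from . import aco_select, classify, enhancement, evaluate, features, gac_segment
from .imaging_io import (ImageRecord, LabeledImageSet, RasterImage, read_image,
                         scan_dataset, to_grayscale, write_image, write_mask)
from .synthetic import TileSpec, generate_dataset, standin_extractor

__all__ = ["PipelineConfig", "run_pipeline", "compare_strategies", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of "stage:global_seed", < 2**31."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    """One config for a full run; unset input_root generates synthetic tiles."""

    out_dir: Union[str, Path] = "run"
    input_root: Optional[str] = None
    extractors: Sequence[str] = ("resnet50", "densenet169", "mobilenet")
    seed: int = 0

    # synthetic data (used when input_root is None)
    tile_size: int = 128
    n_per_class: int = 40
    n_classes: int = 5

    # stage parameters
    enhance_window: int = 5
    gac: gac_segment.GACConfig = field(default_factory=gac_segment.GACConfig)
    subset_size: Optional[int] = None        # None -> published table / heuristic
    aco_iters: int = 10
    aco_ants: int = 10
    split: classify.SplitSpec = field(default_factory=classify.SplitSpec)
    augment: Optional[classify.AugmentConfig] = None   # None = feature pass-through
    classifiers: Sequence[str] = ("dt", "rf")
    rf_trees: int = 200

    def __post_init__(self) -> None:
        if not self.extractors:
            raise ValueError("at least one extractor is required")
        if any(k not in ("dt", "rf") for k in self.classifiers):
            raise ValueError("classifiers must be drawn from {'dt','rf'}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gac" in raw:
            raw["gac"] = gac_segment.GACConfig(**raw["gac"])
        if "split" in raw:
            raw["split"] = classify.SplitSpec(**raw["split"])
        if raw.get("augment"):
            raw["augment"] = classify.AugmentConfig(**raw["augment"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.path = out_dir / "manifest.json"
        self.data = {"config": _config_dict(config), "stages": {}}

    def record(self, stage: str, artifacts: Sequence[Path], seed: int,
               elapsed: float, cached: bool) -> None:
        self.data["stages"][stage] = {
            "artifacts": [str(p.relative_to(self.out_dir)) for p in artifacts],
            "hashes": [_sha256(p) for p in artifacts],
            "seed": seed,
            "elapsed_s": round(elapsed, 3),
            "cached": cached,
        }
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1)


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["out_dir"] = str(d["out_dir"])
    d["extractors"] = list(d["extractors"])
    d["classifiers"] = list(d["classifiers"])
    return d


def _segment_dataset(dataset: LabeledImageSet, config: PipelineConfig,
                     enh_dir: Path, mask_dir: Path, roi_dir: Path) -> None:
    for rec in dataset.records:
        rel = Path(rec.sample_id)
        original = rec.load()
        enhanced = enhancement.enhance(original, size=config.enhance_window)
        write_image(enhanced, enh_dir / rel)
        gray = to_grayscale(enhanced)
        try:
            result = gac_segment.segment(gray, config.gac)
            mask = gac_segment.postprocess_mask(result.mask)
        except (gac_segment.DegenerateRegionError,
                gac_segment.EmptySegmentationError):
            mask = np.ones(gray.pixels.shape, dtype=bool)  # fall back to whole tile
        write_mask(mask, mask_dir / rel.with_suffix(".png"))
        roi = gac_segment.extract_roi(original, mask)
        write_image(roi, roi_dir / rel)


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)

    # ---- stage: dataset -------------------------------------------------
    t0 = time.time()
    data_dir = out / "data"
    seed_data = stage_seed(config.seed, "data")
    cached = resume and data_dir.is_dir() and any(data_dir.iterdir())
    if config.input_root is not None:
        dataset = scan_dataset(config.input_root)
        data_dir = Path(config.input_root)
    elif cached:
        dataset = scan_dataset(data_dir)
    else:
        spec = TileSpec(size=(config.tile_size, config.tile_size),
                        n_classes=config.n_classes, seed=seed_data)
        dataset = generate_dataset(spec, config.n_per_class, seed=seed_data,
                                   out_dir=data_dir)
    manifest.record("data", [], seed_data, time.time() - t0, cached)

    # ---- stage: enhance + segment + ROI export --------------------------
    t0 = time.time()
    enh_dir, mask_dir, roi_dir = out / "enhanced", out / "masks", out / "roi"
    sentinel = out / "segmentation.done"
    cached = resume and sentinel.exists()
    if not cached:
        _segment_dataset(dataset, config, enh_dir, mask_dir, roi_dir)
        sentinel.write_text("ok")
    manifest.record("segment", [sentinel], stage_seed(config.seed, "segment"),
                    time.time() - t0, cached)
    roi_set = scan_dataset(roi_dir)

    # ---- stage: extract per extractor -----------------------------------
    seed_extract = stage_seed(config.seed, "extract")
    matrices = []
    extract_paths = []
    t0 = time.time()
    cached_all = True
    for name in config.extractors:
        path = out / f"features_{name}.csv"
        if resume and path.exists():
            matrices.append(features.read_feature_csv(path))
        else:
            cached_all = False
            extractor = standin_extractor(name, seed=seed_extract)
            m = features.extract_features(roi_set, extractor)
            features.write_feature_csv(m, path)
            matrices.append(m)
        extract_paths.append(path)
    manifest.record("extract", extract_paths, seed_extract,
                    time.time() - t0, cached_all)

    # ---- stage: fuse ----------------------------------------------------
    t0 = time.time()
    fused_path = out / "fused.csv"
    cached = resume and fused_path.exists()
    if cached:
        fused = features.read_feature_csv(fused_path)
    else:
        fused = features.fuse(matrices)
        features.write_feature_csv(fused, fused_path)
    manifest.record("fuse", [fused_path], stage_seed(config.seed, "fuse"),
                    time.time() - t0, cached)

    # ---- stage: split (before selection: the search must not see test data)
    t0 = time.time()
    split_path = out / "split.json"
    seed_split = stage_seed(config.seed, "split")
    cached = resume and split_path.exists()
    if cached:
        split = json.loads(split_path.read_text())
    else:
        spec = classify.SplitSpec(**{**asdict(config.split), "seed": seed_split})
        train, val, test = classify.stratified_split(
            fused.sample_ids, fused.labels, spec)
        split = {"train": train, "val": val, "test": test}
        split_path.write_text(json.dumps(split, indent=1))
    manifest.record("split", [split_path], seed_split, time.time() - t0, cached)

    id_to_row = {sid: i for i, sid in enumerate(fused.sample_ids)}
    rows = {part: [id_to_row[s] for s in split[part]] for part in ("train", "val", "test")}
    y = np.asarray(fused.labels)

    # ---- stage: ACO selection (fit on training rows only) ----------------
    t0 = time.time()
    seed_aco = stage_seed(config.seed, "aco")
    select_path = out / "selection.json"
    cached = resume and select_path.exists()
    if cached:
        selection = json.loads(select_path.read_text())
    else:
        subset_size = config.subset_size
        if subset_size is None:
            subset_size = aco_select.default_subset_size(tuple(config.extractors))
        if subset_size is None:
            subset_size = max(1, fused.n_features // 6)
        subset_size = min(subset_size, fused.n_features)
        aco_cfg = aco_select.ACOConfig(subset_size=subset_size,
                                       n_ants=config.aco_ants,
                                       max_iters=config.aco_iters,
                                       seed=seed_aco)
        train_rows = rows["train"]
        result = aco_select.run_aco(fused.values[train_rows], y[train_rows], aco_cfg)
        selection = {"indices": result.best_subset,
                     "best_score": result.best_score,
                     "score_trace": result.score_trace,
                     "subset_size": subset_size}
        select_path.write_text(json.dumps(selection, indent=1))
    manifest.record("select", [select_path], seed_aco, time.time() - t0, cached)
    selected = fused.select_columns(selection["indices"])

    # ---- stage: train + evaluate per classifier --------------------------
    seed_train = stage_seed(config.seed, "train")
    classes = sorted(set(fused.labels))
    report_paths = []
    reports = {}
    t0 = time.time()
    X_train = selected.values[rows["train"]]
    y_train = y[rows["train"]]
    X_test = selected.values[rows["test"]]
    y_test = y[rows["test"]]
    for kind in config.classifiers:
        if kind == "dt":
            model = classify.train_dt(X_train, y_train, seed=seed_train)
        else:
            model = classify.train_rf(X_train, y_train, seed=seed_train,
                                      n_estimators=config.rf_trees)
        classify.save_model(model, out / f"model_{kind}.bin")
        y_pred = classify.predict(model, X_test)
        proba = classify.predict_proba(model, X_test)
        # align score columns with the evaluation class order
        col = {c: j for j, c in enumerate(model.classes)}
        scores = proba[:, [col[c] for c in classes]]
        cm = evaluate.confusion_matrix(y_test, y_pred, classes)
        report = evaluate.macro_report(cm, scores=scores, y_true=y_test)
        payload = {
            "classifier": kind,
            "classes": classes,
            "test_ids_sha256": hashlib.sha256(
                "\n".join(split["test"]).encode()).hexdigest(),
            "confusion": cm.counts.tolist(),
            "per_class": report.per_class,
            "macro": report.macro,
            "overall_accuracy": report.overall_accuracy,
        }
        path = out / f"report_{kind}.json"
        path.write_text(json.dumps(payload, indent=1))
        report_paths.append(path)
        reports[kind] = payload
    manifest.record("train_evaluate", report_paths, seed_train,
                    time.time() - t0, False)

    # ---- stage: compare classifiers --------------------------------------
    if len(reports) >= 2:
        t0 = time.time()
        cmp_path = out / "comparison.json"
        cmp = compare_strategies(list(reports.values()))
        cmp_path.write_text(json.dumps(cmp, indent=1))
        manifest.record("compare", [cmp_path], stage_seed(config.seed, "compare"),
                        time.time() - t0, False)

    return manifest.data


def _report_payload(source: Union[dict, str, Path]) -> dict:
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.is_dir():
            candidates = sorted(p.glob("report_*.json"))
            if not candidates:
                raise ValueError(f"no report_*.json under {p}")
            return json.loads(candidates[0].read_text())
        return json.loads(p.read_text())
    return source


def compare_strategies(reports: Sequence[Union[dict, str, Path]]) -> dict:
    """Pairwise one-sided paired t-tests over per-class F1 of completed runs.

    All runs must have been evaluated on the same test split (checked by the
    test-id hash embedded in each report).
    """
    payloads = [_report_payload(r) for r in reports]
    if len(payloads) < 2:
        raise ValueError("need at least two reports to compare")
    ref_hash = payloads[0].get("test_ids_sha256")
    names = []
    for p in payloads:
        if p.get("test_ids_sha256") != ref_hash:
            raise ValueError("reports were evaluated on different test splits")
        names.append(p.get("classifier", "model"))
    rows = []
    for i in range(len(payloads)):
        for j in range(len(payloads)):
            if i == j:
                continue
            a, b = payloads[i], payloads[j]
            f1_a = [a["per_class"][c]["f1"] for c in a["classes"]]
            f1_b = [b["per_class"][c]["f1"] for c in b["classes"]]
            res = evaluate.paired_f1_ttest(f1_a, f1_b)
            rows.append({
                "a": names[i], "b": names[j],
                "mean_f1_difference": res.mean_difference,
                "t_statistic": res.t_statistic,
                "df": res.degrees_of_freedom,
                "p_value": res.p_value,
                "significant": res.significant,
            })
    return {"comparisons": rows}
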