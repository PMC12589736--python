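"""Pooling operators, the pluggable extractor contract, and serial feature fusion.

A feature extractor maps an image to an H×W×C spatial feature map; global
average pooling collapses it to a C-vector. Per-image vectors are stacked
into a samples × D feature matrix, and matrices from several extractors are
fused by end-to-end (serial) concatenation of each sample's vectors. Every
matrix carries a provenance record — the ordered list of (extractor name,
channel count) pairs whose widths must sum to D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd

from .imaging_io import LabeledImageSet, RasterImage

__all__ = [
    "FeatureMap",
    "ExtractorSpec",
    "FeatureMatrix",
    "ContractViolationError",
    "max_pool",
    "avg_pool",
    "global_avg_pool",
    "extract_features",
    "fuse",
    "write_feature_csv",
    "read_feature_csv",
]


class ContractViolationError(RuntimeError):
    """An extractor or matrix violated its declared contract."""


@dataclass
class FeatureMap:
    """An H×W×C spatial feature map produced by an extractor."""

    values: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError(f"feature map must be H×W×C, got shape {self.values.shape}")
        if min(self.values.shape) < 1:
            raise ValueError("feature map dimensions must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")

    @property
    def channels(self) -> int:
        return self.values.shape[2]


@dataclass
class ExtractorSpec:
    """Contract: a named deterministic mapping image → FeatureMap with declared C."""

    name: str
    apply: Callable[[RasterImage], FeatureMap]
    output_channels: int

    def __call__(self, img: RasterImage) -> FeatureMap:
        fmap = self.apply(img)
        if fmap.channels != self.output_channels:
            raise ContractViolationError(
                f"extractor {self.name!r} declared {self.output_channels} channels "
                f"but produced {fmap.channels}")
        return fmap


@dataclass
class FeatureMatrix:
    """samples × D matrix with ids, labels and extractor provenance."""

    values: np.ndarray
    sample_ids: list
    labels: list
    provenance: list = field(default_factory=list)  # [(extractor name, channels), ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("one id and one label per row required")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if self.provenance:
            total = sum(c for _, c in self.provenance)
            if total != d:
                raise ContractViolationError(
                    f"provenance channel counts sum to {total} but matrix has D={d}")
        else:
            self.provenance = [("unknown", d)]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_columns(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = list(indices)
        return FeatureMatrix(values=self.values[:, idx],
                             sample_ids=list(self.sample_ids),
                             labels=list(self.labels),
                             provenance=[("selected", len(idx))])


def _pooled_windows(values: np.ndarray, k: int, p: int) -> np.ndarray:
    h, w, _ = values.shape
    if k < 1 or p < 1:
        raise ValueError("window and stride must be >= 1")
    if k % 1:
        raise ValueError("window must be an integer")
    if k > h or k > w:
        raise ValueError(f"window {k} exceeds spatial dims {h}x{w}")
    windows = np.lib.stride_tricks.sliding_window_view(values, (k, k), axis=(0, 1))
    return windows[::p, ::p]  # shape (Ho, Wo, C, k, k)


def max_pool(fmap: FeatureMap, k: int = 2, p: int = 2) -> FeatureMap:
    """Max pooling: per channel, the max over each k×k window advanced by stride p."""
    pooled = _pooled_windows(fmap.values, k, p).max(axis=(3, 4))
    return FeatureMap(values=pooled, source=fmap.source)


def avg_pool(fmap: FeatureMap, k: int = 2, p: int = 2) -> FeatureMap:
    """Average pooling: window means with 1/k² normalization."""
    pooled = _pooled_windows(fmap.values, k, p).mean(axis=(3, 4))
    return FeatureMap(values=pooled, source=fmap.source)


def global_avg_pool(fmap: FeatureMap) -> np.ndarray:
    """Collapse H×W×C to a length-C vector by spatial averaging per channel."""
    return fmap.values.mean(axis=(0, 1))


def extract_features(images: LabeledImageSet, extractor: ExtractorSpec) -> FeatureMatrix:
    """One row per image: the globally average-pooled extractor response."""
    if len(images) == 0:
        raise ValueError("empty image set")
    rows = []
    for rec in images.records:
        fmap = extractor(rec.load())
        rows.append(global_avg_pool(fmap))
    return FeatureMatrix(values=np.vstack(rows),
                         sample_ids=images.sample_ids(),
                         labels=images.labels(),
                         provenance=[(extractor.name, extractor.output_channels)])


def fuse(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Serial fusion: row-wise end-to-end concatenation in the given order."""
    if not matrices:
        raise ValueError("nothing to fuse")
    first = matrices[0]
    for m in matrices[1:]:
        for i, (a, b) in enumerate(zip(first.sample_ids, m.sample_ids)):
            if a != b:
                raise ValueError(f"sample id mismatch at row {i}: {a!r} vs {b!r}")
        for i, (a, b) in enumerate(zip(first.labels, m.labels)):
            if a != b:
                raise ValueError(f"label mismatch at row {i} (sample {first.sample_ids[i]!r})")
        if m.n_samples != first.n_samples:
            raise ValueError("row count mismatch between matrices")
    values = np.hstack([m.values for m in matrices])
    provenance = [entry for m in matrices for entry in m.provenance]
    return FeatureMatrix(values=values, sample_ids=list(first.sample_ids),
                         labels=list(first.labels), provenance=provenance)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_feature_csv(matrix: FeatureMatrix, path: Union[str, Path]) -> Path:
    """Write ``sample_id,label,f000001..fD`` CSV plus a provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = matrix.n_features
    cols = [f"f{j + 1:06d}" for j in range(d)]
    df = pd.DataFrame(matrix.values, columns=cols)
    df.insert(0, "label", matrix.labels)
    df.insert(0, "sample_id", matrix.sample_ids)
    df.to_csv(path, index=False, float_format="%.9f")
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"provenance": [[n, int(c)] for n, c in matrix.provenance]}, fh)
    return path


def read_feature_csv(path: Union[str, Path]) -> FeatureMatrix:
    """Read a feature CSV written by :func:`write_feature_csv`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str, "label": str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed feature CSV {path}: {exc}") from exc
    if list(df.columns[:2]) != ["sample_id", "label"]:
        raise ValueError(
            f"malformed feature CSV {path}: line 1: header must start with "
            f"'sample_id,label', got {list(df.columns[:3])}")
    feature_cols = list(df.columns[2:])
    for j, col in enumerate(feature_cols):
        if col != f"f{j + 1:06d}":
            raise ValueError(f"malformed feature CSV {path}: line 1: unexpected "
                             f"feature column {col!r} at position {j}")
    provenance = []
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            provenance = [(n, int(c)) for n, c in json.load(fh)["provenance"]]
    values = df[feature_cols].to_numpy(dtype=float) if feature_cols else np.empty((len(df), 0))
    return FeatureMatrix(values=values,
                         sample_ids=df["sample_id"].tolist(),
                         labels=df["label"].tolist(),
                         provenance=provenance)
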