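"""Dataset partitioning, training-set augmentation, and DT/RF training.

The partition protocol reserves 40% of each class for testing and splits
the remaining 60% pool 90:10 into training and validation (so 5,000 tiles
per class become 2,700 / 300 / 2,000). Training images — and only training
images — may be augmented with small geometric perturbations (rotation
±15°, shift ±10%, shear ±10%, zoom ±5%, horizontal flips), each original
yielding itself plus a configurable number of transformed copies.

Classification uses a Gini decision tree and a bagged random forest whose
trees vote by majority; both are thin, seeded wrappers over scikit-learn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
from skimage import transform as sktransform
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import ContractViolationError, FeatureMatrix
from .imaging_io import ImageRecord, RasterImage

__all__ = [
    "SplitSpec",
    "AugmentConfig",
    "AugmentedImage",
    "ClassifierModel",
    "stratified_split",
    "augment_training",
    "train_dt",
    "train_rf",
    "predict",
    "predict_proba",
    "save_model",
    "load_model",
]


@dataclass
class SplitSpec:
    """Stratified train/val/test fractions (default 0.54 / 0.06 / 0.40)."""

    train_frac: float = 0.54
    val_frac: float = 0.06
    test_frac: float = 0.40
    seed: int = 0
    stratified: bool = True
    min_class_size: int = 10

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        if min(self.train_frac, self.val_frac, self.test_frac) < 0:
            raise ValueError("fractions must be nonnegative")


def stratified_split(ids: Sequence[str], labels: Sequence[str],
                     spec: Optional[SplitSpec] = None) -> Tuple[list, list, list]:
    """Per class: floor(n·(train+val)) ids to the pool, floor(pool·train/(train+val))
    of those to train, the rest of the pool to validation, the remainder to test.

    The class members are shuffled with the spec's seed before allocation, so
    the partition is deterministic given (ids, labels, seed). Returns three
    id lists that are disjoint and exhaustive.
    """
    if spec is None:
        spec = SplitSpec()
    ids = list(ids)
    labels = list(labels)
    if len(ids) != len(labels):
        raise ValueError("ids and labels must have equal length")
    rng = np.random.default_rng(spec.seed)
    by_class: Dict[str, list] = {}
    for i, lab in zip(ids, labels):
        by_class.setdefault(lab, []).append(i)
    train, val, test = [], [], []
    pool_frac = spec.train_frac + spec.val_frac
    train_share = spec.train_frac / pool_frac if pool_frac > 0 else 0.0
    for lab in sorted(by_class):
        members = by_class[lab]
        if len(members) < spec.min_class_size:
            raise ValueError(f"class {lab!r} has only {len(members)} members "
                             f"(minimum {spec.min_class_size})")
        members = [members[j] for j in rng.permutation(len(members))]
        # tolerance absorbs float error so e.g. 100 * 0.6 floors to 60, not 59
        n_pool = math.floor(len(members) * pool_frac + 1e-9)
        n_train = math.floor(n_pool * train_share + 1e-9)
        train.extend(members[:n_train])
        val.extend(members[n_train:n_pool])
        test.extend(members[n_pool:])
    return train, val, test


@dataclass
class AugmentConfig:
    """Geometric augmentation ranges; parameters are drawn uniformly within them."""

    copies_per_image: int = 5
    rotation_deg: float = 15.0
    shift_frac: float = 0.10
    shear_frac: float = 0.10
    zoom_frac: float = 0.05
    hflip_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")
        for name in ("rotation_deg", "shift_frac", "shear_frac", "zoom_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class AugmentedImage:
    sample_id: str
    label: str
    pixels: np.ndarray
    is_original: bool
    params: dict = field(default_factory=dict)


def _sample_params(rng: np.random.Generator, cfg: AugmentConfig) -> dict:
    return {
        "rotation_deg": float(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)),
        "shift_x_frac": float(rng.uniform(-cfg.shift_frac, cfg.shift_frac)),
        "shift_y_frac": float(rng.uniform(-cfg.shift_frac, cfg.shift_frac)),
        "shear": float(rng.uniform(-cfg.shear_frac, cfg.shear_frac)),
        "zoom": float(rng.uniform(1.0 - cfg.zoom_frac, 1.0 + cfg.zoom_frac)),
        "hflip": bool(rng.random() < cfg.hflip_prob),
    }


def _apply_transform(pixels: np.ndarray, params: dict) -> np.ndarray:
    h, w = pixels.shape[:2]
    center = np.array([w / 2.0, h / 2.0])
    # rotate/shear/zoom about the image center, then translate
    tform = (sktransform.AffineTransform(translation=-center)
             + sktransform.AffineTransform(
                 rotation=np.deg2rad(params["rotation_deg"]),
                 shear=np.arctan(params["shear"]),
                 scale=(params["zoom"], params["zoom"]))
             + sktransform.AffineTransform(translation=center)
             + sktransform.AffineTransform(translation=(
                 params["shift_x_frac"] * w, params["shift_y_frac"] * h)))
    out = sktransform.warp(pixels, tform.inverse, mode="reflect",
                           preserve_range=True)
    if params["hflip"]:
        out = out[:, ::-1].copy()
    return out


def augment_training(records: Sequence, config: Optional[AugmentConfig] = None,
                     passthrough: bool = False) -> List[AugmentedImage]:
    """Each training record yields itself plus ``copies_per_image`` warped copies.

    Records may be :class:`ImageRecord` objects or (sample_id, label, pixels)
    tuples. Transform parameters come from one seeded stream, so the output
    is fully reproducible. ``passthrough`` returns the originals untouched —
    the mode used when the pipeline classifies pre-extracted feature rows
    rather than images.
    """
    if config is None:
        config = AugmentConfig()
    rng = np.random.default_rng(config.seed)
    out: List[AugmentedImage] = []
    for rec in records:
        if isinstance(rec, ImageRecord):
            sample_id, label = rec.sample_id, rec.label
            pixels = rec.load().pixels
        else:
            sample_id, label, pixels = rec
            pixels = pixels.pixels if isinstance(pixels, RasterImage) else np.asarray(pixels)
        out.append(AugmentedImage(sample_id=sample_id, label=label,
                                  pixels=pixels, is_original=True))
        if passthrough:
            continue
        for c in range(config.copies_per_image):
            params = _sample_params(rng, config)
            out.append(AugmentedImage(sample_id=f"{sample_id}#aug{c + 1}",
                                      label=label,
                                      pixels=_apply_transform(pixels, params),
                                      is_original=False, params=params))
    return out


@dataclass
class ClassifierModel:
    """A fitted DT or RF with its class order and training-config echo."""

    kind: str
    estimator: object
    classes: list
    config: dict = field(default_factory=dict)
    n_features: int = 0


def _check_training(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")


def _as_xy(X, y):
    if isinstance(X, FeatureMatrix):
        return X.values, np.asarray(X.labels if y is None else y)
    return np.asarray(X, dtype=float), np.asarray(y)


def train_dt(X, y=None, seed: int = 0, **kwargs) -> ClassifierModel:
    """Gini decision tree, unbounded depth by default."""
    values, labels = _as_xy(X, y)
    _check_training(labels)
    est = DecisionTreeClassifier(criterion="gini", random_state=seed, **kwargs)
    est.fit(values, labels)
    return ClassifierModel(kind="dt", estimator=est, classes=list(est.classes_),
                           config={"seed": seed, **kwargs}, n_features=values.shape[1])


def train_rf(X, y=None, seed: int = 0, n_estimators: int = 200,
             max_features: Union[str, int, float, None] = "sqrt",
             **kwargs) -> ClassifierModel:
    """Random forest: seeded bootstrap trees with √D feature subsampling,
    majority vote over trees."""
    values, labels = _as_xy(X, y)
    _check_training(labels)
    est = RandomForestClassifier(n_estimators=n_estimators, criterion="gini",
                                 max_features=max_features, random_state=seed,
                                 n_jobs=1, **kwargs)
    est.fit(values, labels)
    return ClassifierModel(kind="rf", estimator=est, classes=list(est.classes_),
                           config={"seed": seed, "n_estimators": n_estimators,
                                   "max_features": max_features, **kwargs},
                           n_features=values.shape[1])


def _check_width(model: ClassifierModel, values: np.ndarray) -> None:
    if values.shape[1] != model.n_features:
        raise ContractViolationError(
            f"model trained on {model.n_features} features, got {values.shape[1]}")


def predict(model: ClassifierModel, X) -> np.ndarray:
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    _check_width(model, values)
    return model.estimator.predict(values)


def predict_proba(model: ClassifierModel, X) -> np.ndarray:
    """Per-class scores: tree-vote/leaf-frequency probabilities, rows sum to 1."""
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    _check_width(model, values)
    return model.estimator.predict_proba(values)


def save_model(model: ClassifierModel, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump({"format": "histofuse-model-v1", "model": model}, path)
    return path


def load_model(path: Union[str, Path]) -> ClassifierModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "histofuse-model-v1":
        raise ValueError(f"{path} is not a histofuse model file")
    return payload["model"]
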