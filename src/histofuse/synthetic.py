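"""Seeded synthetic inputs shaped like the pipeline's real data.

Three generators, all pure functions of (spec, seed):

* histology-like RGB tiles — a textured bright stroma background, one
  smooth lesion region at a configured area fraction, and dark disk
  "nuclei" planted inside the lesion at a class-dependent density
  (hematoxylin-like: nuclei darker than stroma, so segmentation polarity
  matches H&E contrast), with the lesion support returned as a truth mask;
* a deterministic stand-in feature extractor that mimics a CNN backbone's
  contract (image → spatial feature map) using seeded random projections of
  local patch statistics — the named presets declare the documented widths
  1024 / 1664 / 2048 for "resnet50" / "densenet169" / "mobilenet";
* labelled feature matrices with k planted informative columns at a known
  effect size, for exercising the subset-selection search against ground
  truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from skimage import transform as sktransform

from .features import ExtractorSpec, FeatureMap, FeatureMatrix
from .imaging_io import (ImageRecord, LabeledImageSet, RasterImage,
                         to_grayscale, write_image, write_mask)

__all__ = [
    "TileSpec",
    "PlantedFeatureProblem",
    "generate_tile",
    "generate_disk_image",
    "generate_dataset",
    "standin_extractor",
    "STANDIN_WIDTHS",
    "generate_feature_problem",
]

#: Documented default widths for the named stand-in extractors.
STANDIN_WIDTHS = {"resnet50": 1024, "densenet169": 1664, "mobilenet": 2048}


@dataclass
class TileSpec:
    """Parameters of the histology-like tile generator.

    Classes differ in three texture cues, mirroring how tissue types differ
    under H&E staining: nucleus density (``nuclei_density``, expected count
    per 1,000 lesion pixels), nucleus size (``nucleus_radius_by_class``),
    and stain uptake of the lesion stroma
    (``foreground_intensity_by_class``). The defaults keep total nucleus
    coverage well below saturation so density stays informative.
    """

    size: Tuple[int, int] = (256, 256)
    n_classes: int = 5
    nuclei_density: Tuple[float, ...] = (1.5, 10.0, 4.5, 7.0, 12.0)
    nucleus_radius_by_class: Optional[Tuple[Tuple[float, float], ...]] = (
        (4.0, 6.0), (2.5, 4.0), (5.0, 7.5), (2.0, 3.5), (3.5, 5.5))
    nucleus_radius: Tuple[float, float] = (2.5, 5.0)
    background_intensity: float = 0.85
    foreground_intensity: float = 0.60
    foreground_intensity_by_class: Optional[Tuple[float, ...]] = (
        0.52, 0.57, 0.62, 0.67, 0.72)
    nucleus_intensity: float = 0.20
    noise_sigma: float = 0.05
    area_fraction: Tuple[float, float] = (0.25, 0.45)
    boundary_wobble: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.nuclei_density) != self.n_classes:
            raise ValueError("need one nuclei density per class")
        if (self.nucleus_radius_by_class is not None
                and len(self.nucleus_radius_by_class) != self.n_classes):
            raise ValueError("need one nucleus radius range per class")
        if (self.foreground_intensity_by_class is not None
                and len(self.foreground_intensity_by_class) != self.n_classes):
            raise ValueError("need one foreground intensity per class")
        if any(d <= 0 for d in self.nuclei_density):
            raise ValueError("densities must be positive")
        for v in (self.background_intensity, self.foreground_intensity,
                  self.nucleus_intensity):
            if not (0.0 <= v <= 1.0):
                raise ValueError("base intensities must lie in [0, 1]")
        lo, hi = self.area_fraction
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("area fraction range must lie in (0, 1)")


def _tile_rng(spec_seed: int, class_index: int, tile_seed) -> np.random.Generator:
    if isinstance(tile_seed, np.random.SeedSequence):
        return np.random.default_rng(tile_seed)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(spec_seed),
                               spawn_key=(int(class_index), int(tile_seed))))


def generate_tile(spec: TileSpec, class_index: int, seed: int = 0
                  ) -> Tuple[RasterImage, np.ndarray]:
    """One RGB tile plus its boolean lesion truth mask."""
    if not (0 <= class_index < spec.n_classes):
        raise ValueError(f"class_index {class_index} out of range")
    h, w = spec.size
    rng = _tile_rng(spec.seed, class_index, seed)

    # lesion support: a disk with a smooth radial perturbation of the boundary
    frac = rng.uniform(*spec.area_fraction)
    r0 = np.sqrt(frac * h * w / np.pi)
    if r0 * (1 + spec.boundary_wobble) >= min(h, w) / 2:
        raise ValueError(f"area fraction {frac:.2f} infeasible for a {h}x{w} tile")
    yy, xx = np.mgrid[0:h, 0:w]
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w
    theta = np.arctan2(yy - cy, xx - cx)
    wobble = np.zeros_like(theta)
    for kmode in range(2, 6):
        amp = rng.normal(0.0, spec.boundary_wobble / 2)
        phase = rng.uniform(0, 2 * np.pi)
        wobble += amp * np.cos(kmode * theta + phase)
    radius = r0 * (1.0 + np.clip(wobble, -spec.boundary_wobble, spec.boundary_wobble))
    mask = np.hypot(yy - cy, xx - cx) < radius

    img = np.full((h, w), spec.background_intensity)
    if spec.foreground_intensity_by_class is not None:
        img[mask] = spec.foreground_intensity_by_class[class_index]
    else:
        img[mask] = spec.foreground_intensity

    # Poisson-placed dark nuclei, clipped to the lesion
    fg_idx = np.flatnonzero(mask.ravel())
    density = spec.nuclei_density[class_index]
    n_nuclei = rng.poisson(density * len(fg_idx) / 1000.0)
    if spec.nucleus_radius_by_class is not None:
        rmin, rmax = spec.nucleus_radius_by_class[class_index]
    else:
        rmin, rmax = spec.nucleus_radius
    for _ in range(n_nuclei):
        flat = fg_idx[rng.integers(len(fg_idx))]
        ny, nx = divmod(int(flat), w)
        nr = rng.uniform(rmin, rmax)
        disk = (yy - ny) ** 2 + (xx - nx) ** 2 < nr ** 2
        img[disk & mask] = spec.nucleus_intensity

    img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    # eosin-like tint so tiles are RGB like real stains
    rgb = np.dstack([img, img * 0.80 + 0.02, img * 0.95])
    rgb = np.clip(rgb, 0.0, 1.0)
    return RasterImage(pixels=rgb, color_mode="rgb"), mask


def generate_disk_image(shape: Tuple[int, int] = (64, 64), radius_frac: float = 0.3,
                        fg: float = 0.8, bg: float = 0.2, sigma: float = 0.05,
                        seed: int = 0) -> Tuple[RasterImage, np.ndarray]:
    """A noisy two-level disk image with its truth mask (segmentation benchmark)."""
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w
    mask = np.hypot(yy - cy, xx - cx) < radius_frac * min(h, w)
    img = np.where(mask, fg, bg) + rng.normal(0.0, sigma, size=(h, w))
    return RasterImage(pixels=np.clip(img, 0.0, 1.0)), mask


def generate_dataset(spec: TileSpec, n_per_class: int, seed: int = 0,
                     out_dir: Union[str, Path, None] = None) -> LabeledImageSet:
    """n tiles per class, optionally exported to ``<out_dir>/<class>/`` PNGs
    with truth masks in ``<out_dir>-masks/<class>/``. Fully deterministic."""
    class_names = [f"class_{i}" for i in range(spec.n_classes)]
    records = []
    base = np.random.SeedSequence(entropy=int(seed))
    for ci, cname in enumerate(class_names):
        for t in range(n_per_class):
            ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(ci, t))
            img, mask = generate_tile(spec, ci, seed=ss)
            sample_id = f"{cname}/tile_{t:04d}.png"
            if out_dir is not None:
                path = Path(out_dir) / cname / f"tile_{t:04d}.png"
                write_image(img, path)
                mask_path = Path(str(out_dir) + "-masks") / cname / f"tile_{t:04d}.png"
                write_mask(mask, mask_path)
                records.append(ImageRecord(sample_id=sample_id, label=cname,
                                           path=path, mask_path=mask_path))
            else:
                records.append(ImageRecord(sample_id=sample_id, label=cname,
                                           image=img, mask=mask))
    return LabeledImageSet(records=records, class_names=class_names)


_N_PATCH_STATS = 8


def _patch_statistics(gray: np.ndarray, grid: int = 4) -> np.ndarray:
    """grid × grid × 8 local statistics per cell: mean, std, gradient
    mean/std, dark-pixel fractions at two thresholds, mean absolute second
    difference, and the non-black (in-ROI) fraction."""
    size = 16 * grid
    resized = sktransform.resize(gray, (size, size), anti_aliasing=True,
                                 preserve_range=True)
    gy, gx = np.gradient(resized)
    grad = np.hypot(gx, gy)
    lap = np.abs(np.diff(resized, n=2, axis=0, prepend=0, append=0))
    stats = np.zeros((grid, grid, _N_PATCH_STATS))
    cell = size // grid
    for i in range(grid):
        for j in range(grid):
            sl = (slice(i * cell, (i + 1) * cell), slice(j * cell, (j + 1) * cell))
            patch, gpatch, lpatch = resized[sl], grad[sl], lap[sl]
            stats[i, j] = (patch.mean(), patch.std(),
                           gpatch.mean(), gpatch.std(),
                           float((patch < 0.35).mean()),
                           float((patch < 0.55).mean()),
                           lpatch.mean(),
                           float((patch > 0.02).mean()))
    return stats


_STANDIN_GRIDS = {"resnet50": 4, "densenet169": 8, "mobilenet": 6}


def standin_extractor(name: str = "resnet50", output_channels: Optional[int] = None,
                      seed: int = 0, grid: Optional[int] = None) -> ExtractorSpec:
    """A deterministic extractor satisfying the backbone contract.

    The feature map is a fixed seeded random projection of a grid of local
    patch statistics; it carries class-discriminative texture information
    (nucleus density, lesion area) without any trained weights. The named
    presets declare the documented channel widths.
    """
    if output_channels is None:
        output_channels = STANDIN_WIDTHS.get(name, 64)
    if grid is None:
        grid = _STANDIN_GRIDS.get(name, 4)
    if output_channels < 1:
        raise ValueError("output_channels must be >= 1")
    proj_seed = (zlib.crc32(name.encode()) + seed) & 0x7FFFFFFF
    proj_rng = np.random.default_rng(proj_seed)
    projection = (proj_rng.normal(0.0, 1.0, size=(_N_PATCH_STATS, output_channels))
                  / np.sqrt(_N_PATCH_STATS))

    def apply(img: RasterImage) -> FeatureMap:
        gray = to_grayscale(img).pixels
        stats = _patch_statistics(gray, grid=grid)
        values = np.tanh(stats @ projection)
        return FeatureMap(values=values, source=name)

    return ExtractorSpec(name=name, apply=apply, output_channels=output_channels)


@dataclass
class PlantedFeatureProblem:
    """A labelled feature matrix with k known informative columns."""

    n_samples: int = 200
    n_features: int = 50
    n_informative: int = 5
    effect_size: float = 2.0        # class-mean spacing in units of noise sigma
    n_classes: int = 2
    class_balance: Optional[Sequence[float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("k informative must be <= d features")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def generate_feature_problem(prob: PlantedFeatureProblem
                             ) -> Tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Returns (matrix, labels, truth indices of the informative columns).

    Informative columns get class-dependent Gaussian means spaced by the
    effect size (noise sigma = 1); all other columns are pure noise. Column
    order is shuffled, with the planted positions recorded as ground truth.
    """
    rng = np.random.default_rng(prob.seed)
    n, d, k = prob.n_samples, prob.n_features, prob.n_informative
    if prob.class_balance is None:
        counts = [n // prob.n_classes] * prob.n_classes
        for i in range(n - sum(counts)):
            counts[i] += 1
    else:
        weights = np.asarray(prob.class_balance, dtype=float)
        counts = np.floor(weights / weights.sum() * n).astype(int)
        counts[-1] += n - counts.sum()
    labels = np.repeat([f"class_{c}" for c in range(prob.n_classes)], counts)

    X = rng.normal(0.0, 1.0, size=(n, d))
    class_idx = np.repeat(np.arange(prob.n_classes), counts)
    for col in range(k):
        X[:, col] += prob.effect_size * class_idx
    order = rng.permutation(d)
    X = X[:, order]
    truth = np.sort(np.argsort(order)[:k])

    perm = rng.permutation(n)
    X, labels, class_idx = X[perm], labels[perm], class_idx[perm]
    matrix = FeatureMatrix(values=X,
                           sample_ids=[f"s{i:05d}" for i in range(n)],
                           labels=list(labels),
                           provenance=[("planted", d)])
    return matrix, labels, truth
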