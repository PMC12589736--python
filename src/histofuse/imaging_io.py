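"""Image and dataset I/O.

Images are held internally as real-valued grids in the canonical range
[0, 1]; 8-bit quantization happens only at write time. Datasets follow the
class-per-folder layout ``<root>/<class_name>/<image>``; ground-truth or
predicted masks are single-channel PNGs (0 background, 255 foreground).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RasterImage",
    "ImageRecord",
    "LabeledImageSet",
    "read_image",
    "write_image",
    "to_grayscale",
    "scan_dataset",
    "IMAGE_EXTENSIONS",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}

#: ITU-R BT.601 luminance weights (R, G, B).
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class RasterImage:
    """A 2-D (grayscale) or H×W×3 (RGB) real-valued intensity grid.

    Parameters
    ----------
    pixels:
        Float array, ``(H, W)`` for grayscale or ``(H, W, 3)`` for RGB.
    color_mode:
        ``"grayscale"`` or ``"rgb"``; must match the array shape.
    value_range:
        Declared (min, max) of the data. Canonical images use ``(0.0, 1.0)``;
        derivative images (e.g. a Laplacian response) may declare a wider
        range.
    """

    pixels: np.ndarray
    color_mode: str = "grayscale"
    value_range: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.color_mode not in ("grayscale", "rgb"):
            raise ValueError(f"unknown color_mode {self.color_mode!r}")
        expected_ndim = 2 if self.color_mode == "grayscale" else 3
        if self.pixels.ndim != expected_ndim:
            raise ValueError(
                f"{self.color_mode} image must be {expected_ndim}-D, "
                f"got shape {self.pixels.shape}"
            )
        if self.color_mode == "rgb" and self.pixels.shape[2] != 3:
            raise ValueError(f"rgb image needs 3 channels, got {self.pixels.shape[2]}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have H >= 1 and W >= 1")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixel values")
        lo, hi = self.value_range
        if self.pixels.size and (self.pixels.min() < lo - 1e-9 or self.pixels.max() > hi + 1e-9):
            raise ValueError(
                f"pixel values [{self.pixels.min()}, {self.pixels.max()}] outside "
                f"declared range {self.value_range}"
            )

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def spatial_shape(self) -> tuple:
        return self.pixels.shape[:2]

    def with_pixels(self, pixels: np.ndarray, value_range: Optional[tuple] = None) -> "RasterImage":
        """Return a copy with new pixel data (same color mode unless ndim changes)."""
        pixels = np.asarray(pixels, dtype=float)
        mode = "grayscale" if pixels.ndim == 2 else "rgb"
        if value_range is None:
            value_range = self.value_range
        return RasterImage(pixels=pixels, color_mode=mode, value_range=value_range)


@dataclass
class ImageRecord:
    """One dataset entry: an image (by path or in memory), a label, optional truth mask."""

    sample_id: str
    label: str
    path: Optional[Path] = None
    image: Optional[RasterImage] = None
    mask_path: Optional[Path] = None
    mask: Optional[np.ndarray] = None

    def load(self) -> RasterImage:
        if self.image is not None:
            return self.image
        if self.path is None:
            raise ValueError(f"record {self.sample_id} has neither image nor path")
        return read_image(self.path)

    def load_mask(self) -> Optional[np.ndarray]:
        if self.mask is not None:
            return self.mask
        if self.mask_path is None:
            return None
        return read_image(self.mask_path).pixels > 0.5


@dataclass
class LabeledImageSet:
    """An ordered collection of labelled image records."""

    records: list = field(default_factory=list)
    class_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.class_names)
        for rec in self.records:
            if rec.label not in known:
                raise ValueError(f"record {rec.sample_id} has label {rec.label!r} "
                                 f"not in class_names {self.class_names}")
        paths = [rec.path for rec in self.records if rec.path is not None]
        if len(paths) != len(set(paths)):
            raise ValueError("duplicate image paths in dataset")

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> list:
        return [rec.label for rec in self.records]

    def sample_ids(self) -> list:
        return [rec.sample_id for rec in self.records]


def _normalize_loaded(arr: np.ndarray) -> np.ndarray:
    """Map a decoded image array to float in [0, 1] based on its dtype."""
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.clip(arr.astype(float), 0.0, 1.0)
    if np.issubdtype(arr.dtype, np.bool_):
        return arr.astype(float)
    raise IOError(f"unsupported image dtype {arr.dtype}")


def read_image(path: Union[str, Path]) -> RasterImage:
    """Read a PNG/JPEG/TIFF image, normalized to the canonical [0, 1] range.

    Color mode is preserved: single-channel files become grayscale images,
    RGB(A) files become RGB (alpha is dropped).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the path attached
        raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    pixels = _normalize_loaded(arr)
    mode = "grayscale" if pixels.ndim == 2 else "rgb"
    return RasterImage(pixels=pixels, color_mode=mode)


def write_image(img: Union[RasterImage, np.ndarray], path: Union[str, Path]) -> Path:
    """Write an image as 8-bit PNG/JPEG/TIFF, quantizing from [0, 1]."""
    path = Path(path)
    pixels = img.pixels if isinstance(img, RasterImage) else np.asarray(img, dtype=float)
    data = np.clip(np.rint(pixels * 255.0), 0, 255).astype(np.uint8)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, data)
    return path


def write_mask(mask: np.ndarray, path: Union[str, Path]) -> Path:
    """Write a binary mask as single-channel PNG (0 background, 255 foreground)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def to_grayscale(img: RasterImage) -> RasterImage:
    """Convert RGB to grayscale with BT.601 weights; identity on grayscale input."""
    if img.color_mode == "grayscale":
        return RasterImage(pixels=img.pixels.copy(), color_mode="grayscale",
                           value_range=img.value_range)
    gray = img.pixels @ _LUMA_WEIGHTS
    return RasterImage(pixels=gray, color_mode="grayscale", value_range=img.value_range)


def scan_dataset(root: Union[str, Path], mask_root: Union[str, Path, None] = None) -> LabeledImageSet:
    """Scan a class-per-folder image tree into a :class:`LabeledImageSet`.

    Class names are the subdirectory names, sorted lexicographically; files
    within a class are sorted by name, so two scans of the same tree yield
    identical ordered records. If ``mask_root`` is given, a mask with the
    same class/file name is attached to each record when present.
    """
    root = Path(root)
    if not root.is_dir():
        raise ValueError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class folders")
    records = []
    class_names = []
    for cdir in class_dirs:
        files = sorted(p for p in cdir.iterdir()
                       if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS)
        if not files:
            raise ValueError(f"class folder {cdir} contains no image files")
        class_names.append(cdir.name)
        for f in files:
            mask_path = None
            if mask_root is not None:
                candidate = Path(mask_root) / cdir.name / (f.stem + ".png")
                if candidate.exists():
                    mask_path = candidate
            records.append(ImageRecord(sample_id=f"{cdir.name}/{f.name}",
                                       label=cdir.name, path=f, mask_path=mask_path))
    return LabeledImageSet(records=records, class_names=class_names)
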