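"""Filter-fusion enhancement of histology tiles.

The enhancement combines two linear filters: a box mean (5×5 by default,
so each pixel becomes the average of its 25 neighbours) that suppresses
staining artifacts, and the second-derivative Laplacian stencil
``[0, 1, 0; 1, -4, 1; 0, 1, 0]`` that responds to edges and fine nuclear
detail. The enhanced tile is ``mean − laplacian``, clipped back to [0, 1]:
a sharpened image in which low-contrast cell boundaries are emphasised.

Both filters are instances of one general 2-D convolution primitive, which
is also the convolution used conceptually by downstream feature extractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import RasterImage

__all__ = [
    "KernelSpec",
    "LAPLACIAN_STENCIL",
    "convolve2d",
    "mean_filter",
    "laplacian_filter",
    "enhance",
]

#: Second-order derivative stencil with negative center (4-neighbour Laplacian).
LAPLACIAN_STENCIL = np.array([[0.0, 1.0, 0.0],
                              [1.0, -4.0, 1.0],
                              [0.0, 1.0, 0.0]])


@dataclass
class KernelSpec:
    """A square odd-sized convolution kernel plus border policy.

    ``name`` tags well-known kernels so their invariants can be checked:
    a ``mean`` kernel must sum to 1, the ``laplacian`` kernel must equal
    the fixed stencil (sums to 0).
    """

    weights: np.ndarray
    border_mode: str = "reflect"
    name: str = "custom"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError(f"kernel must be square 2-D, got shape {self.weights.shape}")
        if self.weights.shape[0] % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {self.weights.shape[0]}")
        if self.border_mode not in ("reflect", "constant"):
            raise ValueError(f"unknown border_mode {self.border_mode!r}")
        if self.name == "mean" and not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("mean kernel must sum to 1")
        if self.name == "laplacian" and not np.array_equal(self.weights, LAPLACIAN_STENCIL):
            raise ValueError("laplacian kernel must equal the fixed 3x3 stencil")

    @classmethod
    def mean(cls, size: int = 5, border_mode: str = "reflect") -> "KernelSpec":
        if size % 2 == 0 or size < 1:
            raise ValueError(f"mean kernel size must be odd and >= 1, got {size}")
        w = np.full((size, size), 1.0 / (size * size))
        return cls(weights=w, border_mode=border_mode, name="mean")

    @classmethod
    def laplacian(cls, border_mode: str = "reflect") -> "KernelSpec":
        return cls(weights=LAPLACIAN_STENCIL.copy(), border_mode=border_mode,
                   name="laplacian")


def _convolve_plane(plane: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    # scipy.ndimage.convolve is true convolution (kernel flipped), "same" output.
    return ndimage.convolve(plane, kernel.weights, mode=kernel.border_mode, cval=0.0)


def convolve2d(img: RasterImage, kernel: KernelSpec) -> RasterImage:
    """True "same" 2-D convolution of an image with a kernel.

    RGB images are convolved independently per channel. The output declares
    its actual value range (a convolution need not stay in [0, 1]).
    """
    if img.color_mode == "rgb":
        out = np.dstack([_convolve_plane(img.pixels[:, :, c], kernel) for c in range(3)])
    else:
        out = _convolve_plane(img.pixels, kernel)
    lo = min(float(out.min()), 0.0)
    hi = max(float(out.max()), 1.0)
    return img.with_pixels(out, value_range=(lo, hi))


def mean_filter(img: RasterImage, size: int = 5, border_mode: str = "reflect") -> RasterImage:
    """Box-average filter: each pixel becomes the mean of its ``size²`` neighbours."""
    return convolve2d(img, KernelSpec.mean(size=size, border_mode=border_mode))


def laplacian_filter(img: RasterImage, border_mode: str = "reflect") -> RasterImage:
    """4-neighbour Laplacian response; not clipped, may be negative."""
    return convolve2d(img, KernelSpec.laplacian(border_mode=border_mode))


def enhance(img: RasterImage, size: int = 5, border_mode: str = "reflect") -> RasterImage:
    """Fuse the two filters: ``mean_filter(img) − laplacian_filter(img)``, clipped to [0, 1].

    Subtracting the (sign-convention negative-center) Laplacian adds the
    edge response back onto the smoothed image — the classic unsharp-style
    sharpening that makes faint cell boundaries visible.
    """
    smoothed = mean_filter(img, size=size, border_mode=border_mode)
    edges = laplacian_filter(img, border_mode=border_mode)
    fused = np.clip(smoothed.pixels - edges.pixels, 0.0, 1.0)
    return img.with_pixels(fused, value_range=(0.0, 1.0))
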