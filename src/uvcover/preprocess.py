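"""Intensity normalisation for UV reflectance photographs.

UV photographs of sunscreen-treated skin are dominated by two effects that
have nothing to do with coverage: overall skin tone (melanin absorbs UV, so
darker phototypes render darker) and uneven flash reflection.  Both are
counteracted with contrast-limited adaptive histogram equalisation (CLAHE):
the image is tiled into small blocks, each block is histogram-equalised with
its histogram clipped to limit noise amplification, and the per-block
transforms are blended bilinearly between block centres to avoid tile seams.
A small Gaussian blur then suppresses residual pixel noise before
thresholding.

The per-block equalisation maps a pixel of intensity ``f`` to
``round(255 * CDF(f))`` where the CDF is the cumulative probability of the
block's (optionally clipped) intensity histogram.  Rounding is half away
from zero throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "EqualizationConfig",
    "GaussianKernelSpec",
    "equalize_block",
    "adaptive_equalize",
    "make_gaussian_kernel",
    "gaussian_blur",
]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (np.round rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _as_grey(image) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D greyscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValueError("intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


@dataclass(frozen=True)
class EqualizationConfig:
    """Parameters of the adaptive equalisation.

    block_rows, block_cols
        Tile size in pixels (the m x n block).  Must be >= 2.
    clip_limit
        Maximum histogram bin height expressed as a multiple of the uniform
        bin height (1/256 of the block's pixels).  Mass above the clip is
        redistributed uniformly over all 256 bins.  ``None`` disables
        clipping, in which case each block undergoes plain histogram
        equalisation.
    interpolate
        Blend neighbouring block transforms bilinearly between block
        centres.  Disabling it applies each block's own transform verbatim
        (visible tile seams; mainly useful for verification).
    """

    block_rows: int = 8
    block_cols: int = 8
    clip_limit: float | None = 2.0
    interpolate: bool = True

    def __post_init__(self):
        if self.block_rows < 2 or self.block_cols < 2:
            raise ValueError("block dimensions must be >= 2")
        if self.clip_limit is not None and self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive or None")


def _block_lut(block: np.ndarray, clip_limit: float | None) -> np.ndarray:
    """256-entry intensity mapping for one block (clipped-CDF transform)."""
    hist = np.bincount(block.ravel(), minlength=256).astype(np.float64)
    hist /= block.size
    if clip_limit is not None:
        cap = clip_limit / 256.0
        excess = np.clip(hist - cap, 0.0, None).sum()
        hist = np.minimum(hist, cap) + excess / 256.0
    cdf = np.cumsum(hist)
    return np.clip(_round_half_away(255.0 * cdf), 0, 255).astype(np.uint8)


def equalize_block(block, config: EqualizationConfig | None = None) -> np.ndarray:
    """Histogram-equalise a single block.

    Each output pixel is ``round(255 * P(intensity <= f))`` with the
    probability taken over the block's own histogram.  With ``config=None``
    (or ``clip_limit=None``) this is plain, unclipped equalisation; a
    configured clip limit flattens the histogram first as in CLAHE.
    """
    arr = _as_grey(block)
    clip = config.clip_limit if config is not None else None
    return _block_lut(arr, clip)[arr]


def _tile_edges(extent: int, block: int) -> np.ndarray:
    """Tile boundaries covering [0, extent); the last tile may be smaller."""
    edges = np.arange(0, extent, block, dtype=np.int64)
    return np.append(edges, extent)


def _axis_weights(extent: int, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-pixel (lower tile index, upper tile index, upper weight)."""
    centers = (edges[:-1] + edges[1:] - 1) / 2.0
    pos = np.arange(extent, dtype=np.float64)
    hi = np.searchsorted(centers, pos)
    lo = np.clip(hi - 1, 0, len(centers) - 1)
    hi = np.clip(hi, 0, len(centers) - 1)
    span = centers[hi] - centers[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(span > 0, (pos - centers[lo]) / np.where(span > 0, span, 1.0), 0.0)
    return lo, hi, w


def adaptive_equalize(image, config: EqualizationConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation.

    The image is tiled into ``block_rows x block_cols`` blocks (the last row
    and column of tiles absorb any remainder), each block's clipped-CDF
    transform is computed, and each pixel is mapped by bilinear
    interpolation between the transforms of the four surrounding block
    centres.  Output dimensions and the [0, 255] range are preserved.
    """
    if config is None:
        config = EqualizationConfig()
    arr = _as_grey(image)
    h, w = arr.shape
    if config.block_rows > h or config.block_cols > w:
        raise ValueError(
            f"block {config.block_rows}x{config.block_cols} larger than image {h}x{w}"
        )

    row_edges = _tile_edges(h, config.block_rows)
    col_edges = _tile_edges(w, config.block_cols)
    n_r, n_c = len(row_edges) - 1, len(col_edges) - 1
    luts = np.empty((n_r, n_c, 256), dtype=np.uint8)
    for i in range(n_r):
        rows = slice(row_edges[i], row_edges[i + 1])
        for j in range(n_c):
            cols = slice(col_edges[j], col_edges[j + 1])
            luts[i, j] = _block_lut(arr[rows, cols], config.clip_limit)

    if not config.interpolate:
        out = np.empty_like(arr)
        for i in range(n_r):
            rows = slice(row_edges[i], row_edges[i + 1])
            for j in range(n_c):
                cols = slice(col_edges[j], col_edges[j + 1])
                out[rows, cols] = luts[i, j][arr[rows, cols]]
        return out

    rlo, rhi, wy = _axis_weights(h, row_edges)
    clo, chi, wx = _axis_weights(w, col_edges)
    wy = wy[:, None]
    wx = wx[None, :]
    rlo, rhi = rlo[:, None], rhi[:, None]
    clo, chi = clo[None, :], chi[None, :]

    v00 = luts[rlo, clo, arr].astype(np.float64)
    v01 = luts[rlo, chi, arr].astype(np.float64)
    v10 = luts[rhi, clo, arr].astype(np.float64)
    v11 = luts[rhi, chi, arr].astype(np.float64)
    blended = (
        (1 - wy) * ((1 - wx) * v00 + wx * v01) + wy * ((1 - wx) * v10 + wx * v11)
    )
    return np.clip(_round_half_away(blended), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class GaussianKernelSpec:
    """Discrete 2-D Gaussian G(x, y) = A exp(-(x-mu_x)^2 / 2 theta_x^2
    - (y-mu_y)^2 / 2 theta_y^2).

    theta_x, theta_y are the kernel spreads in pixels (standard deviations;
    the denominator is 2 theta^2).  The centre (mu_x, mu_y) is fixed at the
    kernel midpoint and the amplitude A normalises the discrete weights to
    unit sum.  ``radius`` is the half-width in pixels; by default
    ``ceil(3 * max(theta))`` so the truncated tails are negligible.
    """

    theta_x: float = 1.0
    theta_y: float = 1.0
    radius: int | None = None

    def __post_init__(self):
        if self.theta_x <= 0 or self.theta_y <= 0:
            raise ValueError("theta must be positive")
        if self.radius is not None and self.radius < 1:
            raise ValueError("radius must be >= 1")

    @property
    def effective_radius(self) -> int:
        if self.radius is not None:
            return int(self.radius)
        return int(np.ceil(3.0 * max(self.theta_x, self.theta_y)))


def make_gaussian_kernel(spec: GaussianKernelSpec) -> np.ndarray:
    """Evaluate the Gaussian on the integer grid and normalise to unit sum."""
    r = spec.effective_radius
    x = np.arange(-r, r + 1, dtype=np.float64)
    gx = np.exp(-(x**2) / (2.0 * spec.theta_x**2))
    gy = np.exp(-(x**2) / (2.0 * spec.theta_y**2))
    kernel = np.outer(gy, gx)
    return kernel / kernel.sum()


def _blur_float(image: np.ndarray, spec: GaussianKernelSpec) -> np.ndarray:
    kernel = make_gaussian_kernel(spec)
    if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
        raise ValueError(
            f"kernel {kernel.shape} larger than image {image.shape}"
        )
    return ndimage.convolve(image.astype(np.float64), kernel, mode="reflect")


def gaussian_blur(image, spec: GaussianKernelSpec | None = None) -> np.ndarray:
    """Smooth an image by convolution with the normalised Gaussian kernel.

    Borders are handled by reflection; because the kernel has unit sum, a
    constant image is a fixed point and the output range never exceeds the
    input range.
    """
    if spec is None:
        spec = GaussianKernelSpec()
    arr = _as_grey(image)
    out = _blur_float(arr, spec)
    return np.clip(_round_half_away(out), 0, 255).astype(np.uint8)
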