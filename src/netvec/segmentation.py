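"""Segmentation of raw images into clean binary network masks.

Images are plain numpy arrays throughout the package: grayscale images are
2-D float arrays (any non-negative range, typically [0, 1]), binary images
are 2-D boolean arrays in which ``True`` marks the network foreground.

The goal of this stage is modest: produce a binary image in which the
network is the largest connected foreground structure.  Stains, specks and
noise do not matter as long as they are not connected to the network --
they are discarded by :func:`largest_component`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from skimage.morphology import closing, disk, opening


class SegmentationError(ValueError):
    """Raised when a segmentation step cannot produce a usable result."""


@dataclass
class SegmentationParams:
    """Knobs of the adaptive binarization pipeline.

    Parameters
    ----------
    block_size : int
        Odd side length (px) of the square window over which the local mean
        intensity is computed.  Must be >= 3.
    offset : float
        A pixel is foreground when its intensity exceeds the local mean by
        more than ``offset`` (same units as the image intensities).
    smoothing_sigma : float
        Scale of an optional Gaussian pre-blur (px); 0 disables it.
    invert : bool
        Set when the network is darker than the background.
    min_hole_area : float
        Background holes of at most this area (px^2) are filled after
        thresholding; genuine network loops are much larger and survive.
    opening_radius, closing_radius : int
        Radii (px) of the disk structuring elements for binary opening
        (speck removal) and closing (small gap bridging); 0 disables.
    """

    block_size: int = 51
    offset: float = 0.1
    smoothing_sigma: float = 0.0
    invert: bool = False
    min_hole_area: float = 0.0
    opening_radius: int = 0
    closing_radius: int = 0

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError(f"block_size must be odd and >= 3, got {self.block_size}")
        if self.opening_radius < 0 or self.closing_radius < 0:
            raise ValueError("morphology radii must be >= 0")
        if self.min_hole_area < 0:
            raise ValueError("min_hole_area must be >= 0")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


def as_gray(img: np.ndarray) -> np.ndarray:
    """Collapse a color image to luminance; pass grayscale through as float."""
    img = np.asarray(img)
    if img.ndim == 3:
        # Rec. 601 luma weights; drop an alpha channel if present.
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D (or RGB) image")
    img = img.astype(float)
    if not np.all(np.isfinite(img)) or img.min() < 0:
        raise ValueError("image intensities must be finite and non-negative")
    return img


def binarize_adaptive(img: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Adaptive (local-mean) thresholding with optional pre-blur and morphology.

    A pixel is foreground when its (optionally Gaussian-smoothed) intensity
    exceeds the arithmetic mean of its ``block_size`` x ``block_size``
    neighborhood by more than ``offset``.  Reflective boundary handling is
    used at the image border.  Opening and closing are applied afterwards
    with disk structuring elements, then holes up to ``min_hole_area`` are
    filled.

    Raises
    ------
    SegmentationError
        If no foreground pixel survives the pipeline.
    """
    params = params or SegmentationParams()
    img = as_gray(img)
    if params.invert:
        img = img.max() - img
    if params.smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, params.smoothing_sigma, mode="reflect")
    local_mean = ndimage.uniform_filter(img, size=params.block_size, mode="reflect")
    binary = img > local_mean + params.offset
    if params.opening_radius > 0:
        binary = opening(binary, disk(params.opening_radius))
    if params.closing_radius > 0:
        binary = closing(binary, disk(params.closing_radius))
    if params.min_hole_area > 0:
        binary = fill_holes(binary, params.min_hole_area)
    if not binary.any():
        raise SegmentationError("segmentation produced no foreground")
    return binary


def binarize_edges(img: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize object *boundaries* via Sobel gradient magnitude.

    Useful for images of blob-like objects (droplets, bubbles) whose
    outlines, rather than interiors, form the network.  The Sobel gradient
    magnitude is thresholded at ``threshold`` times its maximum.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    img = as_gray(img)
    grad = sobel(img)
    gmax = grad.max()
    if gmax <= 1e-12 * max(1.0, float(img.max())):
        raise SegmentationError("zero gradient everywhere: constant image")
    return grad > threshold * gmax


def largest_component(binary: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties between equally large components are broken in favor of the one
    containing the lexicographically smallest (row, col) foreground pixel.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise SegmentationError("largest_component: image has no foreground")
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return binary
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # scipy labels in raster order, so the smallest label among the
        # tied candidates contains the lexicographically smallest pixel.
        winner = best.min()
    else:
        winner = best[0]
    return labels == winner


def fill_holes(binary: np.ndarray, max_area: float) -> np.ndarray:
    """Fill enclosed background holes of area <= ``max_area`` px^2.

    Holes are 4-connected background components not touching the image
    border; larger holes -- the genuine loops of a reticulate network --
    are preserved.  Never removes foreground.
    """
    binary = np.asarray(binary, dtype=bool)
    if max_area <= 0:
        return binary.copy()
    background = ~binary
    labels, n = ndimage.label(background)  # 4-connectivity by default
    if n == 0:
        return binary.copy()
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    sizes = ndimage.sum_labels(background, labels, index=np.arange(1, n + 1))
    fill = np.zeros(n + 1, dtype=bool)
    fill[1:] = sizes <= max_area
    fill[border_labels] = False
    return binary | fill[labels]
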