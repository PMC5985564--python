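"""Segmentation of root-slice fluorescence images.

Turns a composed root-slice image plus a manually marked center into the
three binary masks the downstream geometry needs — oil droplets, center,
root edge — and extracts per-droplet centroids and the ordered edge
contour.

The droplet pipeline mirrors the classical ImageJ-style recipe: convert to
8-bit grayscale, median filter, grayscale dilation, Huang fuzzy-entropy
threshold, then connected-component analysis with particle size and
circularity filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_multiotsu, threshold_otsu

from .errors import (
    AnnotationError,
    DegenerateHistogramError,
    EmptyMaskError,
    InvalidInputError,
)

__all__ = [
    "SegmentationParams",
    "DropletDetection",
    "BinaryMask",
    "to_grayscale8",
    "huang_threshold",
    "binarize_droplets",
    "binarize_tissue",
    "extract_particles",
    "extract_edge_contour",
    "read_center_annotation",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the droplet segmentation.

    Attributes
    ----------
    median_radius : int
        Radius (px) of the disk footprint of the pre-threshold median
        filter. Removes salt noise; 0 disables.
    dilate_radius : int
        Radius (px) of the grayscale dilation applied after the median
        filter. Consolidates droplet cores; 0 disables.
    min_area, max_area : float
        Particle area band in px²; components outside are discarded.
    min_circularity, max_circularity : float
        Circularity band; circularity is 4π·area/perimeter², clipped to 1.
    channel : str
        How RGB input collapses to grayscale: "green" (droplets fluoresce
        green) or "luminance" (ITU-R 601 weighting).
    """

    median_radius: int = 1
    dilate_radius: int = 1
    min_area: float = 5.0
    max_area: float = math.inf
    min_circularity: float = 0.3
    max_circularity: float = 1.0
    channel: str = "green"

    def __post_init__(self) -> None:
        if self.median_radius < 0 or self.dilate_radius < 0:
            raise InvalidInputError("filter radii must be >= 0")
        if not 0 <= self.min_area <= self.max_area:
            raise InvalidInputError("need 0 <= min_area <= max_area")
        if not 0 <= self.min_circularity <= self.max_circularity <= 1:
            raise InvalidInputError("need 0 <= min_circularity <= max_circularity <= 1")
        if self.channel not in ("green", "luminance"):
            raise InvalidInputError(f"unknown channel mode {self.channel!r}")


@dataclass(frozen=True)
class DropletDetection:
    """One segmented oil droplet: centroid (px), area (px²), circularity."""

    centroid_x: float
    centroid_y: float
    area: float
    circularity: float


@dataclass(frozen=True)
class BinaryMask:
    """A boolean mask tied to its source image dimensions."""

    pixels: np.ndarray
    kind: str  # droplets | center | edge

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.dtype != bool:
            raise InvalidInputError("mask must be a 2-D boolean array")
        if self.kind in ("center", "edge") and not self.pixels.any():
            raise EmptyMaskError(f"{self.kind} mask has no foreground")


def to_grayscale8(image: np.ndarray, channel: str = "green") -> np.ndarray:
    """Convert an input image to an 8-bit grayscale array.

    Single-channel integer input wider than 8 bits is linearly rescaled to
    0..255 (16-bit via ``v // 257``); float input is rescaled from its own
    min/max. 3-channel input collapses either to the green channel
    (default — the droplets fluoresce green against a dark background) or
    to ITU-R 601 luminance.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise InvalidInputError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            raise InvalidInputError(f"expected 3 channels, got {arr.shape[2]}")
        if channel == "green":
            arr = arr[:, :, 1]
        else:
            rgb = arr[:, :, :3].astype(np.float64)
            arr = rgb @ np.array([0.299, 0.587, 0.114])
    elif arr.ndim != 2:
        raise InvalidInputError(f"expected 2-D or 3-channel image, got ndim={arr.ndim}")

    if arr.dtype == np.uint8:
        return arr.copy()
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        if info.max <= 255 and info.min >= 0:
            return arr.astype(np.uint8)
        if arr.dtype == np.uint16:
            return (arr // 257).astype(np.uint8)
        lo, hi = int(arr.min()), int(arr.max())
        if hi == lo:
            return np.zeros(arr.shape, dtype=np.uint8)
        return ((arr.astype(np.float64) - lo) * 255.0 / (hi - lo)).round().astype(np.uint8)
    # float input: clip to [0, 255] if already in that range, else rescale
    arr = arr.astype(np.float64)
    if arr.min() >= 0 and arr.max() <= 255:
        return np.clip(arr, 0, 255).round().astype(np.uint8)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return ((arr - lo) * 255.0 / (hi - lo)).round().astype(np.uint8)


def huang_threshold(histogram: Sequence[int] | np.ndarray) -> int:
    """Huang–Wang fuzzy-entropy threshold of a 256-bin grayscale histogram.

    For each candidate level ``t`` the gray levels are split at ``t``
    (foreground strictly above). Each pixel's membership to its own side is
    ``u(g) = 1 / (1 + |g - mu_side| / C)`` with ``C`` the dynamic range
    ``g_max - g_min``, and the cost is the total Shannon fuzzy entropy
    ``sum_g h(g) * S(u(g))`` with ``S(u) = -u ln u - (1-u) ln(1-u)``.
    The returned threshold minimizes this cost; ties break to the lowest
    level.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins carry mass (no contrast to split).
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.ndim != 1 or h.shape[0] != 256:
        raise InvalidInputError("histogram must have 256 bins")
    if np.any(h < 0):
        raise InvalidInputError("histogram counts must be non-negative")
    nz = np.flatnonzero(h)
    if nz.size < 2:
        raise DegenerateHistogramError("histogram mass concentrated in < 2 bins")
    gmin, gmax = int(nz[0]), int(nz[-1])
    c = float(gmax - gmin)

    levels = np.arange(256, dtype=np.float64)
    w = h * levels
    cum_h = np.cumsum(h)
    cum_w = np.cumsum(w)
    tot_h, tot_w = cum_h[-1], cum_w[-1]

    def shannon(u: np.ndarray) -> np.ndarray:
        # S(u) with the 0*log(0) = 0 convention; u in [0.5, 1]
        v = 1.0 - u
        out = np.zeros_like(u)
        m = (u > 0) & (u < 1)
        out[m] = -u[m] * np.log(u[m]) - v[m] * np.log(v[m])
        return out

    best_t, best_s = gmin, np.inf
    for t in range(gmin, gmax):
        h0, w0 = cum_h[t], cum_w[t]
        h1, w1 = tot_h - h0, tot_w - w0
        mu0 = w0 / h0
        mu1 = w1 / h1
        dist = np.where(levels <= t, np.abs(levels - mu0), np.abs(levels - mu1))
        u = 1.0 / (1.0 + dist / c)
        s = float(np.dot(h, shannon(u)))
        if s < best_s - 1e-12:
            best_s, best_t = s, t
    return best_t


def _filtered_gray(gray: np.ndarray, params: SegmentationParams) -> np.ndarray:
    out = gray
    if params.median_radius > 0:
        out = ndimage.median_filter(out, footprint=morphology.disk(params.median_radius))
    if params.dilate_radius > 0:
        out = morphology.dilation(out, morphology.disk(params.dilate_radius))
    return out


def binarize_droplets(
    gray: np.ndarray,
    params: SegmentationParams | None = None,
    roi: np.ndarray | None = None,
) -> BinaryMask:
    """Median-filter, dilate and Huang-threshold an 8-bit image.

    Foreground = pixels strictly above the Huang threshold of the filtered
    image's histogram. If ``roi`` (a boolean mask, typically the tissue
    cross-section) is given, both the histogram and the foreground are
    restricted to it — composed slice images carry a black mounting frame
    around the tissue whose huge dark mode would otherwise dominate the
    fuzzy-entropy criterion and pull the threshold below the tissue
    autofluorescence. Propagates :class:`DegenerateHistogramError` for
    contrast-free images.
    """
    params = params or SegmentationParams()
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise InvalidInputError("binarize_droplets expects a 2-D grayscale array")
    if gray.dtype != np.uint8:
        gray = to_grayscale8(gray)
    filtered = _filtered_gray(gray, params)
    values = filtered[roi] if roi is not None else filtered.ravel()
    hist = np.bincount(values, minlength=256)[:256]
    t = huang_threshold(hist)
    fg = filtered > t
    if roi is not None:
        fg &= roi
    return BinaryMask(pixels=fg, kind="droplets")


def binarize_tissue(gray: np.ndarray, threshold: float | None = None) -> BinaryMask:
    """Segment the whole tissue cross-section (interior) from the dark frame.

    Used to derive the edge mask. A light median filter suppresses noise,
    then a low threshold separates tissue from the black background. By
    default the threshold is the lower cut of a three-class multi-Otsu
    (black frame / tissue autofluorescence / droplet highlights); a fixed
    override is available for images without a dark frame. The largest
    connected component is kept and its holes filled.
    """
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        gray = to_grayscale8(gray)
    smooth = ndimage.median_filter(gray, footprint=morphology.disk(2))
    if threshold is None:
        if smooth.min() == smooth.max():
            raise DegenerateHistogramError("no contrast for tissue mask")
        try:
            threshold = threshold_multiotsu(smooth, classes=3)[0]
        except ValueError:  # fewer than 3 distinct levels
            threshold = threshold_otsu(smooth)
    fg = smooth > threshold
    if not fg.any():
        raise EmptyMaskError("tissue threshold left no foreground")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return BinaryMask(pixels=fg, kind="edge")


def extract_particles(
    mask: BinaryMask | np.ndarray, params: SegmentationParams | None = None
) -> list[DropletDetection]:
    """Label droplet components and apply size/circularity filters.

    Components use 8-connectivity. Circularity is 4π·area/perimeter² with
    a Crofton (anisotropy-corrected) perimeter estimate, clipped to 1.0 —
    rasterized small disks can nominally exceed 1. Detections are sorted
    by centroid (y, then x) so output order is deterministic.
    """
    params = params or SegmentationParams()
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    labels = measure.label(pixels, connectivity=2)
    out: list[DropletDetection] = []
    for rp in measure.regionprops(labels):
        area = float(rp.area)
        if not params.min_area <= area <= params.max_area:
            continue
        perim = float(rp.perimeter_crofton)
        circ = 1.0 if perim <= 0 else min(1.0, 4.0 * math.pi * area / perim**2)
        if not params.min_circularity <= circ <= params.max_circularity:
            continue
        cy, cx = rp.centroid
        out.append(DropletDetection(centroid_x=cx, centroid_y=cy, area=area, circularity=circ))
    out.sort(key=lambda d: (d.centroid_y, d.centroid_x))
    return out


def extract_edge_contour(mask: BinaryMask | np.ndarray) -> np.ndarray:
    """Outer boundary of the largest foreground component as an (N, 2) x-y polygon.

    The polygon is ordered counter-clockwise (positive shoelace area in
    the x-right / y-down pixel frame), has at least 16 vertices and does
    not repeat the first vertex at the end.
    """
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if not pixels.any():
        raise EmptyMaskError("edge mask has no foreground")
    labels, n = ndimage.label(pixels)
    if n > 1:
        sizes = ndimage.sum_labels(pixels, labels, index=np.arange(1, n + 1))
        pixels = labels == (1 + int(np.argmax(sizes)))
    pixels = ndimage.binary_fill_holes(pixels)
    contours = measure.find_contours(pixels.astype(np.float64), 0.5)
    if not contours:
        raise EmptyMaskError("no contour found")
    rc = max(contours, key=len)  # (row, col) vertices, closed
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    xy = rc[:, ::-1].copy()  # -> (x, y)
    if xy.shape[0] < 16:
        raise EmptyMaskError("contour has fewer than 16 vertices")
    # enforce counter-clockwise orientation (positive signed area)
    x, y = xy[:, 0], xy[:, 1]
    signed2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    if signed2 < 0:
        xy = xy[::-1].copy()
    return xy


def read_center_annotation(
    annotations: pd.DataFrame, slice_id: str, image_shape: tuple[int, int]
) -> tuple[float, float]:
    """Look up the manually marked center for one slice.

    Parameters
    ----------
    annotations : DataFrame with columns ``slice_id``, ``x``, ``y``
        Pixel coordinates, origin top-left, 0-based.
    slice_id : the slice to look up.
    image_shape : (height, width) used for the bounds check.

    Returns the annotated point verbatim (no snapping).
    """
    for col in ("slice_id", "x", "y"):
        if col not in annotations.columns:
            raise AnnotationError(f"annotation table lacks column {col!r}")
    rows = annotations[annotations["slice_id"].astype(str) == str(slice_id)]
    if len(rows) == 0:
        raise AnnotationError(f"no center annotation for slice {slice_id!r}")
    if len(rows) > 1:
        raise AnnotationError(f"multiple center annotations for slice {slice_id!r}")
    x = float(rows.iloc[0]["x"])
    y = float(rows.iloc[0]["y"])
    h, w = image_shape
    if not (math.isfinite(x) and math.isfinite(y)):
        raise AnnotationError(f"non-finite center for slice {slice_id!r}")
    if not (0 <= x < w and 0 <= y < h):
        raise AnnotationError(
            f"center ({x}, {y}) outside image bounds {w}x{h} for slice {slice_id!r}"
        )
    return x, y
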