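"""Breast-region detection from a Sobel edge map via projection profiles.

The frontal torso silhouette and the infra-mammary fold are the two
strong edge structures in a breast thermogram.  The pipeline converts
the pseudo-color rendering to grayscale, computes the Sobel gradient,
binarizes the magnitude (Otsu by default), and then reads four limits
off the binary edge map:

* lower limit ``LL`` — bottom-up scan of the horizontal projection
  profile (white-pixel count per row) in the lower part of the image;
  the infra-mammary fold produces the first high count;
* breast height ``h`` — a fraction of the image height, with the
  fraction switched on whether the fold sits within 26 % of the bottom
  (small-breast geometry) or further up (large-breast geometry);
* upper limit ``UL = LL - h`` — the axillary level;
* left/right limits — outermost white-pixel columns within ``[UL, LL]``,
  whose midpoint defines the central axis used to split the two breasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import ColormapSpec, Thermogram, render_rgb

__all__ = [
    "EdgeMap",
    "ProjectionProfile",
    "BreastSegmentation",
    "SegmentationConfig",
    "SegmentationError",
    "to_grayscale",
    "sobel_gradient",
    "binarize_edges",
    "horizontal_projection_profile",
    "vertical_projection_profile",
    "detect_lower_limit",
    "compute_breast_height",
    "detect_upper_limit",
    "detect_side_limits",
    "segment_breasts",
    "segment_thermogram",
]

MIN_ROWS = 32
MIN_COLS = 32

_SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_GY = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)


class SegmentationError(RuntimeError):
    """A structural feature the segmentation relies on was not found."""


@dataclass
class EdgeMap:
    """Sobel gradient magnitude/direction plus the binarized edge image."""

    gradient_magnitude: np.ndarray
    gradient_direction: np.ndarray
    binary: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.gradient_magnitude.shape != self.gradient_direction.shape:
            raise ValueError("magnitude and direction must share dimensions")
        if self.binary is not None and self.binary.shape != self.gradient_magnitude.shape:
            raise ValueError("binary must share dimensions with the gradient")


@dataclass
class ProjectionProfile:
    """Per-row (horizontal) or per-column (vertical) white-pixel counts."""

    counts: np.ndarray
    axis: str  # "horizontal" | "vertical"

    def __post_init__(self) -> None:
        if self.axis not in ("horizontal", "vertical"):
            raise ValueError(f"axis must be horizontal or vertical, got {self.axis!r}")
        self.counts = np.asarray(self.counts, dtype=int)


@dataclass
class BreastSegmentation:
    """Detected region limits and the left/right breast masks.

    ``left_mask``/``right_mask`` are full-size boolean matrices covering
    the rectangles ``[UL..LL] x [left_limit..central_axis-1]`` and
    ``[UL..LL] x [central_axis..right_limit]`` respectively.
    """

    lower_limit: int
    upper_limit: int
    left_limit: int
    right_limit: int
    central_axis: int
    breast_height: int
    left_mask: np.ndarray
    right_mask: np.ndarray

    def __post_init__(self) -> None:
        rows, cols = self.left_mask.shape
        if not (0 <= self.upper_limit < self.lower_limit < rows):
            raise ValueError("limits must satisfy 0 <= UL < LL < rows")
        if not (0 <= self.left_limit < self.central_axis <= self.right_limit < cols):
            raise ValueError("limits must satisfy 0 <= left < axis <= right < cols")
        expected_axis = self.left_limit + (self.right_limit - self.left_limit + 1) // 2
        if self.central_axis != expected_axis:
            raise ValueError("central_axis inconsistent with side limits")
        if np.any(self.left_mask & self.right_mask):
            raise ValueError("left and right masks overlap")


@dataclass
class SegmentationConfig:
    """Tunables of the limit-detection stage.

    ``hpp_threshold_frac`` — fraction of the image width a row's edge
    count must reach to qualify as the infra-mammary line (the original
    preset count was hand-tuned; a width fraction keeps it scale-free).
    ``scan_region_frac`` — fraction of rows, from the bottom, scanned for
    that line.  ``c_small``/``c_large`` — breast height as a fraction of
    image height for small-breast / large-breast geometry (26 % rule).
    ``edge_threshold`` — "otsu" or a fixed gradient-magnitude value.
    """

    hpp_threshold_frac: float = 0.15
    scan_region_frac: float = 0.40
    c_small: float = 0.45
    c_large: float = 0.35
    edge_threshold: Union[str, float] = "otsu"
    colormap: ColormapSpec = field(default_factory=ColormapSpec)

    def __post_init__(self) -> None:
        if not (0.0 < self.c_large <= self.c_small < 1.0):
            raise ValueError("require 0 < c_large <= c_small < 1")
        if not (0.0 < self.hpp_threshold_frac < 1.0):
            raise ValueError("hpp_threshold_frac must be in (0, 1)")
        if not (0.0 < self.scan_region_frac <= 1.0):
            raise ValueError("scan_region_frac must be in (0, 1]")


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an 8-bit RGB image, scaled to [0, 1]."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected rows x cols x 3 image, got shape {rgb.shape}")
    r, g, b = (rgb[..., i].astype(float) for i in range(3))
    return (0.299 * r + 0.587 * g + 0.114 * b) / 255.0


def sobel_gradient(gray: np.ndarray) -> EdgeMap:
    """Sobel gradient magnitude and direction with edge-replicated borders."""
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2 or gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError(f"input must be at least 3x3, got shape {gray.shape}")
    gx = ndimage.correlate(gray, _SOBEL_GX, mode="nearest")
    gy = ndimage.correlate(gray, _SOBEL_GY, mode="nearest")
    return EdgeMap(
        gradient_magnitude=np.hypot(gx, gy),
        gradient_direction=np.arctan2(gy, gx),
    )


def binarize_edges(e: EdgeMap, method: Union[str, float] = "otsu") -> EdgeMap:
    """Fill ``e.binary`` by thresholding the gradient magnitude.

    ``method`` is either "otsu" or a fixed threshold value.  A flat
    (all-zero magnitude) image cannot be thresholded by Otsu; it falls
    back to threshold 0 with a warning and yields an empty edge set.
    """
    mag = e.gradient_magnitude
    if isinstance(method, str):
        if method != "otsu":
            raise ValueError(f"unknown threshold method {method!r}")
        if np.ptp(mag) == 0.0:
            warnings.warn("flat gradient magnitude; falling back to threshold 0")
            thr = 0.0
        else:
            thr = float(threshold_otsu(mag))
    else:
        thr = float(method)
    # a constant image leaves O(eps) convolution residue; snap it to zero
    atol = 1e-9 * max(1.0, float(mag.max()))
    binary = mag >= thr if thr > 0 else mag > atol
    return EdgeMap(
        gradient_magnitude=mag,
        gradient_direction=e.gradient_direction,
        binary=binary.astype(np.uint8),
    )


def horizontal_projection_profile(e: EdgeMap) -> ProjectionProfile:
    """White-pixel count per row (HPP)."""
    if e.binary is None:
        raise ValueError("edge map has no binary image; run binarize_edges first")
    return ProjectionProfile(counts=e.binary.sum(axis=1), axis="horizontal")


def vertical_projection_profile(e: EdgeMap) -> ProjectionProfile:
    """White-pixel count per column (VPP)."""
    if e.binary is None:
        raise ValueError("edge map has no binary image; run binarize_edges first")
    return ProjectionProfile(counts=e.binary.sum(axis=0), axis="vertical")


def detect_lower_limit(
    p: ProjectionProfile,
    hpp_threshold: int,
    scan_region: tuple[int, int],
) -> int:
    """Bottom-up scan for the infra-mammary line.

    Scans rows from ``scan_region[1]`` (inclusive, bottom) upward to
    ``scan_region[0]``; the first row whose count reaches
    ``hpp_threshold`` is the lower limit LL.
    """
    if p.axis != "horizontal":
        raise ValueError("lower-limit detection needs a horizontal profile")
    lo, hi = scan_region
    n = len(p.counts)
    if not (0 <= lo <= hi < n):
        raise ValueError(f"scan region {scan_region} outside image of {n} rows")
    for r in range(hi, lo - 1, -1):
        if p.counts[r] >= hpp_threshold:
            return r
    raise SegmentationError("no infra-mammary line detected")


def compute_breast_height(
    lower_limit: int, m: int, c_small: float = 0.45, c_large: float = 0.35
) -> int:
    """Breast height in rows from the 26 % bottom-distance rule.

    ``d = m - LL`` is the distance from the fold to the image bottom:
    small breasts leave a large d and vice versa, so a *short* distance
    selects the larger height fraction ``c_small`` (the breast fills more
    of the frame) and a long distance the smaller ``c_large``.  The
    result is clamped so the upper limit stays inside the image.
    """
    if not (0 <= lower_limit < m):
        raise ValueError("require 0 <= LL < m")
    if not (0.0 < c_large <= c_small < 1.0):
        raise ValueError("require 0 < c_large <= c_small < 1")
    d = m - lower_limit
    frac = c_small if d < 0.26 * m else c_large
    h = int(np.floor(frac * m + 0.5))
    if h >= lower_limit:
        warnings.warn(
            f"breast height {h} reaches above the image; clamping to LL={lower_limit}"
        )
        h = lower_limit
    return h


def detect_upper_limit(lower_limit: int, h: int) -> int:
    """Axillary (upper) limit: ``UL = LL - h``."""
    if h > lower_limit:
        raise ValueError("breast height exceeds lower limit")
    return lower_limit - h


def detect_side_limits(
    e: EdgeMap, row_range: tuple[int, int]
) -> tuple[int, int, int]:
    """Outermost white-pixel columns within ``[UL, LL]`` and their midline.

    Returns ``(left_limit, right_limit, central_axis)`` where the axis is
    ``left + floor((right - left + 1) / 2)``.
    """
    if e.binary is None:
        raise ValueError("edge map has no binary image; run binarize_edges first")
    ul, ll = row_range
    band = e.binary[ul : ll + 1]
    cols = np.flatnonzero(band.any(axis=0))
    if cols.size == 0:
        raise SegmentationError("no lateral body contour")
    left, right = int(cols[0]), int(cols[-1])
    axis = left + (right - left + 1) // 2
    return left, right, axis


def segment_breasts(
    t: Thermogram,
    limits: tuple[int, int, int, int, int],
    breast_height: Optional[int] = None,
) -> BreastSegmentation:
    """Build left/right breast masks from detected limits.

    ``limits = (UL, LL, left, right, central_axis)``.  The left breast
    occupies columns ``[left .. axis-1]`` and the right breast
    ``[axis .. right]``, both within rows ``[UL .. LL]``.
    """
    ul, ll, left, right, axis = limits
    rows, cols = t.shape
    left_mask = np.zeros((rows, cols), dtype=bool)
    right_mask = np.zeros((rows, cols), dtype=bool)
    left_mask[ul : ll + 1, left:axis] = True
    right_mask[ul : ll + 1, axis : right + 1] = True
    return BreastSegmentation(
        lower_limit=ll,
        upper_limit=ul,
        left_limit=left,
        right_limit=right,
        central_axis=axis,
        breast_height=breast_height if breast_height is not None else ll - ul,
        left_mask=left_mask,
        right_mask=right_mask,
    )


def segment_thermogram(
    t: Thermogram, config: Optional[SegmentationConfig] = None
) -> BreastSegmentation:
    """Run the full limit-detection chain on one thermogram.

    Uses the RGB rendering when present, otherwise renders one with the
    config's colormap; then grayscale -> Sobel -> binarize -> HPP scan
    for LL -> height rule for UL -> side limits -> masks.
    """
    config = config or SegmentationConfig()
    rows, cols = t.shape
    if rows < MIN_ROWS or cols < MIN_COLS:
        raise ValueError(
            f"image {rows}x{cols} too small for segmentation "
            f"(minimum {MIN_ROWS}x{MIN_COLS})"
        )
    rgb = t.rgb if t.rgb is not None else render_rgb(t, config.colormap).rgb
    gray = to_grayscale(rgb)
    edges = binarize_edges(sobel_gradient(gray), config.edge_threshold)
    hpp = horizontal_projection_profile(edges)
    scan_lo = rows - max(1, int(round(config.scan_region_frac * rows)))
    ll = detect_lower_limit(
        hpp,
        hpp_threshold=int(round(config.hpp_threshold_frac * cols)),
        scan_region=(scan_lo, rows - 1),
    )
    h = compute_breast_height(ll, rows, config.c_small, config.c_large)
    ul = detect_upper_limit(ll, h)
    left, right, axis = detect_side_limits(edges, (ul, ll))
    return segment_breasts(t, (ul, ll, left, right, axis), breast_height=h)
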