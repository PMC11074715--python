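"""Brain contour cropping: grayscale, smoothing, binarization, morphology,
external-contour retrieval and largest-contour cropping.

The stage mirrors the classical blob-extraction recipe for skull-background
removal in axial MRI slices: threshold the smoothed image, clean specks with
an erode/dilate pass, trace the outermost boundary of every 8-connected
foreground component, pick the component of largest filled area, and crop the
*original* image to its bounding box.

Coordinates are (row, col), 0-based; bounding boxes are inclusive on both
ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import NoContourFound, ValidationError

__all__ = [
    "BoundingBox",
    "Contour",
    "MorphParams",
    "PrepConfig",
    "to_grayscale",
    "gaussian_smooth",
    "binarize",
    "morph_clean",
    "find_external_contours",
    "largest_contour_bbox",
    "crop",
    "extract_brain",
]

log = logging.getLogger(__name__)

# 8-connectivity structuring element for component labelling.
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive rectangular extent in (row, col) pixel indices."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValidationError(f"degenerate bounding box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min + 1, self.col_max - self.col_min + 1)

    @property
    def area(self) -> int:
        h, w = self.shape
        return h * w


@dataclass(frozen=True)
class Contour:
    """Outer boundary of one 8-connected foreground component.

    ``points`` is the ordered boundary with collinear runs collapsed to their
    endpoints (simple chain approximation); ``area`` is the filled interior
    pixel count of the component (holes included).
    """

    points: tuple[tuple[int, int], ...]
    area: int

    def bbox(self) -> BoundingBox:
        rows = [p[0] for p in self.points]
        cols = [p[1] for p in self.points]
        return BoundingBox(min(rows), min(cols), max(rows), max(cols))


@dataclass(frozen=True)
class MorphParams:
    kernel: np.ndarray = field(default_factory=lambda: np.ones((3, 3), dtype=bool))
    erode_iterations: int = 2
    dilate_iterations: int = 2

    def __post_init__(self):
        if np.asarray(self.kernel).sum() == 0:
            raise ValidationError("structuring element must be non-empty")
        if self.erode_iterations < 0 or self.dilate_iterations < 0:
            raise ValidationError("iteration counts must be >= 0")


@dataclass(frozen=True)
class PrepConfig:
    """Defaults for the composite :func:`extract_brain` pipeline."""

    kernel_size: int = 5
    sigma: float = 0.0  # 0 -> derived from kernel_size
    threshold: int = 45
    morph: MorphParams = field(default_factory=MorphParams)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion, round-half-up; 1-channel input passes through."""
    img = np.asarray(img)
    if img.ndim == 2:
        return img.astype(np.uint8, copy=True)
    if img.ndim == 3 and img.shape[2] == 3:
        y = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
        return np.clip(np.floor(y + 0.5), 0, 255).astype(np.uint8)
    raise ValidationError(f"expected (H, W) or (H, W, 3) image, got shape {img.shape}")


def _gaussian_kernel1d(size: int, sigma: float) -> np.ndarray:
    if sigma <= 0:
        # OpenCV's convention for deriving sigma from an odd kernel size.
        sigma = 0.3 * ((size - 1) * 0.5 - 1) + 0.8
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-(x * x) / (2.0 * sigma * sigma))
    return k / k.sum()


def gaussian_smooth(img: np.ndarray, kernel_size: int = 5, sigma: float = 0.0) -> np.ndarray:
    """Separable Gaussian blur with edge replication, re-quantized to uint8."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValidationError(f"kernel_size must be odd and >= 1, got {kernel_size}")
    img = np.asarray(img, dtype=float)
    k = _gaussian_kernel1d(kernel_size, sigma)
    out = ndimage.convolve1d(img, k, axis=0, mode="nearest")
    out = ndimage.convolve1d(out, k, axis=1, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def binarize(img: np.ndarray, threshold: int) -> np.ndarray:
    """Pixels >= threshold become 255, the rest 0."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValidationError("binarize expects a single-channel image")
    return np.where(img >= threshold, 255, 0).astype(np.uint8)


def morph_clean(mask: np.ndarray, params: MorphParams | None = None) -> np.ndarray:
    """Erode then dilate a {0,255} mask with the given structuring element."""
    params = params or MorphParams()
    m = np.asarray(mask) > 0
    struct = np.asarray(params.kernel) > 0
    if params.erode_iterations:
        m = ndimage.binary_erosion(m, structure=struct, iterations=params.erode_iterations)
    if params.dilate_iterations:
        m = ndimage.binary_dilation(m, structure=struct, iterations=params.dilate_iterations)
    return np.where(m, 255, 0).astype(np.uint8)


# Moore neighbourhood in clockwise order starting east.
_MOORE = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


def _trace_boundary(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-neighbour tracing of the outer boundary, clockwise from ``start``.

    ``start`` must be the first foreground pixel of the component in raster
    scan order (so its west and north neighbours are background).  Stops when
    the start pixel is re-entered with the same backtrack direction (Jacob's
    criterion), which handles one-pixel-wide spurs correctly.
    """
    h, w = mask.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    boundary = [start]
    cur = start
    b = 4  # backtrack direction (towards the west neighbour, background)
    seen = {(cur, b)}
    while True:
        nxt = None
        for step in range(1, 9):
            d = (b + step) % 8
            nr, nc = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(nr, nc):
                nxt = (nr, nc)
                break
        if nxt is None:  # isolated single pixel
            return boundary
        # Backtrack from the new pixel points at the last background pixel
        # examined; in clockwise indexing this collapses to the rule below.
        b = ((d // 2) * 2 + 6) % 8
        cur = nxt
        # The walk is deterministic in the (pixel, backtrack) state, so the
        # first repeated state means at least one full clockwise lap is done.
        if (cur, b) in seen:
            return boundary
        seen.add((cur, b))
        boundary.append(cur)


def _compress_chain(points: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Collapse collinear horizontal/vertical/diagonal runs to their endpoints."""
    if len(points) <= 2:
        return points
    out = [points[0]]
    n = len(points)
    for i in range(1, n):
        prev_pt = points[i - 1]
        nxt = points[(i + 1) % n]
        cur = points[i]
        d1 = (cur[0] - prev_pt[0], cur[1] - prev_pt[1])
        d2 = (nxt[0] - cur[0], nxt[1] - cur[1])
        if d1 != d2:
            out.append(cur)
    # The closing run may make the start point itself redundant.
    if len(out) > 2:
        d1 = (out[0][0] - out[-1][0], out[0][1] - out[-1][1])
        d2 = (out[1][0] - out[0][0], out[1][1] - out[0][1])
        if d1 == d2:
            out.pop(0)
    return out


def find_external_contours(mask: np.ndarray) -> list[Contour]:
    """One contour per 8-connected foreground component, outer boundary only.

    Interior holes are ignored both in the traced boundary and in the
    reported area (the area is the hole-filled pixel count).  Components are
    returned in raster-scan order of their first pixel.
    """
    m = np.asarray(mask) > 0
    if m.ndim != 2:
        raise ValidationError("find_external_contours expects a 2-D mask")
    labels, n = ndimage.label(m, structure=_EIGHT)
    contours: list[Contour] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        rows, cols = np.nonzero(comp)  # raster order: first entry is topmost-leftmost
        start = (int(rows[0]), int(cols[0]))
        boundary = _trace_boundary(comp, start)
        filled = int(ndimage.binary_fill_holes(comp).sum())
        contours.append(Contour(points=tuple(_compress_chain(boundary)), area=filled))
    # scipy labels in raster order already, but make the ordering explicit
    contours.sort(key=lambda c: min(c.points))
    return contours


def largest_contour_bbox(contours: list[Contour]) -> BoundingBox:
    """Bounding box of the maximum-area contour (ties: first in scan order)."""
    if not contours:
        raise NoContourFound("no foreground contour to crop")
    best = max(contours, key=lambda c: c.area)  # max() keeps the first on ties
    return best.bbox()


def crop(img: np.ndarray, box: BoundingBox) -> np.ndarray:
    img = np.asarray(img)
    h, w = img.shape[:2]
    if box.row_min < 0 or box.col_min < 0 or box.row_max >= h or box.col_max >= w:
        raise ValidationError(f"box {box} out of bounds for image {img.shape}")
    return img[box.row_min : box.row_max + 1, box.col_min : box.col_max + 1].copy()


def extract_brain(img: np.ndarray, config: PrepConfig | None = None) -> np.ndarray:
    """Composite stage: smooth, threshold, clean, find the largest blob, crop.

    The crop is taken from the ORIGINAL (pre-binarization) image so that no
    grey-level information is lost downstream.
    """
    config = config or PrepConfig()
    gray = to_grayscale(img)
    smooth = gaussian_smooth(gray, config.kernel_size, config.sigma)
    mask = binarize(smooth, config.threshold)
    clean = morph_clean(mask, config.morph)
    contours = find_external_contours(clean)
    if not contours:
        raise NoContourFound(
            f"no foreground after threshold {config.threshold} and morphology"
        )
    box = largest_contour_bbox(contours)
    log.debug(
        "extract_brain: %d contour(s), selected area %d, box %s",
        len(contours),
        max(c.area for c in contours),
        box,
    )
    return crop(img, box)
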