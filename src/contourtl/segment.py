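"""Resize, affine enhancement, global threshold selection and grey-preserving
tumor segmentation.

Segmentation is the rule

    f(x, y) = f(x, y)  if f(x, y) >= threshold
              0        otherwise

i.e. pixels at or above the threshold keep their original intensity; it does
NOT binarize.  The threshold itself is the grey level maximizing the
between-class variance of the image histogram (Otsu's criterion), computed
deterministically with ties broken toward the smallest qualifying level.  A
fixed manual threshold may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import DegenerateHistogram, ValidationError

__all__ = [
    "EnhanceParams",
    "resize_image",
    "enhance",
    "compute_threshold",
    "segment",
    "segment_pipeline",
]


@dataclass(frozen=True)
class EnhanceParams:
    """Affine intensity map ``alpha * pixel + beta`` (contrast gain, brightness offset)."""

    alpha: float = 1.3
    beta: float = 10.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be > 0, got {self.alpha}")


def resize_image(img: np.ndarray, side: int = 144) -> np.ndarray:
    """Force the image to ``side x side`` via bilinear interpolation.

    Aspect ratio is deliberately not preserved: the classifier consumes a
    fixed square raster.  A same-size input is returned unchanged.
    """
    if side < 1:
        raise ValidationError(f"side must be >= 1, got {side}")
    img = np.asarray(img)
    if img.shape[:2] == (side, side):
        return img.copy()
    shape = (side, side) if img.ndim == 2 else (side, side, img.shape[2])
    out = _sk_resize(img.astype(float), shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def enhance(img: np.ndarray, params: EnhanceParams | None = None) -> np.ndarray:
    """Apply ``clip(round(alpha * pixel + beta), 0, 255)``."""
    params = params or EnhanceParams()
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValidationError("enhance expects a single-channel image")
    out = params.alpha * img.astype(float) + params.beta
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def compute_threshold(img: np.ndarray) -> int:
    """Grey level maximizing between-class variance (Otsu's criterion).

    Candidate thresholds ``t`` split pixels into {< t} and {>= t}, matching
    the segmentation rule.  Only splits with both classes non-empty are
    considered; ties resolve to the smallest qualifying level.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValidationError("compute_threshold expects a single-channel image")
    hist = np.bincount(img.ravel().astype(np.int64), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogram("need >= 2 distinct grey levels to threshold")

    n = hist.sum()
    levels = np.arange(256, dtype=float)
    # cum0[t] = #pixels < t, mass0[t] = sum of levels < t, for t in 0..256
    cum0 = np.concatenate([[0.0], np.cumsum(hist)])
    mass0 = np.concatenate([[0.0], np.cumsum(hist * levels)])
    t = np.arange(257)
    w0 = cum0 / n
    w1 = 1.0 - w0
    valid = (cum0 > 0) & (cum0 < n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mass0 / cum0
        mu1 = (mass0[-1] - mass0) / (n - cum0)
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~valid] = -np.inf
    best = int(np.argmax(var_between))  # argmax keeps the smallest index on ties
    return int(t[best])


def segment(img: np.ndarray, threshold: int) -> np.ndarray:
    """Zero out pixels below the threshold; keep the rest unchanged."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValidationError("segment expects a single-channel image")
    return np.where(img >= threshold, img, 0).astype(img.dtype)


def segment_pipeline(
    img: np.ndarray,
    params: EnhanceParams | None = None,
    side: int = 144,
    threshold: int | None = None,
) -> tuple[np.ndarray, int]:
    """resize -> enhance -> threshold -> segment; returns (segmented, threshold).

    ``threshold=None`` selects the threshold automatically from the enhanced
    image; an integer fixes it manually.
    """
    resized = resize_image(img, side=side)
    if resized.ndim == 3:
        # downstream stages operate on a single channel
        from .prep import to_grayscale

        resized = to_grayscale(resized)
    enhanced = enhance(resized, params)
    t = compute_threshold(enhanced) if threshold is None else int(threshold)
    return segment(enhanced, t), t
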