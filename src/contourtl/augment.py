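"""Deterministic geometric augmentation: rotation, flips and zoom, plus the
fixed expansion plans that multiply a manifest 8-fold or 36-fold.

Every operation preserves image shape and label.  Right-angle rotations and
flips are exact pixel permutations; other rotations use bilinear resampling
about the image centre with zero (black background) fill.  Zoom-in crops the
centre and rescales back; zoom-out shrinks and zero-pads back.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .phantoms import load_png, save_png
from .segment import resize_image

__all__ = [
    "AugmentOp",
    "AugmentationPlan",
    "rotate",
    "flip",
    "zoom",
    "standard_plan",
    "apply_plan",
]


@dataclass(frozen=True)
class AugmentOp:
    """One deterministic transform: rotate by ``theta``, then flip, then zoom.

    The composite form covers the plan catalogues; the single-transform
    helpers below are the common case.  ``flip_axis`` is ``None`` (no flip),
    ``"horizontal"`` (column reversal) or ``"vertical"`` (row reversal).
    """

    theta: float = 0.0
    flip_axis: str | None = None
    factor: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.theta < 360.0):
            raise ValidationError(f"theta must lie in [0, 360), got {self.theta}")
        if self.factor <= 0:
            raise ValidationError(f"zoom factor must be > 0, got {self.factor}")
        if self.flip_axis not in (None, "horizontal", "vertical"):
            raise ValidationError(f"unknown flip axis {self.flip_axis!r}")

    @property
    def kind(self) -> str:
        kinds = []
        if self.theta:
            kinds.append("rotate")
        if self.flip_axis:
            kinds.append(f"flip_{self.flip_axis[0]}")
        if self.factor != 1.0:
            kinds.append("zoom")
        return "+".join(kinds) or "identity"

    @property
    def name(self) -> str:
        parts = []
        if self.theta:
            parts.append(f"rot{self.theta:g}")
        if self.flip_axis:
            parts.append(f"flip{self.flip_axis[0]}")
        if self.factor != 1.0:
            parts.append(f"zoom{self.factor:g}")
        return "_".join(parts) or "identity"

    def apply(self, img: np.ndarray) -> np.ndarray:
        out = np.asarray(img)
        if self.theta:
            out = rotate(out, self.theta)
        if self.flip_axis:
            out = flip(out, self.flip_axis)
        if self.factor != 1.0:
            out = zoom(out, self.factor)
        return out.copy() if out is img else out


IDENTITY = AugmentOp()


@dataclass(frozen=True)
class AugmentationPlan:
    """Ordered catalogue of distinct ops; the first is always the identity."""

    ops: tuple[AugmentOp, ...]
    name: str

    def __post_init__(self):
        if not self.ops:
            raise ValidationError("a plan needs at least one op")
        if self.ops[0] != IDENTITY:
            raise ValidationError("the first op of a plan must be the identity")
        if len(set(self.ops)) != len(self.ops):
            raise ValidationError("plan ops must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.ops)


def rotation_matrix(theta_deg: float) -> np.ndarray:
    """The 2-D rotation matrix R(theta) = [[cos, -sin], [sin, cos]]."""
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def rotate(img: np.ndarray, theta: float) -> np.ndarray:
    """Rotate about the image centre; right angles are exact permutations."""
    img = np.asarray(img)
    theta = theta % 360.0
    if theta == 0.0:
        return img.copy()
    if theta in (90.0, 180.0, 270.0):
        return np.ascontiguousarray(np.rot90(img, k=int(theta // 90)))
    out = ndimage.rotate(
        img.astype(float), theta, axes=(1, 0), reshape=False, order=1,
        mode="constant", cval=0.0,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def flip(img: np.ndarray, axis: str) -> np.ndarray:
    """Mirror the image: vertical negates the row axis, horizontal the column axis."""
    img = np.asarray(img)
    if axis == "vertical":
        return np.ascontiguousarray(img[::-1])
    if axis == "horizontal":
        return np.ascontiguousarray(img[:, ::-1])
    raise ValidationError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")


def zoom(img: np.ndarray, factor: float) -> np.ndarray:
    """Zoom keeping the output shape equal to the input shape.

    factor > 1: crop the central ``side/factor`` window and scale back up.
    factor < 1: scale the whole image down and centre it on zero padding.
    """
    if factor <= 0:
        raise ValidationError(f"zoom factor must be > 0, got {factor}")
    img = np.asarray(img)
    if factor == 1.0:
        return img.copy()
    h, w = img.shape[:2]
    if factor > 1.0:
        ch, cw = int(round(h / factor)), int(round(w / factor))
        if ch < 1 or cw < 1:
            raise ValidationError(f"zoom factor {factor} collapses the image")
        r0, c0 = (h - ch) // 2, (w - cw) // 2
        crop = img[r0 : r0 + ch, c0 : c0 + cw]
        return _resize_to(crop, h, w)
    sh, sw = max(1, int(round(h * factor))), max(1, int(round(w * factor)))
    small = _resize_to(img, sh, sw)
    out = np.zeros_like(img)
    r0, c0 = (h - sh) // 2, (w - sw) // 2
    out[r0 : r0 + sh, c0 : c0 + sw] = small
    return out


def _resize_to(img: np.ndarray, h: int, w: int) -> np.ndarray:
    from skimage.transform import resize as _sk_resize

    if img.shape[:2] == (h, w):
        return np.asarray(img, dtype=np.uint8).copy()
    shape = (h, w) if img.ndim == 2 else (h, w, img.shape[2])
    out = _sk_resize(np.asarray(img, dtype=float), shape, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def standard_plan(k: int) -> AugmentationPlan:
    """The fixed 8-op and 36-op catalogues.

    k=8:  identity, three right-angle rotations, both flips, zoom 1.25 and 0.8
          (253 sources -> 2024 images; 3000 sources -> 24000 images).
    k=36: all combinations of rotations {0, 90, 180, 270, 15, 345} x flips
          {none, horizontal, vertical} x zooms {1.0, 1.25}, identity first
          (253 sources -> 9108 images).
    """
    if k == 8:
        ops = (
            IDENTITY,
            AugmentOp(theta=90),
            AugmentOp(theta=180),
            AugmentOp(theta=270),
            AugmentOp(flip_axis="horizontal"),
            AugmentOp(flip_axis="vertical"),
            AugmentOp(factor=1.25),
            AugmentOp(factor=0.8),
        )
        return AugmentationPlan(ops=ops, name="x8")
    if k == 36:
        ops = [IDENTITY]
        for theta in (0.0, 90.0, 180.0, 270.0, 15.0, 345.0):
            for axis in (None, "horizontal", "vertical"):
                for factor in (1.0, 1.25):
                    op = AugmentOp(theta=theta, flip_axis=axis, factor=factor)
                    if op != IDENTITY:
                        ops.append(op)
        return AugmentationPlan(ops=tuple(ops), name="x36")
    raise ValidationError(f"unsupported plan size {k}; choose 8 or 36")


def apply_plan(
    manifest: pd.DataFrame, plan: AugmentationPlan, out_dir: Path | str
) -> pd.DataFrame:
    """Expand every manifest row through every plan op.

    Returns (and writes to ``out_dir/manifest.csv``) a manifest with columns
    ``path,label,source,op``; output row count is exactly
    ``len(manifest) * len(plan)``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for _, row in manifest.iterrows():
        src = Path(row["path"])
        if not src.exists():
            raise IOError(f"manifest file not readable: {src}")
        img = load_png(src)
        for op in plan.ops:
            out_img = op.apply(img)
            out_path = out_dir / f"{src.stem}__{op.name}.png"
            save_png(out_img, out_path)
            records.append(
                {
                    "path": str(out_path),
                    "label": int(row["label"]),
                    "source": str(src),
                    "op": op.name,
                }
            )
    out = pd.DataFrame.from_records(records, columns=["path", "label", "source", "op"])
    out.to_csv(out_dir / "manifest.csv", index=False)
    return out
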