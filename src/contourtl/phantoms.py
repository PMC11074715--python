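"""Synthetic brain-MRI-like phantoms with known labels and tumor masks.

A phantom is a bright axis-aligned ellipse ("brain") on a dark background,
optionally carrying a brighter disc ("tumor") strictly inside the ellipse,
plus mild additive Gaussian noise.  Phantoms stand in for real T1/T2 MRI
slices so that every pipeline stage — cropping, segmentation, augmentation,
training, evaluation — is testable without downloading clinical data.

Intensity defaults are chosen so that a single global threshold separates
the tumor from the brain tissue: the tumor-brain contrast (>= 120 grey
levels) dominates the brain-background contrast (~60 levels), which is what
makes a between-class-variance threshold latch onto the tumor.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ValidationError

__all__ = [
    "PhantomSpec",
    "PhantomRanges",
    "LabeledImage",
    "generate_phantom",
    "generate_dataset",
    "DEFAULT_RANGES",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of one phantom image.

    All intensities are 8-bit grey levels and must satisfy
    ``tumor_intensity > brain_intensity > background_intensity``.
    """

    height: int = 176
    width: int = 176
    brain_axes: tuple[int, int] = (60, 52)  # (row, col) semi-axes in pixels
    brain_intensity: int = 70
    tumor_present: bool = False
    tumor_radius: int = 16
    tumor_intensity: int = 220
    noise_sd: float = 3.0
    background_intensity: int = 10

    def validate(self) -> None:
        ints = (self.tumor_intensity, self.brain_intensity, self.background_intensity)
        if not all(0 <= v <= 255 for v in ints):
            raise ValidationError(f"intensities must lie in [0, 255], got {ints}")
        if not (self.tumor_intensity > self.brain_intensity > self.background_intensity):
            raise ValidationError(
                "intensity ordering violated: need tumor > brain > background, "
                f"got {ints}"
            )
        if self.height < 1 or self.width < 1:
            raise ValidationError("image dimensions must be >= 1")
        if min(self.brain_axes) < 1:
            raise ValidationError("brain semi-axes must be >= 1 pixel")
        if self.tumor_present and self.tumor_radius >= min(self.brain_axes):
            raise ValidationError(
                f"tumor radius {self.tumor_radius} must be smaller than the "
                f"smallest brain semi-axis {min(self.brain_axes)}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")


@dataclass(frozen=True)
class LabeledImage:
    """A phantom image with its binary label and (for tumors) ground-truth mask."""

    image: np.ndarray  # uint8, (H, W)
    label: int  # 0 = no tumor, 1 = tumor
    tumor_mask: Optional[np.ndarray] = None  # bool, (H, W); present iff label == 1


@dataclass(frozen=True)
class PhantomRanges:
    """Uniform sampling bounds for :func:`generate_dataset`.

    Each pair is (low, high) inclusive.  Axes bounds apply independently to
    the row and column semi-axes.
    """

    height: tuple[int, int] = (160, 192)
    width: tuple[int, int] = (160, 192)
    brain_axis: tuple[int, int] = (48, 68)
    brain_intensity: tuple[int, int] = (60, 80)
    tumor_radius: tuple[int, int] = (12, 20)
    tumor_intensity: tuple[int, int] = (200, 240)
    background_intensity: tuple[int, int] = (5, 15)
    noise_sd: float = 3.0


DEFAULT_RANGES = PhantomRanges()


def _rng_for(seed: int) -> np.random.Generator:
    if seed < 0 or int(seed) != seed:
        raise ValidationError(f"seed must be a non-negative integer, got {seed!r}")
    return np.random.default_rng(int(seed))


def generate_phantom(spec: PhantomSpec, seed: int) -> LabeledImage:
    """Render one phantom deterministically from ``(spec, seed)``.

    The brain ellipse is centred with a seeded jitter of up to +/-5% of the
    image size; a tumor disc, when requested, is placed strictly inside the
    ellipse (its centre is sampled from the ellipse shrunk by the tumor
    radius, which guarantees containment).
    """
    spec.validate()
    rng = _rng_for(seed)

    h, w = spec.height, spec.width
    ay, ax = spec.brain_axes
    cy = h / 2.0 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2.0 + rng.uniform(-0.05, 0.05) * w

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    brain = ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2 <= 1.0

    img = np.full((h, w), float(spec.background_intensity))
    img[brain] = spec.brain_intensity

    tumor_mask = None
    if spec.tumor_present:
        r = spec.tumor_radius
        # Sample the disc centre inside the ellipse eroded by r.
        phi = rng.uniform(0.0, 2.0 * np.pi)
        rho = np.sqrt(rng.uniform(0.0, 1.0))
        ty = cy + rho * (ay - r) * np.sin(phi)
        tx = cx + rho * (ax - r) * np.cos(phi)
        tumor_mask = (rows - ty) ** 2 + (cols - tx) ** 2 <= r * r
        img[tumor_mask] = spec.tumor_intensity

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    label = 1 if spec.tumor_present else 0
    return LabeledImage(image=img, label=label, tumor_mask=tumor_mask)


def _sample_spec(rng: np.random.Generator, ranges: PhantomRanges, tumor: bool) -> PhantomSpec:
    def u(lohi: tuple[int, int]) -> int:
        return int(rng.integers(lohi[0], lohi[1] + 1))

    h, w = u(ranges.height), u(ranges.width)
    ay = min(u(ranges.brain_axis), (h - 2) // 2)
    ax = min(u(ranges.brain_axis), (w - 2) // 2)
    radius = u(ranges.tumor_radius)
    radius = min(radius, min(ay, ax) - 1)
    return PhantomSpec(
        height=h,
        width=w,
        brain_axes=(ay, ax),
        brain_intensity=u(ranges.brain_intensity),
        tumor_present=tumor,
        tumor_radius=radius,
        tumor_intensity=u(ranges.tumor_intensity),
        noise_sd=ranges.noise_sd,
        background_intensity=u(ranges.background_intensity),
    )


def save_png(img: np.ndarray, path: Path | str) -> None:
    """Write an 8-bit image as PNG (lossless; round-trips bit-identically)."""
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(str(path), format="PNG")


def load_png(path: Path | str) -> np.ndarray:
    return np.asarray(Image.open(str(path)))


def generate_dataset(
    n_tumor: int,
    n_normal: int,
    seed: int,
    out_dir: Path | str,
    spec_ranges: PhantomRanges = DEFAULT_RANGES,
    prefix: str = "phantom",
) -> pd.DataFrame:
    """Write ``n_tumor + n_normal`` phantom PNGs plus a ``path,label`` manifest.

    Tumor images come first in the manifest (label 1), then normals (label 0).
    The manifest is also written to ``out_dir/manifest.csv``.  Fully
    deterministic under ``seed``: per-image seeds are derived by hashing
    ``(seed, index)`` so the i-th image does not depend on how many others
    are requested.
    """
    if n_tumor < 0 or n_normal < 0:
        raise ValidationError("class counts must be non-negative")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records = []
    for i in range(n_tumor + n_normal):
        tumor = i < n_tumor
        sub = derive_seed(seed, f"phantom-{i}")
        rng = _rng_for(sub)
        spec = _sample_spec(rng, spec_ranges, tumor)
        labeled = generate_phantom(spec, derive_seed(seed, f"render-{i}"))
        name = f"{prefix}_{i:04d}_{'yes' if tumor else 'no'}.png"
        save_png(labeled.image, out_dir / name)
        records.append({"path": str(out_dir / name), "label": labeled.label})

    manifest = pd.DataFrame.from_records(records, columns=["path", "label"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def derive_seed(seed: int, tag: str) -> int:
    """Derive a stage seed < 2**31 deterministically from a master seed and tag."""
    digest = hashlib.sha256(f"{int(seed)}:{tag}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def tumor_spec(**overrides) -> PhantomSpec:
    """Convenience: the default spec with a tumor present."""
    return replace(PhantomSpec(tumor_present=True), **overrides)


def normal_spec(**overrides) -> PhantomSpec:
    """Convenience: the default tumor-free spec."""
    return replace(PhantomSpec(tumor_present=False), **overrides)
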