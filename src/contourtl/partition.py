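"""Deterministic train/validation/test partitioning of labelled manifests.

Two schemes are used in practice:

* 80/20(+20%) — hold out 20% of all rows for testing, then 20% of the
  remaining pool for validation (so 64/16/20 of the total);
* 70/30 "unseen case" — no internal test split; train/validate 70/30 on one
  dataset and test on a wholly disjoint second dataset.

Counts use ceiling rounding on the test and validation shares with the
remainder going to training — the only rule consistent with the reference
allocation 9108 -> (5828, 1458, 1822).  Splitting is stratified by label by
default and, when augmentation provenance is recorded in a ``source``
column, grouped so that every variant of one source image lands in the same
split (augmented near-duplicates straddling splits would leak test
information into training).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LeakageError, ValidationError

__all__ = [
    "SplitSpec",
    "Partition",
    "partition_sizes",
    "split_dataset",
    "build_unseen_scenario",
]


@dataclass(frozen=True)
class SplitSpec:
    """Fractions are of the total (test) and of the post-test pool (val)."""

    test_fraction: float = 0.20
    val_fraction: float = 0.20
    stratified: bool = True
    group_by_source: bool = True
    seed: int = 0

    def __post_init__(self):
        for f in (self.test_fraction, self.val_fraction):
            if not (0.0 <= f < 1.0):
                raise ValidationError(f"fractions must lie in [0, 1), got {f}")


@dataclass(frozen=True)
class Partition:
    train: pd.DataFrame
    validation: pd.DataFrame
    test: pd.DataFrame

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))

    def as_manifest(self) -> pd.DataFrame:
        """All rows with a ``split`` column added."""
        parts = []
        for name, df in (("train", self.train), ("validation", self.validation),
                         ("test", self.test)):
            d = df.copy()
            d["split"] = name
            parts.append(d)
        return pd.concat(parts, ignore_index=True)


def partition_sizes(total: int, spec: SplitSpec) -> tuple[int, int, int]:
    """(train, val, test) counts: ceil on test, ceil on val, remainder to train."""
    if total < 0:
        raise ValidationError("total must be >= 0")
    test = math.ceil(spec.test_fraction * total)
    pool = total - test
    val = math.ceil(spec.val_fraction * pool)
    train = pool - val
    return (train, val, test)


def _apportion(counts: np.ndarray, k: int) -> np.ndarray:
    """Largest-remainder apportionment of ``k`` items across groups of the
    given sizes; result sums to ``k`` with each share within 1 of exact."""
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    exact = counts * (k / total)
    base = np.floor(exact).astype(int)
    short = k - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return np.minimum(base, counts)


def _validate_manifest(manifest: pd.DataFrame) -> None:
    if len(manifest) == 0:
        raise ValidationError("manifest is empty")
    if manifest["path"].duplicated().any():
        raise ValidationError("manifest paths must be unique")
    labels = set(manifest["label"].unique().tolist())
    if not labels <= {0, 1}:
        raise ValidationError(f"labels must be binary 0/1, got {sorted(labels)}")


def split_dataset(manifest: pd.DataFrame, spec: SplitSpec) -> Partition:
    """Seeded, optionally stratified and source-grouped three-way split.

    Row-level mode (``group_by_source=False`` or no ``source`` column)
    reproduces :func:`partition_sizes` exactly, with per-class proportions
    within one item of the overall fractions when stratified.  Grouped mode
    assigns whole source groups and therefore matches the target sizes only
    to the nearest whole group.
    """
    _validate_manifest(manifest)
    rng = np.random.default_rng(spec.seed)
    n = len(manifest)
    train_n, val_n, test_n = partition_sizes(n, spec)

    grouped = spec.group_by_source and "source" in manifest.columns
    if grouped:
        keys = manifest["source"].to_numpy()
    else:
        keys = manifest["path"].to_numpy()

    # Work at group granularity; in row-level mode every group is a single row.
    df = manifest.reset_index(drop=True)
    group_ids = pd.unique(keys)
    group_label = df.groupby(keys, sort=False)["label"].first()

    test_idx: list[int] = []
    val_idx: list[int] = []
    train_idx: list[int] = []

    if spec.stratified:
        classes = sorted(group_label.unique().tolist())
        class_rows = np.array(
            [int((df["label"] == c).sum()) for c in classes], dtype=int
        )
        test_share = _apportion(class_rows, test_n)
        val_share = _apportion(class_rows - test_share, val_n)
    else:
        classes = [None]
        test_share = np.array([test_n])
        val_share = np.array([val_n])

    all_rows_of = df.groupby(keys, sort=False).indices
    for ci, c in enumerate(classes):
        if c is None:
            gids = list(group_ids)
        else:
            gids = [g for g in group_ids if group_label[g] == c]
        order = rng.permutation(len(gids))
        rows_of = {g: all_rows_of[g].tolist() for g in gids}

        want_test, want_val = int(test_share[ci]), int(val_share[ci])
        got_test = got_val = 0
        for oi in order:
            g = gids[oi]
            rows = rows_of[g]
            if got_test < want_test:
                test_idx.extend(rows)
                got_test += len(rows)
            elif got_val < want_val:
                val_idx.extend(rows)
                got_val += len(rows)
            else:
                train_idx.extend(rows)

    return Partition(
        train=df.loc[sorted(train_idx)].reset_index(drop=True),
        validation=df.loc[sorted(val_idx)].reset_index(drop=True),
        test=df.loc[sorted(test_idx)].reset_index(drop=True),
    )


def _sources(manifest: pd.DataFrame) -> set[str]:
    s = set(manifest["path"].astype(str))
    if "source" in manifest.columns:
        s |= set(manifest["source"].dropna().astype(str))
    return s


def build_unseen_scenario(
    train_manifest: pd.DataFrame,
    test_manifest: pd.DataFrame,
    spec: SplitSpec | None = None,
) -> Partition:
    """Train/validate on one dataset (70/30 by default), test on a disjoint one.

    Raises :class:`LeakageError` if the two manifests share any path or any
    augmentation source image.
    """
    spec = spec or SplitSpec(test_fraction=0.0, val_fraction=0.30)
    _validate_manifest(train_manifest)
    overlap = _sources(train_manifest) & _sources(test_manifest) if len(test_manifest) else set()
    if overlap:
        raise LeakageError(
            f"train and test manifests share {len(overlap)} item(s), e.g. "
            f"{sorted(overlap)[0]!r}"
        )
    inner = SplitSpec(
        test_fraction=0.0,
        val_fraction=spec.val_fraction,
        stratified=spec.stratified,
        group_by_source=spec.group_by_source,
        seed=spec.seed,
    )
    part = split_dataset(train_manifest, inner)
    return Partition(
        train=part.train,
        validation=part.validation,
        test=test_manifest.reset_index(drop=True),
    )
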