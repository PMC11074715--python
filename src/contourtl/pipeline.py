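"""End-to-end experiment orchestration from a single YAML-serializable
configuration: phantom generation (or user manifests) -> contour cropping ->
thresholding segmentation -> deterministic augmentation -> partitioning ->
training -> prediction -> seven-metric report.

One top-level seed drives every stage; stage seeds are derived by hashing
``(seed, stage-tag)`` so that changing one stage's randomness never shifts
another's.  The run directory keeps a copy of the configuration, the
per-epoch history, the partitioned manifest and the metric report, which is
enough to re-execute the run identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import model as tlm
from .augment import standard_plan, apply_plan
from .errors import ValidationError
from .partition import Partition, SplitSpec, build_unseen_scenario, split_dataset
from .phantoms import DEFAULT_RANGES, derive_seed, generate_dataset, load_png, save_png
from .prep import PrepConfig, extract_brain
from .segment import EnhanceParams, segment_pipeline

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "preprocess_manifest"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment needs; loadable from YAML via :meth:`from_yaml`."""

    out_dir: str
    seed: int = 0
    scenario: str = "single"  # "single" (80/20+20%) or "unseen" (70/30 + disjoint test)

    # data: either explicit manifest CSVs ...
    manifest: str | None = None
    test_manifest: str | None = None  # unseen scenario only
    # ... or phantom generation counts (train pool; test pool for unseen)
    phantom_counts: tuple[int, int] | None = None  # (n_tumor, n_normal)
    phantom_test_counts: tuple[int, int] | None = None
    phantom_noise_sd: float = 3.0

    # preprocessing
    crop_threshold: int = 45
    crop_kernel: int = 5
    segment_enabled: bool = True
    alpha: float = 1.3
    beta: float = 10.0
    image_side: int = 144
    fixed_threshold: int | None = None

    # augmentation plan: "x8", "x36" or "none"
    plan: str = "none"

    # partitioning
    test_fraction: float = 0.20
    val_fraction: float = 0.20
    stratified: bool = True
    group_by_source: bool = True

    # model + training
    model: str = "vgg16"  # "vgg16" or "reduced"
    channels: int = 3
    learning_rate: float = 2e-5
    max_epochs: int = 30
    batch_size: int = 32
    patience: int = 5
    weights_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("phantom_counts", "phantom_test_counts"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def preprocess_manifest(
    manifest: pd.DataFrame,
    out_dir: Path,
    config: RunConfig,
) -> pd.DataFrame:
    """Crop each image to its largest contour and (optionally) segment it.

    Writes the processed PNGs and returns a manifest pointing at them,
    preserving labels (and source/op provenance columns when present).
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    prep_cfg = PrepConfig(kernel_size=config.crop_kernel, threshold=config.crop_threshold)
    params = EnhanceParams(alpha=config.alpha, beta=config.beta)
    records = []
    thresholds = []
    for _, row in manifest.iterrows():
        img = load_png(row["path"])
        cropped = extract_brain(img, prep_cfg)
        if config.segment_enabled:
            out, t = segment_pipeline(
                cropped, params, side=config.image_side, threshold=config.fixed_threshold
            )
        else:
            from .segment import resize_image

            out, t = resize_image(cropped, side=config.image_side), -1
        name = Path(row["path"]).stem + "_proc.png"
        save_png(out, out_dir / name)
        # keep provenance: default the source to the raw input path so that
        # downstream grouping and the unseen-case leakage guard can see
        # through the path rewrite
        rec = {
            "path": str(out_dir / name),
            "label": int(row["label"]),
            "source": row["source"] if "source" in row.index else str(row["path"]),
        }
        if "op" in row.index:
            rec["op"] = row["op"]
        records.append(rec)
        thresholds.append({"path": str(row["path"]), "threshold": t})
    pd.DataFrame(thresholds).to_csv(out_dir / "thresholds.csv", index=False)
    out = pd.DataFrame.from_records(records)
    out.to_csv(out_dir / "manifest.csv", index=False)
    return out


def _obtain_manifest(config: RunConfig, out_dir: Path, which: str) -> pd.DataFrame:
    if which == "train":
        manifest_path, counts, tag = config.manifest, config.phantom_counts, "train-data"
    else:
        manifest_path, counts, tag = (
            config.test_manifest,
            config.phantom_test_counts,
            "test-data",
        )
    if manifest_path is not None:
        return pd.read_csv(manifest_path)
    if counts is None:
        raise ValidationError(f"no manifest or phantom counts for the {which} set")
    ranges = dataclasses.replace(DEFAULT_RANGES, noise_sd=config.phantom_noise_sd)
    return generate_dataset(
        counts[0],
        counts[1],
        seed=derive_seed(config.seed, tag),
        out_dir=out_dir / f"phantoms_{which}",
        spec_ranges=ranges,
        prefix=f"{which}",
    )


def _partition(config: RunConfig, train_manifest, test_manifest) -> Partition:
    if config.scenario == "unseen":
        spec = SplitSpec(
            test_fraction=0.0,
            val_fraction=config.val_fraction,
            stratified=config.stratified,
            group_by_source=config.group_by_source,
            seed=derive_seed(config.seed, "split"),
        )
        return build_unseen_scenario(train_manifest, test_manifest, spec)
    spec = SplitSpec(
        test_fraction=config.test_fraction,
        val_fraction=config.val_fraction,
        stratified=config.stratified,
        group_by_source=config.group_by_source,
        seed=derive_seed(config.seed, "split"),
    )
    return split_dataset(train_manifest, spec)


def run_experiment(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict (also on disk)."""
    if config.scenario not in ("single", "unseen"):
        raise ValidationError(f"unknown scenario {config.scenario!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)

    current = {"stage": "setup"}

    def stage(name):
        current["stage"] = name
        log.info("stage: %s", name)

    try:
        stage("data")
        train_raw = _obtain_manifest(config, out, "train")
        test_raw = _obtain_manifest(config, out, "test") if config.scenario == "unseen" else None

        stage("preprocess")
        train_proc = preprocess_manifest(train_raw, out / "processed_train", config)
        test_proc = (
            preprocess_manifest(test_raw, out / "processed_test", config)
            if test_raw is not None
            else None
        )

        stage("augment")
        if config.plan not in ("none", None):
            plan = standard_plan(int(config.plan.lstrip("x")))
            train_proc = apply_plan(train_proc, plan, out / "augmented_train")
            if test_proc is not None:
                test_proc = apply_plan(test_proc, plan, out / "augmented_test")

        stage("split")
        part = _partition(config, train_proc, test_proc)
        part.as_manifest().to_csv(out / "partition.csv", index=False)

        stage("train")
        if config.model == "reduced":
            spec = tlm.ModelSpec.reduced(side=config.image_side, channels=config.channels)
        elif config.model == "vgg16":
            spec = tlm.ModelSpec.vgg16(
                input_shape=(config.image_side, config.image_side, config.channels)
            )
        else:
            raise ValidationError(f"unknown model {config.model!r}")
        model = tlm.build_model(
            spec, seed=derive_seed(config.seed, "init"), weights_path=config.weights_path
        )
        tcfg = tlm.TrainConfig(
            learning_rate=config.learning_rate,
            max_epochs=config.max_epochs,
            batch_size=config.batch_size,
            early_stopping_patience=config.patience,
            seed=derive_seed(config.seed, "train"),
        )
        history = tlm.train(model, part, tcfg)
        pd.DataFrame(
            {
                "epoch": np.arange(1, len(history) + 1),
                "train_loss": history.train_loss,
                "train_accuracy": history.train_accuracy,
                "val_loss": history.val_loss,
                "val_accuracy": history.val_accuracy,
            }
        ).to_csv(out / "history.csv", index=False)

        stage("evaluate")
        probs = tlm.predict(model, part.test)
        y_true = part.test["label"].to_numpy(dtype=int)
        y_pred = probs.argmax(axis=1)
        cm = ev.confusion(y_true, y_pred)
        report_metrics = ev.metrics(cm)
        auc = (
            ev.roc_auc(y_true, probs[:, 1]) if len(np.unique(y_true)) == 2 else None
        )
        report_metrics = dataclasses.replace(report_metrics, roc_auc=auc)
    except Exception as exc:
        exc.args = (f"[stage '{current['stage']}' failed] {exc}",) + exc.args[1:]
        raise

    report = {
        "seed": config.seed,
        "scenario": config.scenario,
        "sizes": {
            "train": len(part.train),
            "validation": len(part.validation),
            "test": len(part.test),
        },
        "confusion_matrix": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "metrics": report_metrics.rounded().as_dict(),
        "stopped_epoch": history.stopped_epoch,
        "best_epoch": history.best_epoch,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
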