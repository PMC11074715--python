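import numpy as np
import pandas as pd
import pytest

from contourtl import phantoms


@pytest.fixture
def tumor_image():
    """A default noisy tumor phantom (deterministic)."""
    return phantoms.generate_phantom(phantoms.tumor_spec(), seed=7)


@pytest.fixture
def normal_image():
    return phantoms.generate_phantom(phantoms.normal_spec(), seed=7)


@pytest.fixture
def small_manifest(tmp_path):
    """A 6-image on-disk phantom dataset with manifest (3 tumor / 3 normal)."""
    return phantoms.generate_dataset(3, 3, seed=11, out_dir=tmp_path / "data")


def synthetic_manifest(n_pos: int, n_neg: int, with_source: bool = False) -> pd.DataFrame:
    """In-memory manifest of fake paths, for partitioning tests (no files)."""
    rows = []
    for i in range(n_pos + n_neg):
        label = 1 if i < n_pos else 0
        rec = {"path": f"img_{i:05d}.png", "label": label}
        if with_source:
            rec["source"] = f"src_{i:05d}.png"
        rows.append(rec)
    return pd.DataFrame(rows)


def expand_manifest(manifest: pd.DataFrame, k: int) -> pd.DataFrame:
    """Simulate a k-fold augmentation expansion (k variants per source row)."""
    rows = []
    for _, row in manifest.iterrows():
        for j in range(k):
            rows.append(
                {
                    "path": f"{row['path']}__v{j}.png",
                    "label": row["label"],
                    "source": row["path"],
                    "op": f"v{j}",
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
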