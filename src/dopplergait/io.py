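"""On-disk formats: PNG images, CSV manifests and feature tables, models.

Every CSV written here carries a leading ``#`` provenance comment embedding
the seed and a short configuration hash, so an output directory is
self-describing; the readers skip such comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import joblib
import numpy as np
import pandas as pd

from .apathy_scale import N_ITEMS, QuestionnaireResponse
from .features import GridSpec, feature_names
from .models import ModelSpec
from .synthgen import SyntheticDataset

__all__ = [
    "config_hash",
    "write_csv",
    "read_csv",
    "save_dataset",
    "load_manifest",
    "load_images",
    "responses_from_manifest",
    "write_features",
    "read_features",
    "save_model",
    "load_model",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> Path:
    """Write a DataFrame with a ``#`` provenance header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fields = ", ".join(f"{k}={v}" for k, v in provenance.items())
            fh.write(f"# {fields}, config_hash={config_hash(provenance)}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> Path:
    """Write PNGs plus ``manifest.csv`` (filename, label, score, q1..q14)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (img, label, resp) in enumerate(zip(dataset.images, dataset.labels, dataset.responses)):
        fname = f"walk_{k:04d}.png"
        iio.imwrite(out_dir / fname, np.asarray(img, dtype=np.uint8))
        row = {"filename": fname, "label": label, "score": resp.score}
        row.update({f"q{i + 1}": v for i, v in enumerate(resp.items)})
        rows.append(row)
    return write_csv(pd.DataFrame(rows), out_dir / "manifest.csv", provenance={"seed": dataset.seed, "n": len(dataset)})


def load_manifest(path: str | Path) -> pd.DataFrame:
    df = read_csv(path)
    missing = {"filename", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks required columns {sorted(missing)}")
    return df


def load_images(image_dir: str | Path, manifest: pd.DataFrame) -> list[np.ndarray]:
    image_dir = Path(image_dir)
    return [np.asarray(iio.imread(image_dir / fname))[:, :, :3] for fname in manifest["filename"]]


def responses_from_manifest(manifest: pd.DataFrame) -> list[QuestionnaireResponse]:
    cols = [f"q{i + 1}" for i in range(N_ITEMS)]
    missing = set(cols) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks questionnaire columns {sorted(missing)}")
    return [QuestionnaireResponse(tuple(row)) for row in manifest[cols].to_numpy()]


def write_features(
    X: np.ndarray,
    manifest: pd.DataFrame,
    path: str | Path,
    channel: str,
    threshold: int,
    grid: GridSpec = GridSpec(),
    provenance: dict | None = None,
) -> Path:
    """Write the feature table (filename, channel, threshold, strips, label)."""
    df = pd.DataFrame(np.asarray(X), columns=feature_names(grid))
    df.insert(0, "filename", manifest["filename"].to_numpy())
    df.insert(1, "channel", channel)
    df.insert(2, "threshold", threshold)
    df["label"] = manifest["label"].to_numpy()
    return write_csv(df, path, provenance=provenance)


def read_features(path: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Return (feature matrix, labels, full table) from a feature CSV."""
    df = read_csv(path)
    meta = {"filename", "channel", "threshold", "label", "score"}
    cols = [c for c in df.columns if c not in meta]
    labels = df["label"].to_numpy(dtype=object) if "label" in df.columns else np.array([], dtype=object)
    return df[cols].to_numpy(dtype=np.float64), labels, df


def save_model(model, spec: ModelSpec, path: str | Path) -> Path:
    """Persist a fitted model with a JSON sidecar recording spec + seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path)
    sidecar = {"name": spec.name, "hyperparameters": spec.hyperparameters, "rng_seed": spec.rng_seed}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2, default=str) + "\n")
    return path


def load_model(path: str | Path):
    """Load a persisted model; returns (model, spec) when the sidecar exists."""
    path = Path(path)
    model = joblib.load(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    spec = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spec = ModelSpec(meta["name"], dict(meta.get("hyperparameters", {})), int(meta.get("rng_seed", 0)))
    return model, spec
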