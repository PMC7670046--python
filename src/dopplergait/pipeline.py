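"""End-to-end pipeline: simulate → score → extract → sweep → report.

:class:`RunConfig` is the single human-editable configuration (YAML or
JSON); unknown keys fail fast with the offending key named.  ``run_pipeline``
executes the full flow into an output directory and leaves four artifacts:
``manifest.csv`` (images + questionnaires + labels), ``features.csv`` (one
reference feature table), ``sweep.csv`` (one row per configuration) and
``summary.json`` (best configuration per model, seeds, config hash).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as dio
from .evaluate import SplitSpec, best_configurations, grid_comparison, sweep_to_dataframe
from .features import CHANNELS, DEFAULT_THRESHOLDS, BinarizationConfig, GridSpec
from .models import MODEL_NAMES
from .synthgen import DEFAULT_CANVAS, DEFAULT_CLASS_EFFECT, GaitParams, simulate_dataset

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    out_dir: str = "dopplergait_run"
    seed: int = 0
    n_apathy: int = 56
    n_nonapathy: int = 122
    canvas: tuple[int, int] = DEFAULT_CANVAS
    class_effect: float = DEFAULT_CLASS_EFFECT
    gait: dict = field(default_factory=dict)  # GaitParams overrides
    channels: tuple[str, ...] = CHANNELS
    thresholds: tuple[int, ...] = DEFAULT_THRESHOLDS
    grids: tuple[str, ...] = ("4x4",)
    models: tuple[str, ...] = MODEL_NAMES
    normalize: bool = True
    split: dict = field(default_factory=dict)  # SplitSpec overrides
    reference_channel: str = "red"
    reference_threshold: int = 170

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("config key 'models' must list at least one model")
        if not self.channels or not self.thresholds or not self.grids:
            raise ValueError("config keys 'channels', 'thresholds' and 'grids' must be non-empty")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"config key 'models' names unknown models {sorted(unknown)}")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"config key 'channels' names unknown channels {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in valid:
                raise ValueError(f"invalid config key {key!r}; valid keys: {sorted(valid)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return dio.config_hash(self.as_dict())

    def gait_params(self) -> GaitParams:
        return GaitParams(**self.gait)

    def split_spec(self) -> SplitSpec:
        return SplitSpec(rng_seed=self.seed, **self.split)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run simulate → extract → sweep → report; return artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"seed": config.seed, "config_hash": config.hash}

    logger.info("stage simulate: %d apathy + %d non-apathy images (seed=%d)", config.n_apathy, config.n_nonapathy, config.seed)
    dataset = simulate_dataset(
        config.n_apathy,
        config.n_nonapathy,
        rng_seed=config.seed,
        params=config.gait_params(),
        canvas=tuple(config.canvas),
        class_effect=config.class_effect,
    )
    manifest_path = dio.save_dataset(dataset, out)
    manifest = dio.load_manifest(manifest_path)

    logger.info("stage extract: reference features channel=%s threshold=%d", config.reference_channel, config.reference_threshold)
    grid = GridSpec.parse(config.grids[0])
    from .evaluate import feature_matrix  # local import to keep module load light

    X = feature_matrix(
        dataset.images,
        BinarizationConfig(config.reference_channel, config.reference_threshold),
        grid,
        config.normalize,
    )
    features_path = dio.write_features(
        X, manifest, out / "features.csv", config.reference_channel, config.reference_threshold, grid, provenance
    )

    logger.info(
        "stage sweep: %d channels x %d thresholds x %d models x %d grids (seed=%d)",
        len(config.channels), len(config.thresholds), len(config.models), len(config.grids), config.seed,
    )
    results = grid_comparison(
        dataset,
        [GridSpec.parse(g) for g in config.grids],
        split=config.split_spec(),
        channels=config.channels,
        thresholds=config.thresholds,
        models=config.models,
        normalize=config.normalize,
        model_seed=config.seed,
    )
    df = sweep_to_dataframe(results)
    sweep_path = dio.write_csv(df, out / "sweep.csv", provenance=provenance)

    summary = {
        "seed": config.seed,
        "config_hash": config.hash,
        "config": config.as_dict(),
        "n_sweep_records": int(len(df)),
        "best_by_model": best_configurations(df).to_dict(orient="records"),
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=str) + "\n")
    logger.info("stage report: %d sweep records -> %s", len(df), summary_path)
    return {"manifest": manifest_path, "features": features_path, "sweep": sweep_path, "summary": summary_path}
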