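"""Evaluation protocol: fixed stratified split, per-class rates, sweeps.

The protocol mirrors a single-split study design: of 178 walking
spectrograms (56 apathy / 122 non-apathy), 150 train (48/102) and 28 test
(8/20).  Accuracy is reported as four rates, each a fraction of the WHOLE
test set:

* Apathy-C / Apathy-M — apathy samples classified correctly / incorrectly,
* Non-Apathy-C / Non-Apathy-M — likewise for non-apathy,

so the four rates sum to one and total accuracy = Apathy-C + Non-Apathy-C.
With this denominator a constant non-apathy predictor scores exactly the
non-apathy test share, 20/28 ≈ 71.4% — the ceiling any majority-class
classifier can reach on the default split.

``run_sweep`` repeats train/evaluate over the full channel × threshold ×
model grid (default 4 × 18 × 7 = 504 configurations) on one fixed split,
and ``grid_comparison`` repeats the sweep for alternative separation grids
(4x5 → 9 features, 5x5 → 10; the network's input width follows the grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apathy_scale import APATHY, LABELS, NON_APATHY
from .features import CHANNELS, DEFAULT_THRESHOLDS, BinarizationConfig, GridSpec, extract_channel, binarize, grid_counts
from .models import ENSEMBLE_MEMBERS, MODEL_NAMES, MajorityVoteEnsemble, make_model
from .synthgen import SyntheticDataset

__all__ = [
    "SplitSpec",
    "ClassMetrics",
    "SweepResult",
    "stratified_split",
    "compute_metrics",
    "feature_matrix",
    "run_sweep",
    "grid_comparison",
    "sweep_to_dataframe",
    "best_configurations",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """Per-class train/test counts plus the shuffle seed."""

    n_train_apathy: int = 48
    n_train_nonapathy: int = 102
    n_test_apathy: int = 8
    n_test_nonapathy: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_train_apathy", "n_train_nonapathy", "n_test_apathy", "n_test_nonapathy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_test(self) -> int:
        return self.n_test_apathy + self.n_test_nonapathy


def stratified_split(labels, spec: SplitSpec = SplitSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/test index arrays with exact per-class counts.

    ``labels`` may be a sequence of labels or a :class:`SyntheticDataset`.
    Within each class the samples are shuffled with the spec's seed, then
    the first ``n_train`` go to training and the next ``n_test`` to test.
    """
    if isinstance(labels, SyntheticDataset):
        labels = labels.labels
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(spec.rng_seed)
    wanted = {
        APATHY: (spec.n_train_apathy, spec.n_test_apathy),
        NON_APATHY: (spec.n_train_nonapathy, spec.n_test_nonapathy),
    }
    train_idx, test_idx = [], []
    for label in LABELS:
        n_train, n_test = wanted[label]
        pool = np.flatnonzero(labels == label)
        if len(pool) < n_train + n_test:
            raise ValueError(
                f"need {n_train + n_test} {label!r} samples ({n_train} train + {n_test} test), have {len(pool)}"
            )
        pool = rng.permutation(pool)
        train_idx.append(pool[:n_train])
        test_idx.append(pool[n_train : n_train + n_test])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class correct/incorrect rates as fractions of the whole test set."""

    apathy_c: float
    apathy_m: float
    nonapathy_c: float
    nonapathy_m: float

    @property
    def total_accuracy(self) -> float:
        return self.apathy_c + self.nonapathy_c

    def as_dict(self) -> dict[str, float]:
        return {
            "apathy_c": self.apathy_c,
            "apathy_m": self.apathy_m,
            "nonapathy_c": self.nonapathy_c,
            "nonapathy_m": self.nonapathy_m,
            "total_accuracy": self.total_accuracy,
        }


def compute_metrics(predictions, truths) -> ClassMetrics:
    """Tally the four rates from predicted and true labels."""
    predictions = np.asarray(predictions, dtype=object)
    truths = np.asarray(truths, dtype=object)
    if len(predictions) != len(truths):
        raise ValueError(f"{len(predictions)} predictions but {len(truths)} truths")
    if len(truths) == 0:
        raise ValueError("cannot compute metrics on an empty test set")
    n = len(truths)
    correct = predictions == truths
    is_ap = truths == APATHY
    return ClassMetrics(
        apathy_c=float((correct & is_ap).sum()) / n,
        apathy_m=float((~correct & is_ap).sum()) / n,
        nonapathy_c=float((correct & ~is_ap).sum()) / n,
        nonapathy_m=float((~correct & ~is_ap).sum()) / n,
    )


@dataclass(frozen=True)
class SweepResult:
    """Metrics for one (channel, threshold, model, grid) configuration."""

    channel: str
    threshold: int
    model: str
    grid: GridSpec
    metrics: ClassMetrics
    seed: int


def feature_matrix(
    images,
    config: BinarizationConfig,
    grid: GridSpec = GridSpec(),
    normalize: bool = True,
    planes: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Stack per-image feature vectors into an (n_images, n_features) matrix.

    ``planes`` may carry the pre-extracted channel planes to avoid repeating
    the channel selection across a threshold ladder.
    """
    if planes is None:
        planes = [extract_channel(img, config.channel) for img in images]
    return np.stack([grid_counts(binarize(p, config.threshold), grid, normalize=normalize) for p in planes])


def run_sweep(
    dataset: SyntheticDataset,
    split: SplitSpec = SplitSpec(),
    channels=CHANNELS,
    thresholds=DEFAULT_THRESHOLDS,
    models=MODEL_NAMES,
    grid: GridSpec = GridSpec(),
    normalize: bool = True,
    model_seed: int = 0,
) -> list[SweepResult]:
    """Train and evaluate every (channel, threshold, model) configuration.

    One record per configuration, all on the same stratified split.  When
    the ensemble is swept together with all of its member models, the
    members fitted for the same configuration are reused rather than
    refitted.
    """
    channels, thresholds, models = list(channels), [int(t) for t in thresholds], list(models)
    if not channels or not thresholds or not models:
        raise ValueError("channels, thresholds and models must all be non-empty")
    train_idx, test_idx = stratified_split(dataset.labels, split)
    labels = np.asarray(dataset.labels, dtype=object)
    y_train, y_test = labels[train_idx], labels[test_idx]

    results: list[SweepResult] = []
    for channel in channels:
        planes = [extract_channel(img, channel) for img in dataset.images]
        for threshold in thresholds:
            X = feature_matrix(dataset.images, BinarizationConfig(channel, threshold), grid, normalize, planes=planes)
            X_train, X_test = X[train_idx], X[test_idx]
            fitted: dict[str, object] = {}
            for name in models:
                if name == "ensemble" and all(m in fitted for m in ENSEMBLE_MEMBERS):
                    model = MajorityVoteEnsemble([fitted[m] for m in ENSEMBLE_MEMBERS], prefitted=True)
                else:
                    model = make_model(name, seed=model_seed)
                    model.fit(X_train, y_train)
                    fitted[name] = model
                metrics = compute_metrics(model.predict(X_test), y_test)
                results.append(SweepResult(channel, threshold, name, grid, metrics, model_seed))
            logger.debug("sweep: channel=%s threshold=%d done", channel, threshold)
        logger.info("sweep: channel=%s done (%d thresholds x %d models)", channel, len(thresholds), len(models))
    return results


def grid_comparison(dataset: SyntheticDataset, grids, **sweep_kwargs) -> list[SweepResult]:
    """Repeat the full sweep for each separation grid."""
    grids = list(grids)
    if not grids:
        raise ValueError("grids must be non-empty")
    results: list[SweepResult] = []
    for grid in grids:
        results.extend(run_sweep(dataset, grid=grid, **sweep_kwargs))
    return results


def sweep_to_dataframe(results: list[SweepResult]) -> pd.DataFrame:
    """One row per configuration with the four rates and total accuracy."""
    rows = []
    for r in results:
        row = {"channel": r.channel, "threshold": r.threshold, "model": r.model, "grid": str(r.grid), "seed": r.seed}
        row.update(r.metrics.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def best_configurations(df: pd.DataFrame) -> pd.DataFrame:
    """Highest-total-accuracy row per model (first threshold wins ties)."""
    idx = df.groupby("model")["total_accuracy"].idxmax()
    return df.loc[idx].sort_values("total_accuracy", ascending=False).reset_index(drop=True)
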