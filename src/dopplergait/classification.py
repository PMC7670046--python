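"""Model/Results front door for one apathy-classification experiment.

:class:`ApathyClassificationModel` bundles a feature configuration
(channel, binarization threshold, separation grid) with a classifier
choice; :meth:`~ApathyClassificationModel.fit` trains on the stratified
split and returns an :class:`ApathyClassificationResults` carrying the
fitted classifier, the held-out predictions, the per-class rates and a
``summary()`` table, in the style of statsmodels' model/results pairs.

    >>> from dopplergait import simulate_dataset, ApathyClassificationModel
    >>> data = simulate_dataset(rng_seed=7)
    >>> res = ApathyClassificationModel.from_dataset(
    ...     data, channel="red", threshold=170, classifier="nn", seed=7).fit()
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import ClassMetrics, SplitSpec, compute_metrics, feature_matrix, stratified_split
from .features import BinarizationConfig, GridSpec, extract_features, feature_names
from .models import MODEL_NAMES, make_model
from .synthgen import SyntheticDataset

__all__ = ["ApathyClassificationModel", "ApathyClassificationResults"]


@dataclass
class ApathyClassificationModel:
    """One experiment: features + labels + a classifier configuration.

    Construct directly from a feature matrix, from a tidy DataFrame
    (:meth:`from_dataframe`), or from a raw image dataset
    (:meth:`from_dataset`, which runs the binarization/grid-count feature
    extraction).
    """

    features: np.ndarray
    labels: np.ndarray
    classifier: str = "nn"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    config: BinarizationConfig | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    normalize: bool = True

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2:
            raise ValueError(f"expected a 2-D feature matrix, got shape {self.features.shape}")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError(f"{self.features.shape[0]} feature rows but {len(self.labels)} labels")
        if self.classifier not in MODEL_NAMES:
            raise ValueError(f"unknown classifier {self.classifier!r}; expected one of {MODEL_NAMES}")

    @classmethod
    def from_dataset(
        cls,
        dataset: SyntheticDataset,
        channel: str = "red",
        threshold: int = 170,
        grid: GridSpec | None = None,
        normalize: bool = True,
        classifier: str = "nn",
        seed: int = 0,
        **hyperparameters,
    ) -> "ApathyClassificationModel":
        grid = grid or GridSpec()
        config = BinarizationConfig(channel, threshold)
        X = feature_matrix(dataset.images, config, grid, normalize)
        return cls(X, np.asarray(dataset.labels, dtype=object), classifier, hyperparameters, seed, config, grid, normalize)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_columns: list[str] | None = None,
        label_column: str = "label",
        **kwargs,
    ) -> "ApathyClassificationModel":
        if feature_columns is None:
            skip = {label_column, "filename", "channel", "threshold", "score"}
            feature_columns = [c for c in df.columns if c not in skip]
        return cls(df[feature_columns].to_numpy(dtype=np.float64), df[label_column].to_numpy(dtype=object), **kwargs)

    def fit(self, split: SplitSpec | None = None) -> "ApathyClassificationResults":
        """Train on the stratified split; evaluate on its held-out test set."""
        split = split or SplitSpec()
        train_idx, test_idx = stratified_split(self.labels, split)
        model = make_model(self.classifier, seed=self.seed, **self.hyperparameters)
        model.fit(self.features[train_idx], self.labels[train_idx])
        predictions = model.predict(self.features[test_idx])
        metrics = compute_metrics(predictions, self.labels[test_idx])
        return ApathyClassificationResults(self, model, split, train_idx, test_idx, predictions, metrics)


@dataclass
class ApathyClassificationResults:
    """Fitted classifier plus held-out predictions and per-class rates."""

    model: ApathyClassificationModel
    classifier_: object
    split: SplitSpec
    train_indices: np.ndarray
    test_indices: np.ndarray
    predictions: np.ndarray
    metrics: ClassMetrics

    @property
    def total_accuracy(self) -> float:
        return self.metrics.total_accuracy

    def predict(self, features_or_image: np.ndarray) -> np.ndarray:
        """Classify new feature vectors, or a raw RGB image when the model
        was built from a dataset (the stored feature config is reapplied)."""
        arr = np.asarray(features_or_image)
        if arr.ndim == 3 and self.model.config is not None:
            arr = extract_features(arr, self.model.config, self.model.grid, self.model.normalize)
        return self.classifier_.predict(np.atleast_2d(np.asarray(arr, dtype=np.float64)))

    def summary(self) -> str:
        """Plain-text summary table of the configuration and test rates."""
        m = self.metrics
        cfg = self.model.config
        lines = [
            "Apathy classification results",
            "=" * 46,
            f"{'classifier':<22}{self.model.classifier}",
            f"{'channel':<22}{cfg.channel if cfg else 'n/a (precomputed features)'}",
            f"{'threshold':<22}{cfg.threshold if cfg else 'n/a'}",
            f"{'grid':<22}{self.model.grid} ({self.model.grid.n_features} features: "
            f"{', '.join(feature_names(self.model.grid))})",
            f"{'seed':<22}{self.model.seed}",
            f"{'train / test':<22}{len(self.train_indices)} / {len(self.test_indices)}",
            "-" * 46,
            f"{'Apathy-C':<22}{m.apathy_c:.4f}",
            f"{'Apathy-M':<22}{m.apathy_m:.4f}",
            f"{'Non-Apathy-C':<22}{m.nonapathy_c:.4f}",
            f"{'Non-Apathy-M':<22}{m.nonapathy_m:.4f}",
            f"{'total accuracy':<22}{m.total_accuracy:.4f}",
            "=" * 46,
        ]
        return "\n".join(lines)
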