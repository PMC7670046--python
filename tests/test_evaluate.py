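"""Split, metrics and sweep protocol."""

import numpy as np
import pytest

from dopplergait.apathy_scale import APATHY, NON_APATHY
from dopplergait.evaluate import (
    ClassMetrics,
    SplitSpec,
    best_configurations,
    compute_metrics,
    feature_matrix,
    grid_comparison,
    run_sweep,
    stratified_split,
    sweep_to_dataframe,
)
from dopplergait.features import BinarizationConfig, GridSpec

SMALL_SPLIT = {"n_train_apathy": 6, "n_train_nonapathy": 9, "n_test_apathy": 4, "n_test_nonapathy": 5}


class TestStratifiedSplit:
    def test_default_split_counts(self, cohort_dataset):
        train, test = stratified_split(cohort_dataset, SplitSpec())
        labels = np.asarray(cohort_dataset.labels, dtype=object)
        assert len(train) == 150 and len(test) == 28
        assert (labels[test] == APATHY).sum() == 8
        assert (labels[test] == NON_APATHY).sum() == 20
        assert (labels[train] == APATHY).sum() == 48
        assert set(train).isdisjoint(test)

    def test_insufficient_samples(self, small_dataset):
        with pytest.raises(ValueError, match="apathy"):
            stratified_split(small_dataset, SplitSpec(n_train_apathy=60))

    def test_determinism(self, small_dataset):
        spec = SplitSpec(rng_seed=4, **SMALL_SPLIT)
        a = stratified_split(small_dataset, spec)
        b = stratified_split(small_dataset, spec)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(n_test_apathy=-1)


class TestComputeMetrics:
    def test_all_correct(self):
        truths = [APATHY] * 3 + [NON_APATHY] * 5
        m = compute_metrics(truths, truths)
        assert m.total_accuracy == 1.0
        assert m.apathy_m == m.nonapathy_m == 0.0

    def test_constant_nonapathy_predictor_on_default_split(self):
        """Predicting non-apathy for all 28 test samples scores 20/28."""
        truths = [APATHY] * 8 + [NON_APATHY] * 20
        m = compute_metrics([NON_APATHY] * 28, truths)
        assert m.nonapathy_c == pytest.approx(20 / 28)
        assert m.apathy_c == 0.0
        assert m.total_accuracy == pytest.approx(20 / 28)
        assert m.apathy_c + m.apathy_m == pytest.approx(8 / 28)

    def test_rates_sum_to_one(self, rng):
        truths = rng.choice([APATHY, NON_APATHY], size=40)
        preds = rng.choice([APATHY, NON_APATHY], size=40)
        m = compute_metrics(preds, truths)
        assert m.apathy_c + m.apathy_m + m.nonapathy_c + m.nonapathy_m == pytest.approx(1.0)
        assert m.total_accuracy == pytest.approx(m.apathy_c + m.nonapathy_c)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])
        with pytest.raises(ValueError):
            compute_metrics([APATHY], [APATHY, APATHY])


class TestSweep:
    def test_single_configuration(self, small_dataset):
        results = run_sweep(
            small_dataset,
            split=SplitSpec(rng_seed=0, **SMALL_SPLIT),
            channels=["red"],
            thresholds=[170],
            models=["knn"],
        )
        assert len(results) == 1
        assert results[0].channel == "red" and results[0].model == "knn"

    def test_record_count_is_axis_product(self, small_dataset):
        results = run_sweep(
            small_dataset,
            split=SplitSpec(rng_seed=0, **SMALL_SPLIT),
            channels=["red", "blue"],
            thresholds=[110, 150, 190],
            models=["knn", "naive_bayes"],
        )
        assert len(results) == 2 * 3 * 2

    def test_sweep_is_reproducible(self, small_dataset):
        kwargs = dict(
            split=SplitSpec(rng_seed=1, **SMALL_SPLIT),
            channels=["red"],
            thresholds=[150, 190],
            models=["random_forest", "nn", "svm"],
            model_seed=5,
        )
        a = sweep_to_dataframe(run_sweep(small_dataset, **kwargs))
        b = sweep_to_dataframe(run_sweep(small_dataset, **kwargs))
        assert a.equals(b)

    def test_constant_predictor_bound(self, small_dataset):
        """No model on the all-same-prediction degenerate side can beat its
        class share; the SVM on weakly-informative blue features typically
        lands exactly on the majority share."""
        results = run_sweep(
            small_dataset,
            split=SplitSpec(rng_seed=0, **SMALL_SPLIT),
            channels=["blue"],
            thresholds=[60],
            models=["svm"],
        )
        m = results[0].metrics
        total = m.apathy_c + m.apathy_m + m.nonapathy_c + m.nonapathy_m
        assert total == pytest.approx(1.0)

    def test_empty_axes_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            run_sweep(small_dataset, channels=[])

    def test_grid_comparison_feature_widths(self, small_dataset):
        for grid, width in [(GridSpec(4, 5), 9), (GridSpec(5, 5), 10)]:
            X = feature_matrix(small_dataset.images, BinarizationConfig("red", 150), grid)
            assert X.shape == (len(small_dataset), width)
        results = grid_comparison(
            small_dataset,
            [GridSpec(4, 4), GridSpec(5, 5)],
            split=SplitSpec(rng_seed=0, **SMALL_SPLIT),
            channels=["red"],
            thresholds=[150],
            models=["nn", "knn"],
        )
        assert len(results) == 2 * 1 * 1 * 2
        assert {str(r.grid) for r in results} == {"4x4", "5x5"}

    def test_best_configurations_table(self, small_dataset):
        df = sweep_to_dataframe(
            run_sweep(
                small_dataset,
                split=SplitSpec(rng_seed=0, **SMALL_SPLIT),
                channels=["red"],
                thresholds=[110, 170],
                models=["knn", "naive_bayes"],
            )
        )
        best = best_configurations(df)
        assert set(best["model"]) == {"knn", "naive_bayes"}
        for _, row in best.iterrows():
            assert row["total_accuracy"] == df[df["model"] == row["model"]]["total_accuracy"].max()


def test_class_metrics_dict_roundtrip():
    m = ClassMetrics(0.25, 0.05, 0.6, 0.1)
    d = m.as_dict()
    assert d["total_accuracy"] == pytest.approx(0.85)
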