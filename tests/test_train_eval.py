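"""Splitting, PCA diagnostic, metrics/banding, CNN training, benchmark."""

import math

import numpy as np
import pytest

from nirquant import (
    SpectraSet,
    TrainConfig,
    ValidationError,
    benchmark,
    build_cnn,
    evaluate,
    lightweight_spec,
    pca_split_diagnostic,
    rpd_band,
    train_cnn,
    train_test_split,
)
from nirquant.train_eval import TrainingDivergence
from nirquant.synthetic import make_fixture


class TestTrainTestSplit:
    def test_617_samples_at_20_percent(self):
        split = train_test_split(617, 0.2, seed=0)
        assert split.n_test == 124
        assert split.n_train == 493

    def test_small_n_ceiling(self):
        for seed in range(5):
            assert train_test_split(10, 0.2, seed=seed).n_test == 2

    def test_partition_is_exact(self):
        split = train_test_split(101, 0.33, seed=5)
        combined = np.concatenate([split.train_indices, split.test_indices])
        assert np.array_equal(np.sort(combined), np.arange(101))
        assert split.n_test == math.ceil(0.33 * 101)

    def test_deterministic_given_seed(self):
        a = train_test_split(50, 0.2, seed=9)
        b = train_test_split(50, 0.2, seed=9)
        assert np.array_equal(a.test_indices, b.test_indices)
        assert not np.array_equal(
            a.test_indices, train_test_split(50, 0.2, seed=10).test_indices
        )

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_domain(self, fraction):
        with pytest.raises(ValueError, match="test_fraction"):
            train_test_split(100, fraction, seed=0)

    def test_minimum_sample_count(self):
        with pytest.raises(ValueError, match="at least 5"):
            train_test_split(4, 0.2, seed=0)


class TestPcaDiagnostic:
    def test_rank_one_data_has_one_component(self, rng):
        direction = rng.standard_normal(30)
        scores1d = rng.standard_normal(12)
        A = 1.0 + np.outer(scores1d, direction)
        s = SpectraSet(A, np.arange(30.0))
        scores, explained = pca_split_diagnostic(s, train_test_split(12, 0.25, 0))
        assert explained[1] == pytest.approx(0.0, abs=1e-18)
        assert explained[0] > 0

    def test_matches_covariance_eigendecomposition(self, rng):
        A = rng.standard_normal((15, 8))
        s = SpectraSet(A, np.arange(8.0))
        scores, explained = pca_split_diagnostic(s, train_test_split(15, 0.2, 0))
        X = A - A.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X / 14)
        np.testing.assert_allclose(explained, evals[::-1][:2], atol=1e-10)
        for j in range(2):
            expected = X @ evecs[:, -1 - j]
            got = scores[:, j]
            sign = np.sign(expected @ got)
            np.testing.assert_allclose(got, sign * expected, atol=1e-8)

    def test_scores_are_centered(self, rng):
        A = rng.standard_normal((20, 10))
        s = SpectraSet(A, np.arange(10.0))
        scores, _ = pca_split_diagnostic(s, train_test_split(20, 0.2, 0))
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-12)

    def test_constant_matrix_rejected(self):
        s = SpectraSet(np.full((5, 6), 2.0), np.arange(6.0))
        with pytest.raises(ValidationError, match="constant"):
            pca_split_diagnostic(s, train_test_split(5, 0.2, 0))


class TestEvaluate:
    def test_perfect_prediction(self):
        rep = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.rmse == 0.0
        assert rep.r2 == 1.0
        assert math.isinf(rep.rpd)
        assert rep.rpd_band == "excellent"

    def test_mean_predictor_is_the_null_model(self):
        rep = evaluate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert rep.r2 == pytest.approx(0.0)
        assert rep.rpd == pytest.approx(1.0)
        assert rep.rpd_band == "poor"

    def test_hand_worked_example(self):
        rep = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert rep.rmse == pytest.approx(math.sqrt(1 / 3), abs=1e-12)
        assert rep.r2 == pytest.approx(0.5, abs=1e-12)
        assert rep.rpd == pytest.approx(math.sqrt(2), abs=1e-12)
        assert rep.rpd_band == "fair"

    def test_matches_closed_form_on_random_pairs(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 30))
            y = rng.standard_normal(n)
            while np.allclose(y, y[0]):
                y = rng.standard_normal(n)
            yhat = rng.standard_normal(n)
            rep = evaluate(y, yhat)
            sse = float(np.sum((yhat - y) ** 2))
            sst = float(np.sum((y - y.mean()) ** 2))
            assert rep.rmse == pytest.approx(math.sqrt(sse / n), abs=1e-10)
            assert rep.r2 == pytest.approx(1 - sse / sst, abs=1e-10)
            assert rep.rpd == pytest.approx(math.sqrt(sst / sse), abs=1e-10)

    def test_rpd_r2_internal_consistency(self, rng):
        y = rng.standard_normal(50)
        yhat = y + 0.3 * rng.standard_normal(50)
        rep = evaluate(y, yhat)
        assert rep.rpd == pytest.approx(1.0 / math.sqrt(1.0 - rep.r2), abs=1e-9)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            evaluate([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            evaluate([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRpdBanding:
    @pytest.mark.parametrize(
        "rpd,band",
        [
            (0.5, "very_poor"),
            (1.0, "poor"),
            (1.2, "poor"),
            (1.4, "fair"),
            (1.8, "good"),
            (1.99, "good"),
            (2.0, "very_good"),
            (2.5, "very_good"),
            (2.5000001, "excellent"),
            (math.inf, "excellent"),
        ],
    )
    def test_cutpoints_and_boundaries(self, rpd, band):
        assert rpd_band(rpd) == band

    def test_monotone_step_function(self):
        order = ["very_poor", "poor", "fair", "good", "very_good", "excellent"]
        grid = np.linspace(0.0, 4.0, 401)
        ranks = [order.index(rpd_band(float(v))) for v in grid]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))


def _toy_problem(rng, n=40, p=16):
    """Noiseless linear data a small CNN can drive the loss down on."""
    X = rng.standard_normal((n, p)).astype(np.float32)
    w = rng.standard_normal(p) / np.sqrt(p)
    y = X @ w
    return X, y.astype(np.float64)


TOY_SPEC = lightweight_spec(input_length=16)


class TestTrainCnn:
    def test_single_epoch_is_deterministic(self, rng):
        X, y = _toy_problem(rng)
        cfg = TrainConfig(epochs=1, batch_size=8, seed=3)
        _, t1 = train_cnn(build_cnn(TOY_SPEC, 5), X, y, cfg)
        _, t2 = train_cnn(build_cnn(TOY_SPEC, 5), X, y, cfg)
        assert t1.train == t2.train
        assert t1.validation == t2.validation

    def test_loss_decreases_over_training(self, rng):
        X, y = _toy_problem(rng)
        cfg = TrainConfig(epochs=50, batch_size=8, validation_fraction=0.0, seed=0)
        _, trace = train_cnn(build_cnn(TOY_SPEC, 1), X, y, cfg)
        assert trace.train[-1] < trace.train[0]
        assert np.mean(trace.train[-5:]) < np.mean(trace.train[:5])

    def test_zero_validation_fraction_has_no_validation_trace(self, rng):
        X, y = _toy_problem(rng)
        cfg = TrainConfig(epochs=2, batch_size=8, validation_fraction=0.0, seed=0)
        _, trace = train_cnn(build_cnn(TOY_SPEC, 1), X, y, cfg)
        assert trace.validation is None
        assert len(trace.train) == 2

    def test_validation_trace_present_and_finite(self, rng):
        X, y = _toy_problem(rng)
        cfg = TrainConfig(epochs=3, batch_size=8, validation_fraction=0.2, seed=0)
        _, trace = train_cnn(build_cnn(TOY_SPEC, 1), X, y, cfg)
        assert len(trace.validation) == 3
        assert all(math.isfinite(v) for v in trace.validation)

    def test_batch_size_exceeding_rows_rejected(self, rng):
        X, y = _toy_problem(rng, n=10)
        cfg = TrainConfig(epochs=1, batch_size=10, validation_fraction=0.2, seed=0)
        with pytest.raises(ValueError, match="batch_size"):
            train_cnn(build_cnn(TOY_SPEC, 1), X, y, cfg)

    def test_divergence_raises_with_epoch_index(self, rng):
        X, y = _toy_problem(rng)
        y = y + 1e200  # squared error overflows -> non-finite loss
        cfg = TrainConfig(epochs=2, batch_size=8, validation_fraction=0.0, seed=0)
        with pytest.raises(TrainingDivergence, match="epoch 0"):
            train_cnn(build_cnn(TOY_SPEC, 1), X, y, cfg)


class TestBenchmark:
    @pytest.fixture()
    def tiny_data(self):
        return make_fixture("tiny", seed=2)

    def test_grid_shape_and_finite_metrics(self, tiny_data):
        s, y = tiny_data
        split = train_test_split(s.n_samples, 0.25, seed=1)
        cfg = TrainConfig(epochs=1, batch_size=4, seed=1)
        table = benchmark(s, y, ["raw", "sg"], ["plsr"], cfg, split)
        assert len(table) == 4  # 2 methods x 1 model x {train, test}
        assert (table["error"] == "").all()
        for col in ("rmse", "r2", "rpd"):
            assert np.isfinite(table[col]).all()

    def test_duplicate_entries_deduplicated_with_warning(self, tiny_data):
        s, y = tiny_data
        split = train_test_split(s.n_samples, 0.25, seed=1)
        cfg = TrainConfig(epochs=1, batch_size=4, seed=1)
        with pytest.warns(UserWarning, match="duplicate"):
            table = benchmark(s, y, ["raw", "raw"], ["plsr"], cfg, split)
        assert len(table) == 2

    def test_cell_failure_recorded_not_fatal(self, tiny_data):
        s, y = tiny_data
        split = train_test_split(s.n_samples, 0.25, seed=1)
        cfg = TrainConfig(epochs=1, batch_size=4, seed=1)
        table = benchmark(s, y, ["raw"], ["plsr", "no-such-model"], cfg, split)
        good = table[(table["model"] == "plsr") & (table["error"] == "")]
        bad = table[table["model"] == "no-such-model"]
        assert len(good) == 2
        assert len(bad) == 1 and "ValueError" in bad.iloc[0]["error"]

    def test_cnn_cell_runs_end_to_end(self, tiny_data):
        s, y = tiny_data
        split = train_test_split(s.n_samples, 0.25, seed=1)
        cfg = TrainConfig(epochs=2, batch_size=4, seed=1)
        table = benchmark(s, y, ["sg"], ["lightweight"], cfg, split)
        assert (table["error"] == "").all()
        assert set(table["split"]) == {"train", "test"}
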