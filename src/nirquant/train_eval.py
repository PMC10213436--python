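"""Data splitting, model training, evaluation metrics and benchmarking.

Metric conventions (the chemometric calibration standard):

* ``RMSE = sqrt( sum_i (yhat_i - y_i)^2 / n )``
* ``R^2  = 1 - SSE / SST``
* ``RPD  = SD / RMSE`` with ``SD = sqrt(SST / n)``

With the population-style SD, these tie together as
``RPD = 1 / sqrt(1 - R^2)`` — an internal consistency the tests check.
RPD is banded into the usual model-quality categories: below 1.0 very
poor, 1.0-1.4 poor, 1.4-1.8 fair, 1.8-2.0 good, 2.0-2.5 very good, and
above 2.5 excellent. Intervals are half-open ``[a, b)`` except that a
value of exactly 2.5 is still "very good" (only values strictly greater
are excellent).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as models_mod
from . import nn
from .preprocess import PreprocessConfig, apply_method, msc, savitzky_golay, snv
from .spectra import ReferenceValues, SpectraSet, ValidationError


class TrainingDivergence(RuntimeError):
    """Loss became non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer hyperparameters for CNN training.

    Defaults follow the reference protocol: Adam, learning rate 1e-4,
    batch size 16, weight decay 1e-8, 1,000 epochs, a validation split of
    0.1 taken out of the training rows, and no early stopping. ``epochs``
    is exposed so desk-scale runs can train shorter.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 16
    weight_decay: float = 1e-8
    epochs: int = 1000
    validation_fraction: float = 0.1
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss != "mse":
            raise ValueError("only the mse loss is supported")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0 and weight_decay >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SplitResult:
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    test_fraction: float = 0.2

    @property
    def n_train(self) -> int:
        return self.train_indices.size

    @property
    def n_test(self) -> int:
        return self.test_indices.size


def train_test_split(n: int, test_fraction: float = 0.2, seed: int = 0) -> SplitResult:
    """Uniform random split; the test set holds ``ceil(test_fraction * n)``
    samples (620 samples at 20% -> 124 test / 496 train)."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_test = math.ceil(test_fraction * n)
    perm = np.random.default_rng(seed).permutation(n)
    return SplitResult(
        train_indices=np.sort(perm[n_test:]),
        test_indices=np.sort(perm[:n_test]),
        seed=seed,
        test_fraction=test_fraction,
    )


def pca_split_diagnostic(
    s: SpectraSet, split: SplitResult
) -> tuple[np.ndarray, np.ndarray]:
    """Project all spectra onto the top-2 principal components so the
    train/test distributions can be compared visually.

    Returns (scores, explained_variance): the n x 2 score matrix (ordered
    as the input samples; use ``split`` to partition it for plotting) and
    the variances explained by the two components. Component signs are
    fixed so the largest-magnitude loading is positive.
    """
    if s.n_samples < 3:
        raise ValidationError("need at least 3 samples for the PCA diagnostic")
    X = s.absorbance - s.absorbance.mean(axis=0)
    if not np.any(X):
        raise ValidationError("constant spectra matrix has no principal components")
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(min(2, Vt.shape[0])):
        pivot = np.argmax(np.abs(Vt[j]))
        if Vt[j, pivot] < 0:
            Vt[j] = -Vt[j]
            U[:, j] = -U[:, j]
    k = min(2, sv.size)
    scores = np.zeros((s.n_samples, 2))
    scores[:, :k] = U[:, :k] * sv[:k]
    explained = np.zeros(2)
    explained[:k] = sv[:k] ** 2 / max(s.n_samples - 1, 1)
    return scores, explained


RPD_BANDS: tuple[tuple[float, str], ...] = (
    (1.0, "very_poor"),
    (1.4, "poor"),
    (1.8, "fair"),
    (2.0, "good"),
    (2.5, "very_good"),
)


def rpd_band(rpd: float) -> str:
    """Model-quality category for an RPD value (monotone step function)."""
    if math.isnan(rpd) or rpd < 0:
        raise ValueError("RPD must be a nonnegative number")
    for upper, name in RPD_BANDS:
        if rpd < upper:
            return name
    return "very_good" if rpd == 2.5 else "excellent"


@dataclass(frozen=True)
class EvaluationReport:
    rmse: float
    r2: float
    rpd: float
    rpd_band: str
    n: int

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "r2": self.r2,
            "rpd": self.rpd,
            "band": self.rpd_band,
            "n": self.n,
        }


def evaluate(y_true: np.ndarray, y_pred: np.ndarray) -> EvaluationReport:
    """RMSE, R-squared, RPD and its quality band for a prediction set."""
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred lengths differ")
    n = y_true.size
    if n < 2:
        raise ValueError("need at least 2 samples to evaluate")
    sse = float(np.sum((y_pred - y_true) ** 2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0.0:
        raise ValidationError("constant y_true: R^2 and RPD are undefined")
    rmse = math.sqrt(sse / n)
    r2 = 1.0 - sse / sst
    rpd = math.inf if rmse == 0.0 else math.sqrt(sst / n) / rmse
    return EvaluationReport(rmse, r2, rpd, rpd_band(rpd), n)


@dataclass
class LossTrace:
    """Per-epoch mean-squared-error traces from CNN training."""

    train: list[float] = field(default_factory=list)
    validation: list[float] | None = None


def train_cnn(
    model: models_mod.CNNRegressor,
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: TrainConfig,
) -> tuple[models_mod.CNNRegressor, LossTrace]:
    """Mini-batch Adam training of a CNN regressor.

    A validation split of ``cfg.validation_fraction`` is carved from the
    training rows (seeded); batches are reshuffled every epoch (seeded);
    the trace records per-epoch training MSE (running average over
    batches) and inference-mode validation MSE. Trains the full epoch
    budget — no early stopping.
    """
    X = np.ascontiguousarray(X_train, dtype=nn.DTYPE)
    y = np.asarray(y_train, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X_train rows must match y_train length")
    n = y.size
    ss = np.random.SeedSequence(cfg.seed)
    rng_split, rng_shuffle = (np.random.default_rng(s) for s in ss.spawn(2))

    if cfg.validation_fraction > 0.0:
        n_val = math.ceil(cfg.validation_fraction * n)
        perm = rng_split.permutation(n)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx = np.empty(0, dtype=int)
        fit_idx = np.arange(n)
    if cfg.batch_size > fit_idx.size:
        raise ValueError(
            f"batch_size {cfg.batch_size} exceeds the {fit_idx.size} rows "
            "available after the validation split"
        )
    X_fit, y_fit = X[fit_idx], y[fit_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    opt = nn.Adam(
        model.net.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    trace = LossTrace(validation=[] if val_idx.size else None)
    n_fit = fit_idx.size
    for epoch in range(cfg.epochs):
        order = rng_shuffle.permutation(n_fit)
        running = 0.0
        for start in range(0, n_fit, cfg.batch_size):
            rows = order[start : start + cfg.batch_size]
            pred = model.forward(X_fit[rows], training=True)
            loss, grad = nn.mse_loss(pred, y_fit[rows, None])
            if not math.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite training loss at epoch {epoch}"
                )
            model.net.backward(grad)
            opt.step()
            running += loss * rows.size
        trace.train.append(running / n_fit)
        if trace.validation is not None:
            val_pred = model.predict(X_val)
            trace.validation.append(float(np.mean((val_pred - y_val) ** 2)))
    return model, trace


# ---------------------------------------------------------------------------
# benchmark harness: preprocessing x model grid
# ---------------------------------------------------------------------------

PREPROCESS_NAMES = ("raw", "sg", "snv", "msc")
MODEL_NAMES = ("lightweight", "dropout-cnn", "plsr", "svr")


def _dedupe(seq, what: str) -> list:
    out: list = []
    for item in seq:
        if item in out:
            warnings.warn(f"duplicate {what} {item!r} ignored", UserWarning, stacklevel=3)
        else:
            out.append(item)
    return out


def _preprocess_pair(
    method: str | PreprocessConfig, train: SpectraSet, test: SpectraSet
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one preprocessing method, fitting any statistics (the MSC
    reference) on training rows only."""
    cfg = (
        method
        if isinstance(method, PreprocessConfig)
        else PreprocessConfig(method=method)
    )
    if cfg.method == "msc":
        train_out, ref = msc(train, cfg.msc_reference)
        test_out, _ = msc(test, ref)
        return train_out.absorbance, test_out.absorbance
    train_out, _ = apply_method(train, cfg)
    test_out, _ = apply_method(test, cfg)
    return train_out.absorbance, test_out.absorbance


def _fit_predict(
    model_name: str,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    cfg: TrainConfig,
) -> tuple[np.ndarray, np.ndarray]:
    if model_name in ("lightweight", "dropout-cnn"):
        spec = (
            models_mod.lightweight_spec(input_length=X_tr.shape[1])
            if model_name == "lightweight"
            else models_mod.dropout_cnn_spec(input_length=X_tr.shape[1])
        )
        model = models_mod.build_cnn(spec, seed=cfg.seed)
        model, _ = train_cnn(model, X_tr, y_tr, cfg)
        return model.predict(X_tr), model.predict(X_te)
    if model_name == "plsr":
        cap = min(20, X_tr.shape[1], len(y_tr) - math.ceil(len(y_tr) / 5))
        fitted = models_mod.fit_plsr(X_tr, y_tr, max_components=cap, folds=5, seed=cfg.seed)
        return fitted.predict(X_tr), fitted.predict(X_te)
    if model_name == "svr":
        fitted = models_mod.fit_svr(X_tr, y_tr, folds=5, seed=cfg.seed)
        return fitted.predict(X_tr), fitted.predict(X_te)
    raise ValueError(f"unknown model {model_name!r}; expected one of {MODEL_NAMES}")


def benchmark(
    s: SpectraSet,
    y: ReferenceValues,
    methods,
    model_names,
    cfg: TrainConfig,
    split: SplitResult,
) -> pd.DataFrame:
    """Evaluate every preprocessing x model combination on one split.

    Preprocessing statistics are fitted on the training rows only. Each
    grid cell contributes two rows (train/test) with RMSE, R^2, RPD and
    the RPD band; a failing cell is recorded in-table under ``error`` and
    does not abort its siblings.
    """
    if len(y) != s.n_samples:
        raise ValueError("reference values must align with the spectra")
    methods = _dedupe(list(methods), "preprocessing method")
    model_names = _dedupe(list(model_names), "model")
    train_s, test_s = s.subset(split.train_indices), s.subset(split.test_indices)
    y_tr = y.values[split.train_indices]
    y_te = y.values[split.test_indices]
    rows = []
    for method in methods:
        method_label = method.method if isinstance(method, PreprocessConfig) else method
        try:
            X_tr, X_te = _preprocess_pair(method, train_s, test_s)
        except Exception as exc:  # degenerate preprocessing is per-cell data
            for name in model_names:
                rows.append(
                    {"method": method_label, "model": name, "split": "train",
                     "error": f"{type(exc).__name__}: {exc}"}
                )
            continue
        for name in model_names:
            try:
                pred_tr, pred_te = _fit_predict(name, X_tr, y_tr, X_te, cfg)
                for split_name, truth, pred in (
                    ("train", y_tr, pred_tr),
                    ("test", y_te, pred_te),
                ):
                    rep = evaluate(truth, pred)
                    rows.append(
                        {"method": method_label, "model": name, "split": split_name,
                         "rmse": rep.rmse, "r2": rep.r2, "rpd": rep.rpd,
                         "band": rep.rpd_band, "error": ""}
                    )
            except Exception as exc:
                rows.append(
                    {"method": method_label, "model": name, "split": "train",
                     "error": f"{type(exc).__name__}: {exc}"}
                )
    return pd.DataFrame(rows)
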