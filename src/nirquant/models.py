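"""Model construction: the lightweight 1D-CNN for spectral regression, a
dropout-regularized comparator, and PLSR/SVR chemometric baselines.

The lightweight CNN stacks four strided valid convolutions (32/64/128/256
channels, kernel 2, stride 2), each followed by batch normalization and
ReLU, then a flatten, a 500-unit ReLU dense layer and a linear scalar
output. ``summarize`` computes the layer-size chain and trainable-parameter
count analytically; ``build_cnn`` constructs the network and the two must
agree exactly (tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import nn


class SpecError(ValueError):
    """Invalid architecture specification."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer-by-layer description of the spectral regression CNN.

    ``norm="batchnorm"`` with ``dropout_rate=0`` is the lightweight
    variant; ``norm="none"`` with ``dropout_rate=0.5`` is the classical
    dropout-regularized comparator.
    """

    input_length: int = 1557
    conv_channels: tuple[int, ...] = (32, 64, 128, 256)
    kernel_size: int = 2
    stride: int = 2
    padding: int = 0
    norm: str = "batchnorm"  # "batchnorm" | "none"
    dropout_rate: float = 0.0
    fc_width: int = 500
    output_dim: int = 1

    def __post_init__(self) -> None:
        if self.norm not in ("batchnorm", "none"):
            raise SpecError(f"unknown norm {self.norm!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise SpecError("dropout_rate must be in [0, 1)")
        if self.output_dim != 1:
            raise SpecError("scalar regression requires output_dim == 1")
        if not self.conv_channels:
            raise SpecError("at least one convolution stage required")
        if self.kernel_size < 1 or self.stride < 1 or self.padding < 0:
            raise SpecError("kernel/stride must be >= 1 and padding >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_channels"] = list(self.conv_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        if "conv_channels" in d:
            d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)


def lightweight_spec(input_length: int = 1557) -> ArchitectureSpec:
    """The batch-normalized lightweight architecture (defaults)."""
    return ArchitectureSpec(input_length=input_length)


def dropout_cnn_spec(input_length: int = 1557) -> ArchitectureSpec:
    """The dropout-regularized comparator: same conv stack, no batch norm,
    dropout 0.5 after the dense ReLU."""
    return ArchitectureSpec(input_length=input_length, norm="none", dropout_rate=0.5)


@dataclass(frozen=True)
class ModelSummary:
    layer_shapes: tuple[tuple[str, int, int], ...]  # (name, channels, length)
    flatten_size: int
    parameter_count: int


def conv_output_length(length_in: int, kernel: int, stride: int, padding: int) -> int:
    """Output length of a strided convolution: floor((L + 2p - k)/s) + 1."""
    if kernel < 1 or stride < 1 or padding < 0 or length_in < 1:
        raise ValueError("lengths/kernel/stride must be >= 1 and padding >= 0")
    eff = length_in + 2 * padding
    if eff < kernel:
        raise ValueError(
            f"input length {length_in} with padding {padding} is shorter than "
            f"kernel {kernel}"
        )
    return (eff - kernel) // stride + 1


def summarize(spec: ArchitectureSpec) -> ModelSummary:
    """Chain the conv length rule through all stages and count trainable
    parameters (conv weights+biases, batch-norm scale+shift pairs, dense and
    output weights+biases; batch-norm running statistics are not trainable
    and are not counted)."""
    shapes: list[tuple[str, int, int]] = [("input", 1, spec.input_length)]
    length = spec.input_length
    c_prev = 1
    count = 0
    for i, c_out in enumerate(spec.conv_channels, start=1):
        try:
            length = conv_output_length(length, spec.kernel_size, spec.stride, spec.padding)
        except ValueError as exc:
            raise SpecError(f"length chain collapses at conv stage {i}: {exc}") from exc
        count += c_out * c_prev * spec.kernel_size + c_out  # weights + bias
        if spec.norm == "batchnorm":
            count += 2 * c_out  # gamma + beta
        shapes.append((f"conv{i}", c_out, length))
        c_prev = c_out
    flatten_size = c_prev * length
    shapes.append(("flatten", 1, flatten_size))
    count += flatten_size * spec.fc_width + spec.fc_width
    shapes.append(("fc", 1, spec.fc_width))
    count += spec.fc_width * spec.output_dim + spec.output_dim
    shapes.append(("output", 1, spec.output_dim))
    return ModelSummary(tuple(shapes), flatten_size, count)


class CNNRegressor:
    """Handle around a built network: prediction, parameter access,
    (de)serialization. Training lives in :mod:`nirquant.train_eval`."""

    def __init__(self, spec: ArchitectureSpec, seed: int) -> None:
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence(self.seed))
        layers: list[nn.Layer] = []
        c_prev = 1
        for i, c_out in enumerate(spec.conv_channels):
            layers.append(
                nn.Conv1d(
                    c_prev,
                    c_out,
                    spec.kernel_size,
                    spec.stride,
                    spec.padding,
                    rng,
                    input_grad=(i > 0),
                )
            )
            if spec.norm == "batchnorm":
                layers.append(nn.BatchNorm1d(c_out, relu=True))
            else:
                layers.append(nn.ReLU())
            c_prev = c_out
        layers.append(nn.Flatten())
        summary = summarize(spec)
        layers.append(nn.Linear(summary.flatten_size, spec.fc_width, rng))
        layers.append(nn.ReLU())
        if spec.dropout_rate > 0.0:
            layers.append(nn.Dropout(spec.dropout_rate, rng))
        layers.append(nn.Linear(spec.fc_width, spec.output_dim, rng))
        self.net = nn.Network(layers)
        self.summary = summary

    def n_parameters(self) -> int:
        """Enumerated trainable parameters of the built network."""
        return self.net.n_parameters()

    def _as_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=nn.DTYPE)
        if X.ndim != 2 or X.shape[1] != self.spec.input_length:
            raise ValueError(
                f"expected (n, {self.spec.input_length}) input, got {X.shape}"
            )
        return X[:, :, None]  # (B, L, 1)

    def forward(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(self._as_input(X), training=training)

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode predictions (batch norm uses running statistics,
        dropout disabled)."""
        X = np.asarray(X, dtype=nn.DTYPE)
        out = [
            self.forward(X[i : i + batch_size], training=False)
            for i in range(0, len(X), batch_size)
        ]
        return np.concatenate(out, axis=0)[:, 0].astype(np.float64)

    def save(self, path, meta: dict | None = None, arrays: dict | None = None) -> None:
        """Checkpoint to ``.npz`` with the architecture embedded; ``meta``
        (JSON-serializable) and extra ``arrays`` ride along, e.g. the
        preprocessing configuration and a fitted MSC reference."""
        import json

        state = self.net.state_dict()
        extras = {f"__array__{k}": v for k, v in (arrays or {}).items()}
        np.savez(
            path,
            __spec__=json.dumps(self.spec.to_dict()),
            __seed__=self.seed,
            __meta__=json.dumps(meta or {}),
            **extras,
            **state,
        )

    @classmethod
    def load(cls, path) -> "CNNRegressor":
        model, _, _ = load_checkpoint(path)
        return model


def build_cnn(spec: ArchitectureSpec, seed: int) -> CNNRegressor:
    """Construct the CNN with deterministic (seeded) initialization."""
    return CNNRegressor(spec, seed)


def load_checkpoint(path) -> tuple[CNNRegressor, dict, dict]:
    """Load a checkpoint; returns (model, meta, extra arrays)."""
    import json

    with np.load(path, allow_pickle=False) as data:
        spec = ArchitectureSpec.from_dict(json.loads(str(data["__spec__"])))
        model = CNNRegressor(spec, seed=int(data["__seed__"]))
        meta = json.loads(str(data["__meta__"])) if "__meta__" in data.files else {}
        arrays = {
            k[len("__array__"):]: data[k]
            for k in data.files
            if k.startswith("__array__")
        }
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model.net.load_state_dict(state)
    return model, meta, arrays


@dataclass
class PLSRModel:
    """Fitted PLSR baseline with the cross-validation record."""

    estimator: PLSRegression
    n_components: int
    cv_rmse: dict[int, float] = field(repr=False, default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X)).ravel()


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 20,
    folds: int = 5,
    seed: int = 0,
) -> PLSRModel:
    """PLSR with the component count selected by minimum K-fold CV RMSE
    over 1..max_components (ties go to the smaller count)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if not 2 <= folds < n:
        raise ValueError("need n_samples > folds >= 2")
    cap = min(n - int(np.ceil(n / folds)), X.shape[1])
    if max_components > cap:
        raise ValueError(
            f"max_components {max_components} exceeds the CV-feasible cap {cap}"
        )
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    cv_rmse: dict[int, float] = {}
    for k in range(1, max_components + 1):
        sse = 0.0
        for tr, te in splits:
            m = PLSRegression(n_components=k, scale=False).fit(X[tr], y[tr])
            resid = np.asarray(m.predict(X[te])).ravel() - y[te]
            sse += float(resid @ resid)
        cv_rmse[k] = np.sqrt(sse / n)
    best = min(cv_rmse, key=lambda k: (cv_rmse[k], k))
    est = PLSRegression(n_components=best, scale=False).fit(X, y)
    return PLSRModel(est, best, cv_rmse)


DEFAULT_SVR_GRID: dict[str, tuple[float, ...]] = {
    "C": (0.1, 1.0, 10.0, 100.0),
    "epsilon": (0.01, 0.1),
    "gamma": (0.001, 0.01, 0.1),
}


@dataclass
class SVRModel:
    """Fitted RBF-kernel SVR baseline with the selected hyperparameters."""

    estimator: SVR
    params: dict[str, float]
    cv_rmse: dict[tuple[float, float, float], float] = field(repr=False, default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X)).ravel()


def fit_svr(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict[str, tuple[float, ...]] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> SVRModel:
    """RBF-kernel SVR; (C, epsilon, gamma) chosen by K-fold CV RMSE over the
    grid, ties broken by grid order."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if grid is None:
        grid = DEFAULT_SVR_GRID
    for key in ("C", "epsilon", "gamma"):
        if not grid.get(key):
            raise ValueError(f"empty SVR grid for {key!r}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    cv_rmse: dict[tuple[float, float, float], float] = {}
    best_key: tuple[float, float, float] | None = None
    for C in grid["C"]:
        for epsilon in grid["epsilon"]:
            for gamma in grid["gamma"]:
                sse = 0.0
                for tr, te in splits:
                    m = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma)
                    m.fit(X[tr], y[tr])
                    resid = m.predict(X[te]) - y[te]
                    sse += float(resid @ resid)
                key = (C, epsilon, gamma)
                cv_rmse[key] = np.sqrt(sse / len(y))
                if best_key is None or cv_rmse[key] < cv_rmse[best_key]:
                    best_key = key
    assert best_key is not None
    C, epsilon, gamma = best_key
    est = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma).fit(X, y)
    return SVRModel(est, {"C": C, "epsilon": epsilon, "gamma": gamma}, cv_rmse)
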