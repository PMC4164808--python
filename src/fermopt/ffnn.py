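"""Single-hidden-layer feed-forward perceptron with Levenberg-Marquardt training.

The network is the 6-h-1 surrogate used to model enzyme activity as a
function of six scaled fermentation factors.  Each hidden node forms the
affine pre-activation ``z_k = Σ_j w_kj x_j + b_k`` and passes it through the
tansig transfer function

    tansig(z) = 2 / (1 + exp(-2 z)) - 1    (identically tanh(z)),

while the single output node is linear:

    y = w_o · tansig(W x + b_h) + b_o.

Training minimizes the full-batch sum of squared errors by damped
Gauss-Newton (Levenberg-Marquardt) with an analytic Jacobian.  Because
random initialization makes any single run a lottery, :func:`train_lm`
restarts from several seeded initializations and keeps the lowest-SSE fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import scaling
from .metrics import MetricsReport, compute_metrics

__all__ = [
    "tansig",
    "NetworkTopology",
    "NetworkParams",
    "TrainingConfig",
    "TrainingResult",
    "SurrogateModel",
    "init_params",
    "forward",
    "train_lm",
    "select_hidden_size",
]


def tansig(z):
    """Hyperbolic-tangent sigmoid, 2/(1+e^(-2z)) - 1 == tanh(z)."""
    return np.tanh(z)


@dataclass(frozen=True)
class NetworkTopology:
    """Layer sizes of the perceptron (inputs - hidden - one linear output)."""

    n_in: int = 6
    n_hidden: int = 10
    n_out: int = 1

    def __post_init__(self) -> None:
        if self.n_in < 1 or self.n_hidden < 1 or self.n_out != 1:
            raise ValueError("topology must be n_in >= 1, n_hidden >= 1, n_out == 1")

    @property
    def n_params(self) -> int:
        """Free parameters: hidden weights + hidden biases + output weights + output bias."""
        return self.n_hidden * (self.n_in + 2) + 1


@dataclass
class NetworkParams:
    """Weights and biases of the perceptron.

    ``hidden_weights`` is (n_hidden, n_in); ``input_bias`` (the per-hidden-node
    bias), ``output_weights`` are length n_hidden; ``output_bias`` is the bias
    on the linear output node.
    """

    hidden_weights: np.ndarray
    input_bias: np.ndarray
    output_weights: np.ndarray
    output_bias: float

    def __post_init__(self) -> None:
        self.hidden_weights = np.asarray(self.hidden_weights, dtype=float)
        self.input_bias = np.asarray(self.input_bias, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        h, n_in = self.hidden_weights.shape
        if self.input_bias.shape != (h,) or self.output_weights.shape != (h,):
            raise ValueError("inconsistent parameter shapes")
        arrays = [self.hidden_weights, self.input_bias, self.output_weights]
        if not all(np.all(np.isfinite(a)) for a in arrays) or not np.isfinite(self.output_bias):
            raise ValueError("non-finite network parameters")

    @property
    def topology(self) -> NetworkTopology:
        h, n_in = self.hidden_weights.shape
        return NetworkTopology(n_in=n_in, n_hidden=h)

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.hidden_weights.ravel(),
                self.input_bias,
                self.output_weights,
                [self.output_bias],
            ]
        )

    @classmethod
    def from_vector(cls, topology: NetworkTopology, vec: np.ndarray) -> "NetworkParams":
        h, n_in = topology.n_hidden, topology.n_in
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (topology.n_params,):
            raise ValueError("parameter vector has wrong length")
        i = h * n_in
        return cls(
            hidden_weights=vec[:i].reshape(h, n_in),
            input_bias=vec[i : i + h],
            output_weights=vec[i + h : i + 2 * h],
            output_bias=float(vec[-1]),
        )

    def to_dict(self) -> dict:
        return {
            "hidden_weights": self.hidden_weights.tolist(),
            "input_bias": self.input_bias.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(
            np.asarray(d["hidden_weights"], dtype=float),
            np.asarray(d["input_bias"], dtype=float),
            np.asarray(d["output_weights"], dtype=float),
            float(d["output_bias"]),
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Levenberg-Marquardt settings.

    Damping starts at ``lm_lambda0`` and is multiplied by ``lm_factor_up`` on
    a rejected step, divided by ``lm_factor_down`` on acceptance.  Training
    stops at ``max_epochs`` accepted iterations, when the SSE drops below
    ``sse_tolerance``, or when the gradient max-norm drops below
    ``gradient_tolerance``.
    """

    max_epochs: int = 1000
    lm_lambda0: float = 1e-3
    lm_factor_up: float = 10.0
    lm_factor_down: float = 10.0
    sse_tolerance: float = 1e-12
    gradient_tolerance: float = 1e-10
    seed: int = 0
    n_restarts: int = 10

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.lm_factor_up <= 1 or self.lm_factor_down <= 1:
            raise ValueError("LM factors must exceed 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class TrainingResult:
    params: NetworkParams
    epochs_run: int
    final_sse: float
    sse_trace: np.ndarray  # accepted SSE per epoch (non-increasing)
    init_seed: int
    train_metrics: MetricsReport | None = None
    test_metrics: MetricsReport | None = None


def init_params(topology: NetworkTopology, seed: int) -> NetworkParams:
    """Random initialization, all parameters i.i.d. uniform on [-0.5, 0.5]."""
    rng = np.random.default_rng(seed)
    vec = rng.uniform(-0.5, 0.5, size=topology.n_params)
    return NetworkParams.from_vector(topology, vec)


def forward(params: NetworkParams, x) -> np.ndarray | float:
    """Network output for one input vector or a (n, n_in) batch."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != params.hidden_weights.shape[1]:
        raise ValueError("input dimension does not match network topology")
    H = tansig(X @ params.hidden_weights.T + params.input_bias)
    y = H @ params.output_weights + params.output_bias
    return float(y[0]) if single else y


def _forward_jacobian(params: NetworkParams, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predictions and the Jacobian d y / d theta, columns in to_vector order."""
    n, n_in = X.shape
    h = params.hidden_weights.shape[0]
    Z = X @ params.hidden_weights.T + params.input_bias
    H = np.tanh(Z)
    dH = 1.0 - H**2  # tanh'
    y = H @ params.output_weights + params.output_bias
    # d y / d W_kj = w_o_k * dH_k * x_j  -> (n, h, n_in)
    J_W = (params.output_weights * dH)[:, :, None] * X[:, None, :]
    J_bh = params.output_weights * dH  # (n, h)
    J_wo = H  # (n, h)
    J_bo = np.ones((n, 1))
    J = np.concatenate([J_W.reshape(n, h * n_in), J_bh, J_wo, J_bo], axis=1)
    return y, J


def _lm_fit(
    p0: np.ndarray,
    topology: NetworkTopology,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
) -> tuple[np.ndarray, int, float, list[float]]:
    """Damped Gauss-Newton on the SSE; returns (params, epochs, sse, trace)."""
    p = p0.copy()
    lam = config.lm_lambda0
    eye = np.eye(p.shape[0])

    def residual(vec: np.ndarray) -> tuple[np.ndarray, float]:
        r = forward(NetworkParams.from_vector(topology, vec), X) - y
        return r, float(r @ r)

    r, sse = residual(p)
    trace = [sse]
    epochs = 0
    for _ in range(config.max_epochs):
        if sse < config.sse_tolerance:
            break
        yp, J = _forward_jacobian(NetworkParams.from_vector(topology, p), X)
        g = J.T @ r
        if np.max(np.abs(g)) < config.gradient_tolerance:
            break
        JTJ = J.T @ J
        accepted = False
        for _try in range(60):
            try:
                delta = np.linalg.solve(JTJ + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= config.lm_factor_up
                continue
            p_new = p + delta
            r_new, sse_new = residual(p_new)
            if np.isfinite(sse_new) and sse_new < sse:
                p, r, sse = p_new, r_new, sse_new
                lam = max(lam / config.lm_factor_down, 1e-15)
                accepted = True
                break
            lam *= config.lm_factor_up
            if lam > 1e12:
                break
        if not accepted:
            break
        epochs += 1
        trace.append(sse)
    return p, epochs, sse, trace


def _restart_seeds(seed: int, n: int) -> list[int]:
    # deterministic per-restart seeds, kept below 2**31
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def train_lm(
    topology: NetworkTopology,
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainingConfig = TrainingConfig(),
) -> TrainingResult:
    """Train the perceptron by Levenberg-Marquardt, best of ``n_restarts`` seeds."""
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.shape[0] or X.shape[0] < 1:
        raise ValueError("X_train must be (n, n_in) and y_train length n, n >= 1")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    if X.shape[1] != topology.n_in:
        raise ValueError("X_train width does not match topology.n_in")

    best: TrainingResult | None = None
    for s in _restart_seeds(config.seed, config.n_restarts):
        p0 = init_params(topology, s).to_vector()
        p, epochs, sse, trace = _lm_fit(p0, topology, X, y, config)
        if best is None or sse < best.final_sse:
            best = TrainingResult(
                params=NetworkParams.from_vector(topology, p),
                epochs_run=epochs,
                final_sse=sse,
                sse_trace=np.asarray(trace),
                init_seed=s,
            )
    assert best is not None
    yp = forward(best.params, X)
    best.train_metrics = compute_metrics(yp, y)
    return best


def _sweep_rank_key(test_rmse: float, test_mape: float | None, n_hidden: int):
    """Ordering for the hidden-size sweep: RMSE, then MAPE, then fewer neurons."""
    return (test_rmse, np.inf if test_mape is None else test_mape, n_hidden)


def select_hidden_size(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    sizes: Sequence[int] = range(3, 19),
    config: TrainingConfig = TrainingConfig(),
) -> tuple[NetworkTopology, pd.DataFrame, TrainingResult]:
    """Sweep hidden-layer sizes and pick the best by held-out error.

    Every size is trained with the identical config and restart seeds.  The
    winner has the lowest test RMSE; ties break by lower test MAPE, then by
    fewer neurons.  Returns the chosen topology, the full sweep table and the
    winning TrainingResult.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("empty hidden-size range")
    n_in = np.asarray(X_train).shape[1]
    rows = []
    results: dict[int, TrainingResult] = {}
    for h in sizes:
        topo = NetworkTopology(n_in=n_in, n_hidden=h)
        res = train_lm(topo, X_train, y_train, config)
        res.test_metrics = compute_metrics(forward(res.params, np.asarray(X_test, float)), y_test)
        results[h] = res
        rows.append(
            {
                "n_hidden": h,
                "train_rmse": res.train_metrics.rmse,
                "train_r2": res.train_metrics.r_squared,
                "test_rmse": res.test_metrics.rmse,
                "test_mae": res.test_metrics.mae,
                "test_mape": res.test_metrics.mape,
                "test_r2": res.test_metrics.r_squared,
            }
        )
    sweep = pd.DataFrame(rows)

    def key(h: int):
        m = results[h].test_metrics
        return _sweep_rank_key(m.rmse, m.mape, h)

    best_h = min(sizes, key=key)
    return NetworkTopology(n_in=n_in, n_hidden=best_h), sweep, results[best_h]


@dataclass
class SurrogateModel:
    """A trained network bundled with its input/output scalers.

    ``predict_natural`` accepts factor settings in natural units and returns
    activity in U/mL; this is the object the optimizer and the surface
    plotter consume.
    """

    topology: NetworkTopology
    params: NetworkParams
    x_scaler: scaling.ScalerParams
    y_scaler: scaling.ScalerParams

    def predict_scaled(self, X_scaled) -> np.ndarray | float:
        return forward(self.params, X_scaled)

    def predict_natural(self, X_natural) -> np.ndarray | float:
        X = np.asarray(X_natural, dtype=float)
        single = X.ndim == 1
        Xs = scaling.transform(self.x_scaler, X[None, :] if single else X)
        ys = forward(self.params, Xs)
        yn = scaling.inverse_transform(self.y_scaler, np.atleast_1d(ys))
        return float(yn[0]) if single else yn

    def to_dict(self) -> dict:
        return {
            "topology": {"n_in": self.topology.n_in, "n_hidden": self.topology.n_hidden, "n_out": 1},
            "params": self.params.to_dict(),
            "x_scaler": self.x_scaler.to_dict(),
            "y_scaler": self.y_scaler.to_dict(),
        }

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateModel":
        topo = NetworkTopology(n_in=int(d["topology"]["n_in"]), n_hidden=int(d["topology"]["n_hidden"]))
        return cls(
            topology=topo,
            params=NetworkParams.from_dict(d["params"]),
            x_scaler=scaling.ScalerParams.from_dict(d["x_scaler"]),
            y_scaler=scaling.ScalerParams.from_dict(d["y_scaler"]),
        )

    @classmethod
    def load_json(cls, path) -> "SurrogateModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
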