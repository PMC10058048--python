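"""Feed-forward network (tanh hidden layer, linear output) with
Levenberg-Marquardt least-squares training.

The default topology is 3-8-1: the three extraction factors feed eight
tanh ("tansig") hidden neurons whose weighted sum, plus a bias, is the linear
("purelin") output — the scaled TPC yield. Training minimises the sum of
squared residuals on a random 70/30 train/test split of the min-max-scaled
data via the damped Gauss-Newton (Levenberg-Marquardt) iteration

    (J'J + lambda I) delta = -J'r

with an analytic residual Jacobian, accepting a step only when the training
SSE strictly decreases. Because the result depends on the random weight
initialisation and the random split, an ensemble of independently seeded fits
is trained; the member with the best test R^2 is the champion and the ensemble
mean is available as a smoother predictor.

Parameter flattening order (used by the Jacobian and the serialised weight
files): input-to-hidden weights row-major (hidden neuron fastest-varying over
inputs), hidden biases, hidden-to-output weights, output bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import (
    Dataset,
    DesignPoint,
    ScalingSpec,
    fit_scaler,
    split_train_test,
)

__all__ = [
    "Topology",
    "NetworkWeights",
    "TrainingConfig",
    "FitResult",
    "EnsembleResult",
    "TrainingError",
    "init_weights",
    "forward",
    "residual_jacobian",
    "train_lm",
    "train_ensemble",
    "predict",
    "fit_metrics",
]


class TrainingError(RuntimeError):
    """Raised when Levenberg-Marquardt cannot make progress (carries the
    accepted-SSE trace on the ``trace`` attribute)."""

    def __init__(self, msg: str, trace: list[float] | None = None):
        super().__init__(msg)
        self.trace = trace or []


@dataclass(frozen=True)
class Topology:
    n_inputs: int = 3
    n_hidden: int = 8
    n_outputs: int = 1

    def __post_init__(self) -> None:
        if self.n_outputs != 1:
            raise ValueError("only single-output networks are supported")
        if self.n_inputs < 1 or self.n_hidden < 1:
            raise ValueError("topology dimensions must be >= 1")

    @property
    def n_params(self) -> int:
        m, n = self.n_inputs, self.n_hidden
        return m * n + n + n + 1


@dataclass(frozen=True)
class NetworkWeights:
    """All weights and biases of one network.

    ``w_in[k, i]`` is the weight from input i to hidden neuron k (the w_ik of
    the connection-weight importance formula); ``w_out[k]`` the weight from
    hidden neuron k to the output (w_kj).
    """

    w_in: np.ndarray  # (n_hidden, n_inputs)
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray  # (n_hidden,)
    b_out: float
    topology: Topology

    def __post_init__(self) -> None:
        m, n = self.topology.n_inputs, self.topology.n_hidden
        w_in = np.asarray(self.w_in, float)
        b_hidden = np.asarray(self.b_hidden, float)
        w_out = np.asarray(self.w_out, float)
        object.__setattr__(self, "w_in", w_in)
        object.__setattr__(self, "b_hidden", b_hidden)
        object.__setattr__(self, "w_out", w_out)
        if w_in.shape != (n, m) or b_hidden.shape != (n,) or w_out.shape != (n,):
            raise ValueError(
                f"weight shapes {w_in.shape}/{b_hidden.shape}/{w_out.shape} "
                f"inconsistent with topology {m}-{n}-1"
            )
        for arr in (w_in, b_hidden, w_out, np.array([self.b_out])):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite weight entry")

    def flatten(self) -> np.ndarray:
        return np.concatenate(
            [self.w_in.ravel(), self.b_hidden, self.w_out, [self.b_out]]
        )

    @classmethod
    def from_flat(cls, theta: np.ndarray, topology: Topology) -> "NetworkWeights":
        m, n = topology.n_inputs, topology.n_hidden
        theta = np.asarray(theta, float)
        if theta.size != topology.n_params:
            raise ValueError(
                f"expected {topology.n_params} parameters, got {theta.size}"
            )
        w_in = theta[: n * m].reshape(n, m)
        b_hidden = theta[n * m : n * m + n]
        w_out = theta[n * m + n : n * m + 2 * n]
        return cls(w_in, b_hidden, w_out, float(theta[-1]), topology)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one Levenberg-Marquardt fit."""

    n_hidden: int = 8
    train_fraction: float = 0.70
    lambda0: float = 1e-3  # initial LM damping
    lambda_increase: float = 10.0
    lambda_decrease: float = 0.1
    lambda_ceiling: float = 1e10
    max_iterations: int = 500
    sse_tolerance: float = 1e-10  # on the scaled-unit train SSE change
    gradient_tolerance: float = 1e-8
    init_scale: float = 0.5  # uniform weight-init half-width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if not (self.lambda_increase > 1 > self.lambda_decrease > 0):
            raise ValueError("need lambda_increase > 1 > lambda_decrease > 0")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class FitResult:
    weights: NetworkWeights
    scaler: ScalingSpec
    train_idx: np.ndarray
    test_idx: np.ndarray
    r2_train: float
    r2_test: float
    mae_train: float  # raw response units (mg/g)
    mae_test: float
    iterations: int
    converged: bool
    sse_trace: tuple[float, ...]  # accepted-step train SSE, scaled units
    seed: int


@dataclass(frozen=True)
class EnsembleResult:
    members: tuple[FitResult, ...]
    champion_index: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty ensemble")
        if not 0 <= self.champion_index < len(self.members):
            raise ValueError("champion index out of range")

    @property
    def champion(self) -> FitResult:
        return self.members[self.champion_index]

    @property
    def scaler(self) -> ScalingSpec:
        return self.members[0].scaler


def save_weights(path, weights: NetworkWeights) -> None:
    """Write weights as flat text: a `topology m n 1` header line followed by
    the flattened parameter vector (documented order), one value per line."""
    topo = weights.topology
    lines = [f"topology {topo.n_inputs} {topo.n_hidden} {topo.n_outputs}"]
    lines += [repr(float(v)) for v in weights.flatten()]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_weights(path) -> NetworkWeights:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 4 or header[0] != "topology":
            raise ValueError(f"{path}: malformed weight-file header")
        topo = Topology(int(header[1]), int(header[2]), int(header[3]))
        theta = np.array([float(line) for line in fh if line.strip()])
    return NetworkWeights.from_flat(theta, topo)


def init_weights(topology: Topology, scale: float, seed: int) -> NetworkWeights:
    """i.i.d. uniform weights and biases on [-scale, +scale], seeded."""
    if scale <= 0:
        raise ValueError("init scale must be > 0")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-scale, scale, size=topology.n_params)
    return NetworkWeights.from_flat(theta, topology)


def _hidden(weights: NetworkWeights, X: np.ndarray) -> np.ndarray:
    return np.tanh(X @ weights.w_in.T + weights.b_hidden)


def forward(weights: NetworkWeights, X: np.ndarray) -> np.ndarray:
    """Network output for each row of the (scaled) input matrix X (N, m)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != weights.topology.n_inputs:
        raise ValueError(
            f"input has {X.shape[1]} columns, topology expects "
            f"{weights.topology.n_inputs}"
        )
    return _hidden(weights, X) @ weights.w_out + weights.b_out


def residual_jacobian(
    weights: NetworkWeights, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals r = yhat - y and the analytic Jacobian dr/dtheta.

    Columns follow the documented flattening order: d/dw_in (row-major),
    d/db_hidden, d/dw_out, d/db_out. Because r = yhat - y, dr/dtheta equals
    dyhat/dtheta.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    H = _hidden(weights, X)  # (N, n)
    r = H @ weights.w_out + weights.b_out - y
    G = (1.0 - H**2) * weights.w_out  # (N, n): d yhat / d preactivation_k
    n_rows = X.shape[0]
    J_w_in = (G[:, :, None] * X[:, None, :]).reshape(n_rows, -1)
    J = np.hstack([J_w_in, G, H, np.ones((n_rows, 1))])
    return r, J


def fit_metrics(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    """Coefficient of determination and mean absolute error.

    R^2 = 1 - SS_res/SS_tot with SS_tot about the observed mean;
    MAE = mean |observed - predicted|.
    """
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: observed values are constant")
    ss_res = float(np.sum((observed - predicted) ** 2))
    mae = float(np.mean(np.abs(observed - predicted)))
    return 1.0 - ss_res / ss_tot, mae


def _lm_minimize(
    theta0: np.ndarray,
    topology: Topology,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainingConfig,
) -> tuple[np.ndarray, int, bool, list[float]]:
    """Core LM loop on one (X, y) set; returns (theta, iters, converged, trace)."""
    theta = theta0.copy()
    w = NetworkWeights.from_flat(theta, topology)
    r, J = residual_jacobian(w, X, y)
    sse = float(r @ r)
    trace = [sse]
    lam = cfg.lambda0
    eye = np.eye(theta.size)
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        g = J.T @ r
        if np.linalg.norm(g, ord=np.inf) < cfg.gradient_tolerance:
            converged = True
            break
        A = J.T @ J
        accepted = False
        solvable = False
        while lam <= cfg.lambda_ceiling:
            try:
                delta = np.linalg.solve(A + lam * eye, -g)
                solvable = True
            except np.linalg.LinAlgError:
                lam *= cfg.lambda_increase
                continue
            w_new = NetworkWeights.from_flat(theta + delta, topology)
            r_new, J_new = residual_jacobian(w_new, X, y)
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                accepted = True
                theta = theta + delta
                w, r, J = w_new, r_new, J_new
                improvement = sse - sse_new
                sse = sse_new
                trace.append(sse)
                lam = max(lam * cfg.lambda_decrease, np.finfo(float).tiny)
                if improvement < cfg.sse_tolerance:
                    converged = True
                break
            lam *= cfg.lambda_increase
        if not accepted:
            if not solvable:
                raise TrainingError(
                    "damped normal equations singular past the damping ceiling",
                    trace,
                )
            # damping exhausted without an improving step: stalled at a
            # (numerical) local minimum; reported as non-converged
            break
        if converged:
            break
    return theta, it, converged, trace


def train_lm(
    dataset: Dataset,
    config: TrainingConfig = TrainingConfig(),
    scaler: ScalingSpec | None = None,
) -> FitResult:
    """One Levenberg-Marquardt fit on a seeded 70/30 split of ``dataset``.

    The scaler (min-max onto [-1, 1] by default) is fitted on the full dataset
    so that member networks of an ensemble share one coordinate system; fit
    metrics are reported in raw response units after inverse scaling. The test
    split is reporting-only — no early stopping.
    """
    if len(dataset) < 4:
        raise ValueError("need at least 4 records to fit")
    if scaler is None:
        scaler = fit_scaler(dataset)
    train_idx, test_idx = split_train_test(
        dataset, config.train_fraction, config.seed
    )
    if len(train_idx) < 2:
        raise ValueError("train split must hold at least 2 records")
    Xs = scaler.forward_X(dataset.X)
    ys = scaler.forward_y(dataset.y)
    topo = Topology(n_inputs=Xs.shape[1], n_hidden=config.n_hidden)
    theta0 = init_weights(topo, config.init_scale, config.seed).flatten()
    theta, iters, converged, trace = _lm_minimize(
        theta0, topo, Xs[train_idx], ys[train_idx], config
    )
    weights = NetworkWeights.from_flat(theta, topo)
    y_hat = scaler.inverse_y(forward(weights, Xs))
    y_raw = dataset.y
    r2_tr, mae_tr = fit_metrics(y_raw[train_idx], y_hat[train_idx])
    r2_te, mae_te = fit_metrics(y_raw[test_idx], y_hat[test_idx])
    return FitResult(
        weights=weights,
        scaler=scaler,
        train_idx=train_idx,
        test_idx=test_idx,
        r2_train=r2_tr,
        r2_test=r2_te,
        mae_train=mae_tr,
        mae_test=mae_te,
        iterations=iters,
        converged=converged,
        sse_trace=tuple(trace),
        seed=config.seed,
    )


def train_ensemble(
    dataset: Dataset,
    config: TrainingConfig = TrainingConfig(),
    n_nets: int = 20,
    base_seed: int = 0,
) -> EnsembleResult:
    """Train ``n_nets`` independent fits with seeds base_seed..base_seed+n-1.

    Each member gets a fresh weight initialisation and a fresh train/test
    split from its seed. The champion is the member with the highest test R^2
    (ties: lower test MAE, then lower seed).
    """
    if n_nets < 1:
        raise ValueError("n_nets must be >= 1")
    scaler = fit_scaler(dataset)
    members: list[FitResult] = []
    failures: list[str] = []
    for s in range(base_seed, base_seed + n_nets):
        try:
            members.append(train_lm(dataset, replace(config, seed=s), scaler))
        except TrainingError as exc:  # pragma: no cover - rare in practice
            failures.append(f"seed {s}: {exc}")
    if not members:
        raise TrainingError("all ensemble members failed: " + "; ".join(failures))
    champion = min(
        range(len(members)),
        key=lambda i: (-members[i].r2_test, members[i].mae_test, members[i].seed),
    )
    return EnsembleResult(members=tuple(members), champion_index=champion)


def predict(
    ensemble: EnsembleResult,
    point: DesignPoint | np.ndarray,
    mode: str = "champion",
) -> float | np.ndarray:
    """TPC prediction (raw units, mg/g) at a point or matrix of raw inputs.

    ``mode='champion'`` uses the best-test-R^2 member; ``mode='mean'`` averages
    all member predictions. Points outside the scaler's training box trigger an
    extrapolation warning, not an error.
    """
    if mode not in ("champion", "mean"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    single = isinstance(point, DesignPoint) or np.asarray(point).ndim == 1
    X = (
        point.as_array()[None, :]
        if isinstance(point, DesignPoint)
        else np.atleast_2d(np.asarray(point, float))
    )
    scaler = ensemble.scaler
    if np.any(X < scaler.mins[:3]) or np.any(X > scaler.maxs[:3]):
        warnings.warn(
            "prediction requested outside the training factor box "
            "(extrapolation)", stacklevel=2,
        )
    Xs = scaler.forward_X(X)
    if mode == "champion":
        ys = forward(ensemble.champion.weights, Xs)
    else:
        ys = np.mean([forward(m.weights, Xs) for m in ensemble.members], axis=0)
    y = scaler.inverse_y(ys)
    return float(y[0]) if single else y
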