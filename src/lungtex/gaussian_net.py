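"""Feedforward classifier with Gaussian activation, trained by a hybrid of
gradient descent with momentum and the real-coded genetic algorithm.

Model
-----
A fully connected net (default topology 12-3-5: one input per texture
feature, three hidden units, one output per class) in which both hidden
and output units apply the Gaussian activation

    g(x) = exp(-(x / sigma)^2)

with spread ``sigma`` (default 3).  g peaks at 1 for zero net input and
decays with distance, so each output unit fires for feature patterns that
drive its net input toward zero.  Classes are one-hot encoded; prediction
takes the argmax output (ties to the lowest index).

Training
--------
Per-pattern (online) gradient descent with momentum on the squared error,
using the true derivative g'(x) = -(2x / sigma^2) g(x):

    delta_k     = (t_k - y_k) g'(y_in_k)
    delta_j     = (sum_k delta_k w_jk) g'(z_in_j)
    dW          = alpha * delta * activation + momentum * dW_old

When the epoch MSE stalls (relative improvement below ``stall_tol`` for
``stall_patience`` consecutive epochs) the genetic algorithm takes over:
the current parameters are encoded as one chromosome, the rest of the
population is drawn uniformly within the gene bounds, the fitness of a
chromosome is the training-set MSE of the decoded network, and the best
evolved chromosome replaces the parameters if it improves the best MSE
ever observed.  Gradient epochs then resume.  The returned parameters are
always the best-ever (lowest training MSE) encountered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np

from .rcga import RCGAConfig, evolve, random_population


@dataclass
class NetworkParams:
    """Weights and biases of the Gaussian-activation network.

    Shapes: ``input_hidden_weights`` (n_in, n_hidden), ``hidden_biases``
    (n_hidden,), ``hidden_output_weights`` (n_hidden, n_out),
    ``output_biases`` (n_out,).  ``spread`` is the Gaussian width sigma.
    """

    input_hidden_weights: np.ndarray
    hidden_biases: np.ndarray
    hidden_output_weights: np.ndarray
    output_biases: np.ndarray
    spread: float = 3.0

    def __post_init__(self) -> None:
        v, v0 = np.asarray(self.input_hidden_weights, float), np.asarray(self.hidden_biases, float)
        w, w0 = np.asarray(self.hidden_output_weights, float), np.asarray(self.output_biases, float)
        if v.ndim != 2 or w.ndim != 2 or v.shape[1] != v0.shape[0] or \
                w.shape[0] != v.shape[1] or w.shape[1] != w0.shape[0]:
            raise ValueError("inconsistent layer shapes")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        for arr in (v, v0, w, w0):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")
        self.input_hidden_weights, self.hidden_biases = v, v0
        self.hidden_output_weights, self.output_biases = w, w0

    @property
    def topology(self) -> tuple[int, int, int]:
        return (self.input_hidden_weights.shape[0],
                self.input_hidden_weights.shape[1],
                self.hidden_output_weights.shape[1])

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.input_hidden_weights.copy(), self.hidden_biases.copy(),
                             self.hidden_output_weights.copy(), self.output_biases.copy(),
                             self.spread)

    @classmethod
    def random(cls, n_in: int = 12, n_hidden: int = 3, n_out: int = 5,
               spread: float = 3.0, scale: float = 0.5,
               rng: np.random.Generator | None = None) -> "NetworkParams":
        """Small random initialization: uniform in [-scale, scale]."""
        rng = np.random.default_rng() if rng is None else rng
        return cls(rng.uniform(-scale, scale, (n_in, n_hidden)),
                   rng.uniform(-scale, scale, n_hidden),
                   rng.uniform(-scale, scale, (n_hidden, n_out)),
                   rng.uniform(-scale, scale, n_out), spread)


@dataclass
class TrainingConfig:
    """Gradient-phase settings; defaults follow the reported parameters."""

    learning_rate: float = 1.0
    momentum: float = 0.2
    max_iterations: int = 100
    target_mse: float = 1e-3
    stall_patience: int = 10
    stall_tol: float = 1e-4
    spread: float = 3.0
    n_hidden: int = 3
    init_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.target_mse < 0:
            raise ValueError("target_mse must be >= 0")


def _gauss(x: np.ndarray, spread: float) -> np.ndarray:
    return np.exp(-(x / spread) ** 2)


def _gauss_prime(x: np.ndarray, spread: float) -> np.ndarray:
    return -(2.0 * x / spread**2) * np.exp(-(x / spread) ** 2)


def forward(params: NetworkParams, features: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass: returns (hidden activations Z, outputs Y).

    ``features`` may be a single vector or an (n_samples, n_in) matrix.
    All activations lie in (0, 1].
    """
    x = np.asarray(features, dtype=float)
    if x.shape[-1] != params.topology[0]:
        raise ValueError(f"expected {params.topology[0]} features, got {x.shape[-1]}")
    z_in = x @ params.input_hidden_weights + params.hidden_biases
    z = _gauss(z_in, params.spread)
    y_in = z @ params.hidden_output_weights + params.output_biases
    return z, _gauss(y_in, params.spread)


@dataclass
class Deltas:
    """Momentum state: previous weight/bias corrections, same shapes as params."""

    dv: np.ndarray
    dv0: np.ndarray
    dw: np.ndarray
    dw0: np.ndarray

    @classmethod
    def zeros(cls, params: NetworkParams) -> "Deltas":
        return cls(np.zeros_like(params.input_hidden_weights),
                   np.zeros_like(params.hidden_biases),
                   np.zeros_like(params.hidden_output_weights),
                   np.zeros_like(params.output_biases))


def gradients(params: NetworkParams, features: np.ndarray, target: np.ndarray
              ) -> tuple[Deltas, float]:
    """Error-term gradients of E = 1/2 sum_k (t_k - y_k)^2 for one sample.

    Returns (dE/dtheta packed like Deltas, E).  The training step applies
    the negative of these scaled by the learning rate.
    """
    x = np.asarray(features, dtype=float)
    t = np.asarray(target, dtype=float)
    s = params.spread
    z_in = x @ params.input_hidden_weights + params.hidden_biases
    z = _gauss(z_in, s)
    y_in = z @ params.hidden_output_weights + params.output_biases
    y = _gauss(y_in, s)
    delta_k = (t - y) * _gauss_prime(y_in, s)
    delta_j = (delta_k @ params.hidden_output_weights.T) * _gauss_prime(z_in, s)
    grad = Deltas(dv=-np.outer(x, delta_j), dv0=-delta_j,
                  dw=-np.outer(z, delta_k), dw0=-delta_k)
    return grad, 0.5 * float(((t - y) ** 2).sum())


def backprop_step(params: NetworkParams, features: np.ndarray, targets: np.ndarray,
                  config: TrainingConfig, deltas: Deltas
                  ) -> tuple[NetworkParams, Deltas, float]:
    """One online pass over a batch: per-pattern momentum updates in order.

    Returns the updated parameters, the final momentum state, and the batch
    MSE measured after all updates (mean over samples and outputs of the
    squared target-output difference).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if X.shape[0] != T.shape[0]:
        raise ValueError("features and targets must have equal sample counts")
    p = params.copy()
    d = Deltas(deltas.dv.copy(), deltas.dv0.copy(), deltas.dw.copy(), deltas.dw0.copy())
    alpha, mom = config.learning_rate, config.momentum
    for x, t in zip(X, T):
        grad, _ = gradients(p, x, t)
        d.dw = -alpha * grad.dw + mom * d.dw
        d.dw0 = -alpha * grad.dw0 + mom * d.dw0
        d.dv = -alpha * grad.dv + mom * d.dv
        d.dv0 = -alpha * grad.dv0 + mom * d.dv0
        for name, arr in (("hidden-output", d.dw), ("output-bias", d.dw0),
                          ("input-hidden", d.dv), ("hidden-bias", d.dv0)):
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite update in {name} layer")
        p.hidden_output_weights += d.dw
        p.output_biases += d.dw0
        p.input_hidden_weights += d.dv
        p.hidden_biases += d.dv0
    return p, d, mse(p, X, T)


def mse(params: NetworkParams, features: np.ndarray, targets: np.ndarray) -> float:
    """Mean over samples and output units of the squared error."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("dataset must be nonempty")
    _, y = forward(params, X)
    return float(((T - y) ** 2).mean())


def encode_params(params: NetworkParams) -> np.ndarray:
    """Flatten parameters into one gene vector.

    Ordering: input-hidden weights row-major, hidden biases, hidden-output
    weights row-major, output biases.
    """
    return np.concatenate([params.input_hidden_weights.ravel(),
                           params.hidden_biases,
                           params.hidden_output_weights.ravel(),
                           params.output_biases])


def gene_length(n_in: int, n_hidden: int, n_out: int) -> int:
    return n_in * n_hidden + n_hidden + n_hidden * n_out + n_out


def decode_params(genes: np.ndarray, n_in: int, n_hidden: int, n_out: int,
                  spread: float = 3.0) -> NetworkParams:
    """Inverse of :func:`encode_params` for the stated topology."""
    genes = np.asarray(genes, dtype=float)
    expected = gene_length(n_in, n_hidden, n_out)
    if genes.shape != (expected,):
        raise ValueError(f"expected gene vector of length {expected}, got {genes.shape}")
    a = n_in * n_hidden
    b = a + n_hidden
    c = b + n_hidden * n_out
    return NetworkParams(genes[:a].reshape(n_in, n_hidden), genes[a:b],
                         genes[b:c].reshape(n_hidden, n_out), genes[c:], spread)


def predict(params: NetworkParams, features: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (argmax output, ties to lowest index) and raw scores."""
    _, y = forward(params, np.atleast_2d(np.asarray(features, dtype=float)))
    return y.argmax(axis=1), y


@dataclass
class TrainingHistory:
    """Per-epoch record of the hybrid run."""

    epochs: list[int] = field(default_factory=list)
    phases: list[str] = field(default_factory=list)     # "gradient" or "rcga"
    mses: list[float] = field(default_factory=list)
    best_mses: list[float] = field(default_factory=list)

    def append(self, epoch: int, phase: str, value: float, best: float) -> None:
        self.epochs.append(epoch)
        self.phases.append(phase)
        self.mses.append(value)
        self.best_mses.append(best)


def train_hybrid(features: np.ndarray, targets: np.ndarray,
                 net_config: TrainingConfig | None = None,
                 ga_config: RCGAConfig | None = None,
                 rng: np.random.Generator | None = None,
                 init_params: NetworkParams | None = None
                 ) -> tuple[NetworkParams, TrainingHistory]:
    """Hybrid gradient/GA training on one-hot-labelled feature vectors.

    Alternates epochs of online momentum gradient descent with genetic
    phases triggered by an MSE stall; returns the parameters with the
    lowest training MSE ever observed, plus the epoch history.
    """
    net_config = net_config or TrainingConfig()
    ga_config = ga_config or RCGAConfig()
    rng = np.random.default_rng() if rng is None else rng
    X = np.atleast_2d(np.asarray(features, dtype=float))
    T = np.atleast_2d(np.asarray(targets, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("dataset must be nonempty")
    n_in, n_out = X.shape[1], T.shape[1]
    n_hidden = net_config.n_hidden
    if init_params is None:
        params = NetworkParams.random(n_in, n_hidden, n_out, net_config.spread,
                                      net_config.init_scale, rng)
    else:
        params = init_params.copy()

    history = TrainingHistory()
    best_params = params.copy()
    best_mse = mse(params, X, T)
    if best_mse <= net_config.target_mse:
        return best_params, history

    deltas = Deltas.zeros(params)
    prev_epoch_mse = best_mse
    stall_count = 0
    lo, hi = ga_config.lower_bound, ga_config.upper_bound
    for epoch in range(1, net_config.max_iterations + 1):
        order = rng.permutation(X.shape[0])
        params, deltas, epoch_mse = backprop_step(params, X[order], T[order],
                                                  net_config, deltas)
        if epoch_mse < best_mse:
            best_mse = epoch_mse
            best_params = params.copy()
        history.append(epoch, "gradient", epoch_mse, best_mse)
        if best_mse <= net_config.target_mse:
            break
        rel_improve = (prev_epoch_mse - epoch_mse) / max(prev_epoch_mse, 1e-300)
        stall_count = stall_count + 1 if rel_improve < net_config.stall_tol else 0
        prev_epoch_mse = epoch_mse
        if stall_count >= net_config.stall_patience:
            stall_count = 0
            length = gene_length(n_in, n_hidden, n_out)
            population = random_population(ga_config.population_size, length, lo, hi, rng)
            population[0] = np.clip(encode_params(best_params), lo, hi)

            def fitness(genes: np.ndarray) -> float:
                return mse(decode_params(genes, n_in, n_hidden, n_out,
                                         net_config.spread), X, T)

            result = evolve(population, fitness, ga_config, rng)
            ga_mse = result.best.fitness
            if ga_mse < best_mse:
                best_mse = ga_mse
                best_params = decode_params(result.best.genes, n_in, n_hidden,
                                            n_out, net_config.spread)
                params = best_params.copy()
                deltas = Deltas.zeros(params)
            history.append(epoch, "rcga", ga_mse, best_mse)
            prev_epoch_mse = best_mse
            if best_mse <= net_config.target_mse:
                break
    return best_params, history


def save_params(params: NetworkParams, path: str | Path) -> None:
    """Serialize parameters to a versioned JSON document."""
    n_in, n_hidden, n_out = params.topology
    doc = {
        "format": "lungtex-gaussian-net",
        "version": 1,
        "topology": [n_in, n_hidden, n_out],
        "ordering": "v-rowmajor,v0,w-rowmajor,w0",
        "spread": params.spread,
        "genes": encode_params(params).tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_params(path: str | Path) -> NetworkParams:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "lungtex-gaussian-net":
        raise ValueError(f"{path}: not a lungtex model file")
    n_in, n_hidden, n_out = doc["topology"]
    return decode_params(np.asarray(doc["genes"], dtype=float),
                         n_in, n_hidden, n_out, doc["spread"])
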