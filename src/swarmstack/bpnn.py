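"""One-hidden-layer sigmoid network trained by nonlinear conjugate gradient.

The network is deliberately small: logistic activations in both layers and
a single output unit, sized by the rule hidden = 2 x input.  Training
minimizes mean binary cross-entropy (squared error optional) with
Polak-Ribiere conjugate gradient: backpropagated gradients, restart to
steepest descent when beta < 0 or every n_parameters iterations, and an
Armijo backtracking line search, which guarantees a non-increasing loss
trace.  Convergence is declared when the gradient norm falls below the
``tolerance`` (default 1e-7) or after ``max_iterations`` (default 100).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataio import ClinicalDataset

__all__ = ["BPNNConfig", "TrainedNetwork", "init_network", "forward",
           "loss_and_gradient", "train_cga", "predict"]

_SIG_CLIP = 500.0  # logistic argument clip; avoids overflow, exact in float64


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_SIG_CLIP, _SIG_CLIP)))


@dataclass(frozen=True)
class BPNNConfig:
    n_input: int
    n_hidden: int | None = None     # defaults to 2 * n_input
    tolerance: float = 1e-7         # gradient-norm stopping threshold
    max_iterations: int = 100
    loss: str = "cross_entropy"     # or "squared_error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_input < 1:
            raise ValueError("need at least one input unit")
        if self.loss not in ("cross_entropy", "squared_error"):
            raise ValueError("loss must be cross_entropy or squared_error")

    @property
    def hidden(self) -> int:
        return 2 * self.n_input if self.n_hidden is None else self.n_hidden


@dataclass
class TrainedNetwork:
    """Weights of the 2-layer sigmoid net plus its training-loss trace."""

    W1: np.ndarray          # (n_hidden, n_input)
    b1: np.ndarray          # (n_hidden,)
    w2: np.ndarray          # (n_hidden,)
    b2: float
    config: BPNNConfig
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return self.W1.size + self.b1.size + self.w2.size + 1

    def pack(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.w2, [self.b2]])

    def unpack(self, theta: np.ndarray) -> None:
        h, d = self.W1.shape
        self.W1 = theta[: h * d].reshape(h, d)
        self.b1 = theta[h * d: h * d + h]
        self.w2 = theta[h * d + h: h * d + 2 * h]
        self.b2 = float(theta[-1])

    def to_json(self, path) -> None:
        obj = {
            "W1": self.W1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2,
            "config": {"n_input": self.config.n_input, "n_hidden": self.config.hidden,
                       "tolerance": self.config.tolerance,
                       "max_iterations": self.config.max_iterations,
                       "loss": self.config.loss, "seed": self.config.seed},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "TrainedNetwork":
        with open(path) as fh:
            obj = json.load(fh)
        cfg = BPNNConfig(**obj["config"])
        return cls(W1=np.asarray(obj["W1"]), b1=np.asarray(obj["b1"]),
                   w2=np.asarray(obj["w2"]), b2=float(obj["b2"]), config=cfg)


def init_network(cfg: BPNNConfig) -> TrainedNetwork:
    """Uniform [-1/sqrt(fan_in), 1/sqrt(fan_in)] initialization, seeded."""
    rng = np.random.default_rng(cfg.seed)
    h = cfg.hidden
    s1 = 1.0 / np.sqrt(cfg.n_input)
    s2 = 1.0 / np.sqrt(h)
    return TrainedNetwork(
        W1=rng.uniform(-s1, s1, size=(h, cfg.n_input)),
        b1=rng.uniform(-s1, s1, size=h),
        w2=rng.uniform(-s2, s2, size=h),
        b2=float(rng.uniform(-s2, s2)),
        config=cfg,
    )


def forward(net: TrainedNetwork, x: np.ndarray) -> np.ndarray:
    """Output probability sigma(w2 . sigma(W1 x + b1) + b2), vectorized."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != net.W1.shape[1]:
        raise ValueError("input dimension mismatch")
    H = _sigmoid(X @ net.W1.T + net.b1)
    out = _sigmoid(H @ net.w2 + net.b2)
    return out if np.ndim(x) > 1 else out[0]


def loss_and_gradient(theta: np.ndarray, net: TrainedNetwork, X: np.ndarray,
                      y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean loss and its backpropagated gradient at parameter vector theta."""
    h, d = net.W1.shape
    W1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d: h * d + h]
    w2 = theta[h * d + h: h * d + 2 * h]
    b2 = theta[-1]
    n = X.shape[0]

    Z1 = X @ W1.T + b1
    H = _sigmoid(Z1)
    z2 = H @ w2 + b2
    p = _sigmoid(z2)

    if net.config.loss == "cross_entropy":
        # stable form: log(1+e^z) - y z, gradient dL/dz2 = p - y
        z = np.clip(z2, -_SIG_CLIP, _SIG_CLIP)
        loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
        dz2 = (p - y) / n
    else:
        loss = float(np.mean((p - y) ** 2))
        dz2 = 2.0 * (p - y) * p * (1.0 - p) / n

    gw2 = H.T @ dz2
    gb2 = dz2.sum()
    dH = np.outer(dz2, w2)
    dZ1 = dH * H * (1.0 - H)
    gW1 = dZ1.T @ X
    gb1 = dZ1.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gw2, [gb2]])
    return loss, grad


def train_cga(net: TrainedNetwork, data: ClinicalDataset,
              cfg: BPNNConfig | None = None) -> TrainedNetwork:
    """Polak-Ribiere conjugate gradient with Armijo backtracking.

    Directions reset to steepest descent when beta < 0 or every
    ``n_parameters`` iterations; the step starts at 1 and halves until the
    Armijo sufficient-decrease condition holds, so the recorded loss trace
    never increases.
    """
    cfg = cfg or net.config
    X = np.asarray(data.X, dtype=float)
    y = np.asarray(data.y, dtype=float)
    if not np.isin(data.y, [0, 1]).all():
        raise ValueError("binary labels required")

    theta = net.pack()
    loss, grad = loss_and_gradient(theta, net, X, y)
    direction = -grad
    trace = [loss]
    c_armijo = 1e-4

    for it in range(cfg.max_iterations):
        gnorm = float(np.linalg.norm(grad))
        if gnorm < cfg.tolerance:
            break
        slope = float(grad @ direction)
        if slope >= 0:               # not a descent direction: restart
            direction = -grad
            slope = -gnorm ** 2
        step = 1.0
        new_theta = theta + step * direction
        new_loss, new_grad = loss_and_gradient(new_theta, net, X, y)
        while new_loss > loss + c_armijo * step * slope and step > 1e-16:
            step *= 0.5
            new_theta = theta + step * direction
            new_loss, new_grad = loss_and_gradient(new_theta, net, X, y)
        if new_loss > loss:          # no admissible step: converged
            break
        beta = float(new_grad @ (new_grad - grad)) / max(grad @ grad, 1e-300)
        if beta < 0 or (it + 1) % net.n_parameters == 0:
            beta = 0.0
        direction = -new_grad + beta * direction
        theta, loss, grad = new_theta, new_loss, new_grad
        trace.append(loss)

    net.unpack(theta)
    net.loss_trace = trace
    return net


def predict(net: TrainedNetwork, x: np.ndarray) -> np.ndarray | int:
    """Hard label: 1 iff the forward probability is >= 0.5."""
    p = forward(net, x)
    if np.ndim(p) == 0:
        return int(p >= 0.5)
    return (p >= 0.5).astype(int)
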