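"""Two-layer perceptron on recognition vectors.

The classifier is deliberately small: y = W1·tanh(W0·ξ + b0) + b1, with a
hidden layer of a few units (default 4 per target syllable) and a *linear*
output layer.  It is trained by full-batch gradient minimization of the
mean squared error against the Gaussian-smoothed targets, with early
stopping on a held-back validation split (80/20 by default), keeping the
parameters from the best validation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["NetworkParams", "TrainConfig", "TrainResult", "forward", "train"]

TRAINER_NAME = "scipy-lbfgsb-fullbatch-mse"


@dataclass
class NetworkParams:
    W0: np.ndarray  # (n_hidden, d)
    b0: np.ndarray  # (n_hidden,)
    W1: np.ndarray  # (n_out, n_hidden)
    b1: np.ndarray  # (n_out,)

    @property
    def input_dim(self) -> int:
        return self.W0.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.W0.copy(), self.b0.copy(),
                             self.W1.copy(), self.b1.copy())


def forward(params: NetworkParams, xi: np.ndarray) -> np.ndarray:
    """Network output for one feature-normalized vector ``(d,)`` or a batch
    ``(n, d)``; returns ``(n_out,)`` or ``(n, n_out)``.  Linear output layer:
    no squashing is applied after W1."""
    xi = np.asarray(xi, dtype=np.float64)
    if xi.shape[-1] != params.input_dim:
        raise ValueError(
            f"input dimension {xi.shape[-1]} != network input {params.input_dim}"
        )
    h = np.tanh(xi @ params.W0.T + params.b0)
    return h @ params.W1.T + params.b1


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``n_hidden`` of None resolves to 4 hidden units per target syllable —
    small enough to train in seconds yet sufficient for stereotyped song.
    """

    n_hidden: int | None = None
    train_frac: float = 0.8
    max_iter: int = 400
    patience: int = 30
    seed: int = 0

    def resolve_hidden(self, n_targets: int) -> int:
        n = 4 * n_targets if self.n_hidden is None else self.n_hidden
        if n < 1:
            raise ValueError("n_hidden must be >= 1")
        return n


@dataclass
class TrainResult:
    params: NetworkParams
    train_loss: np.ndarray = field(repr=False)
    val_loss: np.ndarray = field(repr=False)
    best_iter: int = 0

    @property
    def best_val_loss(self) -> float:
        return float(self.val_loss[self.best_iter])


def _pack(p: NetworkParams) -> np.ndarray:
    return np.concatenate([p.W0.ravel(), p.b0, p.W1.ravel(), p.b1])


def _unpack(theta: np.ndarray, d: int, h: int, o: int) -> NetworkParams:
    i = 0
    W0 = theta[i : i + h * d].reshape(h, d); i += h * d
    b0 = theta[i : i + h]; i += h
    W1 = theta[i : i + o * h].reshape(o, h); i += o * h
    b1 = theta[i : i + o]
    return NetworkParams(W0, b0, W1, b1)


def loss_and_grad(
    theta: np.ndarray, X: np.ndarray, T: np.ndarray, h: int
) -> tuple[float, np.ndarray]:
    """Full-batch MSE and its analytic gradient (backpropagation).

    ``X`` is (n, d) inputs, ``T`` (n, o) targets; the loss is the mean of
    the squared errors over all n·o output elements.
    """
    n, d = X.shape
    o = T.shape[1]
    p = _unpack(theta, d, h, o)
    A = X @ p.W0.T + p.b0  # (n, h)
    H = np.tanh(A)
    Y = H @ p.W1.T + p.b1  # (n, o)
    E = Y - T
    loss = float(np.mean(E**2))
    scale = 2.0 / E.size
    gY = scale * E  # (n, o)
    gW1 = gY.T @ H
    gb1 = gY.sum(axis=0)
    gH = gY @ p.W1  # (n, h)
    gA = gH * (1.0 - H**2)
    gW0 = gA.T @ X
    gb0 = gA.sum(axis=0)
    return loss, np.concatenate([gW0.ravel(), gb0, gW1.ravel(), gb1])


def _init_params(d: int, h: int, o: int, rng: np.random.Generator) -> NetworkParams:
    # small uniform weights scaled by fan-in
    return NetworkParams(
        W0=rng.uniform(-1.0, 1.0, (h, d)) / np.sqrt(d),
        b0=np.zeros(h),
        W1=rng.uniform(-1.0, 1.0, (o, h)) / np.sqrt(h),
        b1=np.zeros(o),
    )


def _stratified_split(
    targets: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random column split, stratified so that peak-target columns land in
    both the training and validation sets."""
    positive = targets.max(axis=1) >= 0.5
    train_idx, val_idx = [], []
    for mask in (positive, ~positive):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        cut = int(round(train_frac * len(idx)))
        cut = min(max(cut, 1 if len(idx) else 0), max(len(idx) - 1, 0))
        train_idx.append(idx[:cut])
        val_idx.append(idx[cut:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def train(
    X: np.ndarray, targets: np.ndarray, cfg: TrainConfig | None = None
) -> TrainResult:
    """Train the perceptron on fully normalized inputs.

    Deterministic for a given config seed (initialization and split are the
    only randomness).  Raises if any target syllable has no positive
    (peak-region) column.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim != 2 or targets.shape[0] != X.shape[0]:
        raise ValueError("targets must be (n_columns, n_targets) matching X")
    for k in range(targets.shape[1]):
        if not (targets[:, k] >= 0.5).any():
            raise ValueError(f"target syllable {k} has no positive examples")

    n, d = X.shape
    o = targets.shape[1]
    h = cfg.resolve_hidden(o)
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _stratified_split(targets, cfg.train_frac, rng)
    Xtr, Ttr = X[train_idx], targets[train_idx]
    Xva, Tva = X[val_idx], targets[val_idx]

    theta0 = _pack(_init_params(d, h, o, rng))
    train_hist: list[float] = []
    val_hist: list[float] = []
    best = {"theta": theta0.copy(), "val": np.inf, "iter": 0}

    def val_loss(theta: np.ndarray) -> float:
        p = _unpack(theta, d, h, o)
        E = forward(p, Xva) - Tva
        return float(np.mean(E**2))

    def callback(theta: np.ndarray) -> None:
        tr, _ = loss_and_grad(theta, Xtr, Ttr, h)
        va = val_loss(theta)
        train_hist.append(tr)
        val_hist.append(va)
        it = len(val_hist) - 1
        if va < best["val"]:
            best.update(theta=theta.copy(), val=va, iter=it)
        elif it - best["iter"] >= cfg.patience:
            raise StopIteration  # early stop: validation loss has plateaued

    callback(theta0)
    minimize(
        loss_and_grad, theta0, args=(Xtr, Ttr, h), jac=True,
        method="L-BFGS-B", callback=callback,
        options={"maxiter": cfg.max_iter, "ftol": 1e-12, "gtol": 1e-10},
    )
    return TrainResult(
        params=_unpack(best["theta"], d, h, o).copy(),
        train_loss=np.asarray(train_hist),
        val_loss=np.asarray(val_hist),
        best_iter=best["iter"],
    )
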