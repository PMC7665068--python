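"""Joint training of the discriminator and generator.

The objective blends the quadratic reconstruction loss L (all traces) with a
hidden-space cross-entropy L_h (synthetic, labeled traces), weighted by an
annealing factor alpha = 0.5 exp(-2k/K) over epochs k = 0..K: labeled
batches minimize (1-alpha) L + alpha L_h, unlabeled batches plain L.  The
network is thus anchored to the synthetic ground truth early in training and
progressively dominated by reconstruction of the (unlabeled, experimental)
traces.  Optimization is plain mini-batch gradient descent with optional
momentum, L2 regularization, gradient-norm clipping and weight thresholding.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._lstm import bilstm_backward
from .model import DGNParams, _disc_forward_batch, _gen_forward_batch
from .sim import LabeledDataset

__all__ = [
    "TrainConfig",
    "DivergenceError",
    "reconstruction_loss",
    "hidden_loss",
    "blend_weight",
    "clip_weights",
    "train_dgn",
]

PROB_FLOOR = 1e-12


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainConfig:
    """Hyperparameters of the blended training procedure.

    ``alpha0`` and ``alpha_decay`` parameterize the annealing weight
    ``alpha0 * exp(-alpha_decay * k / epochs)``.
    """

    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 0.3
    momentum: float = 0.9
    l2_coefficient: float = 1e-4
    weight_clip: float = 1.0
    grad_clip: float = 5.0
    seed: int = 0
    alpha0: float = 0.5
    alpha_decay: float = 2.0
    class_balance: float = 1.0  # exponent on inverse state frequency in L_h
    lr_final_frac: float = 0.2  # linear lr decay to lr*frac at the last epoch
    log_every: int = 0  # epochs between log lines; 0 = silent

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.weight_clip <= 0:
            raise ValueError("weight_clip must be positive")


def reconstruction_loss(xhat: Sequence[float], x: Sequence[float]) -> float:
    """Quadratic reconstruction loss (1/2T) sum_t (xhat_t - x_t)^2."""
    a = np.asarray(xhat, dtype=np.float64)
    b = np.asarray(x, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("xhat and x must be equal-length 1-D sequences")
    return float(np.sum((a - b) ** 2) / (2 * a.size))


def hidden_loss(posterior, truth) -> float:
    """Mean negative log-probability of the true state per frame.

    Probabilities are floored at 1e-12 before the log.
    """
    probs = posterior.probs if hasattr(posterior, "probs") \
        else np.asarray(posterior, dtype=np.float64)
    states = truth.states if hasattr(truth, "states") \
        else np.asarray(truth, dtype=np.int64)
    if probs.shape[0] != states.shape[0]:
        raise ValueError("posterior and truth lengths differ")
    if states.min() < 0 or states.max() >= probs.shape[1]:
        raise ValueError("truth states out of range")
    p = np.clip(probs[np.arange(states.size), states], PROB_FLOOR, None)
    return float(-np.mean(np.log(p)))


def blend_weight(k: int, K: int, alpha0: float = 0.5,
                 decay: float = 2.0) -> float:
    """Annealing weight alpha = alpha0 * exp(-decay * k / K)."""
    if K < 1 or not 0 <= k <= K:
        raise ValueError("need 0 <= k <= K and K >= 1")
    return float(alpha0 * np.exp(-decay * k / K))


def clip_weights(params: DGNParams, c: float) -> DGNParams:
    """Threshold every weight into [-c, c] (in place)."""
    if c <= 0:
        raise ValueError("clip threshold must be positive")
    for _, arr in params.arrays():
        np.clip(arr, -c, c, out=arr)
    return params


def _onehot(y: np.ndarray, n_cls: int, dtype=np.float64) -> np.ndarray:
    out = np.zeros(y.shape + (n_cls,), dtype=dtype)
    np.put_along_axis(out, y[..., None], 1.0, axis=-1)
    return out


def _batch_pass(params: DGNParams, X: np.ndarray, Y: np.ndarray | None,
                labeled: np.ndarray, alpha: float, compute_grads: bool,
                class_weights: np.ndarray | None = None):
    """One forward (and optionally backward) pass over a batch.

    X: (T, B) raw intensities; Y: (T, B) integer truth (arbitrary where
    unlabeled); labeled: (B,) bool.  Returns (objective, grads-or-None).
    The objective is the batch mean of (1-alpha) L + alpha L_h for labeled
    traces and plain L for unlabeled ones.  ``class_weights`` optionally
    re-weights the cross-entropy per frame by the true state's weight
    (frequency balancing for rare states).
    """
    T, B = X.shape
    n_cls = params.s_max + 1
    dt = params.dtype
    Xn = (X / params.unit_intensity).astype(dt, copy=False)

    probs, Hcat, dcf, dcb = _disc_forward_batch(Xn, params)
    prev = np.empty_like(Xn)
    prev[0] = Xn[0]
    prev[1:] = Xn[:-1]  # teacher forcing
    xhat, Gcat, gcf, gcb = _gen_forward_batch(probs, prev, params)

    resid = xhat - Xn
    L_per = (resid ** 2).sum(axis=0) / (2 * T)  # (B,)
    w_rec = np.where(labeled, 1.0 - alpha, 1.0).astype(dt)
    objective = float(np.mean(w_rec * L_per))
    if Y is not None and labeled.any():
        frame_w = np.ones((T, B), dtype=dt) if class_weights is None \
            else class_weights.astype(dt)[Y]
        pt = np.take_along_axis(probs, Y[:, :, None], axis=2)[:, :, 0]
        ce_per = (frame_w * -np.log(np.clip(pt, PROB_FLOOR, None))).mean(axis=0)
        objective += float(np.mean(np.where(labeled, alpha * ce_per, 0.0)))
    if not compute_grads:
        return objective, None

    grads: dict[str, np.ndarray] = {}
    dxhat = (w_rec / (T * B)) * resid  # (T, B)
    grads["gen_W"] = Gcat.reshape(-1, Gcat.shape[2]).T @ dxhat.reshape(-1, 1)
    grads["gen_b"] = np.array([dxhat.sum()])
    dGcat = dxhat[:, :, None] * params.gen_W[None, None, :, 0]
    dgin, ggrads = bilstm_backward(dGcat, gcf, gcb, params.gen)
    for k, v in ggrads.items():
        grads[f"gen.{k}"] = v

    dprobs = dgin[:, :, :n_cls]
    dlogits = probs * (dprobs - (dprobs * probs).sum(axis=2, keepdims=True))
    if Y is not None and labeled.any():
        ce_w = (np.where(labeled, alpha, 0.0) / (T * B)).astype(dt)
        dlogits = dlogits + (ce_w[None, :] * frame_w)[:, :, None] \
            * (probs - _onehot(Y, n_cls, dt))
    grads["disc_W"] = Hcat.reshape(-1, Hcat.shape[2]).T \
        @ dlogits.reshape(-1, n_cls)
    grads["disc_b"] = dlogits.sum(axis=(0, 1))
    dHcat = dlogits @ params.disc_W.T
    _, dgrads = bilstm_backward(dHcat, dcf, dcb, params.disc)
    for k, v in dgrads.items():
        grads[f"disc.{k}"] = v
    return objective, grads


def _collect(dataset: LabeledDataset):
    lengths = {len(r.trace) for r in dataset.records}
    if len(lengths) > 1:
        raise ValueError("all traces in a training set must share one length")
    X = np.stack([r.trace.intensities for r in dataset.records], axis=1)
    labeled = np.array([r.path is not None for r in dataset.records])
    T, n = X.shape
    Y = np.zeros((T, n), dtype=np.int64)
    for j, r in enumerate(dataset.records):
        if r.path is not None:
            Y[:, j] = r.path.states
    return X, Y, labeled


def train_dgn(
    train_set: LabeledDataset,
    val_set: LabeledDataset | None,
    config: TrainConfig,
    s_max: int | None = None,
    unit_intensity: float | None = None,
    params: DGNParams | None = None,
) -> tuple[DGNParams, pd.DataFrame]:
    """Train the DGN; returns trained parameters and a per-epoch history.

    ``train_set`` may mix labeled (synthetic) and unlabeled (experimental)
    records; it must contain at least one labeled record.  All randomness
    (weight init, shuffling) derives from ``config.seed``.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    X, Y, labeled = _collect(train_set)
    if not labeled.any():
        raise ValueError("training set needs at least one labeled record")
    if s_max is None:
        s_max = train_set.s_max
    if unit_intensity is None:
        if train_set.noise is None:
            raise ValueError("unit_intensity required when the dataset "
                             "carries no noise model")
        unit_intensity = train_set.noise.unit_intensity
    if Y.max() > s_max:
        raise ValueError("labels exceed s_max")

    rng = np.random.default_rng(config.seed)
    if params is None:
        params = DGNParams.init(s_max, unit_intensity, seed=rng)
    velocity = {name: np.zeros_like(arr) for name, arr in params.arrays()}

    # inverse-frequency class weights for the hidden loss: without them the
    # briefly-visited high states contribute almost no gradient share and
    # are never learned.  The flip side - a mild bias toward rare states in
    # ambiguous frames - is accepted; see the methods note.
    class_weights = None
    if config.class_balance > 0:
        counts = np.bincount(Y[:, labeled].ravel(), minlength=s_max + 1)
        freq = counts / max(counts.sum(), 1)
        w = np.where(freq > 0, freq, 1.0) ** (-config.class_balance)
        w[freq == 0] = 0.0
        class_weights = w / max((freq * w).sum(), 1e-12)

    Xv = Yv = labeled_v = None
    if val_set is not None and len(val_set):
        Xv, Yv, labeled_v = _collect(val_set)

    n = X.shape[1]
    bs = config.batch_size
    rows = []
    for k in range(config.epochs):
        alpha = blend_weight(k, config.epochs, config.alpha0,
                             config.alpha_decay)
        frac = k / max(config.epochs - 1, 1)
        lr = config.learning_rate * (1 - frac * (1 - config.lr_final_frac))
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            obj, grads = _batch_pass(
                params, X[:, idx], Y[:, idx], labeled[idx], alpha, True,
                class_weights)
            if not np.isfinite(obj):
                raise DivergenceError(k)
            epoch_loss += obj
            n_batches += 1
            if config.grad_clip > 0:
                gnorm = np.sqrt(sum(float((g ** 2).sum())
                                    for g in grads.values()))
                if gnorm > config.grad_clip:
                    scale = config.grad_clip / gnorm
                    for g in grads.values():
                        g *= scale
            for name, arr in params.arrays():
                g = grads[name]
                is_bias = name.split(".")[-1] in ("b_f", "b_b",
                                                  "disc_b", "gen_b")
                if config.l2_coefficient and not is_bias:
                    g = g + config.l2_coefficient * arr
                v = velocity[name]
                v *= config.momentum
                v -= lr * g
                arr += v
            clip_weights(params, config.weight_clip)
        train_loss = epoch_loss / max(n_batches, 1)
        if Xv is not None:
            val_loss, _ = _batch_pass(params, Xv, Yv, labeled_v, alpha, False,
                                      class_weights)
        else:
            val_loss = np.nan
        rows.append({"epoch": k, "alpha": alpha, "train_loss": train_loss,
                     "val_loss": val_loss, "wall_time": time.time()})
        if config.log_every and (k % config.log_every == 0
                                 or k == config.epochs - 1):
            print(f"epoch {k:3d}  alpha {alpha:.4f}  "
                  f"train {train_loss:.4f}  val {val_loss:.4f}")
    return params, pd.DataFrame(rows)
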