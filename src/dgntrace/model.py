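"""The discriminator-generator network (DGN).

The discriminator is a bidirectional LSTM (32 units per direction) followed
by a per-frame softmax over hidden states 0..s_max; it maps a fluorescence
trace to a posterior over the emitting-fluorophore count at every frame.
The generator is a second biLSTM (16 units per direction) with a linear
output head; conditioned on the discriminator's posterior and the previous
intensity value, it reconstructs the trace.  Joint reconstruction training
makes the posterior informative without labels; once trained, the
discriminator alone yields the hidden state path.

Intensities are normalized by the single-fluorophore unit intensity before
entering either network, so one fluorophore corresponds to 1.0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._lstm import bilstm_forward, bilstm_backward
from .sim import LabeledDataset, StatePath, Trace

__all__ = [
    "HiddenPosterior",
    "DGNParams",
    "discriminator_forward",
    "generator_forward",
    "predict_state_path",
    "DGNModel",
    "DGNResults",
]

DISC_HIDDEN = 32
GEN_HIDDEN = 16


@dataclass
class HiddenPosterior:
    """Per-frame probability simplex over hidden states (T x (s_max+1))."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a T x (s_max+1) matrix")
        if np.any(self.probs < -1e-9):
            raise ValueError("probabilities must be non-negative")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("each row must sum to 1 within 1e-6")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def argmax_states(self) -> np.ndarray:
        # np.argmax returns the first maximum: ties break to the lower state
        return np.argmax(self.probs, axis=1)


def _init_bilstm(rng: np.random.Generator, in_dim: int, hidden: int,
                 dtype) -> dict:
    """Uniform init ~ 1/sqrt(hidden); forget-gate biases start at 1 to ease
    gradient flow through time."""
    a = 1.0 / np.sqrt(hidden)
    params = {}
    for d in ("f", "b"):
        Wx = rng.uniform(-a, a, size=(in_dim, 4 * hidden))
        Wh = rng.uniform(-a, a, size=(hidden, 4 * hidden))
        bias = np.zeros(4 * hidden)
        bias[hidden:2 * hidden] = 1.0
        params[f"Wx_{d}"] = Wx.astype(dtype)
        params[f"Wh_{d}"] = Wh.astype(dtype)
        params[f"b_{d}"] = bias.astype(dtype)
    return params


@dataclass
class DGNParams:
    """All DGN weights plus the state cardinality and normalization constant."""

    s_max: int
    unit_intensity: float
    disc: dict = field(repr=False)
    disc_W: np.ndarray = field(repr=False)
    disc_b: np.ndarray = field(repr=False)
    gen: dict = field(repr=False)
    gen_W: np.ndarray = field(repr=False)
    gen_b: np.ndarray = field(repr=False)

    @classmethod
    def init(cls, s_max: int, unit_intensity: float,
             seed: int | np.random.Generator = 0,
             dtype=np.float32) -> "DGNParams":
        """Fresh random parameters.

        float32 is the default working precision (training is ~30% faster
        and numerically indistinguishable at these scales); float64 is used
        where exact gradients are checked.
        """
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        n_cls = s_max + 1
        disc = _init_bilstm(rng, 1, DISC_HIDDEN, dtype)
        a = 1.0 / np.sqrt(2 * DISC_HIDDEN)
        disc_W = rng.uniform(-a, a, size=(2 * DISC_HIDDEN, n_cls))
        disc_b = np.zeros(n_cls)
        gen = _init_bilstm(rng, n_cls + 1, GEN_HIDDEN, dtype)
        ag = 1.0 / np.sqrt(2 * GEN_HIDDEN)
        gen_W = rng.uniform(-ag, ag, size=(2 * GEN_HIDDEN, 1))
        gen_b = np.zeros(1)
        return cls(s_max, float(unit_intensity), disc,
                   disc_W.astype(dtype), disc_b.astype(dtype),
                   gen, gen_W.astype(dtype), gen_b.astype(dtype))

    @property
    def dtype(self):
        return self.disc_W.dtype

    def arrays(self):
        """Yield (name, array) for every weight tensor, in a fixed order."""
        for k in sorted(self.disc):
            yield f"disc.{k}", self.disc[k]
        yield "disc_W", self.disc_W
        yield "disc_b", self.disc_b
        for k in sorted(self.gen):
            yield f"gen.{k}", self.gen[k]
        yield "gen_W", self.gen_W
        yield "gen_b", self.gen_b

    def copy(self) -> "DGNParams":
        return DGNParams(self.s_max, self.unit_intensity,
                         {k: v.copy() for k, v in self.disc.items()},
                         self.disc_W.copy(), self.disc_b.copy(),
                         {k: v.copy() for k, v in self.gen.items()},
                         self.gen_W.copy(), self.gen_b.copy())

    def save(self, path) -> None:
        flat = {name.replace(".", "__"): arr for name, arr in self.arrays()}
        meta = json.dumps({"s_max": self.s_max,
                           "unit_intensity": self.unit_intensity})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **flat)

    @classmethod
    def load(cls, path) -> "DGNParams":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = cls.init(meta["s_max"], meta["unit_intensity"], seed=0,
                              dtype=z["disc_W"].dtype)
            for name, arr in params.arrays():
                arr[...] = z[name.replace(".", "__")]
        return params


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _squash(xn: np.ndarray, s_max: int) -> np.ndarray:
    """Fixed affine map of unit-normalized intensities onto ~[-1, 1].

    Keeps LSTM pre-activations in the responsive range of tanh/sigmoid for
    any state cardinality; without it, states above ~4 saturate the gates
    and become indistinguishable.
    """
    half = s_max / 2.0
    return (xn - half) / half


def _disc_forward_batch(Xn: np.ndarray, params: DGNParams):
    """Xn: (T, B) normalized intensities -> (probs (T,B,C), Hcat, caches)."""
    X = np.ascontiguousarray(
        _squash(Xn, params.s_max)[:, :, None].astype(params.dtype, copy=False))
    Hcat, cf, cb = bilstm_forward(X, params.disc)
    logits = Hcat @ params.disc_W + params.disc_b
    return _softmax(logits), Hcat, cf, cb


def _gen_forward_batch(probs: np.ndarray, prev: np.ndarray, params: DGNParams):
    """probs (T,B,C), prev (T,B, normalized units) -> (xhat (T,B), Gcat, caches)."""
    gin = np.concatenate(
        [probs.astype(params.dtype, copy=False),
         _squash(prev, params.s_max)[:, :, None].astype(params.dtype,
                                                        copy=False)], axis=2)
    gin = np.ascontiguousarray(gin)
    Gcat, cf, cb = bilstm_forward(gin, params.gen)
    xhat = (Gcat @ params.gen_W)[:, :, 0] + params.gen_b[0]
    return xhat, Gcat, cf, cb


def _check_trace(trace: Trace) -> None:
    if len(trace) < 2:
        raise ValueError("trace must have at least 2 frames")
    if not np.all(np.isfinite(trace.intensities)):
        raise ValueError("trace intensities must be finite")


def discriminator_forward(trace: Trace, params: DGNParams) -> HiddenPosterior:
    """Full-sequence posterior over hidden states for one trace.

    Raw intensities are normalized by ``params.unit_intensity`` internally.
    Deterministic given the trace and parameters.
    """
    _check_trace(trace)
    Xn = (trace.intensities / params.unit_intensity)[:, None]
    probs, _, _, _ = _disc_forward_batch(Xn, params)
    return HiddenPosterior(probs[:, 0, :])


def generator_forward(
    posterior: HiddenPosterior,
    previous_values: Sequence[float],
    params: DGNParams,
) -> np.ndarray:
    """Reconstructed intensity sequence (normalized units).

    ``previous_values`` supplies the conditioning value for each frame: the
    previous measured intensity during training (teacher forcing) or the
    previous prediction at evaluation.
    """
    prev = np.asarray(previous_values, dtype=np.float64)
    if prev.shape[0] != len(posterior):
        raise ValueError("previous_values length must match posterior length")
    xhat, _, _, _ = _gen_forward_batch(
        posterior.probs[:, None, :], prev[:, None], params)
    return xhat[:, 0]


def _autoregressive_prev(probs: np.ndarray, xhat: np.ndarray | None) -> np.ndarray:
    """Conditioning sequence for evaluation-time generation (T,B)."""
    if xhat is None:  # first pass: posterior-weighted state mean
        states = np.arange(probs.shape[2], dtype=np.float64)
        m = probs @ states
    else:
        m = xhat
    prev = np.empty_like(m)
    prev[0] = m[0]
    prev[1:] = m[:-1]
    return prev


def reconstruct_trace(trace: Trace, params: DGNParams,
                      n_passes: int = 2) -> np.ndarray:
    """Autoregressive reconstruction of a trace (normalized units).

    The bidirectional generator needs its whole conditioning sequence up
    front, so prediction iterates: the first pass conditions on the shifted
    posterior-weighted state mean, later passes on the shifted previous
    reconstruction.
    """
    post = discriminator_forward(trace, params)
    probs = post.probs[:, None, :]
    xhat = None
    for _ in range(n_passes):
        prev = _autoregressive_prev(probs, xhat)
        xhat, _, _, _ = _gen_forward_batch(probs, prev, params)
    return xhat[:, 0]


def predict_state_path(trace: Trace, params: DGNParams) -> StatePath:
    """Most probable state per frame (argmax posterior, ties to lower state)."""
    post = discriminator_forward(trace, params)
    return StatePath(post.argmax_states(), s_max=params.s_max,
                     frame_interval=trace.frame_interval)


def _predict_paths_batch(traces: list[Trace], params: DGNParams,
                         batch_size: int = 64) -> list[StatePath]:
    """Batched argmax decoding; traces must share a common length."""
    out: list[StatePath] = []
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        return [predict_state_path(t, params) for t in traces]
    for i in range(0, len(traces), batch_size):
        chunk = traces[i:i + batch_size]
        X = np.stack([t.intensities for t in chunk], axis=1)
        probs, _, _, _ = _disc_forward_batch(X / params.unit_intensity, params)
        states = np.argmax(probs, axis=2)
        for j, t in enumerate(chunk):
            out.append(StatePath(states[:, j], s_max=params.s_max,
                                 frame_interval=t.frame_interval))
    return out


# ---------------------------------------------------------------------------
# statsmodels-style front end


class DGNModel:
    """Discriminator-generator network bound to a dataset.

    Parameters
    ----------
    dataset
        Labeled (synthetic) and optionally unlabeled (experimental) traces
        with train/val/test split tags.
    unit_intensity
        Single-fluorophore mean intensity used to normalize inputs; defaults
        to the dataset's noise model when available.
    s_max
        Hypothetical maximum state number; defaults to the dataset's.
    """

    def __init__(self, dataset: LabeledDataset,
                 unit_intensity: float | None = None,
                 s_max: int | None = None):
        self.dataset = dataset
        self.s_max = int(s_max if s_max is not None else dataset.s_max)
        if unit_intensity is None:
            if dataset.noise is None:
                raise ValueError(
                    "unit_intensity not given and dataset has no noise model; "
                    "estimate it with sim.fit_unit_intensity first")
            unit_intensity = dataset.noise.unit_intensity
        self.unit_intensity = float(unit_intensity)

    def fit(self, config=None, **overrides) -> "DGNResults":
        """Train the network; returns a :class:`DGNResults`."""
        from .train import TrainConfig, train_dgn

        if config is None:
            config = TrainConfig(**overrides)
        elif overrides:
            raise ValueError("pass either config or keyword overrides")
        params, history = train_dgn(
            self.dataset.subset("train"), self.dataset.subset("val"),
            config, s_max=self.s_max, unit_intensity=self.unit_intensity)
        return DGNResults(self, params, history, config)


class DGNResults:
    """Fitted DGN: trained weights, training history, and predictors."""

    def __init__(self, model: DGNModel | None, params: DGNParams,
                 history, config):
        self.model = model
        self.params = params
        self.history = history
        self.config = config

    def posterior(self, trace: Trace) -> HiddenPosterior:
        return discriminator_forward(trace, self.params)

    def predict_path(self, trace: Trace) -> StatePath:
        return predict_state_path(trace, self.params)

    def predict_paths(self, traces: Sequence[Trace]) -> list[StatePath]:
        return _predict_paths_batch(list(traces), self.params)

    def reconstruct(self, trace: Trace, raw_units: bool = False) -> np.ndarray:
        xhat = reconstruct_trace(trace, self.params)
        return xhat * self.params.unit_intensity if raw_units else xhat

    def save(self, path) -> None:
        self.params.save(path)

    @classmethod
    def from_file(cls, path) -> "DGNResults":
        return cls(None, DGNParams.load(path), None, None)

    def plot_path(self, trace: Trace, ax=None):
        """Overlay the predicted state path on a trace (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(len(trace)) * trace.frame_interval
        ax.plot(t, trace.intensities / self.params.unit_intensity,
                color="0.3", lw=0.7, label="trace (units of 1 fluorophore)")
        ax.step(t, self.predict_path(trace).states, where="post",
                color="purple", lw=1.5, label="predicted state path")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("fluorophores")
        ax.legend()
        return ax

    def summary(self) -> str:
        n_par = sum(a.size for _, a in self.params.arrays())
        lines = [
            "Discriminator-Generator Network Results",
            "=" * 43,
            f"states (s_max + background): {self.params.s_max} + 1",
            f"unit intensity (normalization): {self.params.unit_intensity:g}",
            f"parameters: {n_par}",
        ]
        if self.history is not None and len(self.history):
            h = self.history
            lines += [
                f"epochs: {len(h)}",
                f"final train loss: {h['train_loss'].iloc[-1]:.4f}",
                f"final val loss:   {h['val_loss'].iloc[-1]:.4f}",
                f"final alpha:      {h['alpha'].iloc[-1]:.4f}",
            ]
        return "\n".join(lines)
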