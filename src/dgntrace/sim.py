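"""Synthetic single-molecule fluorescence trace generation.

This module emulates the generative process behind single-molecule
photobleaching and aggregation-dynamics experiments: a piecewise-constant
hidden path of nominal fluorophore counts, an emission process perturbed by
reversible photoblinking, and a camera-level intensity read-out corrupted by
Poisson shot noise and additive Gaussian noise.  Noise magnitude is
calibrated to a target adjusted signal-to-noise ratio (aSNR), the mean over
adjacent fluorescence states of twice the step height divided by the sum of
the two states' intensity standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "StatePath",
    "Trace",
    "NoiseModel",
    "TraceRecord",
    "LabeledDataset",
    "CalibrationInfeasibleError",
    "ConvergenceError",
    "sample_bleach_path",
    "sample_dynamic_path",
    "apply_blinking",
    "render_trace",
    "compute_asnr",
    "calibrate_noise_for_asnr",
    "synthesize_dataset",
    "default_dynamic_transition",
    "fit_unit_intensity",
]

DEFAULT_FRAME_INTERVAL = 0.1  # seconds; 10 Hz acquisition


class CalibrationInfeasibleError(ValueError):
    """Requested aSNR cannot be reached with the given noise model."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge."""


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class StatePath:
    """Per-frame hidden state sequence of nominal fluorophore counts.

    State 0 is the fully-bleached background.  The nominal count ignores
    reversible blinking: a fluorophore in a transient dark state still counts.
    """

    states: np.ndarray
    s_max: int
    frame_interval: float = DEFAULT_FRAME_INTERVAL

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1 or self.states.size < 2:
            raise ValueError("state path must be 1-D with length >= 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.states.min() < 0 or self.states.max() > self.s_max:
            raise ValueError("states must lie in [0, s_max]")

    def __len__(self) -> int:
        return self.states.size


@dataclass
class Trace:
    """A measured fluorescence intensity time trace (one value per frame)."""

    intensities: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 1 or self.intensities.size < 2:
            raise ValueError("trace must be 1-D with length >= 2")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("trace intensities must be finite")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.intensities.size


@dataclass
class NoiseModel:
    """Emission and read-out noise parameters.

    unit_intensity
        Mean fluorescence contributed by one emitting fluorophore.
    gaussian_sd
        Standard deviation of the additive Gaussian (camera/background) noise.
    shot_noise
        If true, per-frame photon counts are Poisson distributed around
        ``count * unit_intensity``.
    blink_rate
        Per-fluorophore, per-frame probability of entering a reversible dark
        state while emitting.
    blink_mean_duration
        Mean dark-state dwell in frames (geometric recovery).
    """

    unit_intensity: float = 100.0
    gaussian_sd: float = 0.0
    shot_noise: bool = True
    blink_rate: float = 0.01
    blink_mean_duration: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_intensity <= 0:
            raise ValueError("unit_intensity must be positive")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be non-negative")
        if not 0 <= self.blink_rate < 1:
            raise ValueError("blink_rate must be in [0, 1)")
        if self.blink_mean_duration < 1:
            raise ValueError("blink_mean_duration must be >= 1 frame")


@dataclass
class TraceRecord:
    trace: Trace
    path: StatePath | None
    split: Literal["train", "val", "test"]


@dataclass
class LabeledDataset:
    """Traces with optional ground-truth paths and a train/val/test split."""

    records: list[TraceRecord]
    mode: Literal["photobleach", "dynamic"]
    s_max: int
    achieved_asnr: float | None = None
    noise: NoiseModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.path is not None and len(rec.path) != len(rec.trace):
                raise ValueError("path length must equal trace length")

    def subset(self, split: str) -> "LabeledDataset":
        recs = [r for r in self.records if r.split == split]
        return LabeledDataset(recs, self.mode, self.s_max,
                              self.achieved_asnr, self.noise, self.seed)

    def traces(self) -> list[Trace]:
        return [r.trace for r in self.records]

    def paths(self) -> list[StatePath | None]:
        return [r.path for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Hidden-path sampling


def sample_bleach_path(
    n_init: int,
    bleach_rate: float,
    n_frames: int,
    seed: int | np.random.Generator | None = None,
    s_max: int | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> StatePath:
    """Sample a stepwise-decreasing photobleaching path.

    Each of the ``n_init`` fluorophores bleaches independently with
    probability ``bleach_rate`` per frame, so dwell times in high states are
    shorter than in low states (order statistics of geometric lifetimes).
    """
    if s_max is None:
        s_max = n_init
    if not 0 <= n_init <= s_max:
        raise ValueError("need 0 <= n_init <= s_max")
    if not 0 <= bleach_rate <= 1:
        raise ValueError("bleach_rate must be in [0, 1]")
    states = _sample_bleach_paths(
        np.full(1, n_init), bleach_rate, n_frames, _rng(seed))[0]
    return StatePath(states, s_max=s_max, frame_interval=frame_interval)


def _sample_bleach_paths(
    n_init: np.ndarray, bleach_rate: float, n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized bleach-path sampling; returns (n_traces, n_frames) ints."""
    n = n_init.size
    max_init = int(n_init.max(initial=0))
    if max_init == 0 or bleach_rate == 0:
        return np.repeat(n_init[:, None], n_frames, axis=1)
    # lifetime in frames of each fluorophore ~ Geometric(bleach_rate)
    life = rng.geometric(bleach_rate, size=(n, max_init)).astype(np.float64)
    alive_mask = np.arange(max_init)[None, :] < n_init[:, None]
    life[~alive_mask] = 0.0
    t = np.arange(n_frames, dtype=np.float64)
    # state at frame t = number of fluorophores with lifetime > t
    return (life[:, :, None] > t[None, None, :]).sum(axis=1).astype(np.int64)


def default_dynamic_transition(s_max: int, stay: float = 0.85) -> np.ndarray:
    """Default per-frame transition matrix for dynamic (switching) paths.

    States 1..s_max form a symmetric chain with self-transition probability
    ``stay`` and uniform switching to the other active states; state 0
    (background) is absorbing and unvisited.  With ``stay=0.85`` at 10 Hz the
    total leave-rate is 1.5 s^-1, in the range typical of receptor
    association/dissociation kinetics.
    """
    if s_max < 2:
        raise ValueError("dynamic mode needs s_max >= 2")
    P = np.zeros((s_max + 1, s_max + 1))
    P[0, 0] = 1.0
    off = (1.0 - stay) / (s_max - 1)
    for i in range(1, s_max + 1):
        P[i, 1:] = off
        P[i, i] = stay
    return P


def _stationary(P: np.ndarray) -> np.ndarray:
    from scipy.linalg import null_space

    ns = null_space(P.T - np.eye(P.shape[0]))
    candidates = []
    for k in range(ns.shape[1]):
        v = ns[:, k]
        v = v / v.sum() if abs(v.sum()) > 1e-12 else v
        if np.all(v >= -1e-10):
            candidates.append(np.clip(v, 0, None) / np.clip(v, 0, None).sum())
    if len(candidates) != 1:
        raise ValueError(
            "stationary distribution is not unique; pass start_state")
    return candidates[0]


def sample_dynamic_path(
    s_max: int,
    per_frame_transition: np.ndarray,
    n_frames: int,
    seed: int | np.random.Generator | None = None,
    start_state: int | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> StatePath:
    """Sample a state-switching path from a first-order Markov chain.

    Started at ``start_state`` if given, otherwise at the chain's (unique)
    stationary distribution.
    """
    P = np.asarray(per_frame_transition, dtype=np.float64)
    if P.shape != (s_max + 1, s_max + 1):
        raise ValueError("transition matrix must be (s_max+1) x (s_max+1)")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    rng = _rng(seed)
    if start_state is None:
        pi = _stationary(P)
        start = int(rng.choice(s_max + 1, p=pi))
    else:
        start = int(start_state)
    states = _sample_chain_paths(P, np.full(1, start), n_frames, rng)[0]
    return StatePath(states, s_max=s_max, frame_interval=frame_interval)


def _sample_chain_paths(
    P: np.ndarray, start: np.ndarray, n_frames: int, rng: np.random.Generator,
) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    n = start.size
    out = np.empty((n, n_frames), dtype=np.int64)
    state = start.astype(np.int64)
    out[:, 0] = state
    for t in range(1, n_frames):
        u = rng.random(n)
        state = (u[:, None] > cum[state]).sum(axis=1)
        out[:, t] = state
    return out


# ---------------------------------------------------------------------------
# Emission and read-out


def apply_blinking(
    path: StatePath,
    model: NoiseModel,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-frame count of *emitting* fluorophores under reversible blinking.

    Emitting fluorophores enter a dark state with probability
    ``model.blink_rate`` per frame; dark dwells are geometric with mean
    ``model.blink_mean_duration`` frames.  The nominal path is unchanged:
    ground-truth labels ignore blinks.
    """
    return _apply_blinking_batch(path.states[None, :], model, _rng(seed))[0]


def _apply_blinking_batch(
    nominal: np.ndarray, model: NoiseModel, rng: np.random.Generator,
) -> np.ndarray:
    n, T = nominal.shape
    if model.blink_rate == 0:
        return nominal.copy()
    p_rec = 1.0 / model.blink_mean_duration
    dark = np.zeros(n, dtype=np.int64)
    emit = np.empty_like(nominal)
    prev = nominal[:, 0]
    for t in range(T):
        nom = nominal[:, t]
        lost = prev - nom  # bleached this frame (photobleach mode)
        lose_mask = lost > 0
        if np.any(lose_mask):
            # a bleached fluorophore is uniformly random among the survivors,
            # so darks are lost hypergeometrically
            dark_lost = rng.hypergeometric(
                dark[lose_mask], prev[lose_mask] - dark[lose_mask],
                lost[lose_mask])
            dark[lose_mask] -= dark_lost
        dark = np.minimum(dark, nom)
        recovered = rng.binomial(dark, p_rec)
        dark = dark - recovered
        new_dark = rng.binomial(nom - dark, model.blink_rate)
        dark = dark + new_dark
        emit[:, t] = nom - dark
        prev = nom
    return emit


def render_trace(
    emitting: np.ndarray,
    model: NoiseModel,
    seed: int | np.random.Generator | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> Trace:
    """Render emitting counts into a noisy intensity trace.

    Per frame: a Poisson draw with mean ``count * unit_intensity`` (or the
    mean itself with shot noise off) plus additive Gaussian noise.  Values are
    not clipped at zero, as in baseline-subtracted EMCCD data.
    """
    counts = np.asarray(emitting)
    if np.any(counts < 0):
        raise ValueError("emitting counts must be non-negative")
    x = _render_batch(counts[None, :], model, _rng(seed))[0]
    return Trace(x, frame_interval=frame_interval)


def _render_batch(
    counts: np.ndarray, model: NoiseModel, rng: np.random.Generator,
) -> np.ndarray:
    mean = counts * float(model.unit_intensity)
    if model.shot_noise:
        x = rng.poisson(mean).astype(np.float64)
    else:
        x = mean.astype(np.float64)
    if model.gaussian_sd > 0:
        x = x + rng.normal(0.0, model.gaussian_sd, size=x.shape)
    return x


# ---------------------------------------------------------------------------
# aSNR


def compute_asnr(state_means: Sequence[float], state_sds: Sequence[float]) -> float:
    """Adjusted signal-to-noise ratio.

    Mean over adjacent state pairs i of ``2 (mu_{i+1} - mu_i) / (sd_i + sd_{i+1})``.
    """
    mu = np.asarray(state_means, dtype=np.float64)
    sd = np.asarray(state_sds, dtype=np.float64)
    if mu.size < 2:
        raise ValueError("need at least two states")
    if mu.size != sd.size:
        raise ValueError("means and sds must have equal length")
    if np.any(np.diff(mu) < 0):
        raise ValueError("state means must be sorted ascending")
    if np.any(sd < 0):
        raise ValueError("state sds must be non-negative")
    denom = sd[:-1] + sd[1:]
    if np.any(denom <= 0):
        raise ValueError("adjacent sd sums must be positive")
    return float(np.mean(2.0 * np.diff(mu) / denom))


def _theoretical_asnr(model: NoiseModel, s_max: int, gaussian_sd: float) -> float:
    n = np.arange(s_max + 1, dtype=np.float64)
    mu = n * model.unit_intensity
    var = gaussian_sd**2 + (n * model.unit_intensity if model.shot_noise else 0.0)
    sd = np.sqrt(var)
    denom = sd[:-1] + sd[1:]
    if denom[0] == 0:  # shot off and sigma 0: infinite aSNR
        return np.inf
    return float(np.mean(2.0 * np.diff(mu) / denom))


def calibrate_noise_for_asnr(
    target_asnr: float, model: NoiseModel, s_max: int,
    rel_tol: float = 1e-3,
) -> float:
    """Gaussian noise level that yields a target aSNR.

    State means are taken equally spaced at ``n * unit_intensity`` for
    n = 0..s_max with per-state variance ``n*unit_intensity`` (shot noise, if
    on) plus ``sigma^2``; the returned sigma solves aSNR(sigma) = target by
    monotone bisection (closed form with shot noise off).
    """
    if target_asnr <= 0:
        raise ValueError("target_asnr must be positive")
    if not model.shot_noise:
        return model.unit_intensity / target_asnr
    floor = _theoretical_asnr(model, s_max, 0.0)
    if target_asnr > floor:
        raise CalibrationInfeasibleError(
            f"target aSNR {target_asnr:.3g} exceeds the shot-noise "
            f"floor {floor:.3g} for s_max={s_max}")
    lo, hi = 0.0, model.unit_intensity / target_asnr
    while _theoretical_asnr(model, s_max, hi) > target_asnr:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _theoretical_asnr(model, s_max, mid) > target_asnr:
            lo = mid
        else:
            hi = mid
        if hi - lo <= rel_tol * max(hi, 1e-12):
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Dataset synthesis


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    f = np.asarray(fractions, dtype=np.float64)
    if abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("split fractions must sum to 1")
    quotas = f * n
    counts = np.floor(quotas).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for i in range(rem):
        counts[order[i]] += 1
    return counts.tolist()


def _measure_asnr(traces: np.ndarray, emitting: np.ndarray) -> float | None:
    """Empirical aSNR from pooled frames grouped by emitting count."""
    counts = np.unique(emitting)
    mus, sds = [], []
    for c in counts:
        vals = traces[emitting == c]
        if vals.size >= 2:
            mus.append(vals.mean())
            sds.append(vals.std(ddof=1))
    if len(mus) < 2:
        return None
    order = np.argsort(mus)
    mu = np.asarray(mus)[order]
    sd = np.asarray(sds)[order]
    return float(np.mean(2.0 * np.diff(mu) / (sd[:-1] + sd[1:])))


def synthesize_dataset(
    mode: Literal["photobleach", "dynamic"],
    s_max: int,
    n_traces: int,
    n_frames: int = 400,
    target_asnr: float = 2.98,
    state_mix: Sequence[float] | None = None,
    split: Sequence[float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    noise: NoiseModel | None = None,
    bleach_rate: float = 0.02,
    transition: np.ndarray | None = None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
    min_steps: int | None = None,
) -> LabeledDataset:
    """Generate a labeled synthetic dataset at a calibrated aSNR.

    ``state_mix`` gives the proportions of initial (photobleach) or start
    (dynamic) states 1..s_max; default is equal.  ``min_steps`` (photobleach
    only) rejects traces with fewer bleaching steps, e.g. ``min_steps=1``
    excludes zero-step traces as in method-comparison test sets.
    Fully deterministic given ``seed``.
    """
    if mode not in ("photobleach", "dynamic"):
        raise ValueError("mode must be 'photobleach' or 'dynamic'")
    rng = _rng(seed)
    base = noise or NoiseModel()
    sigma = calibrate_noise_for_asnr(target_asnr, base, s_max)
    nm = NoiseModel(base.unit_intensity, sigma, base.shot_noise,
                    base.blink_rate, base.blink_mean_duration)

    if state_mix is None:
        state_mix = np.full(s_max, 1.0 / s_max)
    state_mix = np.asarray(state_mix, dtype=np.float64)
    if state_mix.size != s_max or abs(state_mix.sum() - 1.0) > 1e-8:
        raise ValueError("state_mix must give proportions for states 1..s_max")

    # deterministic class counts (largest remainder), randomized order
    per_class = _largest_remainder(n_traces, state_mix)
    init = np.repeat(np.arange(1, s_max + 1), per_class)
    rng.shuffle(init)

    if mode == "photobleach":
        nominal = _sample_bleach_paths(init, bleach_rate, n_frames, rng)
        if min_steps is not None:
            for attempt in range(200):
                steps = nominal[:, 0] - nominal[:, -1]
                bad = steps < min_steps
                if not np.any(bad):
                    break
                nominal[bad] = _sample_bleach_paths(
                    init[bad], bleach_rate, n_frames, rng)
            else:
                raise RuntimeError("rejection sampling for min_steps stalled")
    else:
        P = transition if transition is not None \
            else default_dynamic_transition(s_max)
        P = np.asarray(P, dtype=np.float64)
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition matrix rows must sum to 1")
        nominal = _sample_chain_paths(P, init, n_frames, rng)

    emitting = _apply_blinking_batch(nominal, nm, rng)
    intensities = _render_batch(emitting, nm, rng)
    achieved = _measure_asnr(intensities, emitting)

    counts = _largest_remainder(n_traces, split)
    tags = np.repeat(np.array(["train", "val", "test"]), counts)
    tags = tags[rng.permutation(n_traces)]

    records = []
    for i in range(n_traces):
        tr = Trace(intensities[i], frame_interval,
                   metadata={"trace_id": i})
        sp = StatePath(nominal[i], s_max=s_max, frame_interval=frame_interval)
        records.append(TraceRecord(tr, sp, str(tags[i])))
    return LabeledDataset(records, mode, s_max, achieved, nm, int(seed)
                          if not isinstance(seed, np.random.Generator) else None)


# ---------------------------------------------------------------------------
# Unit-intensity extraction


def fit_unit_intensity(
    samples: Sequence[float],
    n_components: int = 2,
    min_weight: float = 0.05,
    seed: int = 0,
    max_iter: int = 500,
) -> float:
    """Single-fluorophore unit intensity from raw intensity samples.

    Fits a Gaussian mixture by EM and returns the mean of the lowest-mean
    component whose weight is at least ``min_weight`` (lighter components are
    treated as background/outliers).
    """
    x = np.asarray(samples, dtype=np.float64).reshape(-1, 1)
    if x.shape[0] < 10 * n_components:
        raise ValueError("need at least 10 samples per mixture component")
    gm = GaussianMixture(n_components=n_components, max_iter=max_iter,
                         n_init=3, random_state=seed)
    gm.fit(x)
    if not gm.converged_:
        raise ConvergenceError("Gaussian mixture EM did not converge")
    means = gm.means_.ravel()
    weights = gm.weights_.ravel()
    ok = weights >= min_weight
    if not np.any(ok):
        ok = np.ones_like(ok, dtype=bool)
    return float(means[ok].min())
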