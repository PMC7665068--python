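"""Scoring and downstream kinetics analytics.

Frame-wise confusion matrices and minimum per-state accuracy score predicted
state paths against ground truth; step counting and population distributions
summarize photobleaching stoichiometry; occupancies, transition rates and
exponential dwell fits characterize switching dynamics; and a bootstrap
utility (72% sub-datasets, 5 replicates) attaches mean +- SD to any
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .sim import StatePath

__all__ = [
    "ConfusionReport",
    "DynamicsSummary",
    "BootstrapSummary",
    "confusion_and_accuracy",
    "count_bleach_steps",
    "population_distribution",
    "state_occupancy",
    "transition_rates",
    "dwell_durations",
    "fit_exponential_dwell",
    "bootstrap_stat",
    "summarize_dynamics",
]


@dataclass
class ConfusionReport:
    """Frame-wise confusion between true and predicted states."""

    counts: np.ndarray          # raw counts, true x predicted
    normalized: np.ndarray      # row-normalized; NaN rows for absent states
    per_state_accuracy: dict    # state -> diagonal of normalized matrix
    min_state_accuracy: float   # min over states with >= 1 true frame
    absent_states: list

    def to_frame(self) -> pd.DataFrame:
        n = self.normalized.shape[0]
        return pd.DataFrame(self.normalized,
                            index=pd.Index(range(n), name="true"),
                            columns=pd.Index(range(n), name="predicted"))


def confusion_and_accuracy(
    pred: Sequence[StatePath], truth: Sequence[StatePath],
    states: Sequence[int] | None = None,
) -> ConfusionReport:
    """Confusion matrix over all frames of all trace pairs.

    ``states`` optionally restricts the minimum per-state accuracy to a
    subset of states (e.g. the first five states of a ten-state model);
    the matrices always cover all states.
    """
    if len(pred) != len(truth) or len(pred) == 0:
        raise ValueError("pred and truth must be equal-length non-empty lists")
    n_cls = max(max(p.s_max for p in pred), max(t.s_max for t in truth)) + 1
    counts = np.zeros((n_cls, n_cls), dtype=np.int64)
    for p, t in zip(pred, truth):
        if len(p) != len(t):
            raise ValueError("paired paths must have equal length")
        np.add.at(counts, (t.states, p.states), 1)
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        normalized = counts / row_tot[:, None]
    present = row_tot > 0
    acc = {s: float(normalized[s, s]) for s in range(n_cls) if present[s]}
    absent = [s for s in range(n_cls) if not present[s]]
    pool = acc if states is None else \
        {s: a for s, a in acc.items() if s in set(states)}
    if not pool:
        raise ValueError("no requested state has any true frame")
    return ConfusionReport(counts, normalized, acc, min(pool.values()), absent)


def count_bleach_steps(path: StatePath) -> tuple[int, bool]:
    """Number of bleaching steps (initial minus final state).

    Returns ``(steps, monotone)``; a non-monotone path (any upward
    transition, e.g. residual blinking in a predicted path) is flagged, not
    corrected: down-transitions minus up-transitions still equals
    initial - final.
    """
    s = path.states
    steps = int(s[0] - s[-1])
    monotone = bool(np.all(np.diff(s) <= 0))
    return steps, monotone


def population_distribution(paths: Sequence[StatePath],
                            max_steps: int | None = None) -> np.ndarray:
    """Fraction of traces per bleaching-step count (normalized histogram)."""
    if len(paths) == 0:
        raise ValueError("need at least one path")
    steps = np.array([count_bleach_steps(p)[0] for p in paths])
    if np.any(steps < 0):
        raise ValueError("negative net step count; not a photobleaching set")
    n = max_steps if max_steps is not None else max(p.s_max for p in paths)
    hist = np.bincount(steps, minlength=n + 1).astype(float)
    return hist / hist.sum()


def state_occupancy(paths: Sequence[StatePath]) -> np.ndarray:
    """Fraction of all frames spent in each state 0..s_max; sums to 1."""
    if len(paths) == 0:
        raise ValueError("need at least one path")
    n_cls = max(p.s_max for p in paths) + 1
    counts = np.zeros(n_cls)
    for p in paths:
        counts += np.bincount(p.states, minlength=n_cls)
    return counts / counts.sum()


def transition_rates(paths: Sequence[StatePath],
                     frame_interval: float | None = None) -> pd.DataFrame:
    """Per-second transition rates a_ij between states.

    a_ij (i != j) = (number of frame-to-frame i->j transitions) / (seconds
    spent in state i, counting every frame in i except each trace's final
    frame).  The diagonal is reported as 1/frame_interval - sum_{j!=i} a_ij.
    Rows of states never visited are NaN (absent, not zero).
    """
    if len(paths) == 0:
        raise ValueError("need at least one path")
    if frame_interval is None:
        frame_interval = paths[0].frame_interval
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    n_cls = max(p.s_max for p in paths) + 1
    njump = np.zeros((n_cls, n_cls))
    time_in = np.zeros(n_cls)
    for p in paths:
        s = p.states
        np.add.at(njump, (s[:-1], s[1:]), 1)
        time_in += np.bincount(s[:-1], minlength=n_cls) * frame_interval
    np.fill_diagonal(njump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = njump / time_in[:, None]
    rates[time_in == 0] = np.nan
    visited = time_in > 0
    diag = 1.0 / frame_interval - np.nansum(
        np.where(np.eye(n_cls, dtype=bool), 0.0, rates), axis=1)
    for i in range(n_cls):
        rates[i, i] = diag[i] if visited[i] else np.nan
    idx = pd.Index(range(n_cls), name="from")
    return pd.DataFrame(rates, index=idx,
                        columns=pd.Index(range(n_cls), name="to"))


def dwell_durations(paths: Sequence[StatePath], state: int) -> np.ndarray:
    """Complete dwell durations (seconds) of a state across traces.

    Maximal runs of ``state`` converted to seconds; runs touching either
    trace boundary are right/left-censored and excluded.
    """
    if state < 0:
        raise ValueError("state must be a valid state index")
    out: list[float] = []
    for p in paths:
        s = p.states
        is_s = np.concatenate(([False], s == state, [False]))
        d = np.diff(is_s.astype(int))
        starts = np.where(d == 1)[0]
        ends = np.where(d == -1)[0]
        for a, b in zip(starts, ends):
            if a == 0 or b == len(s):  # touches a boundary: censored
                continue
            out.append((b - a) * p.frame_interval)
    return np.asarray(out)


def fit_exponential_dwell(durations: Sequence[float]) -> float:
    """Maximum-likelihood exponential time constant (the sample mean)."""
    d = np.asarray(durations, dtype=np.float64)
    if d.size < 5:
        raise ValueError("need at least 5 dwell durations")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    return float(d.mean())


@dataclass
class BootstrapSummary:
    """Replicate values and mean +- SD of a statistic over sub-datasets."""

    name: str
    values: np.ndarray
    mean: float
    sd: float
    fraction: float
    replicates: int


def bootstrap_stat(
    items: Sequence,
    stat: Callable[[list], float],
    fraction: float = 0.72,
    replicates: int = 5,
    seed: int | np.random.Generator | None = 0,
    name: str = "statistic",
) -> BootstrapSummary:
    """Mean +- SD of ``stat`` over sub-datasets drawn without replacement.

    Each replicate draws ``round(fraction * n)`` items; SD uses the n-1
    denominator.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    items = list(items)
    k = int(round(fraction * len(items)))
    vals = []
    for r in range(replicates):
        idx = rng.choice(len(items), size=k, replace=False)
        try:
            vals.append(float(stat([items[i] for i in idx])))
        except Exception as exc:
            raise RuntimeError(f"statistic failed on replicate {r}") from exc
    vals = np.asarray(vals)
    return BootstrapSummary(name, vals, float(vals.mean()),
                            float(vals.std(ddof=1)), fraction, replicates)


@dataclass
class DynamicsSummary:
    """Occupancies, transition rates, and dwell time constant of a state set."""

    occupancy: np.ndarray
    rate_matrix: pd.DataFrame
    dwell_tau: dict = field(default_factory=dict)
    n_traces: int = 0


def summarize_dynamics(paths: Sequence[StatePath],
                       dwell_states: Sequence[int] = ()) -> DynamicsSummary:
    """One-call dynamics report: occupancy, rates, and dwell taus."""
    occ = state_occupancy(paths)
    rates = transition_rates(paths)
    taus = {}
    for s in dwell_states:
        d = dwell_durations(paths, s)
        taus[s] = fit_exponential_dwell(d) if d.size >= 5 else np.nan
    return DynamicsSummary(occ, rates, taus, len(paths))
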