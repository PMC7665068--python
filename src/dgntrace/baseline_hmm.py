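"""Gaussian-emission hidden Markov model baseline.

A from-scratch Baum-Welch (EM) fitter and Viterbi decoder used as the
classical comparator for the DGN discriminator.  Emission means are
initialized on an evenly spaced grid between the 1st and 99th intensity
percentiles with random restarts; fitted states are mapped to fluorophore
counts by the rank of their means so that the same scoring and kinetics
analytics apply to HMM paths and DGN paths alike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .sim import StatePath, Trace

__all__ = ["GaussianHMM", "fit_hmm", "fit_hmm_bic", "viterbi_path",
           "GaussianHMMModel", "GaussianHMMResults"]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class GaussianHMM:
    """Fitted HMM parameters: start distribution, transitions, emissions."""

    startprob: np.ndarray
    transmat: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float = np.nan

    def __post_init__(self) -> None:
        if abs(self.startprob.sum() - 1.0) > 1e-6:
            raise ValueError("startprob must sum to 1")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("transmat rows must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("emission SDs must be positive")

    @property
    def n_states(self) -> int:
        return self.means.size


@njit(cache=True)
def _emission_probs(x, means, sds):
    T = x.size
    S = means.size
    B = np.empty((T, S))
    for t in range(T):
        for s in range(S):
            z = (x[t] - means[s]) / sds[s]
            B[t, s] = np.exp(-0.5 * z * z) / (sds[s] * _SQRT2PI)
    return B


@njit(cache=True)
def _forward_backward(x, pi, A, means, sds):
    """Scaled forward-backward; returns (loglik, gamma, xi_sum)."""
    B = _emission_probs(x, means, sds)
    T, S = B.shape
    alpha = np.empty((T, S))
    c = np.empty(T)
    tiny = 1e-300
    a = pi * B[0]
    c[0] = max(a.sum(), tiny)
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = np.dot(alpha[t - 1], A) * B[t]
        c[t] = max(a.sum(), tiny)
        alpha[t] = a / c[t]
    beta = np.empty((T, S))
    beta[T - 1] = 1.0
    xi_sum = np.zeros((S, S))
    for t in range(T - 2, -1, -1):
        bb = B[t + 1] * beta[t + 1]
        beta[t] = np.dot(A, bb) / c[t + 1]
        for i in range(S):
            for j in range(S):
                xi_sum[i, j] += alpha[t, i] * A[i, j] * bb[j] / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        g = gamma[t].sum()
        if g > 0:
            gamma[t] /= g
    return np.log(c).sum(), gamma, xi_sum


@njit(cache=True)
def _viterbi(x, pi, A, means, sds):
    B = _emission_probs(x, means, sds)
    T, S = B.shape
    tiny = 1e-300
    logA = np.log(A + tiny)
    delta = np.log(pi + tiny) + np.log(B[0] + tiny)
    psi = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(S)
        for j in range(S):
            best = -1e308
            arg = 0
            for i in range(S):
                v = delta[i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            new[j] = best + np.log(B[t, j] + tiny)
            psi[t, j] = arg
        delta = new
    states = np.empty(T, dtype=np.int64)
    states[T - 1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return states


def _em_run(seqs: list[np.ndarray], pi, A, means, sds,
            max_iter: int, tol: float, var_floor: float,
            tied_variance: bool = False):
    prev_ll = -np.inf
    ll_hist = []
    floored = False
    for _ in range(max_iter):
        ll = 0.0
        S = means.size
        g_sum = np.zeros(S)
        g_first = np.zeros(S)
        xi_tot = np.zeros((S, S))
        mu_num = np.zeros(S)
        var_num = np.zeros(S)
        gammas = []
        for x in seqs:
            ll_i, gamma, xi = _forward_backward(x, pi, A, means, sds)
            ll += ll_i
            g_first += gamma[0]
            g_sum += gamma.sum(axis=0)
            xi_tot += xi
            mu_num += gamma.T @ x
            gammas.append(gamma)
        ll_hist.append(ll)
        pi = g_first / g_first.sum()
        denom = xi_tot.sum(axis=1)
        A = np.where(denom[:, None] > 0, xi_tot / np.maximum(denom, 1e-300)[:, None],
                     np.eye(S))
        A = A / A.sum(axis=1, keepdims=True)
        means = mu_num / np.maximum(g_sum, 1e-300)
        for k, x in enumerate(seqs):
            var_num += (gammas[k] * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
        if tied_variance:
            var = np.full(S, var_num.sum() / g_sum.sum())
        else:
            var = var_num / np.maximum(g_sum, 1e-300)
        if np.any(var < var_floor):
            floored = True
        sds = np.sqrt(np.maximum(var, var_floor))
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return pi, A, means, sds, ll_hist, floored


def fit_hmm(
    traces: Sequence[Trace],
    n_states: int,
    max_iter: int = 50,
    tol: float = 1e-3,
    seed: int | np.random.Generator | None = 0,
    n_restarts: int = 3,
    tied_variance: bool = False,
) -> GaussianHMM:
    """Fit a Gaussian-emission HMM to one or more traces by Baum-Welch.

    Means start on an evenly spaced grid between the pooled 1st and 99th
    intensity percentiles (jittered across restarts); the best restart by
    log-likelihood is kept, preferring restarts whose emission variances
    never hit the degeneracy floor (1e-6 of the data range) - an
    unboundedly-large likelihood from a collapsed component is a singularity
    of the Gaussian EM objective, not a better fit.  ``tied_variance``
    shares one emission variance across states, the robust choice when a
    state may cover few frames.  Per-iteration log-likelihood is
    non-decreasing up to the convergence tolerance.
    """
    if n_states < 2:
        raise ValueError("need n_states >= 2")
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    seqs = [np.ascontiguousarray(t.intensities, dtype=np.float64)
            for t in traces]
    pooled = np.concatenate(seqs)
    lo, hi = np.percentile(pooled, [1, 99])
    if hi <= lo:
        hi = lo + 1.0
    span = hi - lo
    var_floor = (1e-6 * span) ** 2
    grid = np.linspace(lo, hi, n_states)
    spacing = span / max(n_states - 1, 1)
    best = None
    any_floored = False
    for r in range(n_restarts):
        means = grid.copy() if r == 0 else \
            np.sort(grid + rng.normal(0.0, spacing / 4, size=n_states))
        sds = np.full(n_states, max(spacing / 2, np.sqrt(var_floor)))
        pi = np.full(n_states, 1.0 / n_states)
        A = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
        np.fill_diagonal(A, 0.9)
        pi_f, A_f, mu_f, sd_f, ll_hist, floored = _em_run(
            seqs, pi, A, means, sds, max_iter, tol, var_floor, tied_variance)
        any_floored |= floored
        key = (not floored, ll_hist[-1])  # non-degenerate fits first
        if best is None or key > best[0]:
            best = (key, pi_f, A_f, mu_f, sd_f, ll_hist[-1])
    if any_floored:
        warnings.warn("emission variance floored in at least one restart",
                      RuntimeWarning, stacklevel=2)
    _, pi_f, A_f, mu_f, sd_f, ll = best
    return GaussianHMM(pi_f, A_f, mu_f, sd_f, ll)


def fit_hmm_bic(
    trace: Trace,
    max_states: int,
    min_states: int = 2,
    max_iter: int = 30,
    tol: float = 1e-2,
    seed: int | np.random.Generator | None = 0,
    tied_variance: bool = True,
) -> GaussianHMM:
    """Fit HMMs with 2..max_states states to one trace; keep the best BIC.

    With the state number fixed above the trace's true level count, EM
    duplicates emission levels and rank-mapped labels inflate; selecting the
    state number per trace by the Bayesian information criterion is the
    standard resolution in HMM step counting.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    T = len(trace)
    best = None
    for S in range(min_states, max_states + 1):
        hmm = fit_hmm([trace], S, max_iter=max_iter, tol=tol, seed=rng,
                      n_restarts=1, tied_variance=tied_variance)
        n_par = (S - 1) + S * (S - 1) + S + (1 if tied_variance else S)
        bic = -2.0 * hmm.log_likelihood + n_par * np.log(T)
        if best is None or bic < best[0]:
            best = (bic, hmm)
    return best[1]


def viterbi_path(trace: Trace, hmm: GaussianHMM,
                 map_by_mean: bool = True,
                 merge_sigma: float = 0.0) -> StatePath:
    """Most probable state sequence (log-domain Viterbi).

    With ``map_by_mean`` (default) the decoded labels are the rank of the
    fitted emission means, so label k means "k-th lowest intensity level" -
    the fluorophore-count convention used throughout this package.
    ``merge_sigma > 0`` merges fitted states whose sorted means are closer
    than ``merge_sigma`` times the mean emission SD before ranking: when EM
    is given more states than a trace has levels, duplicate levels would
    otherwise inflate every rank above them, and levels closer than the
    noise scale are not resolvable states in the aSNR sense.
    """
    x = np.ascontiguousarray(trace.intensities, dtype=np.float64)
    states = _viterbi(x, hmm.startprob, hmm.transmat, hmm.means, hmm.sds)
    if map_by_mean:
        order = np.argsort(hmm.means)
        if merge_sigma > 0:
            mu = hmm.means[order]
            sigma = float(hmm.sds.mean())
            cluster = np.zeros(mu.size, dtype=np.int64)
            for i in range(1, mu.size):
                cluster[i] = cluster[i - 1] + \
                    (1 if mu[i] - mu[i - 1] > merge_sigma * sigma else 0)
        else:
            cluster = np.arange(hmm.n_states)
        label = np.empty(hmm.n_states, dtype=np.int64)
        label[order] = cluster
        states = label[states]
    return StatePath(states, s_max=hmm.n_states - 1,
                     frame_interval=trace.frame_interval)


class GaussianHMMModel:
    """statsmodels-style front end: HMM bound to a set of traces."""

    def __init__(self, traces: Sequence[Trace], n_states: int):
        self.traces = list(traces)
        self.n_states = int(n_states)

    def fit(self, max_iter: int = 50, tol: float = 1e-3, seed: int = 0,
            n_restarts: int = 3) -> "GaussianHMMResults":
        hmm = fit_hmm(self.traces, self.n_states, max_iter, tol, seed,
                      n_restarts)
        return GaussianHMMResults(self, hmm)


class GaussianHMMResults:
    def __init__(self, model: GaussianHMMModel, hmm: GaussianHMM):
        self.model = model
        self.hmm = hmm

    def predict_path(self, trace: Trace) -> StatePath:
        return viterbi_path(trace, self.hmm)

    def predict_paths(self, traces: Sequence[Trace] | None = None):
        traces = self.model.traces if traces is None else traces
        return [viterbi_path(t, self.hmm) for t in traces]

    def summary(self) -> str:
        h = self.hmm
        lines = ["Gaussian HMM Results", "=" * 30,
                 f"states: {h.n_states}",
                 f"log-likelihood: {h.log_likelihood:.2f}",
                 "state  mean      sd       stay-prob"]
        for s in range(h.n_states):
            lines.append(f"{s:5d}  {h.means[s]:8.2f}  {h.sds[s]:7.2f}  "
                         f"{h.transmat[s, s]:9.3f}")
        return "\n".join(lines)
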