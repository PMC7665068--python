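"""Tests for scoring and kinetics analytics."""

import numpy as np
import pytest

from dgntrace.analyze import (bootstrap_stat, confusion_and_accuracy,
                              count_bleach_steps, dwell_durations,
                              fit_exponential_dwell, population_distribution,
                              state_occupancy, transition_rates)
from dgntrace.sim import StatePath, sample_dynamic_path


def path(states, s_max=None, fi=0.1):
    states = np.asarray(states, dtype=int)
    return StatePath(states, s_max=int(states.max()) if s_max is None
                     else s_max, frame_interval=fi)


class TestConfusion:
    def test_perfect_prediction_identity(self):
        p = [path([0, 1, 2, 2, 1])]
        rep = confusion_and_accuracy(p, p)
        assert rep.min_state_accuracy == 1.0
        present = ~np.isnan(rep.normalized).any(axis=1)
        assert np.allclose(rep.normalized[present].sum(axis=1), 1.0)

    def test_two_state_hand_count(self):
        pred = [path([0, 1, 1, 1], s_max=1)]
        truth = [path([0, 0, 1, 1], s_max=1)]
        rep = confusion_and_accuracy(pred, truth)
        assert rep.per_state_accuracy[0] == pytest.approx(0.5)
        assert rep.per_state_accuracy[1] == pytest.approx(1.0)
        assert rep.min_state_accuracy == pytest.approx(0.5)

    def test_raw_diagonal_matches_brute_force(self):
        rng = np.random.default_rng(7)
        truth = [path(rng.integers(0, 4, 30), s_max=3) for _ in range(5)]
        pred = [path(rng.integers(0, 4, 30), s_max=3) for _ in range(5)]
        rep = confusion_and_accuracy(pred, truth)
        agree = np.zeros(4, dtype=int)
        for p, t in zip(pred, truth):
            for a, b in zip(p.states, t.states):
                if a == b:
                    agree[b] += 1
        assert np.array_equal(np.diag(rep.counts), agree)

    def test_min_not_above_any_per_state(self):
        rng = np.random.default_rng(8)
        truth = [path(rng.integers(0, 3, 50), s_max=2)]
        pred = [path(rng.integers(0, 3, 50), s_max=2)]
        rep = confusion_and_accuracy(pred, truth)
        assert all(rep.min_state_accuracy <= a
                   for a in rep.per_state_accuracy.values())

    def test_absent_state_excluded_from_min(self):
        pred = [path([0, 0, 1, 1], s_max=5)]
        truth = [path([0, 0, 1, 1], s_max=5)]
        rep = confusion_and_accuracy(pred, truth)
        assert set(rep.absent_states) == {2, 3, 4, 5}
        assert rep.min_state_accuracy == 1.0

    def test_misaligned_pair_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_accuracy([path([0, 1, 1])], [path([0, 1])])


class TestStepCounting:
    def test_constant_path_zero_steps(self):
        assert count_bleach_steps(path([4] * 6))[0] == 0

    def test_simple_staircase(self):
        steps, mono = count_bleach_steps(path([3, 3, 2, 1, 1, 0]))
        assert steps == 3 and mono

    def test_non_monotone_flagged(self):
        steps, mono = count_bleach_steps(path([2, 1, 2, 1, 0]))
        assert steps == 2 and not mono

    def test_population_distribution_construction(self):
        paths = [path([s] * 3 + [0], s_max=10) for s in range(1, 11)] * 10
        dist = population_distribution(paths)
        assert dist.sum() == pytest.approx(1.0)
        assert np.allclose(dist[1:], 0.1)
        assert dist[0] == 0.0


class TestOccupancy:
    def test_single_constant_path(self):
        occ = state_occupancy([path([2, 2, 2], s_max=3)])
        assert occ[2] == 1.0 and occ.sum() == pytest.approx(1.0)

    def test_half_and_half(self):
        occ = state_occupancy([path([0, 0, 1, 1], s_max=1)])
        assert np.allclose(occ, [0.5, 0.5])

    def test_matches_chain_stationary(self):
        P = np.array([[0.9, 0.1], [0.2, 0.8]])
        p = sample_dynamic_path(1, P, 150_000, seed=3)
        occ = state_occupancy([p])
        pi = np.array([2 / 3, 1 / 3])
        se = np.sqrt(pi * (1 - pi) / (150_000 / 15))
        assert np.all(np.abs(occ - pi) < 3 * se)


class TestTransitionRates:
    def test_constant_path_zero_off_diagonal(self):
        r = transition_rates([path([1, 1, 1, 1], s_max=2)])
        assert r.loc[1, 2] == 0.0
        assert r.loc[1, 1] == pytest.approx(10.0)
        assert np.isnan(r.loc[0]).all()

    def test_strict_alternation_rate(self):
        r = transition_rates([path([0, 1] * 50, s_max=1, fi=0.1)])
        assert r.loc[0, 1] == pytest.approx(10.0)
        assert r.loc[1, 0] == pytest.approx(10.0)

    def test_generator_recovery_within_three_se(self):
        p_switch = 0.147
        P = np.array([[1 - p_switch, p_switch], [p_switch, 1 - p_switch]])
        paths = [sample_dynamic_path(1, P, 2000, seed=s) for s in range(50)]
        r = transition_rates(paths, frame_interval=0.1)
        n0 = sum(np.sum(p.states[:-1] == 0) for p in paths)
        se = np.sqrt(p_switch * (1 - p_switch) / n0) / 0.1
        assert abs(r.loc[0, 1] - 1.47) < 3 * se

    def test_diagonal_definition(self):
        r = transition_rates([path([0, 1, 0, 1, 1, 0], s_max=1, fi=0.1)])
        assert r.loc[0, 0] == pytest.approx(10.0 - r.loc[0, 1])


class TestDwell:
    def test_interior_run_measured(self):
        d = dwell_durations([path([1, 2, 2, 2, 1], s_max=2)], state=2)
        assert np.allclose(d, [0.3])

    def test_absent_state_empty(self):
        assert dwell_durations([path([1, 1, 1], s_max=2)], state=2).size == 0

    def test_boundary_runs_censored(self):
        d = dwell_durations([path([2, 2, 1], s_max=2)], state=2)
        assert d.size == 0

    def test_mle_equals_mean(self):
        d = np.full(10, 0.5)
        assert fit_exponential_dwell(d) == pytest.approx(0.5)

    def test_mle_consistency(self):
        rng = np.random.default_rng(0)
        d = rng.exponential(0.54, size=10_000)
        assert fit_exponential_dwell(d) == pytest.approx(0.54, rel=0.02)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        d = rng.exponential(1.0, size=100)
        assert fit_exponential_dwell(2 * d) \
            == pytest.approx(2 * fit_exponential_dwell(d))

    def test_too_few_durations_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_dwell([0.1, 0.2])


class TestBootstrap:
    def test_constant_statistic_zero_sd(self):
        bs = bootstrap_stat(list(range(100)), lambda s: 1.0, seed=0)
        assert bs.sd == 0.0 and bs.mean == 1.0

    def test_full_fraction_zero_sd(self):
        bs = bootstrap_stat(list(range(50)), lambda s: float(np.mean(s)),
                            fraction=1.0, seed=0)
        assert bs.sd == pytest.approx(0.0)

    def test_subset_size_rounding(self):
        sizes = []
        bootstrap_stat(list(range(2224)),
                       lambda s: sizes.append(len(s)) or 0.0, seed=1)
        assert sizes == [1601] * 5

    def test_statistic_failure_reports_replicate(self):
        def bad(_):
            raise RuntimeError("boom")
        with pytest.raises(RuntimeError, match="replicate 0"):
            bootstrap_stat(list(range(10)), bad, seed=0)
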