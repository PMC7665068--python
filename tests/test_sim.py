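"""Tests for the trace simulator: hidden paths, blinking, noise, aSNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgntrace import sim
from dgntrace.sim import (NoiseModel, StatePath, apply_blinking,
                          calibrate_noise_for_asnr, compute_asnr,
                          render_trace, sample_bleach_path,
                          sample_dynamic_path, synthesize_dataset,
                          fit_unit_intensity)


class TestBleachPath:
    def test_no_bleaching_is_constant(self):
        p = sample_bleach_path(5, 0.0, 10, seed=0)
        assert np.array_equal(p.states, np.full(10, 5))

    def test_zero_initial_stays_zero(self):
        p = sample_bleach_path(0, 0.5, 10, seed=0, s_max=5)
        assert np.array_equal(p.states, np.zeros(10))

    def test_paths_are_non_increasing(self):
        for seed in range(20):
            p = sample_bleach_path(8, 0.1, 50, seed=seed, s_max=10)
            assert np.all(np.diff(p.states) <= 0)
            assert p.states[0] == 8

    def test_first_drop_matches_geometric_closed_form(self):
        # min of 3 iid geometric lifetimes ~ Geometric(1-(1-r)^3)
        r, n = 0.05, 3
        rng = np.random.default_rng(99)
        drops = []
        for _ in range(10_000):
            p = sample_bleach_path(n, r, 400, seed=rng)
            first = np.argmax(p.states < n)
            drops.append(first if p.states[-1] < n else 400)
        expected = 1.0 / (1.0 - (1.0 - r) ** n)
        assert np.mean(drops) == pytest.approx(expected, rel=0.05)

    def test_exceeding_s_max_raises(self):
        with pytest.raises(ValueError):
            sample_bleach_path(6, 0.1, 10, seed=0, s_max=5)


class TestDynamicPath:
    def test_identity_matrix_constant_path(self):
        P = np.eye(3)
        p = sample_dynamic_path(2, P, 50, seed=1, start_state=1)
        assert np.all(p.states == 1)

    def test_symmetric_two_state_occupancy(self):
        P = np.array([[0.5, 0.5], [0.5, 0.5]])
        p = sample_dynamic_path(1, P, 100_000, seed=3)
        occ = np.mean(p.states == 0)
        assert occ == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(100_000) * 2)

    def test_occupancy_matches_stationary_eigenvector(self):
        P = np.array([[0.8, 0.15, 0.05],
                      [0.10, 0.8, 0.10],
                      [0.05, 0.25, 0.7]])
        n = 200_000
        p = sample_dynamic_path(2, P, n, seed=5)
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi = pi / pi.sum()
        occ = np.bincount(p.states, minlength=3) / n
        # autocorrelated chain: allow 3 SE with a generous effective n
        se = np.sqrt(pi * (1 - pi) / (n / 10))
        assert np.all(np.abs(occ - pi) < 3 * se)

    def test_non_stochastic_matrix_rejected(self):
        P = np.array([[0.9, 0.2], [0.5, 0.5]])
        with pytest.raises(ValueError):
            sample_dynamic_path(1, P, 10, seed=0)


class TestBlinking:
    def test_zero_rate_identity(self):
        p = sample_bleach_path(5, 0.02, 100, seed=0, s_max=5)
        nm = NoiseModel(blink_rate=0.0)
        assert np.array_equal(apply_blinking(p, nm, seed=1), p.states)

    def test_all_zero_path_stays_dark(self):
        p = StatePath(np.zeros(50, dtype=int), s_max=3)
        nm = NoiseModel(blink_rate=0.3)
        assert np.array_equal(apply_blinking(p, nm, seed=1), np.zeros(50))

    def test_emitting_never_exceeds_nominal(self):
        p = sample_bleach_path(8, 0.01, 200, seed=2, s_max=10)
        nm = NoiseModel(blink_rate=0.2, blink_mean_duration=3)
        emit = apply_blinking(p, nm, seed=3)
        assert np.all(emit <= p.states)
        assert np.all(emit >= 0)

    def test_dark_fraction_matches_renewal_theory(self):
        # single always-on fluorophore: dark fraction = r*d/(1+r*d)
        r, d = 0.05, 4.0
        p = StatePath(np.ones(200_000, dtype=int), s_max=1)
        nm = NoiseModel(blink_rate=r, blink_mean_duration=d)
        emit = apply_blinking(p, nm, seed=4)
        expected = r * d / (1 + r * d)
        assert np.mean(emit == 0) == pytest.approx(expected, rel=0.05)


class TestRenderTrace:
    def test_noiseless_is_exact_linear_map(self):
        nm = NoiseModel(unit_intensity=100.0, gaussian_sd=0.0,
                        shot_noise=False, blink_rate=0.0)
        tr = render_trace(np.array([2, 1, 0]), nm, seed=0)
        assert np.array_equal(tr.intensities, [200.0, 100.0, 0.0])

    def test_shot_noise_variance(self):
        nm = NoiseModel(unit_intensity=100.0, gaussian_sd=0.0,
                        shot_noise=True, blink_rate=0.0)
        counts = np.full(100_000, 3)
        tr = render_trace(counts, nm, seed=1)
        assert tr.intensities.var() == pytest.approx(300.0, rel=0.05)
        assert tr.intensities.mean() == pytest.approx(300.0, rel=0.01)

    def test_variance_additivity(self):
        nm = NoiseModel(unit_intensity=100.0, gaussian_sd=20.0,
                        shot_noise=True, blink_rate=0.0)
        tr = render_trace(np.full(100_000, 2), nm, seed=2)
        assert tr.intensities.var() == pytest.approx(200.0 + 400.0, rel=0.05)


class TestAsnr:
    def test_two_state_hand_value(self):
        assert compute_asnr([0, 1], [1, 1]) == pytest.approx(1.0)

    def test_three_state_hand_value(self):
        assert compute_asnr([2, 6, 10], [1, 1, 1]) == pytest.approx(4.0)

    def test_equal_means_zero(self):
        assert compute_asnr([5, 5, 5], [1, 2, 1]) == 0.0

    def test_single_state_rejected(self):
        with pytest.raises(ValueError):
            compute_asnr([1.0], [1.0])

    @given(c=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, c):
        mu = np.array([0.0, 1.0, 3.0, 7.0])
        sd = np.array([0.5, 1.0, 2.0, 1.5])
        base = compute_asnr(mu, sd)
        assert compute_asnr(c * mu, c * sd) == pytest.approx(base, rel=1e-9)


class TestCalibration:
    def test_closed_form_without_shot_noise(self):
        nm = NoiseModel(unit_intensity=1.0, shot_noise=False)
        for a in (0.5, 1.0, 3.0):
            assert calibrate_noise_for_asnr(a, nm, 10) == pytest.approx(1 / a)

    @pytest.mark.parametrize("target", [0.5, 1.0, 1.69, 2.98, 5.0])
    def test_round_trip_within_one_percent(self, target):
        nm = NoiseModel(unit_intensity=100.0, shot_noise=True)
        sigma = calibrate_noise_for_asnr(target, nm, 10)
        n = np.arange(11)
        sds = np.sqrt(n * 100.0 + sigma**2)
        assert compute_asnr(n * 100.0, sds) == pytest.approx(target, rel=0.01)

    def test_target_above_shot_floor_infeasible(self):
        nm = NoiseModel(unit_intensity=100.0, shot_noise=True)
        with pytest.raises(sim.CalibrationInfeasibleError):
            calibrate_noise_for_asnr(1000.0, nm, 10)


class TestSynthesizeDataset:
    def test_equal_mix_gives_equal_class_counts(self):
        ds = synthesize_dataset("photobleach", s_max=10, n_traces=1000,
                                n_frames=60, target_asnr=2.98, seed=0)
        init = np.array([r.path.states[0] for r in ds.records])
        counts = np.bincount(init, minlength=11)[1:]
        assert np.all(counts == 100)

    def test_same_seed_bit_identical(self):
        a = synthesize_dataset("photobleach", 10, 50, 80, 2.0, seed=9)
        b = synthesize_dataset("photobleach", 10, 50, 80, 2.0, seed=9)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.trace.intensities, rb.trace.intensities)
            assert np.array_equal(ra.path.states, rb.path.states)
            assert ra.split == rb.split

    def test_split_largest_remainder(self):
        ds = synthesize_dataset("photobleach", 10, 20, 60, 2.0,
                                split=(0.7, 0.15, 0.15), seed=1)
        tags = [r.split for r in ds.records]
        assert (tags.count("train"), tags.count("val"),
                tags.count("test")) == (14, 3, 3)

    def test_achieved_asnr_near_target(self):
        ds = synthesize_dataset("photobleach", 10, 300, 200, 2.98, seed=3)
        assert ds.achieved_asnr == pytest.approx(2.98, rel=0.1)

    def test_dynamic_mode_visits_active_states(self):
        ds = synthesize_dataset("dynamic", 5, 100, 100, 3.0, seed=4)
        states = np.concatenate([r.path.states for r in ds.records])
        assert set(np.unique(states)) == set(range(1, 6))

    def test_min_steps_excludes_zero_step_traces(self):
        ds = synthesize_dataset("photobleach", 10, 200, 100, 2.0, seed=5,
                                state_mix=np.r_[0, [0.25] * 4, [0] * 5],
                                min_steps=1)
        steps = [r.path.states[0] - r.path.states[-1] for r in ds.records]
        assert min(steps) >= 1


class TestUnitIntensity:
    def test_identical_samples_recovered(self):
        v = fit_unit_intensity(np.full(100, 42.0), n_components=1)
        assert v == pytest.approx(42.0, abs=1e-6)

    def test_single_gaussian_mle(self, rng):
        x = rng.normal(100, 10, size=10_000)
        v = fit_unit_intensity(x, n_components=1)
        assert v == pytest.approx(100.0, abs=0.5)

    def test_two_component_mixture(self, rng):
        x = np.concatenate([rng.normal(100, 8, 5000),
                            rng.normal(200, 8, 5000)])
        v = fit_unit_intensity(x, n_components=2)
        assert v == pytest.approx(100.0, rel=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_unit_intensity(np.ones(15), n_components=2)
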