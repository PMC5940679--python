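"""Tests for the three-population FLIP kinetic model and its inference."""

import math

import numpy as np
import pytest

from osmochrom.flip import (
    HYPO_PRESET,
    ISO_PRESET,
    FLIPProtocol,
    FLIPTrace,
    PolIIKineticModel,
    TriExpFit,
    TriExponentialDecay,
    compare_half_lives,
    fit_triexponential,
    half_life,
    population_fractions,
    simulate_flip,
)


class TestModelValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PolIIKineticModel(0.5, 0.3, 0.3, 0.01, 0.001)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            PolIIKineticModel(-0.1, 0.6, 0.5, 0.01, 0.001)

    def test_rate_ordering_enforced(self):
        # the initiation-bound pool must exchange faster than the engaged one
        with pytest.raises(ValueError, match="k_init_off > k_elong_off"):
            PolIIKineticModel(0.4, 0.3, 0.3, 0.001, 0.01)

    def test_protocol_bounds(self):
        with pytest.raises(ValueError):
            FLIPProtocol(bleach_fraction=1.0)
        with pytest.raises(ValueError):
            FLIPProtocol(pulse_interval=10.0, duration=5.0)


class TestSimulation:
    def test_free_pool_halves_per_pulse(self):
        # a perfectly mixed free pool loses the bleached fraction at each pulse
        model = PolIIKineticModel(1.0, 0.0, 0.0, 0.01, 0.0)
        trace = simulate_flip(model)
        n = np.arange(len(trace))
        np.testing.assert_allclose(trace.intensities, 0.5**n, rtol=1e-12)

    def test_locked_elongating_pool_is_constant(self):
        model = PolIIKineticModel(0.0, 0.0, 1.0, 0.01, 0.0)
        trace = simulate_flip(model)
        np.testing.assert_allclose(trace.intensities, 1.0, atol=1e-12)

    def test_first_intensity_exactly_one_before_noise(self):
        for noise in (0.0, 0.01):
            trace = simulate_flip(ISO_PRESET, noise_sd=noise, seed=5)
            assert trace.intensities[0] == 1.0

    def test_trace_monotone_without_noise(self):
        trace = simulate_flip(ISO_PRESET)
        assert np.all(np.diff(trace.intensities) <= 1e-12)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_flip(ISO_PRESET, noise_sd=-0.01)

    def test_finite_mixing_approaches_complete_for_fast_exchange(self):
        fast = PolIIKineticModel(0.4, 0.3, 0.3, 0.01, 0.001, mixing=100.0)
        complete = PolIIKineticModel(0.4, 0.3, 0.3, 0.01, 0.001, mixing="complete")
        yf = simulate_flip(fast).intensities
        yc = simulate_flip(complete).intensities
        np.testing.assert_allclose(yf, yc, atol=5e-3)

    def test_slow_mixing_retards_the_decay(self):
        slow = PolIIKineticModel(1.0, 0.0, 0.0, 0.01, 0.0, mixing=0.05)
        ys = simulate_flip(slow).intensities
        yc = simulate_flip(PolIIKineticModel(1.0, 0.0, 0.0, 0.01, 0.0)).intensities
        assert ys[1:20].min() > yc[1:20].min()

    def test_stochastic_matches_deterministic_within_3_se(self):
        # per-molecule Monte Carlo and the compartment expectation must agree
        n = 10_000
        det = simulate_flip(ISO_PRESET).intensities
        sto = simulate_flip(ISO_PRESET, mode="stochastic", n_molecules=n, seed=2).intensities
        n_unbleached = n * 0.5
        se = np.sqrt(det * (1 - det) / n_unbleached) + det / math.sqrt(n_unbleached)
        assert np.all(np.abs(sto - det) <= 3 * se + 1e-9)

    def test_seeded_reproducibility(self):
        a = simulate_flip(ISO_PRESET, noise_sd=0.01, seed=7).intensities
        b = simulate_flip(ISO_PRESET, noise_sd=0.01, seed=7).intensities
        np.testing.assert_array_equal(a, b)


class TestTriexponentialFit:
    def test_exact_recovery_from_closed_form_samples(self):
        t = np.arange(0, 901, 5.0)
        true_a, true_r = np.array([0.5, 0.3, 0.2]), np.array([0.1, 0.01, 0.0005])
        y = (true_a[:, None] * np.exp(-np.outer(true_r, t))).sum(axis=0)
        fit = fit_triexponential(FLIPTrace(t, y))
        np.testing.assert_allclose(fit.amplitudes, true_a, rtol=1e-4)
        np.testing.assert_allclose(fit.rates, true_r, rtol=1e-4)
        assert fit.r_squared > 1 - 1e-12

    def test_single_exponential_is_a_nested_solution(self):
        t = np.arange(0, 901, 5.0)
        y = np.exp(-0.01 * t)
        fit = fit_triexponential(FLIPTrace(t, y))
        amps = np.sort(fit.amplitudes)
        assert amps[:2].sum() <= 1e-6
        assert abs(amps[2] - 1.0) < 1e-6

    def test_rates_sorted_descending(self):
        trace = simulate_flip(ISO_PRESET, noise_sd=0.01, seed=3)
        fit = fit_triexponential(trace)
        assert fit.rates[0] >= fit.rates[1] >= fit.rates[2] >= 0

    def test_too_few_points_rejected(self):
        t = np.arange(0, 50, 5.0)
        with pytest.raises(ValueError, match="12 points"):
            fit_triexponential(FLIPTrace(t, np.exp(-0.01 * t)))

    def test_simulate_fit_round_trip_recovers_model(self):
        # spec'd example: f=(0.4,0.3,0.3), k_init=0.01/s, k_elong=ln2/960 s
        trace = simulate_flip(ISO_PRESET)
        fit = fit_triexponential(trace)
        fracs = population_fractions(fit)
        assert abs(fracs[1] - 0.3) < 0.02 and abs(fracs[2] - 0.3) < 0.02
        assert abs(half_life(fit.rates[2]) - 16.0) / 16.0 < 0.05

    def test_slowest_rate_converges_to_k_elong_off_at_low_noise(self):
        trace = simulate_flip(ISO_PRESET, noise_sd=0.001, seed=11)
        fit = fit_triexponential(trace)
        assert abs(fit.rates[2] - ISO_PRESET.k_elong_off) / ISO_PRESET.k_elong_off < 0.05

    def test_sklearn_estimator_contract(self):
        est = TriExponentialDecay(n_starts=10, random_state=0)
        assert est.get_params()["n_starts"] == 10
        trace = simulate_flip(ISO_PRESET, noise_sd=0.01, seed=1)
        est.fit(trace.times.reshape(-1, 1), trace.intensities)
        pred = est.predict(trace.times)
        assert pred.shape == trace.intensities.shape
        assert est.r_squared_ > 0.99


class TestDerivedQuantities:
    def test_population_fractions_are_amplitude_shares(self):
        fit = TriExpFit((0.5, 0.3, 0.2), (0.1, 0.01, 0.001), 1.0, 0.0)
        assert population_fractions(fit) == pytest.approx((0.5, 0.3, 0.2))
        fit_eq = TriExpFit((0.2, 0.2, 0.2), (0.1, 0.01, 0.001), 1.0, 0.0)
        assert population_fractions(fit_eq) == pytest.approx((1 / 3,) * 3)

    def test_zero_amplitudes_rejected(self):
        fit = TriExpFit((0.0, 0.0, 0.0), (0.1, 0.01, 0.001), 0.0, 0.0)
        with pytest.raises(ValueError, match="zero"):
            population_fractions(fit)

    @pytest.mark.parametrize(
        "rate, minutes",
        [(math.log(2), 1 / 60), (math.log(2) / 960, 16.0), (math.log(2) / 8400, 140.0)],
    )
    def test_half_life_closed_form(self, rate, minutes):
        assert half_life(rate) == pytest.approx(minutes)

    def test_half_life_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError):
            half_life(0.0)

    def test_fit_json_round_trip(self):
        fit = TriExpFit((0.5, 0.3, 0.2), (0.1, 0.01, 0.001), 0.999, 1e-4)
        assert TriExpFit.from_json(fit.to_json()) == fit


class TestGroupComparison:
    @staticmethod
    def _group_fits(model, noise, seeds):
        return [
            fit_triexponential(simulate_flip(model, noise_sd=noise, seed=s), seed=s)
            for s in seeds
        ]

    def test_identical_groups_have_zero_difference(self):
        fits = self._group_fits(ISO_PRESET, 0.0, [1, 2])
        comp = compare_half_lives(fits, fits)
        assert comp.difference == pytest.approx(0.0)

    def test_iso_vs_hypo_gap_recovered(self):
        iso = self._group_fits(ISO_PRESET, 0.01, range(10))
        hypo = self._group_fits(HYPO_PRESET, 0.002, range(10, 20))
        comp = compare_half_lives(hypo, iso)
        true_gap = 140.0 - 16.0
        assert abs(comp.difference - true_gap) / true_gap < 0.25
        assert comp.p_value < 0.05

    def test_single_fit_group_rejected(self):
        fits = self._group_fits(ISO_PRESET, 0.0, [1, 2])
        with pytest.raises(ValueError, match="at least 2"):
            compare_half_lives(fits[:1], fits)
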