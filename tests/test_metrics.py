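"""Rate estimation, bandwidth selection, CF, KL, synchrony, logistic map."""

import numpy as np
import pytest

from ffnprop.lif_network import weight_for_psp
from ffnprop.metrics import (
    RateTrace,
    bandwidth_cost,
    coding_fraction,
    delay_compensate,
    detect_synchrony,
    fidelity,
    instantaneous_rate,
    kl_divergence_rates,
    logistic_map,
    optimal_kernel_width,
    synchrony_spike_threshold,
)


def poisson_spikes(rate_fn, duration, dt, seed):
    """Inhomogeneous Poisson spikes on the dt grid by thinning."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt)
    lam = rate_fn(t) * dt * 1e-3
    return t[rng.random(len(t)) < lam]


class TestInstantaneousRate:
    def test_no_spikes_gives_zero_trace(self):
        r = instantaneous_rate(np.array([]), 25.0, duration=1_000.0)
        np.testing.assert_array_equal(r.values, 0.0)

    @pytest.mark.parametrize("width", [5.0, 25.0, 100.0])
    def test_rate_mass_equals_spike_count(self, width):
        # unit-area kernel: integral of rate * n_neurons returns the count
        rng = np.random.default_rng(4)
        spikes = np.sort(rng.uniform(2_000.0, 18_000.0, 500))
        r = instantaneous_rate(spikes, width, dt=0.1, n_neurons=7,
                               duration=20_000.0)
        mass = r.values.sum() * r.dt * 1e-3 * r.n_neurons
        assert mass == pytest.approx(500, rel=0.01)

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            instantaneous_rate(np.array([1.0]), 0.0)


class TestBandwidthSelection:
    def test_cost_matches_brute_force_pair_sum(self):
        # O(n^2) oracle on a small grid-aligned spike set
        rng = np.random.default_rng(9)
        spikes = np.sort(rng.integers(0, 20_000, 300)) * 0.1
        for w in (2.0, 10.0, 40.0):
            d = spikes[:, None] - spikes[None, :]
            k2 = np.exp(-(d**2) / (4 * w * w)) / (2 * np.sqrt(np.pi) * w)
            k1 = np.exp(-(d**2) / (2 * w * w)) / (np.sqrt(2 * np.pi) * w)
            off = ~np.eye(len(spikes), dtype=bool)
            brute = k2.sum() - 2 * k1[off].sum()
            assert bandwidth_cost(spikes, w) == pytest.approx(brute, rel=1e-9)

    def test_fast_modulation_needs_narrower_kernel(self):
        fast = poisson_spikes(
            lambda t: 400 * (1 + np.sin(2 * np.pi * t / 20.0)), 30_000.0, 0.1, 1
        )
        slow = poisson_spikes(
            lambda t: 400 * (1 + np.sin(2 * np.pi * t / 800.0)), 30_000.0, 0.1, 2
        )
        assert optimal_kernel_width(fast) < optimal_kernel_width(slow)

    def test_requires_two_spikes(self):
        with pytest.raises(ValueError):
            optimal_kernel_width(np.array([5.0]))


class TestDelayCompensation:
    def test_identical_traces_need_no_shift(self):
        rng = np.random.default_rng(3)
        v = np.abs(rng.standard_normal(20_000)) + 1
        r = RateTrace(v, 0.1, 25.0, 1)
        shift, a, b = delay_compensate(r, r)
        assert shift == 0.0
        np.testing.assert_array_equal(a.values, b.values)

    def test_recovers_constructed_three_ms_shift_exactly(self):
        rng = np.random.default_rng(5)
        base = np.convolve(rng.standard_normal(30_000), np.ones(200) / 200,
                           mode="same") + 5
        lag = 30  # 3 ms at dt=0.1
        r1 = RateTrace(base[lag:], 0.1, 25.0, 1)
        r2 = RateTrace(base[:-lag], 0.1, 25.0, 1)
        shift, _, aligned = delay_compensate(r1, r2, max_lag=10.0)
        assert shift == pytest.approx(3.0, abs=1e-12)
        np.testing.assert_allclose(aligned.values, r1.values[: len(aligned.values)])

    def test_rejects_excessive_lag_window(self):
        r = RateTrace(np.ones(100), 0.1, 25.0, 1)
        with pytest.raises(ValueError):
            delay_compensate(r, r, max_lag=6.0)


class TestCodingFraction:
    def test_perfect_transmission_is_one(self):
        r = RateTrace(np.random.default_rng(0).random(1000) + 1, 0.1, 25.0, 1)
        assert coding_fraction(r, r) == pytest.approx(1.0, abs=1e-12)

    def test_doubled_trace_scores_zero(self):
        v = np.random.default_rng(1).random(1000) + 1
        r1 = RateTrace(v, 0.1, 25.0, 1)
        r2 = RateTrace(2 * v, 0.1, 25.0, 1)
        assert coding_fraction(r1, r2) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(2)
        a = RateTrace(rng.random(500) + 1, 0.1, 25.0, 1)
        b = RateTrace(rng.random(500) + 1, 0.1, 25.0, 1)
        cf = coding_fraction(a, b)
        a3 = RateTrace(3 * a.values, 0.1, 25.0, 1)
        b3 = RateTrace(3 * b.values, 0.1, 25.0, 1)
        assert coding_fraction(a3, b3) == pytest.approx(cf, rel=1e-12)

    def test_zero_reference_is_undefined(self):
        z = RateTrace(np.zeros(100), 0.1, 25.0, 1)
        with pytest.raises(ValueError):
            coding_fraction(z, z)


class TestKLDivergence:
    def test_self_divergence_vanishes(self):
        rng = np.random.default_rng(6)
        r = RateTrace(rng.gamma(4.0, 2.0, 20_000), 0.1, 25.0, 1)
        assert kl_divergence_rates(r, r) < 1e-6

    def test_unit_shifted_gaussians_give_half_nat(self):
        # closed form: KL(N(1,1) || N(0,1)) = 0.5
        rng = np.random.default_rng(7)
        r1 = RateTrace(rng.standard_normal(40_000), 0.1, 25.0, 1)
        r2 = RateTrace(rng.standard_normal(40_000) + 1.0, 0.1, 25.0, 1)
        kl = kl_divergence_rates(r2, r1)  # D(P_r2 || P_r1) convention
        assert kl == pytest.approx(0.5, abs=0.08)

    def test_kde_estimate_converges_with_sample_size(self):
        rng = np.random.default_rng(8)
        errs = []
        for n in (1_000, 100_000):
            a = RateTrace(rng.standard_normal(n), 0.1, 25.0, 1)
            b = RateTrace(rng.standard_normal(n) + 1.0, 0.1, 25.0, 1)
            errs.append(abs(kl_divergence_rates(b, a) - 0.5))
        assert errs[1] < errs[0]

    def test_nonnegative_on_arbitrary_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = RateTrace(rng.gamma(2, 3, 5_000), 0.1, 25.0, 1)
            b = RateTrace(rng.gamma(5, 1, 5_000), 0.1, 25.0, 1)
            assert kl_divergence_rates(a, b) >= 0.0

    def test_constant_trace_is_degenerate(self):
        c = RateTrace(np.full(1000, 2.0), 0.1, 25.0, 1)
        r = RateTrace(np.random.default_rng(0).random(1000), 0.1, 25.0, 1)
        with pytest.raises(ValueError):
            kl_divergence_rates(c, r)


class TestSynchrony:
    def test_spike_threshold_for_half_millivolt_psp(self, lif, kernel):
        # 0.5 mV per spike: 41 spikes needed to exceed 20 mV
        w = weight_for_psp(0.5, lif, kernel)
        assert synchrony_spike_threshold(w, lif, kernel) == 41

    def test_sparse_raster_has_no_events(self, lif, kernel):
        w = weight_for_psp(0.5, lif, kernel)
        spikes = np.arange(0.0, 1_000.0, 50.0)  # far below 41 per 10 ms
        assert detect_synchrony(spikes, w, lif, kernel) == 0

    def test_burst_counts_as_single_merged_event(self, lif, kernel):
        w = weight_for_psp(0.5, lif, kernel)
        burst = np.linspace(500.0, 501.0, 60)  # 60 spikes in 1 ms
        spikes = np.concatenate([np.arange(0, 400.0, 40.0), burst])
        assert detect_synchrony(np.sort(spikes), w, lif, kernel,
                                duration=1_000.0) == 1

    def test_event_count_monotone_in_spike_threshold(self, lif, kernel):
        rng = np.random.default_rng(10)
        spikes = np.sort(rng.uniform(0, 10_000.0, 3_000))
        weak = weight_for_psp(0.3, lif, kernel)   # high n*
        strong = weight_for_psp(1.2, lif, kernel)  # low n*
        assert (
            detect_synchrony(spikes, strong, lif, kernel, duration=10_000.0)
            >= detect_synchrony(spikes, weak, lif, kernel, duration=10_000.0)
        )

    def test_zero_weight_rejected(self, lif, kernel):
        with pytest.raises(ValueError):
            detect_synchrony(np.array([1.0]), 0.0, lif, kernel)


class TestLogisticMap:
    def test_identity_input_lies_on_diagonal(self):
        v = np.random.default_rng(11).uniform(0, 30, 10_000)
        centers, means = logistic_map(v, v, bin_width=2.0)
        np.testing.assert_allclose(means, centers, atol=0.6)

    def test_matches_group_by_average_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 10, 5_000)
        y = 2 * x + rng.standard_normal(5_000)
        centers, means = logistic_map(x, y, bin_width=1.0)
        for c, m in zip(centers, means):
            sel = (x >= c - 0.5) & (x < c + 0.5)
            assert m == pytest.approx(y[sel].mean(), rel=1e-9)

    def test_empty_bins_are_omitted(self):
        x = np.array([0.5, 0.6, 5.5])
        y = np.array([1.0, 2.0, 3.0])
        centers, means = logistic_map(x, y, bin_width=1.0)
        np.testing.assert_allclose(centers, [0.5, 5.5])
        np.testing.assert_allclose(means, [1.5, 3.0])


class TestFidelity:
    def test_delayed_copy_recovers_high_cf(self):
        rng = np.random.default_rng(13)
        base = np.convolve(rng.standard_normal(60_000), np.ones(500) / 500,
                           mode="same") + 5
        lag = 30
        r1 = RateTrace(base[lag:], 0.1, 2.0, 1)
        r2 = RateTrace(base[:-lag], 0.1, 2.0, 1)
        res = fidelity(r1, r2, max_lag=10.0)
        assert res.delay_shift == pytest.approx(3.0, abs=1e-12)
        assert res.cf > 0.999
        assert res.kl < 1e-3
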