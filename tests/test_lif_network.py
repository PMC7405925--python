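"""LIF dynamics, synaptic kernel, PSPs and network wiring."""

import numpy as np
import pytest

import ffnprop as fp
from ffnprop.lif_network import (
    LIFParams,
    NetworkConfig,
    SpikeRaster,
    build_synapse_kernel,
    draw_delays,
    psp_amplitude,
    simulate_lif,
    synaptic_drive,
    weight_for_psp,
)
from ffnprop.stimuli import SignalTrace


class TestSingleNeuron:
    def test_rests_at_leak_potential_without_input(self, lif):
        trace = SignalTrace(np.zeros(10_000), lif.dt)
        v, spikes = simulate_lif(lif, trace)
        np.testing.assert_allclose(v, lif.e_l, atol=1e-9)
        assert len(spikes) == 0

    @pytest.mark.parametrize("ri", [35.0, 40.0, 45.0, 50.0, 55.0, 60.0])
    def test_constant_drive_isi_matches_closed_form(self, lif, ri):
        # tau_V * ln((E_L + RI - V_reset)/(E_L + RI - V_th)), from the exact
        # solution of the leaky integrator between reset and threshold
        trace = SignalTrace(np.full(20_000, ri), lif.dt)
        _, spikes = simulate_lif(lif, trace)
        isi = np.diff(spikes)[1:]  # first interval starts from rest, skip
        expected = lif.tau_v * np.log(
            (lif.e_l + ri - lif.v_reset) / (lif.e_l + ri - lif.v_th)
        )
        assert np.all(np.abs(isi - expected) <= lif.dt + 1e-12)

    def test_rejects_nan_input_and_mismatched_dt(self, lif):
        with pytest.raises(ValueError):
            simulate_lif(lif, SignalTrace(np.full(10, 1.0), dt=0.2))
        bad = SignalTrace(np.zeros(10), lif.dt)
        bad.values[3] = np.nan
        with pytest.raises(ValueError):
            simulate_lif(lif, bad)

    def test_spike_count_stable_under_dt_refinement(self):
        # halving dt changes layer-1 spike counts by < 2%
        counts = {}
        for dt in (0.1, 0.05):
            lif = LIFParams(dt=dt)
            kernel = build_synapse_kernel(dt=dt)
            stim = fp.generate_ou(
                fp.OUParams(mean=16.0, std=15.0, tau=50.0, dt=dt), 30_000.0, seed=31
            )
            cfg = NetworkConfig(n_layers=1, n_per_layer=200, noise_std=30.0)
            raster = fp.simulate_ffn(cfg, stim, lif, kernel, master_seed=32)
            counts[dt] = raster.spike_count(0)
        assert abs(counts[0.1] - counts[0.05]) / counts[0.05] < 0.02


class TestSynapseKernel:
    def test_peak_position_matches_analytic_argmax(self, kernel):
        t_star = (0.5 * 5.0 / (5.0 - 0.5)) * np.log(5.0 / 0.5)
        assert kernel.peak_time == pytest.approx(t_star, abs=1e-12)
        k_peak_idx = np.argmax(kernel.samples)
        assert k_peak_idx * kernel.dt == pytest.approx(t_star, abs=kernel.dt)

    def test_unit_peak_and_nonnegative(self, kernel):
        assert kernel.samples.max() == pytest.approx(1.0, abs=1e-12)
        assert np.all(kernel.samples >= 0)

    def test_rejects_degenerate_time_constants(self):
        with pytest.raises(ValueError):
            build_synapse_kernel(tau_rise=5.0, tau_fall=5.0)
        with pytest.raises(ValueError):
            build_synapse_kernel(tau_rise=6.0, tau_fall=5.0)

    def test_apply_matches_fir_convolution(self, kernel):
        rng = np.random.default_rng(0)
        x = np.zeros(4000)
        x[rng.integers(0, 2000, 20)] += rng.uniform(0.5, 2.0, 20)
        iir = kernel.apply(x)
        fir = np.convolve(x, kernel.samples)[: len(x)]
        np.testing.assert_allclose(iir, fir, atol=1e-5)


class TestPSP:
    def test_zero_weight_zero_psp(self, lif, kernel):
        assert psp_amplitude(0.0, lif, kernel) == 0.0

    def test_linearity_against_direct_simulation(self, lif, kernel):
        # oracle: two independent passive-membrane simulations
        pad = np.zeros(1000)
        for w in (0.5, 1.7):
            cur = SignalTrace(np.concatenate([w * kernel.samples, pad]), lif.dt)
            v, _ = simulate_lif(lif, cur, threshold=False)
            direct = v.max() - lif.e_l
            assert psp_amplitude(w, lif, kernel) == pytest.approx(direct, rel=1e-12)
        assert psp_amplitude(2.4, lif, kernel) == pytest.approx(
            2 * psp_amplitude(1.2, lif, kernel), rel=1e-12
        )

    def test_fixed_weight_baseline_round_trip(self, lif, kernel):
        # the "fixed weights" baseline: the weight whose PSP is 0.5 mV
        w = weight_for_psp(0.5, lif, kernel)
        assert psp_amplitude(w, lif, kernel) == pytest.approx(0.5, rel=1e-12)
        # membrane filtering makes the PSP smaller than the peak current
        assert psp_amplitude(1.0, lif, kernel) < 1.0


class TestNetwork:
    def test_silent_downstream_without_weights_or_noise(self, lif, kernel):
        stim = fp.generate_ou(
            fp.OUParams(mean=16.0, std=15.0, tau=50.0, dt=lif.dt), 2_000.0, seed=1
        )
        cfg = NetworkConfig(
            n_layers=3, n_per_layer=20, weight_mean=0.0, weight_std=0.0,
            noise_std=0.0, layer1_noise=False,
        )
        raster = fp.simulate_ffn(cfg, stim, lif, kernel, master_seed=5)
        assert raster.spike_count(0) > 0  # suprathreshold mean drive
        assert raster.spike_count(1) == 0
        assert raster.spike_count(2) == 0

    def test_rejects_negative_weights(self, lif, kernel):
        stim = fp.generate_ou(
            fp.OUParams(mean=16.0, std=15.0, tau=50.0, dt=lif.dt), 500.0, seed=1
        )
        cfg = NetworkConfig(n_layers=2, n_per_layer=3, noise_std=0.0)
        w = np.full((3, 3), -0.1)
        with pytest.raises(ValueError, match="negative"):
            fp.simulate_ffn(cfg, stim, lif, kernel, weights=[w], master_seed=0)

    def test_synaptic_drive_equals_brute_force_on_toy_network(self, lif, kernel):
        # 3 presynaptic neurons, hand-summed kernel contributions
        n_steps = 3000
        spike_steps = np.array([100, 400, 401, 900], dtype=np.int64)
        spike_ids = np.array([0, 1, 2, 0], dtype=np.int64)
        w = np.array([[0.5], [1.0], [2.0]])
        delay_steps = np.array([[30], [40], [50]], dtype=np.int64)
        drive = synaptic_drive(spike_steps, spike_ids, w, delay_steps, n_steps, kernel)
        expected = np.zeros(n_steps)
        for s, i in zip(spike_steps, spike_ids):
            t0 = s + delay_steps[i, 0]
            seg = kernel.samples[: n_steps - t0]
            expected[t0 : t0 + len(seg)] += w[i, 0] * seg
        np.testing.assert_allclose(drive[0], expected, atol=1e-5)

    def test_delay_mean_shifts_population_response(self, lif, kernel):
        # identical runs except delay_mean 3 vs 6 ms: the cross-correlation
        # argmax between layer rates must shift by exactly the 3 ms difference
        from ffnprop.metrics import delay_compensate, instantaneous_rate

        stim = fp.generate_ou(
            fp.OUParams(mean=16.0, std=15.0, tau=50.0, dt=lif.dt), 20_000.0, seed=8
        )
        shifts = {}
        for dmean in (3.0, 6.0):
            cfg = NetworkConfig(
                n_layers=2, n_per_layer=100, weight_mean=0.55, weight_std=0.1,
                delay_mean=dmean, delay_std=0.0, noise_std=30.0,
            )
            raster = fp.simulate_ffn(cfg, stim, lif, kernel, master_seed=9)
            # narrow 5 ms smoothing keeps the cross-correlation peak sharp
            r1 = instantaneous_rate(raster.spike_times(0), 5.0, lif.dt, 100,
                                    duration=20_000.0)
            r2 = instantaneous_rate(raster.spike_times(1), 5.0, lif.dt, 100,
                                    duration=20_000.0)
            shifts[dmean], _, _ = delay_compensate(r1, r2, max_lag=25.0)
        assert shifts[6.0] - shifts[3.0] == pytest.approx(3.0, abs=0.3)

    def test_layer1_firing_is_asynchronous_under_independent_noise(self, lif, kernel):
        # no stimulus: pairwise spike-count correlations vanish
        stim = SignalTrace(np.zeros(300_000), lif.dt)
        cfg = NetworkConfig(n_layers=1, n_per_layer=60, noise_std=35.0)
        raster = fp.simulate_ffn(cfg, stim, lif, kernel, master_seed=77)
        times, ids = raster.layers[0]
        bins = np.arange(0.0, 30_000.0 + 50.0, 50.0)
        counts = np.stack(
            [np.histogram(times[ids == i], bins)[0] for i in range(60)]
        )
        c = np.corrcoef(counts)
        off_diag = c[np.triu_indices(60, k=1)]
        assert abs(np.nanmean(off_diag)) < 0.01

    def test_same_master_seed_bit_identical(self, lif, kernel):
        stim = fp.generate_ou(
            fp.OUParams(mean=16.0, std=15.0, tau=50.0, dt=lif.dt), 3_000.0, seed=2
        )
        cfg = NetworkConfig(
            n_layers=2, n_per_layer=30, weight_mean=0.5, weight_std=0.2,
            delay_std=0.5, noise_std=30.0,
        )
        a = fp.simulate_ffn(cfg, stim, lif, kernel, master_seed=13)
        b = fp.simulate_ffn(cfg, stim, lif, kernel, master_seed=13)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la[0], lb[0])
            np.testing.assert_array_equal(la[1], lb[1])

    def test_delays_strictly_positive_and_deterministic(self):
        rng = np.random.default_rng(0)
        d = draw_delays(50, 50, mean=3.0, std=1.5, rng=rng)
        assert (d > 0).all()
        d0 = draw_delays(4, 4, mean=3.0, std=0.0, rng=rng)
        np.testing.assert_array_equal(d0, 3.0)

    def test_raster_tsv_round_trip(self, tmp_path, lif, kernel):
        stim = fp.generate_ou(
            fp.OUParams(mean=16.0, std=15.0, tau=50.0, dt=lif.dt), 1_000.0, seed=3
        )
        cfg = NetworkConfig(n_layers=2, n_per_layer=10, weight_mean=0.5,
                            noise_std=30.0)
        raster = fp.simulate_ffn(cfg, stim, lif, kernel, master_seed=4)
        path = tmp_path / "raster.tsv"
        raster.to_tsv(path)
        back = SpikeRaster.from_tsv(path, 10, 1_000.0, lif.dt)
        assert back.n_layers == raster.n_layers
        for la, lb in zip(raster.layers, back.layers):
            np.testing.assert_allclose(np.sort(la[0]), np.sort(lb[0]), atol=1e-3)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_layers=0, n_per_layer=10)
        with pytest.raises(ValueError):
            NetworkConfig(n_layers=2, n_per_layer=10, delay_mean=0.0)
        with pytest.raises(ValueError):
            NetworkConfig(n_layers=2, n_per_layer=10, weight_mean=-1.0)
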