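"""Leaky integrate-and-fire neurons and the all-to-all feedforward network.

The membrane obeys

    tau_V dV/dt = -(V - E_L) + R * I_inj

with a spike emitted when V crosses V_th and the voltage reset on the next
step.  Default constants: E_L = -70 mV, tau_V = 10 ms, V_th = -40 mV,
reset -90 mV, R numerically 1 so stated input units map one-to-one onto mV
of drive.  There is no refractory period.

Synaptic currents are weighted, delayed copies of presynaptic spike trains
convolved with a shared double-exponential waveform (rise 0.5 ms, fall
5 ms, normalized to unit peak).  Each (pre, post) connection carries a
fixed transmission delay drawn once from a Gaussian (mean 3 ms), modeling
unequal axonal distances; every neuron additionally receives independent
Ornstein-Uhlenbeck background noise (time constant 5 ms, zero mean).

First-layer neurons are driven by the shared slow stimulus plus their own
background noise; deeper layers by the summed synaptic input plus noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _core
from .stimuli import SignalTrace

__all__ = [
    "LIFParams",
    "SynapseKernel",
    "NetworkConfig",
    "SpikeRaster",
    "build_synapse_kernel",
    "simulate_lif",
    "simulate_ffn",
    "psp_amplitude",
    "weight_for_psp",
    "draw_delays",
]

#: post-synaptic neurons are simulated in blocks of this size to bound the
#: memory of the dense drive matrix (n_steps x block)
NEURON_BLOCK = 128

#: relative amplitude below which the sampled synaptic waveform is truncated
KERNEL_TRUNCATION = 1e-6


@dataclass(frozen=True)
class LIFParams:
    """Membrane constants of the leaky integrate-and-fire neuron."""

    e_l: float = -70.0      # resting potential, mV
    r: float = 1.0          # input resistance; numerically 1 (units -> mV)
    tau_v: float = 10.0     # membrane time constant, ms
    v_th: float = -40.0     # spike threshold, mV
    v_reset: float = -90.0  # post-spike reset, mV
    dt: float = 0.1         # integration step, ms

    def __post_init__(self) -> None:
        if self.tau_v <= 0:
            raise ValueError("tau_v must be > 0")
        if self.v_reset >= self.v_th:
            raise ValueError("require v_reset < v_th")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass(frozen=True)
class SynapseKernel:
    """Unit-peak double-exponential synaptic waveform.

    ``samples[k]`` is the waveform at ``k * dt`` ms, truncated once it has
    decayed below ``KERNEL_TRUNCATION`` of the peak.  ``apply`` convolves a
    signal with the *untruncated* waveform using an exact pair of first-order
    recursive filters (the double exponential is a difference of two
    geometric impulse responses), which agrees with FIR convolution by
    ``samples`` to the truncation tolerance while costing O(T) per signal.
    """

    tau_rise: float
    tau_fall: float
    dt: float
    samples: np.ndarray = field(repr=False)
    peak_time: float
    _peak_unscaled: float = field(repr=False)

    def apply(self, x: np.ndarray, axis: int = -1) -> np.ndarray:
        """Convolve ``x`` (impulse amplitudes per time bin) with the kernel.

        Time must run along the last axis (1-D signals are fine).
        """
        if axis not in (-1, x.ndim - 1):
            raise ValueError("time must run along the last axis")
        pf = np.exp(-self.dt / self.tau_fall)
        pr = np.exp(-self.dt / self.tau_rise)
        return _core.double_exp_filter(x, pf, pr, 1.0 / self._peak_unscaled)

    @property
    def integral(self) -> float:
        """Time integral of the unit-peak waveform, ms."""
        return float(self.samples.sum() * self.dt)


def build_synapse_kernel(
    tau_rise: float = 0.5, tau_fall: float = 5.0, dt: float = 0.1
) -> SynapseKernel:
    """Sample the unit-peak double exponential e^(-t/tau_fall) - e^(-t/tau_rise).

    The analytic peak sits at t* = tau_r tau_f / (tau_f - tau_r) *
    ln(tau_f/tau_r); normalization uses the maximum over the sampling grid so
    that discrete convolution paths are exactly unit-peak.
    """
    if tau_rise <= 0 or tau_fall <= tau_rise:
        raise ValueError("require tau_fall > tau_rise > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    # length such that the slow exponential has decayed below truncation
    t_end = tau_fall * np.log(2.0 / KERNEL_TRUNCATION)
    t = np.arange(0.0, t_end, dt)
    u = np.exp(-t / tau_fall) - np.exp(-t / tau_rise)
    peak = float(u.max())
    keep = u >= KERNEL_TRUNCATION * peak
    # trim only the decayed tail (the initial sample u(0)=0 is kept)
    last = np.nonzero(keep)[0][-1]
    u = u[: last + 1]
    samples = u / peak
    t_star = tau_rise * tau_fall / (tau_fall - tau_rise) * np.log(tau_fall / tau_rise)
    return SynapseKernel(
        tau_rise=tau_rise,
        tau_fall=tau_fall,
        dt=dt,
        samples=samples,
        peak_time=t_star,
        _peak_unscaled=peak,
    )


def simulate_lif(
    params: LIFParams,
    input_current: SignalTrace,
    threshold: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a single LIF neuron driven by ``input_current``.

    Exponential-Euler update (exact for the linear leak between spikes);
    a spike is recorded when V >= V_th and the reset is applied on the
    following step.  With ``threshold=False`` the neuron integrates
    passively (used to measure subthreshold responses).

    Returns ``(membrane_trace_mv, spike_times_ms)``.
    """
    if input_current.dt != params.dt:
        raise ValueError(
            f"input dt {input_current.dt} != neuron dt {params.dt}"
        )
    current = input_current.values
    if not np.all(np.isfinite(current)):
        raise ValueError("input current contains non-finite values")
    alpha = np.exp(-params.dt / params.tau_v)
    v_inf = params.e_l + params.r * current
    n = len(current)
    v = np.empty(n)
    v_prev = params.e_l
    spikes = []
    reset_pending = False
    for k in range(n):
        if reset_pending:
            v_prev = params.v_reset
            reset_pending = False
        vk = v_inf[k] + (v_prev - v_inf[k]) * alpha
        v[k] = vk
        if threshold and vk >= params.v_th:
            spikes.append(k * params.dt)
            reset_pending = True
        v_prev = vk
    return v, np.asarray(spikes)


def psp_amplitude(
    weight: float, lif: LIFParams, kernel: SynapseKernel
) -> float:
    """Peak subthreshold membrane deflection (mV) from one presynaptic spike.

    Injects the current waveform ``weight * kernel`` into a quiescent neuron
    with the threshold disabled and reports the peak excursion above rest.
    Linear in ``weight`` because the subthreshold dynamics are linear.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if weight == 0:
        return 0.0
    pad = int(round(5 * lif.tau_v / lif.dt))
    current = np.concatenate([kernel.samples, np.zeros(pad)])
    trace = SignalTrace(values=current, dt=lif.dt)
    v, _ = simulate_lif(lif, trace, threshold=False)
    return float(weight * (v.max() - lif.e_l))


def weight_for_psp(
    psp_mv: float, lif: LIFParams, kernel: SynapseKernel
) -> float:
    """Synaptic weight whose single-spike PSP equals ``psp_mv`` millivolts."""
    return psp_mv / psp_amplitude(1.0, lif, kernel)


@dataclass(frozen=True)
class NetworkConfig:
    """Layered all-to-all feedforward topology and its statistical knobs."""

    n_layers: int
    n_per_layer: int
    weight_mean: float = 0.0
    weight_std: float = 0.0
    delay_mean: float = 3.0   # ms
    delay_std: float = 0.0    # ms
    noise_std: float = 0.0    # input units
    seed: int = 0
    layer1_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.n_per_layer < 1:
            raise ValueError("n_per_layer must be >= 1")
        if self.delay_mean <= 0:
            raise ValueError("delay_mean must be > 0")
        if self.delay_std < 0 or self.noise_std < 0 or self.weight_std < 0:
            raise ValueError("std parameters must be >= 0")
        if self.weight_mean < 0:
            raise ValueError("weight_mean must be >= 0 (excitatory network)")


@dataclass
class SpikeRaster:
    """Spike times per layer of the network.

    ``layers[l]`` is a pair ``(times_ms, neuron_ids)``, sorted by time.
    """

    layers: list[tuple[np.ndarray, np.ndarray]]
    n_neurons: int
    duration: float
    dt: float

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def spike_times(self, layer: int) -> np.ndarray:
        """Pooled spike times (ms) of one layer (0-based index)."""
        return self.layers[layer][0]

    def spike_count(self, layer: int) -> int:
        return len(self.layers[layer][0])

    def mean_rate(self, layer: int) -> float:
        """Mean single-neuron firing rate of a layer, Hz."""
        return self.spike_count(layer) / self.n_neurons / (self.duration / 1000.0)

    def to_tsv(self, path) -> None:
        """Write as TSV with columns layer, neuron_id, spike_time_ms."""
        with open(path, "w") as fh:
            fh.write("layer\tneuron_id\tspike_time_ms\n")
            for l, (times, ids) in enumerate(self.layers):
                for t, i in zip(times, ids):
                    fh.write(f"{l + 1}\t{i}\t{t:.4f}\n")

    @classmethod
    def from_tsv(cls, path, n_neurons: int, duration: float, dt: float) -> "SpikeRaster":
        data = np.loadtxt(path, skiprows=1)
        data = np.atleast_2d(data)
        layers = []
        if data.size:
            for l in range(1, int(data[:, 0].max()) + 1):
                sel = data[:, 0] == l
                layers.append(
                    (data[sel, 2].astype(float), data[sel, 1].astype(np.int32))
                )
        return cls(layers=layers, n_neurons=n_neurons, duration=duration, dt=dt)


def draw_delays(
    n_pre: int,
    n_post: int,
    mean: float,
    std: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-connection transmission delays ~ N(mean, std^2), truncated positive.

    Non-positive draws are resampled so every delay is strictly positive.
    """
    if std == 0:
        return np.full((n_pre, n_post), mean)
    d = rng.normal(mean, std, size=(n_pre, n_post))
    bad = d <= 0
    while bad.any():
        d[bad] = rng.normal(mean, std, size=int(bad.sum()))
        bad = d <= 0
    return d


def synaptic_drive(
    spike_steps: np.ndarray,
    spike_ids: np.ndarray,
    weights: np.ndarray,
    delay_steps: np.ndarray,
    n_steps: int,
    kernel: SynapseKernel,
) -> np.ndarray:
    """Summed synaptic input current to each postsynaptic neuron.

    ``out[j, t] = sum_i w[i, j] * (delayed spike train of i * kernel)(t)``
    in (neuron, time) layout so the kernel filtering and the integrator both
    stream contiguously.  Dense result; callers with large populations
    should pass column blocks of ``weights``/``delay_steps``.
    """
    impulses = _core.scatter_impulses(
        spike_steps, spike_ids, weights, delay_steps, n_steps
    )
    return kernel.apply(impulses, axis=1)


def simulate_ffn(
    config: NetworkConfig,
    stimulus: SignalTrace,
    lif: LIFParams,
    kernel: SynapseKernel,
    weights: list[np.ndarray] | None = None,
    master_seed: int | None = None,
) -> SpikeRaster:
    """Simulate the full feedforward network.

    Layer 1 receives the shared stimulus plus independent background noise;
    layer l > 1 receives the weighted, delayed, kernel-filtered spikes of
    layer l-1 plus independent background noise.

    Parameters
    ----------
    weights : list of (n_pre, n_post) arrays, optional
        One matrix per layer gap.  When omitted, matrices are drawn i.i.d.
        from N(weight_mean, weight_std^2) clipped at zero.
    master_seed : int, optional
        Overrides ``config.seed``.  Stimulus, weights, delays and every
        neuron's noise derive from independent child seeds, so the run is
        bit-reproducible and the factors can be varied independently.
    """
    if stimulus.dt != lif.dt or kernel.dt != lif.dt:
        raise ValueError("stimulus, neuron and kernel dt must agree")
    seed = config.seed if master_seed is None else master_seed
    root = np.random.SeedSequence(seed)
    c_weights, c_delays, c_noise = root.spawn(3)
    weight_children = c_weights.spawn(max(config.n_layers - 1, 1))
    delay_children = c_delays.spawn(max(config.n_layers - 1, 1))
    noise_children = c_noise.spawn(config.n_layers)

    n_steps = len(stimulus.values)
    n = config.n_per_layer

    if weights is not None:
        if len(weights) != config.n_layers - 1:
            raise ValueError("need one weight matrix per layer gap")
        for w in weights:
            w = np.asarray(w)
            if w.shape != (n, n):
                raise ValueError("weight matrix shape mismatch")
            if (w < 0).any():
                raise ValueError("negative synaptic weights in an excitatory network")

    layers: list[tuple[np.ndarray, np.ndarray]] = []

    # --- layer 1: shared stimulus + noise -------------------------------
    noise1 = config.noise_std if config.layer1_noise else 0.0
    steps, ids = _core.integrate_population(
        n_neurons=n,
        n_steps=n_steps,
        dt=lif.dt,
        tau_v=lif.tau_v,
        e_l=lif.e_l,
        v_th=lif.v_th,
        v_reset=lif.v_reset,
        shared_drive=lif.r * stimulus.values,
        per_neuron_drive=None,
        noise_std=noise1,
        noise_tau=5.0,
        seed=noise_children[0],
    )
    layers.append((steps * lif.dt, ids))
    prev_steps, prev_ids = steps, ids

    # --- deeper layers ---------------------------------------------------
    for gap in range(config.n_layers - 1):
        if weights is not None:
            w = np.asarray(weights[gap], dtype=np.float64)
        else:
            rng_w = np.random.default_rng(weight_children[gap])
            w = np.clip(rng_w.normal(config.weight_mean, config.weight_std, (n, n)), 0.0, None)
        rng_d = np.random.default_rng(delay_children[gap])
        delays = draw_delays(n, n, config.delay_mean, config.delay_std, rng_d)
        delay_steps = np.round(delays / lif.dt).astype(np.int64)

        block_seeds = noise_children[gap + 1].spawn(
            (n + NEURON_BLOCK - 1) // NEURON_BLOCK
        )
        all_steps: list[np.ndarray] = []
        all_ids: list[np.ndarray] = []
        for b, j0 in enumerate(range(0, n, NEURON_BLOCK)):
            j1 = min(j0 + NEURON_BLOCK, n)
            drive = synaptic_drive(
                prev_steps, prev_ids, w[:, j0:j1], delay_steps[:, j0:j1],
                n_steps, kernel,
            )
            drive *= lif.r
            s, i = _core.integrate_population(
                n_neurons=j1 - j0,
                n_steps=n_steps,
                dt=lif.dt,
                tau_v=lif.tau_v,
                e_l=lif.e_l,
                v_th=lif.v_th,
                v_reset=lif.v_reset,
                shared_drive=None,
                per_neuron_drive=drive,
                noise_std=config.noise_std,
                noise_tau=5.0,
                seed=block_seeds[b],
            )
            all_steps.append(s)
            all_ids.append(i + j0)
        steps = np.concatenate(all_steps)
        ids = np.concatenate(all_ids)
        order = np.lexsort((ids, steps))
        steps, ids = steps[order], ids[order]
        layers.append((steps * lif.dt, ids))
        prev_steps, prev_ids = steps, ids

    return SpikeRaster(
        layers=layers,
        n_neurons=n,
        duration=n_steps * lif.dt,
        dt=lif.dt,
    )
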