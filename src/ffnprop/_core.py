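"""Compiled inner loops for the network simulation.

The per-step, per-neuron work (membrane update, threshold test, OU noise
state update) and the synaptic impulse scatter with per-connection delays
are the only two hot spots of the pipeline; both are jitted here.  Noise
innovations are *consumed* inside the loop but *generated* outside it in
time-chunks by a numpy PCG64 generator, so seeding semantics stay entirely
in numpy land.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: steps per noise chunk handed to the jitted integrator (tuned for cache
#: friendliness; has no effect on results because the generator state is
#: carried across chunks)
CHUNK_STEPS = 50_000


@njit(cache=True)
def _integrate_chunk(
    z,          # (n, n_steps) standard-normal innovations
    shared,     # (n_steps,) drive common to all neurons (stimulus), may be zeros
    per,        # (n_per, n_steps) per-neuron drive (synaptic), n_per in {0, n}
    eta,        # (n,) OU noise state, updated in place
    v,          # (n,) membrane potential, updated in place
    refr,       # (n,) bool flag: spiked on previous step -> reset now
    alpha,      # exp(-dt/tau_v)
    phi,        # exp(-dt/tau_noise)
    sigma_step, # noise innovation scale
    e_l,
    v_th,
    v_reset,
    t0,         # absolute step index of chunk start
    out_steps,  # growing spike-step buffer
    out_ids,    # growing spike-neuron buffer
    n_spikes,
):
    n, n_steps = z.shape
    has_per = per.shape[0] == n
    cap = out_steps.shape[0]
    # neuron-outer loop keeps every time series contiguous in memory;
    # spikes come out grouped by neuron and are sorted by the caller
    for i in range(n):
        eta_i = eta[i]
        v_i = v[i]
        refr_i = refr[i]
        for t in range(n_steps):
            eta_i = eta_i * phi + sigma_step * z[i, t]
            drive = shared[t] + eta_i
            if has_per:
                drive += per[i, t]
            v_inf = e_l + drive
            if refr_i:
                v_i = v_reset
                refr_i = False
            else:
                v_i = v_inf + (v_i - v_inf) * alpha
            if v_i >= v_th:
                if n_spikes < cap:
                    out_steps[n_spikes] = t0 + t
                    out_ids[n_spikes] = i
                n_spikes += 1
                refr_i = True
        eta[i] = eta_i
        v[i] = v_i
        refr[i] = refr_i
    return n_spikes


@njit(cache=True)
def _scatter_impulses(
    spike_steps,  # (S,) presynaptic spike step indices
    spike_ids,    # (S,) presynaptic neuron indices
    weights_t,    # (n_post, n_pre), transposed for row locality
    delay_steps_t,  # (n_post, n_pre) integer delays in steps
    out,          # (n_post, n_steps) accumulated weighted impulses
):
    n_post = out.shape[0]
    n_steps = out.shape[1]
    n_spk = spike_steps.shape[0]
    # post-neuron-major: each iteration touches one output row and one
    # (n_pre)-sized weight/delay row that stays in L1
    for j in range(n_post):
        w_row = weights_t[j]
        d_row = delay_steps_t[j]
        o_row = out[j]
        for s in range(n_spk):
            ta = spike_steps[s] + d_row[spike_ids[s]]
            if ta < n_steps:
                o_row[ta] += w_row[spike_ids[s]]


@njit(cache=True)
def _double_exp_filter(x, out, p_fall, p_rise, scale):
    """Difference of two AR(1) filters along the last axis, times ``scale``.

    Impulse response: scale * (p_fall^k - p_rise^k), i.e. the sampled
    double-exponential synaptic waveform when scale = 1/peak.
    """
    n_rows, n_cols = x.shape
    for i in range(n_rows):
        sf = 0.0
        sr = 0.0
        for t in range(n_cols):
            sf = sf * p_fall + x[i, t]
            sr = sr * p_rise + x[i, t]
            out[i, t] = (sf - sr) * scale


def integrate_population(
    n_neurons: int,
    n_steps: int,
    dt: float,
    tau_v: float,
    e_l: float,
    v_th: float,
    v_reset: float,
    shared_drive: np.ndarray | None,
    per_neuron_drive: np.ndarray | None,
    noise_std: float,
    noise_tau: float,
    seed: int | np.random.SeedSequence,
    v0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``n_neurons`` independent LIF neurons for ``n_steps``.

    Exponential-Euler membrane update (exact for the linear leak between
    spikes); a spike is emitted when V >= V_th and the reset is applied on
    the following step.  Each neuron carries an independent OU noise state
    with exact discretization, seeded deterministically from ``seed``.
    ``per_neuron_drive`` uses (neuron, time) layout.

    Returns ``(spike_steps, spike_ids)`` as int64/int32 arrays sorted by
    time (and by neuron index within a step).
    """
    alpha = np.exp(-dt / tau_v)
    phi = np.exp(-dt / noise_tau)
    sigma_step = noise_std * np.sqrt(1.0 - phi * phi)

    if shared_drive is None:
        shared_drive = np.zeros(n_steps)
    shared_drive = np.ascontiguousarray(shared_drive, dtype=np.float64)
    if per_neuron_drive is None:
        per = np.zeros((0, n_steps))
    else:
        per = per_neuron_drive
        if per.shape != (n_neurons, n_steps):
            raise ValueError("per-neuron drive has wrong shape")

    # generous initial buffer; grown (with a full deterministic re-run from
    # the same seed) in the rare case a runaway-amplification regime fires
    # above the initial per-neuron rate allowance
    rate_cap_hz = 400.0
    while True:
        rng = np.random.default_rng(seed)
        v = np.full(n_neurons, e_l if v0 is None else v0, dtype=np.float64)
        # noise state starts in its stationary distribution
        eta = noise_std * rng.standard_normal(n_neurons)
        refr = np.zeros(n_neurons, dtype=np.bool_)

        cap = int(n_neurons * n_steps * dt / 1000.0 * rate_cap_hz) + 64
        out_steps = np.empty(cap, dtype=np.int64)
        out_ids = np.empty(cap, dtype=np.int32)
        n_spikes = 0

        for t0 in range(0, n_steps, CHUNK_STEPS):
            t1 = min(t0 + CHUNK_STEPS, n_steps)
            if noise_std > 0:
                z = rng.standard_normal((n_neurons, t1 - t0))
            else:
                z = np.zeros((n_neurons, t1 - t0))
            n_spikes = _integrate_chunk(
                z,
                shared_drive[t0:t1],
                per[:, t0:t1],
                eta,
                v,
                refr,
                alpha,
                phi,
                sigma_step,
                e_l,
                v_th,
                v_reset,
                t0,
                out_steps,
                out_ids,
                n_spikes,
            )
        if n_spikes <= cap:
            steps, ids = out_steps[:n_spikes], out_ids[:n_spikes]
            order = np.lexsort((ids, steps))
            return steps[order], ids[order]
        rate_cap_hz *= 4.0
        if rate_cap_hz > 1.0 / dt * 1000.0 * 4.0:
            raise RuntimeError("spike buffer overflow beyond the 1/dt rate bound")


def scatter_impulses(
    spike_steps: np.ndarray,
    spike_ids: np.ndarray,
    weights: np.ndarray,
    delay_steps: np.ndarray,
    n_steps: int,
) -> np.ndarray:
    """Weighted, delayed impulse trains seen by each postsynaptic neuron.

    ``out[j, t] = sum over presynaptic spikes (i, t_s) with
    t_s + delay_steps[i, j] == t of weights[i, j]``.  The (neuron, time)
    layout keeps the subsequent kernel filtering contiguous in time.
    Spikes delayed past the end of the window are dropped.
    """
    n_post = weights.shape[1]
    out = np.zeros((n_post, n_steps), dtype=np.float64)
    _scatter_impulses(
        np.ascontiguousarray(spike_steps, dtype=np.int64),
        np.ascontiguousarray(spike_ids, dtype=np.int64),
        np.ascontiguousarray(weights.T, dtype=np.float64),
        np.ascontiguousarray(delay_steps.T, dtype=np.int64),
        out,
    )
    return out


def double_exp_filter(
    x: np.ndarray, p_fall: float, p_rise: float, scale: float
) -> np.ndarray:
    """Convolve rows of ``x`` with the discrete double-exponential kernel."""
    x2 = np.ascontiguousarray(np.atleast_2d(x), dtype=np.float64)
    out = np.empty_like(x2)
    _double_exp_filter(x2, out, p_fall, p_rise, scale)
    return out.reshape(x.shape)
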