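"""Optimal synaptic weights by stimulus reconstruction.

The network's synaptic weights are not free parameters: they are estimated
from a reduced, vectorized view of the first layer.  Writing rho_i for the
spike train of layer-1 neuron i and k for the unit-peak synaptic waveform,
the input a second-layer neuron would receive is

    s_hat(t) = sum_i w_i (rho_i * k)(t)

and the optimal weight vector minimizes the L2 reconstruction error
|| s - s_hat ||_2 subject to w >= 0 (the network is purely excitatory),
i.e. a non-negative least-squares problem.  The mean and standard deviation
of the fitted vector then parameterize a Gaussian from which all deeper
all-to-all weight matrices are drawn.

The NNLS is solved in Gram form: with A the (time x neuron) design matrix,
G = A'A = R'R (Cholesky) and c = A's, the minimizer of ||Aw - s|| equals
the minimizer of ||Rw - R^(-T)c||, a small square problem independent of
the trace length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .lif_network import LIFParams, SpikeRaster, SynapseKernel, psp_amplitude
from .stimuli import SignalTrace

__all__ = [
    "WeightEstimate",
    "reconstruct_stimulus",
    "estimate_optimal_weights",
    "draw_weight_matrix",
    "classify_psp_regime",
]

#: PSP bounds (mV per presynaptic spike) outside which synapses are judged
#: biologically unrealistic
PSP_WEAK_MV = 0.05
PSP_STRONG_MV = 1.5


@dataclass
class WeightEstimate:
    """Fitted per-neuron weight vector and its Gaussian summary."""

    weights: np.ndarray          # length-N, all >= 0
    weight_mean: float
    weight_std: float
    reconstruction_error: float  # attained L2 norm of the residual

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "weights": self.weights.tolist(),
                    "weight_mean": self.weight_mean,
                    "weight_std": self.weight_std,
                    "reconstruction_error": self.reconstruction_error,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "WeightEstimate":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(
            weights=np.asarray(d["weights"]),
            weight_mean=d["weight_mean"],
            weight_std=d["weight_std"],
            reconstruction_error=d["reconstruction_error"],
        )


def _spike_count_matrix(
    raster: SpikeRaster, layer: int, n_steps: int
) -> np.ndarray:
    """Dense (n_steps, N) matrix of per-bin spike counts."""
    times, ids = raster.layers[layer]
    steps = np.round(times / raster.dt).astype(np.int64)
    counts = np.zeros((n_steps, raster.n_neurons))
    np.add.at(counts, (steps, ids), 1.0)
    return counts


def _design_matrix(
    raster: SpikeRaster,
    kernel: SynapseKernel,
    n_steps: int,
    downsample: int,
    block: int = 64,
) -> np.ndarray:
    """Columns = per-neuron spike trains convolved with the kernel.

    Convolution runs on the simulation grid; rows are then decimated by
    ``downsample`` to keep the normal-equation products cheap.
    """
    n = raster.n_neurons
    rows = len(range(0, n_steps, downsample))
    a = np.empty((rows, n))
    times, ids = raster.layers[0]
    steps = np.round(times / raster.dt).astype(np.int64)
    for j0 in range(0, n, block):
        j1 = min(j0 + block, n)
        sel = (ids >= j0) & (ids < j1)
        counts = np.zeros((j1 - j0, n_steps))
        np.add.at(counts, (ids[sel] - j0, steps[sel]), 1.0)
        a[:, j0:j1] = kernel.apply(counts, axis=1)[:, ::downsample].T
    return a


def reconstruct_stimulus(
    weights: np.ndarray,
    raster_layer1: SpikeRaster,
    kernel: SynapseKernel,
    n_steps: int | None = None,
) -> SignalTrace:
    """Weighted kernel-smoothed sum of layer-1 spike trains, s_hat(t)."""
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != raster_layer1.n_neurons:
        raise ValueError(
            f"{len(weights)} weights for {raster_layer1.n_neurons} neurons"
        )
    if n_steps is None:
        n_steps = int(round(raster_layer1.duration / raster_layer1.dt))
    times, ids = raster_layer1.layers[0]
    steps = np.round(times / raster_layer1.dt).astype(np.int64)
    impulses = np.zeros(n_steps)
    np.add.at(impulses, steps, weights[ids])
    values = kernel.apply(impulses)
    return SignalTrace(values=values, dt=raster_layer1.dt)


def estimate_optimal_weights(
    raster_layer1: SpikeRaster,
    stimulus: SignalTrace,
    kernel: SynapseKernel,
    downsample: int = 10,
    nonnegative: bool = True,
) -> WeightEstimate:
    """Fit w = argmin_{w >= 0} || s - sum_i w_i (rho_i * k) ||_2.

    Parameters
    ----------
    downsample : int
        Row decimation of the design matrix before forming the normal
        equations (the kernel is built on the full simulation grid first,
        so no synaptic structure is lost).  The reported residual is on the
        decimated grid.
    nonnegative : bool
        If False, solve the unconstrained least-squares problem instead
        (for comparison; may return negative weights).
    """
    if raster_layer1.spike_count(0) == 0:
        raise ValueError(
            "layer-1 raster contains no spikes; cannot estimate weights "
            "(check noise level and stimulus drive)"
        )
    if stimulus.dt != raster_layer1.dt:
        raise ValueError("stimulus and raster dt mismatch")
    n_steps = len(stimulus.values)
    a = _design_matrix(raster_layer1, kernel, n_steps, downsample)
    s = stimulus.values[::downsample]

    g = a.T @ a
    c = a.T @ s
    ss = float(s @ s)
    n = g.shape[0]
    try:
        r_chol = scipy.linalg.cholesky(g, lower=False)
    except scipy.linalg.LinAlgError:
        lam = 1e-10 * (np.trace(g) / n + 1.0)
        warnings.warn(
            f"rank-deficient design matrix (silent neurons?); adding ridge "
            f"lambda={lam:.3e} to the normal equations",
            RuntimeWarning,
            stacklevel=2,
        )
        g = g + lam * np.eye(n)
        r_chol = scipy.linalg.cholesky(g, lower=False)

    b = scipy.linalg.solve_triangular(r_chol, c, trans="T")
    if nonnegative:
        w, _ = scipy.optimize.nnls(r_chol, b)
    else:
        w = scipy.linalg.solve_triangular(r_chol, b)
    resid_sq = ss - 2.0 * float(c @ w) + float(w @ g @ w)
    return WeightEstimate(
        weights=w,
        weight_mean=float(w.mean()),
        weight_std=float(w.std()),
        reconstruction_error=float(np.sqrt(max(resid_sq, 0.0))),
    )


def draw_weight_matrix(
    weight_mean: float,
    weight_std: float,
    n_pre: int,
    n_post: int,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """All-to-all weight matrix with i.i.d. N(mean, std^2) entries, clipped at 0."""
    if weight_mean < 0:
        raise ValueError("weight_mean must be >= 0")
    rng = np.random.default_rng(seed)
    w = rng.normal(weight_mean, weight_std, size=(n_pre, n_post))
    return np.clip(w, 0.0, None)


def classify_psp_regime(
    weight_mean: float, lif: LIFParams, kernel: SynapseKernel
) -> str:
    """Label the mean synapse as biologically plausible or not.

    Synapses whose single-spike PSP is below 0.05 mV are ``unrealistic-weak``
    and above 1.5 mV ``unrealistic-strong``; anything between is
    ``realistic``.
    """
    if weight_mean < 0:
        raise ValueError("weight_mean must be >= 0")
    psp = psp_amplitude(weight_mean, lif, kernel)
    if psp < PSP_WEAK_MV:
        return "unrealistic-weak"
    if psp > PSP_STRONG_MV:
        return "unrealistic-strong"
    return "realistic"
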