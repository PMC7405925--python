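"""Two-layer propagation scored with coding fraction and KL divergence.

The full recipe: estimate weights from a dedicated first-layer run, wire a
two-layer all-to-all network with Gaussian weights and 3 ms delays, then
compare the instantaneous firing rates of the layers after compensating
the transmission delay.
"""

import numpy as np

import ffnprop as fp
from ffnprop.experiments import STIMULUS_PARAMS
from ffnprop.experiments import estimate_weights_for

lif = fp.LIFParams()
kernel = fp.build_synapse_kernel(dt=lif.dt)
duration, n, sigma = 20_000.0, 200, 30.0

est = estimate_weights_for(n, sigma, duration, seed=21, lif=lif, kernel=kernel)
stim = fp.generate_ou(fp.OUParams(dt=lif.dt, **STIMULUS_PARAMS), duration, seed=22)
config = fp.NetworkConfig(
    n_layers=2, n_per_layer=n, weight_mean=est.weight_mean,
    weight_std=est.weight_std, noise_std=sigma,
)
raster = fp.simulate_ffn(config, stim, lif, kernel, master_seed=23)

r1 = fp.instantaneous_rate(raster.spike_times(0), 25.0, lif.dt, n, duration=duration)
r2 = fp.instantaneous_rate(raster.spike_times(1), 25.0, lif.dt, n, duration=duration)
res = fp.fidelity(r1, r2, sync_spike_times=raster.spike_times(1),
                  weight_mean=est.weight_mean, lif=lif, kernel=kernel)

print(f"layer rates        : {raster.mean_rate(0):.1f} -> {raster.mean_rate(1):.1f} Hz")
print(f"delay shift        : {res.delay_shift:.1f} ms")
print(f"coding fraction    : {res.cf:.3f}   (1 = perfect rate transmission)")
print(f"modulation CF      : {res.cf_mod:.3f}   (means removed; the discriminating form)")
print(f"KL divergence      : {res.kl:.3f} nats (0 = identical rate distributions)")
print(f"synchrony events   : {res.sync_event_count}")
print()
print("A high CF with low KL means the second layer's time-varying rate")
print("faithfully tracks the first layer's; synchrony events flag breakdowns")
print("of the asynchronous rate code.")
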