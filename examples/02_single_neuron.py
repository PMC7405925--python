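"""A single LIF neuron: closed-form spiking and postsynaptic potentials.

With a constant suprathreshold drive the interspike interval has an exact
solution; one synaptic kernel injection gives the PSP used to judge whether
estimated weights are biologically realistic.
"""

import numpy as np

import ffnprop as fp
from ffnprop.stimuli import SignalTrace

lif = fp.LIFParams()
kernel = fp.build_synapse_kernel(dt=lif.dt)

ri = 40.0  # constant drive, mV above rest
trace = SignalTrace(np.full(20_000, ri), lif.dt)
_, spikes = fp.simulate_lif(lif, trace)
isi = np.diff(spikes)[1:].mean()
closed = lif.tau_v * np.log((lif.e_l + ri - lif.v_reset) / (lif.e_l + ri - lif.v_th))
print(f"constant drive {ri} mV: mean ISI {isi:.2f} ms, closed form {closed:.2f} ms")

for w in (0.5, 1.0, 2.0):
    print(f"weight {w:.1f} -> PSP {fp.psp_amplitude(w, lif, kernel):.3f} mV")

w_fixed = fp.weight_for_psp(0.5, lif, kernel)
print(f"fixed-weight baseline (0.5 mV PSP): weight = {w_fixed:.3f}")
print(f"regime of that weight: {fp.classify_psp_regime(w_fixed, lif, kernel)}")
print()
print("PSPs scale linearly with the weight; 0.05-1.5 mV per spike counts as")
print("biologically realistic.")
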