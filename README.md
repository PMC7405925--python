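# ffnprop

Propagation of slowly time-varying firing rates through feedforward
networks of leaky integrate-and-fire neurons.

## The problem

Cortical information often travels as a *rate code*: the instantaneous
population firing rate tracks a slowly varying stimulus, and downstream
layers must reproduce that rate without collapsing into synchronous
volleys (a temporal code) or drifting to a fixed rate.  `ffnprop` is a
seeded, configurable pipeline for asking when that works.  It simulates a
layered, all-to-all excitatory feedforward network (FFN) of LIF neurons

    tau_V dV/dt = -(V - E_L) + R I_inj,        spike & reset at V_th,

driven in layer 1 by a shared slow Ornstein-Uhlenbeck stimulus
(tau = 50 ms) plus independent per-neuron OU background noise
(tau = 5 ms), with double-exponential synapses (rise 0.5 ms, fall 5 ms)
and Gaussian per-connection delays (mean 3 ms).  Synaptic weights are not
free parameters: they are fitted by non-negative least squares so that the
weighted, kernel-smoothed layer-1 spike trains reconstruct the stimulus,

    w = argmin_{w >= 0} || s - sum_i w_i (rho_i * k) ||_2,

and the fitted mean/std parameterize the deeper all-to-all weight
matrices.  Propagation fidelity between layers is scored by the coding
fraction CF = 1 - ||r2 - r1||_2 / ||r1||_2 on delay-compensated
instantaneous rates (reported both raw and on mean-subtracted rate
modulations), by the KL divergence between the layers' rate
distributions, and by counting synchrony events (10 ms windows whose
spikes would sum to > 20 mV of postsynaptic potential).

The package reproduces the study's main findings: transmission has an
interior optimum in background noise (std ~ 20-30 input units), weights
fitted for the wrong network size amplify or attenuate the signal layer by
layer, delay variability barely matters, and input rates of roughly
5-25 Hz cross five layers near-linearly.  See `docs/methods.md` for the
model conventions and the two places where printed source numbers could
not be reproduced as stated.

## Worked example

`examples/` holds one short script per capability (stimulus generation,
single-neuron checks, weight estimation, two-layer fidelity, bandwidth
selection, deep propagation).  For instance:

```bash
$ python examples/04_two_layer_fidelity.py
layer rates        : 19.0 -> 18.7 Hz
delay shift        : 10.6 ms
coding fraction    : 0.941   (1 = perfect rate transmission)
modulation CF      : 0.730   (means removed; the discriminating form)
KL divergence      : 0.032 nats (0 = identical rate distributions)
synchrony events   : 7
```

A 200-neuron, 20-s network at the noise optimum: the second layer arrives
~10.6 ms late (3 ms synaptic delay plus synaptic and membrane filtering),
but after compensation its rate tracks layer 1 closely — raw CF 0.94,
modulation CF 0.73, near-zero KL, and only a handful of synchrony events.

```bash
$ python examples/06_deep_propagation.py
weight summary: mean 0.657, std 0.180
per-layer mean rates: 18.3 17.9 17.6 17.3 17.2 Hz
CF layer 1 -> 2: 0.940
CF layer 1 -> 3: 0.912
CF layer 1 -> 4: 0.879
CF layer 1 -> 5: 0.838
```

Matched weights keep the mean rate and the rate modulation stable through
five layers; weight summaries borrowed from a 400- or 600-neuron fit
instead produce runaway amplification or die-out (see
`ffnprop.run_weight_misspecification`).

The experiment drivers (`run_size_noise_grid`, `run_background_calibration`,
`run_deep_propagation`, `run_delay_sweep`, `run_logistic_map`,
`run_weight_misspecification`) return pandas DataFrames and are fully
deterministic given a master seed; YAML run configs are supported via
`ffnprop.config`.

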