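"""YAML/JSON run configuration.

A config file carries the stimulus, noise, network and sweep blocks, e.g.::

    stimulus: {mean: 16.0, std: 15.0, tau_ms: 50.0, dt_ms: 0.1}
    noise:    {std: 30.0, tau_ms: 5.0}
    network:  {n_layers: 2, n_per_layer: 500, delay_mean_ms: 3.0, delay_std_ms: 0.0}
    sweep:
      sizes: [50, 100, 200, 300, 400, 500, 750, 1000]
      noise_stds: [5, 10, 15, 20, 25, 30, 35, 40]
      delay_stds: [0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5]
      duration_ms: 100000
      n_replicates: 5
      master_seed: 0

Unspecified fields fall back to the study defaults.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .experiments import SweepSpec
from .lif_network import LIFParams, NetworkConfig
from .stimuli import OUParams

__all__ = ["load_config", "sweep_from_config", "lif_from_config",
           "stimulus_params_from_config", "network_from_config"]


def load_config(path) -> dict:
    """Parse a YAML (or JSON) config file into a nested dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text) or {}


def stimulus_params_from_config(cfg: dict) -> OUParams:
    blk = cfg.get("stimulus", {})
    return OUParams(
        mean=blk.get("mean", 16.0),
        std=blk.get("std", 15.0),
        tau=blk.get("tau_ms", 50.0),
        dt=blk.get("dt_ms", 0.1),
    )


def lif_from_config(cfg: dict) -> LIFParams:
    blk = cfg.get("neuron", {})
    return LIFParams(
        e_l=blk.get("e_l_mv", -70.0),
        r=blk.get("r", 1.0),
        tau_v=blk.get("tau_v_ms", 10.0),
        v_th=blk.get("v_th_mv", -40.0),
        v_reset=blk.get("v_reset_mv", -90.0),
        dt=blk.get("dt_ms", cfg.get("stimulus", {}).get("dt_ms", 0.1)),
    )


def network_from_config(cfg: dict) -> NetworkConfig:
    blk = cfg.get("network", {})
    noise = cfg.get("noise", {})
    return NetworkConfig(
        n_layers=blk.get("n_layers", 2),
        n_per_layer=blk.get("n_per_layer", 500),
        weight_mean=blk.get("weight_mean", 0.0),
        weight_std=blk.get("weight_std", 0.0),
        delay_mean=blk.get("delay_mean_ms", 3.0),
        delay_std=blk.get("delay_std_ms", 0.0),
        noise_std=noise.get("std", 0.0),
        seed=blk.get("seed", 0),
        layer1_noise=blk.get("layer1_noise", True),
    )


def sweep_from_config(cfg: dict) -> SweepSpec:
    blk = cfg.get("sweep", {})
    spec = SweepSpec()
    return SweepSpec(
        sizes=blk.get("sizes", spec.sizes),
        noise_stds=blk.get("noise_stds", spec.noise_stds),
        delay_stds=blk.get("delay_stds", spec.delay_stds),
        n_layers=blk.get("n_layers", spec.n_layers),
        duration_ms=blk.get("duration_ms", spec.duration_ms),
        n_replicates=blk.get("n_replicates", spec.n_replicates),
        master_seed=blk.get("master_seed", spec.master_seed),
    )
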