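"""Ornstein-Uhlenbeck stimulus and background-noise generation.

Every input in this study is synthetic: a slow OU process (time constant
50 ms) plays the role of the sensory signal delivered to the first layer,
and fast, zero-mean OU processes (time constant 5 ms) model the background
synaptic noise injected independently into every neuron.

The OU process obeys

    dx/dt = -(x - mu)/tau + a * sqrt(2/tau) * xi(t)

with xi white Gaussian noise, so the stationary distribution is
N(mu, a^2) and the autocorrelation decays as exp(-lag/tau).  Sample paths
are generated with the exact transition-density update

    x(t+dt) = mu + (x(t) - mu) * exp(-dt/tau)
              + a * sqrt(1 - exp(-2 dt/tau)) * eta,   eta ~ N(0,1)

which reproduces the continuous-time first and second moments for any dt,
unlike Euler-Maruyama whose moments carry O(dt) bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = ["OUParams", "SignalTrace", "generate_ou", "generate_noise_bank"]

#: default integration step of the whole pipeline, ms
DEFAULT_DT = 0.1


@dataclass(frozen=True)
class OUParams:
    """Parameters of an Ornstein-Uhlenbeck process.

    Attributes
    ----------
    mean : float
        Stationary mean mu, in input units (the study's "pA").
    std : float
        Stationary standard deviation a, same units.
    tau : float
        Correlation time constant, ms.
    dt : float
        Sampling step, ms.  Must satisfy dt <= tau/10 so the discrete
        path resolves the correlation structure.
    """

    mean: float
    std: float
    tau: float
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError(f"std must be >= 0, got {self.std}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.dt > self.tau / 10:
            raise ValueError(
                f"dt={self.dt} ms too coarse for tau={self.tau} ms; "
                "require dt <= tau/10"
            )


@dataclass
class SignalTrace:
    """A discretized signal on a uniform time grid.

    ``values[k]`` is the signal at time ``k * dt`` ms.
    """

    values: np.ndarray
    dt: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("SignalTrace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SignalTrace contains non-finite values")

    @property
    def duration(self) -> float:
        """Trace duration in ms."""
        return len(self.values) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt

    def to_csv(self, path) -> None:
        """Write as two-column CSV (time_ms, value)."""
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            delimiter=",",
            header="time_ms,value",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "SignalTrace":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        t, v = arr[:, 0], arr[:, 1]
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(values=v, dt=dt)


def _exact_ou_path(
    params: OUParams, n_steps: int, rng: np.random.Generator, x0: float
) -> np.ndarray:
    """Exact-discretization OU sample path of length ``n_steps``.

    The AR(1) recursion is evaluated with a single IIR filter pass so long
    traces are generated at memory bandwidth rather than Python-loop speed.
    """
    phi = np.exp(-params.dt / params.tau)
    sigma_step = params.std * np.sqrt(1.0 - phi * phi)
    innov = sigma_step * rng.standard_normal(n_steps)
    innov[0] = x0 - params.mean  # path starts exactly at x0
    # y[n] = phi * y[n-1] + innov[n]  (y = x - mean)
    y = lfilter([1.0], [1.0, -phi], innov)
    return params.mean + y


def generate_ou(
    params: OUParams,
    duration: float,
    seed: int | np.random.SeedSequence,
    x0: float | str = "stationary",
) -> SignalTrace:
    """Generate one seeded OU sample path.

    Parameters
    ----------
    params : OUParams
    duration : float
        Trace length, ms.  Number of samples is ``round(duration/dt)``.
    seed : int or numpy SeedSequence
        Reproducibility handle; the same seed gives a bit-identical trace.
    x0 : float or "stationary"
        Initial value.  The default draws from the stationary distribution
        N(mean, std^2), which avoids any burn-in transient.

    Returns
    -------
    SignalTrace
    """
    if duration < params.dt:
        raise ValueError("duration must be at least one time step")
    n_steps = int(round(duration / params.dt))
    rng = np.random.default_rng(seed)
    if isinstance(x0, str):
        if x0 != "stationary":
            raise ValueError(f"unknown x0 mode {x0!r}")
        start = params.mean + params.std * rng.standard_normal()
    else:
        start = float(x0)
    values = _exact_ou_path(params, n_steps, rng, start)
    int_seed = seed if isinstance(seed, (int, np.integer)) else None
    return SignalTrace(values=values, dt=params.dt, seed=int_seed)


def generate_noise_bank(
    std: float,
    n_neurons: int,
    duration: float,
    dt: float = DEFAULT_DT,
    seed: int | np.random.SeedSequence = 0,
    tau: float = 5.0,
) -> list[SignalTrace]:
    """Independent zero-mean OU noise traces, one per neuron.

    Each neuron's trace uses a child seed spawned deterministically from the
    master seed, so traces are mutually independent yet fully reproducible.
    The zero mean reflects a balance of background excitatory and inhibitory
    input; the 5 ms default time constant is the standard fast-synaptic
    background value.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if std < 0:
        raise ValueError("std must be >= 0")
    params = OUParams(mean=0.0, std=std, tau=tau, dt=dt)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_neurons)
    return [generate_ou(params, duration, child, x0="stationary") for child in children]
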