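"""Doubly stochastic renewal (DSR) spike-train simulator.

A DSR point process is defined by a pair ``{g(.), lambda(t)}``: a renewal
interspike-interval (ISI) density ``g`` in operational time with unit mean,
and a stochastic instantaneous firing rate.  Spikes are generated per trial by
a three-step algorithm:

1. draw a realization ``lambda(t)`` of the rate process;
2. sample i.i.d. ISIs from ``g`` to place events in operational time, where
   the process is stationary renewal at 1 Hz;
3. map events to real time through the inverse cumulative rate
   ``t = Lambda^{-1}(t')`` with ``Lambda(t) = int_0^t lambda(s) ds``.

The ISI density is a gamma distribution parameterized by its squared
coefficient of variation ``phi`` (shape ``1/phi``, scale ``phi``), so a single
irregularity parameter spans sub-Poisson (``phi < 1``), Poisson (``phi = 1``,
exponential ISIs) and super-Poisson (``phi > 1``) spiking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .rate_models import RatePath, trial_rng

__all__ = [
    "ISIModel",
    "SpikeTrainSet",
    "OperationalMap",
    "cumulative_rate",
    "sample_operational_isis",
    "warp_to_real_time",
    "simulate_dsr",
    "simulate_inhomogeneous_poisson",
]

#: Default equilibrium burn-in, in operational seconds (= mean ISIs).  The
#: renewal process is started this long before the window so that the window
#: sees an (approximately) equilibrium renewal process rather than an ordinary
#: one with a spike pinned at the origin.
DEFAULT_BURN_IN = 10.0

#: Floor on sampled ISIs; gamma samples at very small phi can underflow to 0.
_ISI_FLOOR = 1e-9


@dataclass(frozen=True)
class ISIModel:
    """Renewal ISI density in operational time, unit mean.

    ``phi`` is the squared coefficient of variation of the density.  For the
    gamma family, shape ``k = 1/phi`` and scale ``theta = phi`` give mean
    ``k*theta = 1``, variance ``k*theta^2 = phi`` and third central moment
    ``2*k*theta^3 = 2*phi^2``.  ``phi = 1`` is the exponential density.
    """

    phi: float
    family: str = "gamma"

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.family not in ("gamma", "exponential"):
            raise ValueError("family must be 'gamma' or 'exponential'")
        if self.family == "exponential" and not np.isclose(self.phi, 1.0):
            raise ValueError("exponential family requires phi = 1")

    mu_g: float = 1.0

    @property
    def shape(self) -> float:
        return 1.0 / self.phi

    @property
    def scale(self) -> float:
        return self.phi

    @property
    def third_central_moment(self) -> float:
        return 2.0 * self.phi**2

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        isis = rng.gamma(self.shape, self.scale, size=n)
        return np.maximum(isis, _ISI_FLOOR)


@dataclass(frozen=True)
class SpikeTrainSet:
    """A collection of trials, each a sorted array of spike times in seconds."""

    trials: tuple
    t_start: float
    t_end: float
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        cleaned = []
        for k, st in enumerate(self.trials):
            st = np.asarray(st, dtype=float)
            if st.size and (np.any(np.diff(st) <= 0)):
                raise ValueError(f"trial {k}: spike times must be strictly increasing")
            if st.size and (st[0] < self.t_start - 1e-12 or st[-1] > self.t_end + 1e-12):
                raise ValueError(f"trial {k}: spike times outside [t_start, t_end]")
            cleaned.append(st)
        object.__setattr__(self, "trials", tuple(cleaned))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_spikes(self) -> int:
        return int(sum(st.size for st in self.trials))

    def mean_rate(self) -> float:
        """Grand-average firing rate (total spikes / total observed time), Hz."""
        return self.n_spikes / (self.n_trials * self.duration)


@dataclass(frozen=True)
class OperationalMap:
    """Cumulative rate Lambda(t) per trial on the rate time grid."""

    time_grid: np.ndarray
    Lambda: np.ndarray  # (n_trials, n_time), non-decreasing, Lambda[:, 0] = 0

    @property
    def total_mass(self) -> np.ndarray:
        return self.Lambda[:, -1]


def cumulative_rate(rate_path: RatePath) -> OperationalMap:
    """Trapezoidal cumulative integral of the rate, per trial."""
    Lam = cumulative_trapezoid(rate_path.rates, rate_path.time_grid, axis=1, initial=0.0)
    return OperationalMap(rate_path.time_grid, Lam)


def sample_operational_isis(
    isi_model: ISIModel,
    mass: float,
    seed_or_rng,
    equilibrium_burn_in: float = DEFAULT_BURN_IN,
) -> np.ndarray:
    """Sorted renewal event times in ``[0, mass]`` of operational time.

    The renewal process starts ``equilibrium_burn_in`` operational seconds
    before 0; events occurring before 0 are discarded, which removes the
    ordinary-renewal transient at the window start.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    total = mass + equilibrium_burn_in
    # Expected number of unit-mean ISIs to cover `total`, with margin.
    n_guess = int(total + 6.0 * np.sqrt(max(isi_model.phi * total, 1.0)) + 20)
    times = np.cumsum(isi_model.sample(n_guess, rng)) - equilibrium_burn_in
    while times[-1] < mass:
        extra = np.cumsum(isi_model.sample(n_guess, rng)) + times[-1]
        times = np.concatenate([times, extra])
    return times[(times >= 0.0) & (times <= mass)]


def warp_to_real_time(op_events: np.ndarray, op_map: OperationalMap, trial: int) -> np.ndarray:
    """Map operational-time events to real time by inverting Lambda.

    The inverse is computed by monotone linear interpolation of Lambda on its
    time grid.  Events beyond ``Lambda(t_end)`` are dropped (their count can be
    recovered from the input size).
    """
    Lam = op_map.Lambda[trial]
    keep = op_events <= Lam[-1]
    t = np.interp(op_events[keep], Lam, op_map.time_grid)
    # Flat segments of Lambda (zero rate) can map distinct operational events
    # to one grid time; enforce strict ordering at float resolution.
    if t.size > 1:
        t = np.maximum.accumulate(t)
        dup = np.diff(t) <= 0
        if dup.any():
            t[1:][dup] += np.cumsum(dup)[dup] * 1e-12
    return t


def simulate_dsr(
    isi_model: ISIModel,
    rate_path: RatePath,
    seed: int = 0,
    equilibrium_burn_in: float = DEFAULT_BURN_IN,
) -> SpikeTrainSet:
    """Generate a DSR spike-train set from ``{g(.), lambda(t)}``."""
    op_map = cumulative_rate(rate_path)
    trials = []
    for k in range(rate_path.n_trials):
        mass = float(op_map.total_mass[k])
        if mass <= 0:
            trials.append(np.empty(0))
            continue
        rng = trial_rng(seed, k, stream=3)
        events = sample_operational_isis(isi_model, mass, rng, equilibrium_burn_in)
        trials.append(warp_to_real_time(events, op_map, k))
    meta = {
        "generator": "dsr",
        "phi": isi_model.phi,
        "seed": seed,
        "rate_model": dict(rate_path.meta),
    }
    return SpikeTrainSet(
        tuple(trials), float(rate_path.time_grid[0]), float(rate_path.time_grid[-1]), meta
    )


def simulate_inhomogeneous_poisson(rate_path: RatePath, seed: int = 0) -> SpikeTrainSet:
    """Inhomogeneous Poisson spikes: the ``phi = 1`` special case of the DSR model."""
    out = simulate_dsr(ISIModel(phi=1.0), rate_path, seed=seed)
    out.metadata["generator"] = "poisson"
    return out
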