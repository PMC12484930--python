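"""Stochastic firing-rate processes.

The instantaneous firing rate :math:`\\lambda(t)` is the first stage of a
doubly stochastic renewal (DSR) generative model: each trial draws one
realization of the rate process, and spikes are then generated from that
realization by a renewal process in operational time (see
:mod:`dsrspike.simulator`).

Three rate families are provided:

* a constant rate (identical within and across trials),
* a rate constant within each trial but drawn uniformly across trials from
  ``[mu - w/2, mu + w/2]``,
* a drift--diffusion process with sticky boundaries, the classic
  decision-variable model.

All rates are in Hz and all times in seconds.  Per-trial random substreams
are derived deterministically from one root seed, so increasing ``n_trials``
extends the trial set without reshuffling earlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RatePath",
    "DriftDiffusionSpec",
    "UniformTrialRateSpec",
    "sample_constant_rate",
    "sample_uniform_trial_rates",
    "sample_drift_diffusion",
    "trial_rng",
]

#: Unit conversion: drift nu is given in Hz/ms, diffusion D in Hz^2/ms.
#: Internally the Euler--Maruyama step runs in seconds, so both are scaled
#: by 1000 (ms -> s) exactly once, here.
_MS_PER_S = 1000.0


def trial_rng(seed: int, trial: int, stream: int = 0) -> np.random.Generator:
    """Deterministic per-trial random substream.

    Uses ``SeedSequence(seed, spawn_key=(stream, trial))`` so that streams for
    different trials (and different consumers) never collide and are stable
    under changes of ``n_trials``.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, trial)))


@dataclass(frozen=True)
class RatePath:
    """Per-trial instantaneous firing rate on a common uniform time grid.

    Attributes
    ----------
    time_grid:
        Strictly increasing times (s) with a constant step.
    rates:
        Array of shape ``(n_trials, n_time)``, non-negative, in Hz.
    """

    time_grid: np.ndarray
    rates: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid, dtype=float)
        r = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time_grid must be 1-D with at least two points")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time_grid must be strictly increasing")
        # rounding of long float grids limits achievable uniformity to ~ulp(t_end)/dt
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time_grid step must be uniform")
        if r.shape[1] != t.size:
            raise ValueError("rates and time_grid have incompatible shapes")
        if np.any(r < 0) or not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite and non-negative")
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "rates", r)

    @property
    def n_trials(self) -> int:
        return self.rates.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time_grid[1] - self.time_grid[0])

    @property
    def duration(self) -> float:
        return float(self.time_grid[-1] - self.time_grid[0])


@dataclass(frozen=True)
class DriftDiffusionSpec:
    """Drift--diffusion rate model with sticky boundaries.

    Parameters follow the convention of decision-making models: drift ``nu``
    in Hz/ms, diffusion ``D`` in Hz^2/ms, boundaries ``b_l < b_u`` in Hz.
    Once a path reaches a boundary its derivative is zero, i.e. the boundary
    is absorbing.
    """

    nu: float = 0.0
    D: float = 9.0
    b_l: float = 1.0
    b_u: float = 60.0
    lambda0: float = 30.0

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("diffusion coefficient D must be >= 0")
        if not self.b_l < self.b_u:
            raise ValueError("require b_l < b_u")
        if not (self.b_l <= self.lambda0 <= self.b_u):
            raise ValueError("initial rate must lie within [b_l, b_u]")


# Fig-style presets for the two published drift--diffusion settings.
DDM_SLOW = DriftDiffusionSpec(nu=0.0, D=9.0, b_l=1.0, b_u=20.0, lambda0=10.0)
DDM_BENCH = DriftDiffusionSpec(nu=0.0138, D=9.0, b_l=1.0, b_u=60.0, lambda0=30.0)


@dataclass(frozen=True)
class UniformTrialRateSpec:
    """Rate constant within a trial, uniform on [mu - w/2, mu + w/2] across trials."""

    mu: float = 30.0
    w: float = 20.0

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("width w must be >= 0")
        if self.mu - self.w / 2 < 0:
            raise ValueError("mu - w/2 must be >= 0 (rates cannot be negative)")


def _grid(duration: float, dt: float) -> np.ndarray:
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt))
    return np.linspace(0.0, n * dt, n + 1)


def sample_constant_rate(rate: float, duration: float, dt: float = 1e-3, n_trials: int = 1) -> RatePath:
    """Flat rate, identical within and across trials."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    t = _grid(duration, dt)
    r = np.full((n_trials, t.size), float(rate))
    return RatePath(t, r, meta={"model": "constant", "rate": rate})


def sample_uniform_trial_rates(
    spec: UniformTrialRateSpec,
    duration: float,
    dt: float = 1e-3,
    n_trials: int = 1,
    seed: int = 0,
) -> RatePath:
    """Each trial flat in time at a level drawn uniformly across trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    t = _grid(duration, dt)
    levels = np.empty(n_trials)
    lo, hi = spec.mu - spec.w / 2, spec.mu + spec.w / 2
    for k in range(n_trials):
        levels[k] = trial_rng(seed, k, stream=1).uniform(lo, hi)
    r = np.repeat(levels[:, None], t.size, axis=1)
    return RatePath(t, r, meta={"model": "uniform", "mu": spec.mu, "w": spec.w, "seed": seed})


def sample_drift_diffusion(
    spec: DriftDiffusionSpec,
    duration: float,
    dt: float = 1e-3,
    n_trials: int = 1,
    seed: int = 0,
    sticky_reentry: bool = False,
) -> RatePath:
    """Euler--Maruyama paths of the sticky-boundary drift--diffusion rate.

    With ``sticky_reentry=False`` (default) a path that reaches a boundary is
    clamped there and frozen for the rest of the trial, implementing the
    boundary condition d(lambda)/dt = 0 at b_l and b_u literally.  With
    ``sticky_reentry=True`` paths are clipped to [b_l, b_u] each step but may
    re-enter the interior.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    t = _grid(duration, dt)
    n_steps = t.size - 1
    nu_s = spec.nu * _MS_PER_S          # Hz/s
    sigma = np.sqrt(2.0 * spec.D * _MS_PER_S)  # Hz/sqrt(s)
    out = np.empty((n_trials, t.size))
    for k in range(n_trials):
        rng = trial_rng(seed, k, stream=2)
        noise = sigma * np.sqrt(dt) * rng.standard_normal(n_steps)
        increments = nu_s * dt + noise
        if sticky_reentry:
            path = np.empty(t.size)
            lam = spec.lambda0
            path[0] = lam
            for i in range(n_steps):
                lam = min(max(lam + increments[i], spec.b_l), spec.b_u)
                path[i + 1] = lam
            out[k] = path
            continue
        # Absorbing boundary: until first passage the path equals the free
        # (unconstrained) path, after which it is frozen at the boundary hit.
        free = np.empty(t.size)
        free[0] = spec.lambda0
        free[1:] = spec.lambda0 + np.cumsum(increments)
        hit = (free <= spec.b_l) | (free >= spec.b_u)
        if hit.any():
            i0 = int(np.argmax(hit))
            level = spec.b_l if free[i0] <= spec.b_l else spec.b_u
            free[i0:] = level
        out[k] = free
    meta = {
        "model": "ddm",
        "nu": spec.nu,
        "D": spec.D,
        "b_l": spec.b_l,
        "b_u": spec.b_u,
        "lambda0": spec.lambda0,
        "seed": seed,
        "sticky_reentry": sticky_reentry,
    }
    return RatePath(t, out, meta=meta)
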