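"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from dsrspike import RatePath, SpikeTrainSet


def poisson_thinning(rate_path: RatePath, seed: int) -> SpikeTrainSet:
    """Inhomogeneous Poisson simulation by thinning.

    Independent of the renewal-based simulator: candidate events are drawn
    homogeneously at the per-trial maximum rate and kept with probability
    ``lambda(t)/lambda_max``.  Used only as a distributional oracle.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = rate_path.time_grid[0], rate_path.time_grid[-1]
    trials = []
    for k in range(rate_path.n_trials):
        lam_max = rate_path.rates[k].max()
        if lam_max <= 0:
            trials.append(np.empty(0))
            continue
        n = rng.poisson(lam_max * (t1 - t0))
        cand = np.sort(rng.uniform(t0, t1, size=n))
        lam = np.interp(cand, rate_path.time_grid, rate_path.rates[k])
        keep = rng.uniform(0, lam_max, size=n) < lam
        trials.append(cand[keep])
    return SpikeTrainSet(tuple(trials), float(t0), float(t1), {"generator": "thinning"})


def equilibrium_renewal_counts(
    phi: float, T: float, n: int, rng: np.random.Generator, burn_in: float = 20.0
) -> np.ndarray:
    """Counts of a unit-rate gamma renewal process in [0, T], equilibrium start.

    Brute-force oracle: each replicate runs its own renewal sequence started
    ``burn_in`` mean ISIs before the window.
    """
    total = T + burn_in
    m = int(total + 6 * np.sqrt(max(phi * total, 1.0)) + 30)
    isis = np.maximum(rng.gamma(1.0 / phi, phi, size=(n, m)), 1e-12)
    times = np.cumsum(isis, axis=1) - burn_in
    assert times[:, -1].min() > T, "oracle ISI buffer too short"
    return ((times >= 0.0) & (times <= T)).sum(axis=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_count_trials() -> SpikeTrainSet:
    """Three trials with 1, 2, 3 spikes in [0, 1): count mean 2, variance 1."""
    return SpikeTrainSet(
        (np.array([0.5]), np.array([0.2, 0.6]), np.array([0.1, 0.45, 0.8])), 0.0, 1.0
    )
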