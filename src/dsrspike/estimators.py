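"""Estimation of spiking irregularity and spike-count variance partitioning.

The observable on trial-structured data is the spike count ``N_T`` in bins of
size ``T``.  For a doubly stochastic renewal process whose rate varies slowly
relative to ``T``, the law of total variance splits the across-trial count
variance into a firing-rate component and a point-process component::

    Var(N_T) = Var(lambda*T) + phi*E[N_T] + (1/6)*(1 - phi^2) + O(1/T)

for a gamma ISI density with unit mean and squared coefficient of variation
``phi``.  Applying this relation at two bin sizes ``T`` and ``alpha*T``
eliminates the unknown rate variance and yields a quadratic in ``phi`` whose
coefficients are count moments measurable from data — the DSR estimator.

Two reference estimators are provided for comparison:

* DTR (deterministic time rescaling): rescale spikes by the trial-averaged
  rate (PSTH) and take the CV^2 of rescaled ISIs.  Unbiased only when the
  rate is identical on every trial; otherwise overestimates ``phi``.
* MR (minimum ratio): the minimum Fano factor over window positions.  Biased
  by the rate variance, bin size, and ``phi`` itself.

Exact renewal count moments and the closed-form MR error prediction are
included as analytic oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rate_models import RatePath
from .simulator import ISIModel, SpikeTrainSet

__all__ = [
    "CountStats",
    "PhiEstimate",
    "PartitionResult",
    "count_stats",
    "choose_bin_size",
    "dsr_phi_from_moments",
    "estimate_phi_dsr",
    "partition_variance",
    "estimate_phi_dtr",
    "estimate_phi_mr",
    "renewal_count_moments",
    "mr_error_prediction",
    "select_units",
    "modulation_index",
]


def _window(spikes: SpikeTrainSet, window) -> tuple:
    if window is None:
        return spikes.t_start, spikes.t_end
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window end must exceed window start")
    return lo, hi


@dataclass(frozen=True)
class CountStats:
    """Across-trial spike-count mean and unbiased variance per window position."""

    bin_size: float
    positions: np.ndarray      # left edges t_i; counts from [t_i, t_i + T)
    mean: np.ndarray
    variance: np.ndarray
    n_trials: int

    @property
    def fano(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.mean > 0, self.variance / self.mean, np.nan)


@dataclass(frozen=True)
class PhiEstimate:
    phi: float
    method: str
    bin_size: float
    n_valid_windows: int
    diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def valid(self) -> bool:
        return np.isfinite(self.phi) and self.n_valid_windows > 0


@dataclass(frozen=True)
class PartitionResult:
    """Per-window decomposition of Var(N_T) into rate and point-process parts."""

    positions: np.ndarray
    total_variance: np.ndarray
    rate_variance: np.ndarray        # Var(lambda*T), clipped at 0
    point_process_variance: np.ndarray
    phi: float
    bin_size: float
    diagnostics: dict = field(default_factory=dict, compare=False)


def _counts_matrix(spikes: SpikeTrainSet, edges_lo: np.ndarray, edges_hi: np.ndarray) -> np.ndarray:
    """Counts per trial (rows) in half-open bins [lo_i, hi_i)."""
    out = np.empty((spikes.n_trials, edges_lo.size), dtype=float)
    for k, st in enumerate(spikes.trials):
        out[k] = np.searchsorted(st, edges_hi, side="left") - np.searchsorted(
            st, edges_lo, side="left"
        )
    return out


def count_stats(
    spikes: SpikeTrainSet,
    T: float,
    stride: float | None = None,
    window=None,
) -> CountStats:
    """Across-trial count mean and unbiased (n-1) variance on a sliding grid.

    Window positions are ``t_i = lo, lo + stride, ...`` with
    ``t_i + T <= hi``; default stride is ``T/2``.
    """
    if T <= 0:
        raise ValueError("bin size T must be positive")
    if spikes.n_trials < 2:
        raise ValueError("count statistics require at least 2 trials")
    lo, hi = _window(spikes, window)
    if stride is None:
        stride = T / 2
    positions = np.arange(lo, hi - T + 1e-12, stride)
    if positions.size == 0:
        return CountStats(T, positions, np.empty(0), np.empty(0), spikes.n_trials)
    counts = _counts_matrix(spikes, positions, positions + T)
    return CountStats(
        T, positions, counts.mean(axis=0), counts.var(axis=0, ddof=1), spikes.n_trials
    )


def choose_bin_size(spikes: SpikeTrainSet, window=None, round_to: float = 1e-3) -> float:
    """Bin size ``T = 2 / E[lambda]`` from the grand-average rate in the window.

    ``T`` must exceed one mean ISI for the count-moment expansion to hold, yet
    be small enough that the rate is roughly constant within a bin; twice the
    mean ISI satisfies both.  Rounded to the nearest ``round_to`` (default the
    1 ms rate grid).
    """
    lo, hi = _window(spikes, window)
    total = sum(int(np.searchsorted(st, hi) - np.searchsorted(st, lo)) for st in spikes.trials)
    if total == 0:
        raise ValueError("no spikes in window; supply a bin size explicitly")
    rate = total / (spikes.n_trials * (hi - lo))
    T = 2.0 / rate
    return max(round(T / round_to), 1) * round_to


def dsr_phi_from_moments(
    mean_T: float,
    var_T: float,
    mean_aT: float,
    var_aT: float,
    alpha: float = 2.0,
) -> float:
    """Solve the two-bin-size quadratic for phi from exact or sample moments.

    The quadratic is::

        ((alpha^2-1)/6) phi^2 - (alpha^2 E[N_T] - E[N_aT]) phi
            + alpha^2 Var(N_T) - Var(N_aT) - (alpha^2-1)/6 = 0

    Returns the smaller (moment-stable) real root, or ``nan`` when the
    discriminant is negative.  With exact Poisson moments the roots are
    ``{1, 4m - 1}`` (for ``alpha = 2``): only the smaller root is stable as
    the mean count ``m`` varies, so that branch is always selected.  With
    noisy sample moments the stable branch can dip below zero; callers
    average roots across window positions and clip the final estimate at
    zero, which keeps the estimator continuous in the moments (jumping to the
    distant second root when the product of roots changes sign would create
    extreme positive outliers at small phi).
    """
    if alpha <= 1:
        raise ValueError("alpha must exceed 1")
    a = (alpha**2 - 1.0) / 6.0
    b = -(alpha**2 * mean_T - mean_aT)
    c = alpha**2 * var_T - var_aT - (alpha**2 - 1.0) / 6.0
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return np.nan
    sq = np.sqrt(disc)
    roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    return float(roots.min())


def estimate_phi_dsr(
    spikes: SpikeTrainSet,
    T: float | None = None,
    alpha: float = 2.0,
    stride: float | None = None,
    window=None,
) -> PhiEstimate:
    """DSR estimate of spiking irregularity from spike counts at two bin sizes.

    At each window position ``t_i`` the quadratic is solved from the
    across-trial moments of counts in ``[t_i, t_i + T)`` and
    ``[t_i, t_i + alpha*T)``; the estimate is the mean of the stable-branch
    roots over positions, clipped at zero.  Positions with a negative
    discriminant are dropped and reported in the diagnostics.
    """
    lo, hi = _window(spikes, window)
    if T is None:
        T = choose_bin_size(spikes, window=(lo, hi))
    if stride is None:
        stride = T / 2
    positions = np.arange(lo, hi - alpha * T + 1e-12, stride)
    diagnostics = {"n_positions": int(positions.size), "n_discriminant_failures": 0, "n_negative_roots": 0}
    if positions.size == 0:
        diagnostics["reason"] = "window shorter than alpha*T"
        return PhiEstimate(np.nan, "DSR", T, 0, diagnostics)
    c_small = _counts_matrix(spikes, positions, positions + T)
    c_big = _counts_matrix(spikes, positions, positions + alpha * T)
    roots = []
    for i in range(positions.size):
        phi_i = dsr_phi_from_moments(
            c_small[:, i].mean(),
            c_small[:, i].var(ddof=1),
            c_big[:, i].mean(),
            c_big[:, i].var(ddof=1),
            alpha,
        )
        if np.isnan(phi_i):
            diagnostics["n_discriminant_failures"] += 1
        else:
            if phi_i < 0:
                diagnostics["n_negative_roots"] += 1
            roots.append(phi_i)
    if not roots:
        return PhiEstimate(np.nan, "DSR", T, 0, diagnostics)
    phi = max(float(np.mean(roots)), 0.0)
    return PhiEstimate(phi, "DSR", T, len(roots), diagnostics)


def partition_variance(
    spikes: SpikeTrainSet,
    phi: float,
    T: float,
    stride: float | None = None,
    window=None,
) -> PartitionResult:
    """Split Var(N_T) into firing-rate and point-process components.

    The rate component is ``Var(N_T) - phi*E[N_T] - (1/6)(1 - phi^2)``
    (gamma ISI density); negative estimates are clipped to zero with the raw
    values retained in the diagnostics.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    cs = count_stats(spikes, T, stride=stride, window=window)
    point = phi * cs.mean + (1.0 - phi**2) / 6.0
    raw_rate = cs.variance - point
    return PartitionResult(
        cs.positions,
        cs.variance,
        np.maximum(raw_rate, 0.0),
        point,
        phi,
        T,
        diagnostics={"raw_rate_variance": raw_rate},
    )


def estimate_phi_dtr(
    spikes: SpikeTrainSet,
    psth_window: float = 0.06,
    psth_step: float = 0.01,
    rate_floor: float = 0.1,
    window=None,
) -> PhiEstimate:
    """Deterministic-time-rescaling estimate of irregularity.

    The trial-averaged rate is estimated with a sliding-window PSTH
    (60 ms window, 10 ms increments by default), each trial's spikes are
    rescaled by its cumulative integral, and the estimate is the CV^2 of the
    pooled within-trial rescaled ISIs.  PSTH values are floored at
    ``rate_floor`` (Hz) so the cumulative map stays invertible.
    """
    if spikes.n_trials < 2:
        raise ValueError("DTR requires at least 2 trials")
    lo, hi = _window(spikes, window)
    centers = np.arange(lo + psth_window / 2, hi - psth_window / 2 + 1e-12, psth_step)
    if centers.size < 2:
        raise ValueError("window too short for the PSTH")
    counts = _counts_matrix(spikes, centers - psth_window / 2, centers + psth_window / 2)
    psth = counts.mean(axis=0) / psth_window
    n_floored = int(np.sum(psth < rate_floor))
    psth = np.maximum(psth, rate_floor)
    # extend to the window edges with constant rate for integration
    grid = np.concatenate([[lo], centers, [hi]])
    rate = np.concatenate([[psth[0]], psth, [psth[-1]]])
    Lam = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(grid))])
    isis = []
    for st in spikes.trials:
        st = st[(st >= lo) & (st <= hi)]
        if st.size > 1:
            isis.append(np.diff(np.interp(st, grid, Lam)))
    if not isis:
        return PhiEstimate(np.nan, "DTR", psth_window, 0, {"reason": "no ISIs in window"})
    isis = np.concatenate(isis)
    phi = float(isis.var(ddof=1) / isis.mean() ** 2)
    diagnostics = {
        "n_isis": int(isis.size),
        "rescaled_isi_mean": float(isis.mean()),
        "n_psth_bins_floored": n_floored,
    }
    return PhiEstimate(phi, "DTR", psth_window, int(isis.size), diagnostics)


def estimate_phi_mr(
    spikes: SpikeTrainSet,
    T: float = 0.06,
    stride: float | None = None,
    window=None,
) -> PhiEstimate:
    """Minimum-ratio estimate: the minimum Fano factor over window positions."""
    cs = count_stats(spikes, T, stride=stride, window=window)
    ff = cs.fano
    valid = np.isfinite(ff)
    if not valid.any():
        return PhiEstimate(np.nan, "MR", T, 0, {"reason": "all bins empty"})
    phi = max(float(np.nanmin(ff)), 0.0)
    return PhiEstimate(phi, "MR", T, int(valid.sum()), {"n_empty_bins": int((~valid).sum())})


def renewal_count_moments(isi_model: ISIModel, T: float) -> tuple:
    """Exact large-T count mean and variance of a unit-rate renewal process.

    For ISI moments ``(mu, sigma^2, mu_3)`` the count in a bin of size ``T``
    has mean ``T/mu`` and variance
    ``(sigma^2/mu^3) T + sigma^4/(2 mu^4) + 1/6 - mu_3/(3 mu^3) + O(1/T)``;
    with the gamma parameterization (``mu = 1``, ``sigma^2 = phi``,
    ``mu_3 = 2 phi^2``) the variance is ``phi*T + 1/6 - phi^2/6``.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    mu = isi_model.mu_g
    var = isi_model.phi * mu**2
    mu3 = isi_model.third_central_moment
    mean = T / mu
    variance = (var / mu**3) * T + var**2 / (2 * mu**4) + 1.0 / 6.0 - mu3 / (3 * mu**3)
    return mean, variance


def mr_error_prediction(isi_model: ISIModel, rate_path: RatePath, T: float) -> float:
    """Closed-form prediction of the MR estimator's error ``phi_MR - phi``.

    The bias is the minimum over time of a rate-variance term that grows with
    ``T`` and a finite-size renewal correction that shrinks with ``T``::

        min_t { T Var(lambda(t))/E[lambda(t)]
                + (1/T) (1/6 + phi^2/2 - psi(phi)/3) / E[lambda(t)] }

    with ``psi(phi) = 2 phi^2`` for the gamma family.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    mean_rate = rate_path.rates.mean(axis=0)
    var_rate = rate_path.rates.var(axis=0, ddof=1) if rate_path.n_trials > 1 else np.zeros_like(mean_rate)
    ok = mean_rate > 0
    if not ok.any():
        raise ValueError("mean rate is zero at all times")
    phi = isi_model.phi
    corr = 1.0 / 6.0 + phi**2 / 2.0 - isi_model.third_central_moment / 3.0
    terms = T * var_rate[ok] / mean_rate[ok] + corr / (T * mean_rate[ok])
    return float(terms.min())


def select_units(summaries: pd.DataFrame, min_trials: int = 20, min_spikes: int = 500) -> list:
    """Units for which *every* condition passes the trial- and spike-count filters.

    ``summaries`` must have columns ``unit``, ``condition``, ``n_trials``,
    ``n_spikes`` (one row per unit x condition, counts within the analysis
    window).
    """
    required = {"unit", "condition", "n_trials", "n_spikes"}
    if not required.issubset(summaries.columns):
        raise ValueError(f"summaries must have columns {sorted(required)}")
    ok = (summaries["n_trials"] >= min_trials) & (summaries["n_spikes"] >= min_spikes)
    kept = summaries.assign(ok=ok).groupby("unit")["ok"].all()
    return sorted(kept.index[kept].tolist())


def modulation_index(a: float, b: float, convention: str = "half") -> float:
    """Normalized difference ``(a-b)/(a+b)``; ``convention='full'`` doubles it."""
    if a + b == 0:
        raise ValueError("modulation index undefined for a + b = 0")
    mi = (a - b) / (a + b)
    if convention == "full":
        return 2.0 * mi
    if convention != "half":
        raise ValueError("convention must be 'half' or 'full'")
    return mi
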