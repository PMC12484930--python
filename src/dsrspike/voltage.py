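"""Voltage-based validation of the renewal partitioning framework.

For neurons recorded intracellularly, the subthreshold membrane potential
provides a firing-rate proxy that is independent of the spike times: across
integrate-and-fire-type models the mean firing rate is a monotone (power-law)
function ``f(v)`` of the subthreshold voltage.  The pipeline is

1. detect spikes as upward threshold crossings and excise their waveforms,
2. bin the recording in time, pair mean subthreshold voltage with spike
   count per bin, and average counts within 1 mV voltage bins,
3. fit a smoothing spline ``f(v)`` to the binned voltage--rate relation,
4. evaluate ``lambda(t) = f(v(t))``, rescale spikes to operational time with
   the cumulative rate, and report the mean and CV^2 of the rescaled ISIs.

If the renewal model holds, the rescaled-ISI mean is ~1 (operational rate
1 Hz) and the CV^2 is an estimate of the irregularity ``phi`` that uses no
across-trial count statistics — an independent check on the spike-only
estimator.  A synthetic voltage-trace generator with known ground truth makes
the whole pipeline testable without recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.signal import lfilter

from .rate_models import RatePath
from .simulator import ISIModel, simulate_dsr

__all__ = [
    "VoltageTrace",
    "RateMap",
    "detect_and_remove_spikes",
    "bin_voltage_rate",
    "fit_rate_map",
    "phi_from_voltage",
    "make_synthetic_voltage",
]

SPIKE_THRESHOLD_MV = -30.0
REMOVE_BEFORE_S = 3e-3
REMOVE_AFTER_S = 5e-3
DEDUP_WINDOW_S = 2e-3
V_RANGE_MV = (-68.0, -40.0)


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled membrane potential, in mV."""

    sample_rate: float
    voltage: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("voltage must be a finite 1-D array")
        object.__setattr__(self, "voltage", v)

    @property
    def duration(self) -> float:
        return self.voltage.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.voltage.size) / self.sample_rate


@dataclass(frozen=True)
class RateMap:
    """Fitted voltage-to-rate map f(v) >= 0, constant-extrapolated outside its range."""

    knots: np.ndarray
    _spline: object = field(compare=False)
    v_range: tuple = V_RANGE_MV

    def __call__(self, v) -> np.ndarray:
        v = np.clip(np.asarray(v, dtype=float), self.v_range[0], self.v_range[1])
        return np.maximum(self._spline(v), 0.0)


def detect_and_remove_spikes(
    trace: VoltageTrace, threshold: float = SPIKE_THRESHOLD_MV
) -> tuple:
    """Spike times at upward threshold crossings, plus the de-spiked trace.

    Crossings closer than 2 ms are merged into one spike.  The trace segment
    from 3 ms before to 5 ms after each spike is replaced by a straight line
    between the boundary samples (one-sided at the trace edges).
    """
    if trace.sample_rate < 1000:
        raise ValueError("sample rate must be at least 1 kHz for spike detection")
    v = trace.voltage
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    spikes = []
    for idx in crossings:
        if spikes and (idx - spikes[-1]) / trace.sample_rate < DEDUP_WINDOW_S:
            continue
        spikes.append(idx)
    spike_idx = np.asarray(spikes, dtype=int)
    spike_times = spike_idx / trace.sample_rate

    sub = v.copy()
    before = int(round(REMOVE_BEFORE_S * trace.sample_rate))
    after = int(round(REMOVE_AFTER_S * trace.sample_rate))
    # Removal windows: every contiguous run above threshold (covers waveforms
    # of merged double-crossings too), extended 3 ms back and 5 ms forward.
    runs_start = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8)])) == 1)
    runs_end = np.flatnonzero(np.diff(np.concatenate([above.view(np.int8), [0]])) == -1)
    if runs_start.size:
        starts = np.maximum(runs_start - before, 0)
        ends = np.minimum(runs_end + after, v.size - 1)
        merged = [[starts[0], ends[0]]]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            left = sub[s - 1] if s > 0 else (sub[e + 1] if e + 1 < sub.size else threshold - 1.0)
            right = sub[e + 1] if e + 1 < sub.size else left
            sub[s : e + 1] = np.linspace(left, right, e - s + 1)
    clean = VoltageTrace(trace.sample_rate, sub, meta=dict(trace.meta))
    return spike_times, clean


def bin_voltage_rate(
    subthreshold: VoltageTrace,
    spike_times: np.ndarray,
    dt_bin: float = 0.05,
    v_range: tuple = V_RANGE_MV,
    dv: float = 1.0,
) -> pd.DataFrame:
    """Voltage-binned firing rates.

    Each time bin ``i`` of width ``dt_bin`` yields a pair (mean subthreshold
    voltage ``V_i``, spike count ``N_i``); pairs are grouped into voltage bins
    of width ``dv`` and the rate per voltage bin is
    ``r_k = sum_i N_i / (|S_k| * dt_bin)``.  Bin centers are geometric
    (``v_lo + (k - 1/2) dv``); empty voltage bins are omitted.
    """
    n_bins = int(subthreshold.duration / dt_bin + 1e-9)
    if n_bins < 1:
        raise ValueError("trace shorter than one time bin")
    per_bin = int(round(dt_bin * subthreshold.sample_rate))
    v = subthreshold.voltage[: n_bins * per_bin].reshape(n_bins, per_bin)
    v_mean = v.mean(axis=1)
    counts = np.histogram(spike_times, bins=np.arange(n_bins + 1) * dt_bin)[0]
    edges = np.arange(v_range[0], v_range[1] + dv / 2, dv)
    which = np.digitize(v_mean, edges) - 1
    rows = []
    for k in range(edges.size - 1):
        sel = which == k
        if not sel.any():
            continue
        rows.append(
            {
                "v_mv": edges[k] + dv / 2,
                "rate_hz": counts[sel].sum() / (sel.sum() * dt_bin),
                "n_points": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["v_mv", "rate_hz", "n_points"])


def fit_rate_map(binned: pd.DataFrame, v_range: tuple = V_RANGE_MV) -> RateMap:
    """Cubic smoothing spline through the (V_k, r_k) pairs.

    The smoothing parameter is chosen by generalized cross-validation; the
    fitted map is clamped at zero from below and constant-extrapolated
    outside the voltage range.
    """
    if len(binned) < 4:
        raise ValueError("need at least 4 populated voltage bins to fit a rate map")
    x = binned["v_mv"].to_numpy(dtype=float)
    y = binned["rate_hz"].to_numpy(dtype=float)
    spline = make_smoothing_spline(x, y, w=binned["n_points"].to_numpy(dtype=float))
    return RateMap(knots=x, _spline=spline, v_range=v_range)


def phi_from_voltage(
    subthreshold: VoltageTrace, rate_map: RateMap, spike_times: np.ndarray
) -> tuple:
    """CV^2 and mean of spike ISIs rescaled by the voltage-derived rate.

    Returns ``(phi_voltage, mu_hat_g)``: the irregularity estimate and the
    rescaled-ISI mean (which should be near 1 if the rate proxy is faithful).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if spike_times.size < 3:
        raise ValueError("need at least 3 spikes")
    t = subthreshold.times
    lam = rate_map(subthreshold.voltage)
    dt = 1.0 / subthreshold.sample_rate
    Lam = np.concatenate([[0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1]) * dt)])
    if Lam[-1] <= 0:
        raise ValueError("rate map evaluates to zero over the whole trace")
    rescaled = np.interp(spike_times, t, Lam)
    isis = np.diff(rescaled)
    isis = isis[isis > 0]
    mu = float(isis.mean())
    phi = float(isis.var(ddof=1) / mu**2)
    return phi, mu


def _power_law_rate(c: float = 12.0 / 196.0, v0: float = -70.0, p: float = 2.0):
    """Monotone voltage-to-rate ground truth f(v) = c * max(v - v0, 0)^p."""

    def f(v):
        return c * np.maximum(np.asarray(v, dtype=float) - v0, 0.0) ** p

    return f


def make_synthetic_voltage(
    duration: float,
    phi: float = 0.5,
    seed: int = 0,
    sample_rate: float = 20000.0,
    ou_tau: float = 0.5,
    ou_mean: float = -56.0,
    ou_sigma: float = 4.0,
    f_true=None,
):
    """Synthetic intracellular trace with known rate and irregularity.

    The subthreshold voltage is an Ornstein--Uhlenbeck fluctuation (time
    constant ``ou_tau`` s, i.e. slow relative to ISIs) clipped to the
    physiological range; the true instantaneous rate is ``f_true(v(t))`` for a
    monotone power law; spikes are drawn from the renewal model at that rate;
    and a stereotyped action-potential waveform is pasted at each spike time.

    Returns ``(trace, rate_path, true_spike_times)`` with ground-truth
    provenance (phi, seed, f_true parameters) in ``trace.meta``.
    """
    if f_true is None:
        f_true = _power_law_rate()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    n = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate
    # exact AR(1) discretization of the OU process
    rho = np.exp(-dt / ou_tau)
    innov = rng.standard_normal(n) * ou_sigma * np.sqrt(1 - rho**2)
    v = lfilter([1.0], [1.0, -rho], innov) + ou_mean
    v = np.clip(v, V_RANGE_MV[0], V_RANGE_MV[1])

    # rate on a 1 ms grid from the voltage (block means keep it smooth)
    per_ms = max(int(round(1e-3 * sample_rate)), 1)
    n_ms = n // per_ms
    v_ms = v[: n_ms * per_ms].reshape(n_ms, per_ms).mean(axis=1)
    grid = np.arange(n_ms + 1) * 1e-3
    lam = f_true(np.concatenate([v_ms, v_ms[-1:]]))
    rate_path = RatePath(grid, lam[None, :], meta={"model": "voltage", "phi": phi, "seed": seed})
    spikes = simulate_dsr(ISIModel(phi), rate_path, seed=seed).trials[0]

    # stereotyped spike waveform: 0.5 ms rise to +10 mV, 1.5 ms fall below rest
    t_wave = np.arange(int(2e-3 * sample_rate)) * dt
    wave = np.where(
        t_wave < 5e-4,
        -30.0 + 40.0 * t_wave / 5e-4,
        10.0 - 75.0 * (t_wave - 5e-4) / 1.5e-3,
    )
    out = v.copy()
    for st in spikes:
        i0 = int(round(st * sample_rate))
        seg = wave[: max(min(n - i0, wave.size), 0)]
        out[i0 : i0 + seg.size] = seg
    meta = {
        "synthetic": True,
        "phi": phi,
        "seed": seed,
        "ou_tau": ou_tau,
        "ou_mean": ou_mean,
        "ou_sigma": ou_sigma,
    }
    return VoltageTrace(sample_rate, out, meta=meta), rate_path, spikes
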