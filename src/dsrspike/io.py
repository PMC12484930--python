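"""Delimited-text I/O for spike trains and rate paths.

Formats are deliberately plain:

* spike trains: CSV with header ``trial,spike_time_s``, one row per spike;
* rate paths: CSV with header ``time_s,trial_0,trial_1,...``, one row per
  grid point;
* metadata sidecars: JSON next to the data file (``<name>.meta.json``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .rate_models import RatePath
from .simulator import SpikeTrainSet

__all__ = [
    "read_spike_trains",
    "write_spike_trains",
    "read_rate_path",
    "write_rate_path",
]


def _sidecar(path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.json")


def write_spike_trains(spikes: SpikeTrainSet, path) -> None:
    rows = [
        (k, t) for k, st in enumerate(spikes.trials) for t in st
    ]
    df = pd.DataFrame(rows, columns=["trial", "spike_time_s"])
    df.to_csv(path, index=False, float_format="%.9f")
    meta = dict(spikes.metadata)
    meta.update({"t_start": spikes.t_start, "t_end": spikes.t_end, "n_trials": spikes.n_trials})
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))


def read_spike_trains(path, t_start: float | None = None, t_end: float | None = None) -> SpikeTrainSet:
    """Read a ``trial,spike_time_s`` file; trials are canonically sorted.

    Unsorted spike times within a trial are sorted with a warning in the
    metadata; negative times or malformed rows raise with the line number.
    """
    df = pd.read_csv(path)
    if list(df.columns) != ["trial", "spike_time_s"]:
        raise ValueError(f"{path}: expected header 'trial,spike_time_s', got {list(df.columns)}")
    bad = df["spike_time_s"].isna() | df["trial"].isna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # +2: header + 1-indexing
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    if (df["spike_time_s"] < 0).any():
        lines = (np.flatnonzero((df["spike_time_s"] < 0).to_numpy()) + 2).tolist()
        raise ValueError(f"{path}: negative spike times at lines {lines}")

    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    n_trials = int(meta.get("n_trials", df["trial"].max() + 1 if len(df) else 0))

    trials, n_sorted = [], 0
    for k in range(n_trials):
        st = df.loc[df["trial"] == k, "spike_time_s"].to_numpy(dtype=float)
        if st.size and np.any(np.diff(st) < 0):
            st = np.sort(st)
            n_sorted += 1
        trials.append(np.unique(st) if st.size else st)
    lo = t_start if t_start is not None else float(meta.get("t_start", 0.0))
    hi = (
        t_end
        if t_end is not None
        else float(meta.get("t_end", max((st[-1] for st in trials if st.size), default=1.0)))
    )
    if n_sorted:
        meta["n_trials_resorted"] = n_sorted
    return SpikeTrainSet(tuple(trials), lo, hi, meta)


def write_rate_path(rate_path: RatePath, path) -> None:
    cols = {"time_s": rate_path.time_grid}
    for k in range(rate_path.n_trials):
        cols[f"trial_{k}"] = rate_path.rates[k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9f")
    _sidecar(path).write_text(json.dumps(dict(rate_path.meta), indent=1, default=str))


def read_rate_path(path) -> RatePath:
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be 'time_s'")
    t = df["time_s"].to_numpy(dtype=float)
    rates = df.iloc[:, 1:].to_numpy(dtype=float).T
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return RatePath(t, rates, meta=meta)
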