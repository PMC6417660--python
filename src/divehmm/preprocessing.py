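"""Reduce 1 Hz depth traces to dive summaries and build covariates.

A dive is scored whenever the depth record exceeds the dive threshold
(default 20 m) between two consecutive surface-zero measurements.  With a
0.5 m depth resolution, any sample at or below half the resolution
(0.25 m) counts as a surface zero; this tolerance is configurable.

Per dive we record maximum depth MD (m), dive duration DT (min, the time
between the delimiting surface zeros) and post-dive surface time PD (min,
everything up to the opening zero of the next dive, including sub-threshold
excursions).  Covariates per dive: tau_t, hours since the end (resurfacing)
of the last deep dive (>= 350 m by default); d_t, the number of consecutive
deep dives immediately preceding dive t; and hour, the fractional hour of
day at dive initiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIVE_COLUMNS = ["DiveNumber", "Date", "StartTime", "MaxDepth", "Duration", "PostDiveDur"]


@dataclass
class DepthTrace:
    """Uniform 1 Hz depth record.

    ``times`` are seconds since record start (strictly increasing, unit
    step); ``depth`` is in metres, non-negative, at 0.5 m resolution.
    """

    times: np.ndarray
    depth: np.ndarray
    start: pd.Timestamp | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.times.shape != self.depth.shape or self.times.ndim != 1:
            raise ValueError("times and depth must be 1-d arrays of equal length")
        if len(self.times) == 0:
            raise ValueError("empty trace")
        steps = np.diff(self.times)
        if len(steps) and not np.allclose(steps, steps[0]) or (len(steps) and steps[0] <= 0):
            raise ValueError("trace must be uniformly sampled with increasing times")
        if np.any(self.depth < 0):
            raise ValueError("negative depths in trace")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 1.0


def extract_dives(trace: DepthTrace, dive_threshold: float = 20.0,
                  surface_tol: float = 0.25) -> pd.DataFrame:
    """Score dives from a depth trace.

    Returns a DataFrame in the standard dive-summary layout (DiveNumber,
    Date, StartTime, MaxDepth, Duration, PostDiveDur) plus a ``start_s``
    column with the opening-zero time in seconds since record start.
    Leading/trailing partial dives (record starting or ending underwater)
    are discarded with a warning.
    """
    depth = trace.depth
    t = trace.times
    zero_idx = np.flatnonzero(depth <= surface_tol)
    if len(zero_idx) == 0:
        logger.warning("trace never reaches the surface; no dives scored")
        return _empty_dive_table()
    if zero_idx[0] != 0:
        logger.warning("record starts underwater; leading partial dive discarded")
    if zero_idx[-1] != len(depth) - 1 and np.any(depth[zero_idx[-1] + 1:] > dive_threshold):
        logger.warning("record ends underwater; trailing partial dive discarded")

    dives = []  # (start_idx, end_idx) of the delimiting zeros
    for a, b in zip(zero_idx[:-1], zero_idx[1:]):
        if b - a < 2:
            continue
        seg_max = depth[a + 1:b].max()
        if seg_max >= dive_threshold:
            dives.append((a, b, seg_max))

    if not dives:
        return _empty_dive_table()

    rows = []
    for k, (a, b, md) in enumerate(dives):
        if k + 1 < len(dives):
            pd_end = t[dives[k + 1][0]]
        else:
            pd_end = t[zero_idx[-1]]  # surface time to the last surface sample
        start_t = t[a]
        dur_min = (t[b] - t[a]) / 60.0
        post_min = (pd_end - t[b]) / 60.0
        rows.append((k + 1, start_t, md, dur_min, post_min))

    out = pd.DataFrame(rows, columns=["DiveNumber", "start_s", "MaxDepth",
                                      "Duration", "PostDiveDur"])
    start = trace.start if trace.start is not None else pd.Timestamp("2000-01-01")
    stamps = start + pd.to_timedelta(out["start_s"], unit="s")
    out.insert(1, "Date", stamps.dt.strftime("%Y-%m-%d"))
    out.insert(2, "StartTime", stamps.dt.strftime("%H:%M:%S"))
    return out[DIVE_COLUMNS + ["start_s"]]


def _empty_dive_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=("int64" if c == "DiveNumber" else
                                             "float64" if c in ("MaxDepth", "Duration",
                                                                "PostDiveDur", "start_s")
                                             else "object"))
                         for c in DIVE_COLUMNS + ["start_s"]})


def dive_start_timestamps(dives: pd.DataFrame) -> pd.Series:
    """Combine Date and StartTime columns into timestamps."""
    if "start_ts" in dives:
        return pd.to_datetime(dives["start_ts"])
    return pd.to_datetime(dives["Date"].astype(str) + " " + dives["StartTime"].astype(str))


def compute_covariates(dives: pd.DataFrame, deep_threshold: float = 350.0,
                       tau_reference: str = "end",
                       record_start: pd.Timestamp | None = None) -> pd.DataFrame:
    """Per-dive covariates (tau_h, d_count, hour).

    tau_t is measured from the resurfacing (end) of the most recent prior
    deep dive to the start of dive t (``tau_reference="start"`` measures
    start-to-start instead).  Before the first deep dive, tau counts hours
    since the record start (the first dive's start unless ``record_start``
    is given); those rows are flagged ``pre_first_deep`` so the burn-in can
    be dropped.
    """
    if tau_reference not in ("end", "start"):
        raise ValueError("tau_reference must be 'end' or 'start'")
    starts = dive_start_timestamps(dives)
    if starts.is_monotonic_increasing is False:
        raise ValueError("dives must be time-ordered")
    md = np.asarray(dives["MaxDepth"], dtype=float)
    dur_min = np.asarray(dives["Duration"], dtype=float)
    n = len(md)
    t0 = pd.Timestamp(record_start) if record_start is not None else starts.iloc[0]

    tau = np.empty(n)
    d = np.zeros(n, dtype=int)
    pre = np.zeros(n, dtype=bool)
    last_ref = None  # timestamp of the tau reference point
    run = 0
    for i in range(n):
        d[i] = run
        if last_ref is None:
            tau[i] = (starts.iloc[i] - t0).total_seconds() / 3600.0
            pre[i] = True
        else:
            tau[i] = (starts.iloc[i] - last_ref).total_seconds() / 3600.0
        if md[i] >= deep_threshold:
            run += 1
            last_ref = (starts.iloc[i] + pd.Timedelta(minutes=dur_min[i])
                        if tau_reference == "end" else starts.iloc[i])
        else:
            run = 0
    hour = ((starts - starts.dt.normalize()).dt.total_seconds() / 3600.0
            ).to_numpy() % 24.0
    return pd.DataFrame({"tau_h": tau, "d_count": d, "hour": hour,
                         "pre_first_deep": pre}, index=dives.index)
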