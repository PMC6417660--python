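"""CSV readers/writers, run configuration and summary tables.

Dive-summary files use the standard six-column layout: DiveNumber, Date,
StartTime (hh:mm:ss), MaxDepth (m), Duration (min), PostDiveDur (min).
Writers prepend ``#`` comment headers recording the package version, seed
and a configuration hash, so re-running with an identical configuration
reproduces byte-identical CSV bodies.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .preprocessing import DIVE_COLUMNS, DepthTrace

DEFAULT_BANDS = ((20.0, 50.0), (50.0, 350.0), (350.0, np.inf))


# ---------------------------------------------------------------------------
# depth traces

def read_trace_csv(path) -> DepthTrace:
    """Read a (timestamp, depth_m) CSV into a DepthTrace."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    if "depth_m" not in cols or "timestamp" not in cols:
        raise ValueError("trace CSV must have 'timestamp' and 'depth_m' columns")
    ts = pd.to_datetime(df[cols["timestamp"]])
    secs = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    return DepthTrace(times=secs, depth=df[cols["depth_m"]].to_numpy(dtype=float),
                      start=ts.iloc[0])


def write_trace_csv(trace: DepthTrace, path, seed=None, config=None):
    start = trace.start if trace.start is not None else pd.Timestamp("2000-01-01")
    ts = start + pd.to_timedelta(trace.times, unit="s")
    df = pd.DataFrame({"timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
                       "depth_m": trace.depth})
    _write_with_header(df, path, seed=seed, config=config)


# ---------------------------------------------------------------------------
# dive tables

def read_dive_csv(path, dayfirst: bool | None = None) -> pd.DataFrame:
    """Read and validate a dive-summary CSV.

    Requires exactly the six standard columns (order-insensitive); rows
    failing validation are reported with their 1-based data row number.
    Returns the table with an added parsed ``start_ts`` column.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = set(DIVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing dive-table columns: {sorted(missing)}")
    extra = set(df.columns) - set(DIVE_COLUMNS)
    if extra:
        raise ValueError(f"unexpected dive-table columns: {sorted(extra)}")
    df = df[list(DIVE_COLUMNS)]
    for col in ("MaxDepth", "Duration", "PostDiveDur"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if len(bad):
            raise ValueError(f"unparseable {col} at data row {bad[0] + 1}")
        df[col] = vals.astype(float)
    bad = np.flatnonzero((df["Duration"] <= 0).to_numpy())
    if len(bad):
        raise ValueError(f"non-positive Duration at data row {bad[0] + 1}")
    try:
        ts = pd.to_datetime(df["Date"].astype(str) + " " + df["StartTime"].astype(str),
                            dayfirst=bool(dayfirst) if dayfirst is not None else False,
                            format="mixed" if dayfirst is None else None)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable Date/StartTime: {exc}") from exc
    out = df.copy()
    out["start_ts"] = ts
    return out


def write_dive_csv(dives: pd.DataFrame, path, seed=None, config=None,
                   extra_columns: pd.DataFrame | None = None):
    out = dives.copy()
    if extra_columns is not None:
        out = pd.concat([out, extra_columns.reset_index(drop=True)], axis=1)
    if "start_ts" in out:
        out = out.drop(columns=["start_ts"])
    _write_with_header(out, path, seed=seed, config=config)


def _config_hash(config) -> str:
    return hashlib.sha1(json.dumps(config, sort_keys=True, default=str)
                        .encode()).hexdigest()[:12]


def _write_with_header(df: pd.DataFrame, path, seed=None, config=None):
    header = [f"# divehmm {__version__}"]
    if seed is not None:
        header.append(f"# seed = {seed}")
    if config is not None:
        header.append(f"# config_hash = {_config_hash(config)}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        # %.17g guarantees float round-trip through the CSV
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


# ---------------------------------------------------------------------------
# empirical summaries

def summarize(dives: pd.DataFrame, bands=DEFAULT_BANDS) -> pd.DataFrame:
    """Empirical per-band moments of (MD, DT, PD), Table-4-style.

    Bands partition dives by maximum depth (default 20-50, 50-350,
    >= 350 m).  Sample (n-1) SDs; single-dive bands report SD 0 and are
    flagged; empty bands are reported as missing.
    """
    x = dives[["MaxDepth", "Duration", "PostDiveDur"]].to_numpy(dtype=float)
    out = {}
    for lo, hi in bands:
        name = f"MD {lo:g}-{hi:g}" if np.isfinite(hi) else f"MD >{lo:g}"
        sel = x[(x[:, 0] >= lo) & (x[:, 0] < hi)]
        col = {}
        if len(sel) == 0:
            out[name] = {k: np.nan for k in
                         ["n", "E_MD", "SD_MD", "E_DT", "SD_DT", "E_PD", "SD_PD",
                          "Corr_MD_DT", "Corr_MD_PD", "Corr_DT_PD"]}
            continue
        col["n"] = len(sel)
        for k, c in enumerate(("MD", "DT", "PD")):
            col[f"E_{c}"] = sel[:, k].mean()
            col[f"SD_{c}"] = sel[:, k].std(ddof=1) if len(sel) > 1 else 0.0
        if len(sel) > 1 and np.all(sel.std(axis=0) > 0):
            r = np.corrcoef(sel.T)
            col["Corr_MD_DT"], col["Corr_MD_PD"], col["Corr_DT_PD"] = \
                r[0, 1], r[0, 2], r[1, 2]
        else:
            col["Corr_MD_DT"] = col["Corr_MD_PD"] = col["Corr_DT_PD"] = np.nan
        out[name] = col
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# configuration and fit serialization

_KNOWN_KEYS = {"dives", "trace", "out", "states", "family", "dependence",
               "covariate_model", "eta", "spline_df", "dive_threshold",
               "deep_threshold", "tau_reference", "starts", "seed", "maxiter",
               "ftol", "gtol"}


def load_config(path) -> dict:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return config


def fit_to_json(results, path, seed=None):
    """Serialise a fit to a diffable JSON document."""
    r = results._result
    spec = r.spec
    doc = {
        "divehmm_version": __version__,
        "seed": seed,
        "spec": {"m": spec.m, "family": spec.family,
                 "dependence": spec.dependence,
                 "covariate_model": spec.covariate_model.name or "custom",
                 "terms": {f"{i}->{j}": list(t) for (i, j), t
                           in spec.covariate_model.terms.items()}},
        "llf": r.llf, "aic": r.aic, "n_params": r.n_params,
        "emission": {"mu": r.params.emission.mu.tolist(),
                     "sigma": r.params.emission.sigma.tolist(),
                     "rho": r.params.emission.rho.tolist()},
        "beta": dict(zip(spec.covariate_model.coef_names(),
                         r.params.beta.tolist())),
        "working": r.working.tolist(),
        "labels": r.labels,
        "se_working": None if r.se_working is None else r.se_working.tolist(),
        "starts": r.starts.to_dict(orient="records"),
        "best_start": r.best_start,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
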