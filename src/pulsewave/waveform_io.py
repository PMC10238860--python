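"""Waveform and report I/O.

Canonical internal units are mmHg, mL/s and seconds; every conversion happens
at this boundary. Waveform files are plain comma-delimited text with a header
``time_s,pressure_mmHg[,flow_<unit>]``; ground truth for simulated recordings
is written as a ``key: value`` sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SamplingError, SchemaError, UnitError

#: Multiplicative factors to canonical mL/s.
_FLOW_FACTORS = {
    "ml/s": 1.0,
    "l/min": 1000.0 / 60.0,
    "ml/min": 1.0 / 60.0,
}

#: Column-suffix spellings accepted in waveform headers, per unit.
_FLOW_SUFFIXES = {
    "ml_s": "ml/s",
    "l_min": "l/min",
    "ml_min": "ml/min",
}

#: 1 mmHg * 1 mL/s = 133.322 Pa * 1e-6 m^3/s = 133.322 uW.
MMHG_MLS_TO_UW = 133.322

#: 1 mmHg*s/mL = 1000/60 mmHg*min/L.
S_PER_ML_TO_MIN_PER_L = 1000.0 / 60.0


@dataclass
class Recording:
    """A uniformly sampled pressure (and optional flow) recording.

    Parameters
    ----------
    t : array of float
        Time grid in seconds, strictly increasing and uniform.
    p : array of float
        Arterial pressure in mmHg.
    q : array of float, optional
        Aortic flow in mL/s, same length as ``p``.
    fs_hz : float
        Sampling rate.
    meta : dict
        Free-form labels (subject id, session label, simulation truth, ...).
    """

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray | None = None
    fs_hz: float = 500.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.q is not None:
            self.q = np.asarray(self.q, dtype=float)
        if self.fs_hz <= 0:
            raise SamplingError("fs_hz must be positive")
        if self.t.ndim != 1 or self.t.size != self.p.size:
            raise SchemaError("t and p must be 1-D arrays of equal length")
        if self.q is not None and self.q.size != self.p.size:
            raise SchemaError("flow must have the same length as pressure")
        if not np.all(np.isfinite(self.p)):
            raise SchemaError("pressure contains non-finite samples")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise SamplingError("time grid must be strictly increasing")
            mean_dt = dt.mean()
            if np.any(np.abs(dt - mean_dt) > 1e-6 * max(mean_dt, 1.0)):
                raise SamplingError("time grid is not uniform")

    @property
    def n_samples(self) -> int:
        return self.p.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


def read_recording(
    path: str | Path, config: Mapping[str, str] | None = None
) -> Recording:
    """Read a delimited waveform file into a :class:`Recording`.

    ``config`` may remap column names and declare the flow unit::

        {"time": "t", "pressure": "bp", "flow": "q", "flow_unit": "L/min"}

    Without a config, columns are matched against the canonical header
    ``time_s, pressure_mmHg, flow_<unit>`` where ``<unit>`` is one of
    ``ml_s``, ``l_min``, ``ml_min``. Flow is converted to mL/s.
    """
    config = dict(config or {})
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}

    def find(role: str, candidates: list[str]) -> str | None:
        if role in config:
            name = config[role]
            if name not in cols:
                raise SchemaError(f"{path}: declared {role} column {name!r} missing")
            return cols[name]
        for cand in candidates:
            if cand in cols:
                return cols[cand]
        return None

    t_col = find("time", ["time_s", "t"])
    p_col = find("pressure", ["pressure_mmHg", "pressure", "p"])
    if t_col is None or p_col is None:
        raise SchemaError(f"{path}: missing required time/pressure columns")

    flow_unit = config.get("flow_unit")
    q_col = None
    if "flow" in config:
        q_col = find("flow", [])
    else:
        for suffix, unit in _FLOW_SUFFIXES.items():
            name = f"flow_{suffix}"
            if name in cols:
                q_col = cols[name]
                flow_unit = flow_unit or unit
                break

    q = None
    if q_col is not None:
        if flow_unit is None:
            raise UnitError(f"{path}: flow column {q_col!r} has no declared unit")
        key = flow_unit.strip().lower()
        if key not in _FLOW_FACTORS:
            raise UnitError(
                f"unknown flow unit {flow_unit!r}; expected one of "
                f"{sorted(_FLOW_FACTORS)}"
            )
        q = df[q_col].to_numpy(dtype=float) * _FLOW_FACTORS[key]

    t = df[t_col].to_numpy(dtype=float)
    if t.size >= 2:
        fs = float(config.get("fs_hz", 1.0 / np.mean(np.diff(t))))
    else:
        fs = float(config.get("fs_hz", 1.0))
    return Recording(t=t, p=df[p_col].to_numpy(dtype=float), q=q, fs_hz=fs,
                     meta={"source": str(path)})


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as canonical waveform CSV (flow in mL/s)."""
    path = Path(path)
    data = {"time_s": rec.t, "pressure_mmHg": rec.p}
    if rec.q is not None:
        data["flow_ml_s"] = rec.q
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")
    return path


def write_truth_sidecar(truth: Mapping[str, object], path: str | Path) -> Path:
    """Write generative ground truth as ``key: value`` lines."""
    path = Path(path)
    lines = []
    for key, val in truth.items():
        if isinstance(val, (list, tuple, np.ndarray)):
            val = ",".join(f"{v:g}" if isinstance(v, float) else str(v) for v in val)
        lines.append(f"{key}: {val}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_truth_sidecar(path: str | Path) -> dict:
    out: dict = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, val = line.partition(":")
        out[key.strip()] = val.strip()
    return out


def convert_power_units(x: float | np.ndarray) -> float | np.ndarray:
    """Convert wave power from mmHg*mL/s to microwatts (exact linear map)."""
    return x * MMHG_MLS_TO_UW


def convert_zc_units(zc_s_per_ml: float) -> float:
    """Convert characteristic impedance from mmHg*s/mL to mmHg*min/L."""
    return zc_s_per_ml * S_PER_ML_TO_MIN_PER_L


def write_report(results: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-ensemble-group index table plus session-mean summary.

    One row per ensemble group (per flow source, when a ``flow_source``
    column is present), followed by one ``session_mean`` summary row per flow
    source holding the arithmetic mean of every numeric column.
    """
    if results is None or len(results) == 0:
        raise SchemaError("empty results: nothing to report")
    path = Path(path)
    df = results.copy()
    if "row" not in df.columns:
        if "group" in df.columns:
            df.insert(0, "row", [f"group_{g}" for g in df["group"]])
        else:
            df.insert(0, "row", [f"group_{i}" for i in range(len(df))])
    num_cols = df.select_dtypes(include=[np.number]).columns
    summaries = []
    if "flow_source" in df.columns:
        for src, block in df.groupby("flow_source", sort=True):
            row = {c: block[c].mean() for c in num_cols}
            row["row"] = "session_mean"
            row["flow_source"] = src
            summaries.append(row)
    else:
        row = {c: df[c].mean() for c in num_cols}
        row["row"] = "session_mean"
        summaries.append(row)
    out = pd.concat([df, pd.DataFrame(summaries)], ignore_index=True)
    out.to_csv(path, index=False, float_format="%.10g")
    return path
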