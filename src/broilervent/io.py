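"""Reading and writing operation logs (CSV and the PLC JSON dialect).

CSV is the canonical interchange format: one row per control interval with
the fixed header ``timestamp_s, Ti_C, To_C, RHo_pct, Td_C, age_days, stage,
n_fans, pad_on, actual_vent_m3h``. Timestamps are seconds from period
start and the decimal separator is always '.'.

The PLC JSON dialect mirrors how an on-farm programmable logic controller
dumps its state: a versioned document with a fixed record cadence (10 s)
and one object per interval. ``read_log`` can resample such high-rate logs
to a coarser audit cadence: temperatures and airflow by interval mean,
fan and pad states by time-weighted duty.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import LOG_COLUMNS, TimeSeriesLog

PLC_JSON_VERSION = 1

#: JSON record field -> CSV column
_PLC_FIELDS = {
    "t": "timestamp_s",
    "temp_in": "Ti_C",
    "temp_out": "To_C",
    "rh_out": "RHo_pct",
    "temp_set": "Td_C",
    "age": "age_days",
    "fan_stage": "stage",
    "fans_on": "n_fans",
    "pad": "pad_on",
    "vent": "actual_vent_m3h",
}


def write_log(log: TimeSeriesLog, path: str | Path) -> None:
    """Write a log as canonical CSV (header always present, '.' decimal)."""
    frame = log.frame.loc[:, list(LOG_COLUMNS)].copy()
    frame["pad_on"] = frame["pad_on"].astype(int)
    try:
        frame.to_csv(path, index=False, float_format="%.6f")
    except OSError as exc:
        raise OSError(f"failed to write log to {path}: {exc}") from exc


def _validate_frame(frame: pd.DataFrame, path: str | Path) -> TimeSeriesLog:
    missing = [c for c in LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frame = frame.loc[:, list(LOG_COLUMNS)].copy()
    frame["pad_on"] = frame["pad_on"].astype(bool)
    ts = frame["timestamp_s"].to_numpy(dtype=float)
    if len(ts) > 1:
        if not np.all(np.diff(ts) > 0):
            raise ValueError(f"{path}: timestamps must be strictly increasing")
        interval = float(ts[1] - ts[0])
    else:
        interval = 0.0
    if frame[["Ti_C", "To_C", "RHo_pct", "Td_C", "actual_vent_m3h"]].isna().any().any():
        bad = int(frame[["Ti_C", "To_C", "RHo_pct", "Td_C",
                         "actual_vent_m3h"]].isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing value in record {bad}")
    return TimeSeriesLog(frame=frame, interval_s=interval)


def _resample(frame: pd.DataFrame, source_interval: float,
              cadence_s: float) -> tuple[pd.DataFrame, float]:
    """Aggregate a fine-cadence log into ``cadence_s`` bins.

    Continuous channels (temperatures, RH, airflow, fan count) take the
    bin mean; pad state becomes on when its duty in the bin is >= 0.5;
    stage and age take the rounded mean. Bin timestamps are the bin starts.
    """
    if cadence_s <= source_interval:
        return frame, source_interval
    per_bin = int(round(cadence_s / source_interval))
    n = len(frame)
    bins = np.arange(n) // per_bin
    grouped = frame.groupby(bins)
    out = pd.DataFrame({
        "timestamp_s": grouped["timestamp_s"].first(),
        "Ti_C": grouped["Ti_C"].mean(),
        "To_C": grouped["To_C"].mean(),
        "RHo_pct": grouped["RHo_pct"].mean(),
        "Td_C": grouped["Td_C"].mean(),
        "age_days": grouped["age_days"].mean().round().astype(int),
        "stage": grouped["stage"].mean().round().astype(int),
        "n_fans": grouped["n_fans"].mean(),
        "pad_on": grouped["pad_on"].mean() >= 0.5,
        "actual_vent_m3h": grouped["actual_vent_m3h"].mean(),
    }).reset_index(drop=True)
    return out, cadence_s


def read_log(path: str | Path, dialect: str = "csv",
             cadence_s: float | None = None) -> TimeSeriesLog:
    """Read an operation log.

    ``dialect='csv'`` expects the canonical CSV schema. ``dialect='plc_json'``
    expects the versioned PLC JSON document (10 s records); pass ``cadence_s``
    to resample to an audit cadence (e.g. 600 for 10 min). Malformed rows
    are reported with their record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"log file not found: {path}")
    if dialect == "csv":
        frame = pd.read_csv(path)
        log = _validate_frame(frame, path)
    elif dialect == "plc_json":
        log = _read_plc_json(path)
    else:
        raise ValueError(f"unknown log dialect {dialect!r}")
    if cadence_s is not None and len(log) > 1:
        frame, interval = _resample(log.frame, log.interval_s, cadence_s)
        log = TimeSeriesLog(frame=frame, interval_s=interval)
    return log


def _read_plc_json(path: Path) -> TimeSeriesLog:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or "records" not in doc:
        raise ValueError(f"{path}: PLC document must be an object with 'records'")
    version = doc.get("version")
    if version != PLC_JSON_VERSION:
        raise ValueError(f"{path}: unsupported PLC schema version {version!r}")
    interval = float(doc.get("interval_s", 10.0))
    rows = []
    for idx, rec in enumerate(doc["records"]):
        row = {}
        for field, column in _PLC_FIELDS.items():
            if field not in rec:
                raise ValueError(f"{path}: record {idx} missing field {field!r}")
            value = rec[field]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValueError(f"{path}: record {idx} has null {field!r}")
            row[column] = value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(LOG_COLUMNS))
    log = _validate_frame(frame, path)
    if len(log) > 1 and abs(log.interval_s - interval) > 1e-6:
        raise ValueError(f"{path}: record spacing disagrees with declared interval_s")
    return log


def write_plc_json(log: TimeSeriesLog, path: str | Path) -> None:
    """Write a log in the PLC JSON dialect (inverse of the plc_json reader)."""
    records = []
    for row in log.frame.itertuples(index=False):
        records.append({
            "t": float(row.timestamp_s),
            "temp_in": float(row.Ti_C),
            "temp_out": float(row.To_C),
            "rh_out": float(row.RHo_pct),
            "temp_set": float(row.Td_C),
            "age": int(row.age_days),
            "fan_stage": int(row.stage),
            "fans_on": float(row.n_fans),
            "pad": bool(row.pad_on),
            "vent": float(row.actual_vent_m3h),
        })
    doc = {"version": PLC_JSON_VERSION, "interval_s": log.interval_s,
           "records": records}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
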