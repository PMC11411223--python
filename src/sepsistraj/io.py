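"""Reading and writing the event-table schema.

One file per table kind (``patients``, ``observations``, ``infusions``,
``antibiotics``, ``cultures``, ``sofa``, optionally ``ground_truth``),
as CSV or Parquet.  Times are written as ISO-8601 timestamps at millisecond
precision relative to a fixed epoch; since all in-memory times are quantized
to milli-hours the round trip is exact.  Unknown extra columns are accepted
with a warning and ignored; a missing table or missing required column is a
:class:`~sepsistraj.errors.FormatError` naming the offender.

The column dictionary shipped with the package
(``sepsistraj/data/schema.md``) documents names and units.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .synthetic import BundleSet

__all__ = ["write_bundles", "read_bundles", "EPOCH", "SCHEMA"]

#: All ISO timestamps in files are relative to this epoch.
EPOCH = pd.Timestamp("2021-01-01T00:00:00")

_MS_PER_HOUR = 3_600_000

#: table -> (required columns, optional columns, time-valued columns)
SCHEMA: dict[str, tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]] = {
    "patients": (("patient_id", "age_years", "sex", "weight_kg", "icu_in",
                  "icu_out", "death_time"), (),
                 ("icu_in", "icu_out", "death_time")),
    "observations": (("patient_id", "time_hours", "variable", "value"), (),
                     ("time_hours",)),
    "infusions": (("patient_id", "drug_name", "rate_value", "rate_units",
                   "weight_based", "start_hours", "end_hours"), (),
                  ("start_hours", "end_hours")),
    "antibiotics": (("patient_id", "time_hours"), (), ("time_hours",)),
    "cultures": (("patient_id", "time_hours"), (), ("time_hours",)),
    "sofa": (("patient_id", "time_hours", "total_score"), (), ("time_hours",)),
    "ground_truth": (("patient_id", "planted_class", "planted_onset"),
                     ("planted_eligible", "perturbation"),
                     ("planted_onset",)),
}


def _hours_to_ts(hours: pd.Series) -> pd.Series:
    ms = np.round(hours.astype(float) * _MS_PER_HOUR)
    out = pd.Series(pd.NaT, index=hours.index, dtype="datetime64[ms]")
    ok = np.isfinite(ms.to_numpy(dtype=float))
    out[ok] = EPOCH + pd.to_timedelta(ms[ok].astype("int64"), unit="ms")
    return out


def _ts_to_hours(ts: pd.Series) -> pd.Series:
    t = pd.to_datetime(ts, format="ISO8601", errors="coerce")
    ms = (t - EPOCH).dt.total_seconds() * 1000.0
    return np.round(ms) / _MS_PER_HOUR


def _timestamp_name(col: str) -> str:
    return {"time_hours": "timestamp", "start_hours": "start_timestamp",
            "end_hours": "end_timestamp"}.get(col, col)


def write_bundles(bundles, path, fmt: str = "csv",
                  ground_truth: pd.DataFrame | None = None) -> Path:
    """Write all event tables under directory ``path``; returns the path."""
    if not isinstance(bundles, BundleSet):
        bundles = BundleSet.from_bundles(list(bundles))
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tables = dict(bundles.tables)
    if ground_truth is not None:
        tables["ground_truth"] = ground_truth
    for name, df in tables.items():
        _, _, time_cols = SCHEMA[name]
        out = df.copy()
        for c in time_cols:
            if c in out.columns:
                out[c] = _hours_to_ts(out[c])
        out = out.rename(columns={c: _timestamp_name(c) for c in time_cols})
        if fmt == "csv":
            out.to_csv(path / f"{name}.csv", index=False)
        elif fmt == "parquet":
            out.to_parquet(path / f"{name}.parquet", index=False)
        else:
            raise FormatError(f"unknown format {fmt!r} (csv or parquet)")
    return path


def _read_table(path: Path, name: str, fmt: str) -> pd.DataFrame | None:
    f = path / f"{name}.{'csv' if fmt == 'csv' else 'parquet'}"
    if not f.exists():
        return None
    df = pd.read_csv(f) if fmt == "csv" else pd.read_parquet(f)
    required, optional, time_cols = SCHEMA[name]
    rename = {_timestamp_name(c): c for c in time_cols}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"table {name!r} is missing column(s) {missing}")
    keep = list(required) + [c for c in optional if c in df.columns]
    extra = [c for c in df.columns if c not in keep]
    if extra:
        warnings.warn(
            f"table {name!r}: ignoring unknown column(s) {extra}",
            stacklevel=3)
    df = df[keep].copy()
    for c in time_cols:
        df[c] = _ts_to_hours(df[c])
    if "perturbation" in df.columns:  # empty string means "none"
        df["perturbation"] = df["perturbation"].fillna("").astype(str)
    return df


def read_bundles(path, fmt: str | None = None
                 ) -> tuple[BundleSet, pd.DataFrame | None]:
    """Read event tables from ``path``; returns (bundles, ground_truth|None)."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if (path / "patients.csv").exists() else "parquet"
    tables = {}
    for name in BundleSet.TABLE_NAMES:
        df = _read_table(path, name, fmt)
        if df is None:
            raise FormatError(f"required table {name!r} not found in {path}")
        tables[name] = df
    for name in ("observations", "patients"):
        for col in ("variable", "patient_id"):
            if col in tables[name].columns:
                tables[name][col] = tables[name][col].astype(str)
    truth = _read_table(path, "ground_truth", fmt)
    return BundleSet(**tables), truth
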