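"""Readers and writers for observed-PK tables, parameter files and results.

One canonical tabular dialect: comma-separated, header row, dot decimal,
UTF-8.  Observed concentration-time records use the columns
(study, species, analyte, matrix, dose_mgkg, time_day, conc, unit).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .metrics import OBSERVED_COLUMNS, ANALYTES
from .units import SUPPORTED_UNITS


class ObservedSchemaError(ValueError):
    """Raised for malformed observed-data tables; cites the offending row/column."""


def _validate_observed(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OBSERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ObservedSchemaError(f"missing column(s): {', '.join(missing)}")
    norm_units = df["unit"].astype(str).str.replace("µ", "u", regex=False).str.strip()
    bad_unit = ~norm_units.isin(SUPPORTED_UNITS)
    if bad_unit.any():
        row = int(df.index[bad_unit][0])
        raise ObservedSchemaError(
            f"row {row}: unsupported unit {df['unit'].iloc[row]!r} "
            f"(expected one of {SUPPORTED_UNITS})")
    bad_analyte = ~df["analyte"].isin(ANALYTES)
    if bad_analyte.any():
        row = int(df.index[bad_analyte][0])
        raise ObservedSchemaError(
            f"row {row}: unknown analyte {df['analyte'].iloc[row]!r}")
    if (df["conc"].astype(float) < 0).any():
        row = int(df.index[df["conc"].astype(float) < 0][0])
        raise ObservedSchemaError(f"row {row}: negative concentration")
    df = df.copy()
    df["unit"] = norm_units
    return df


def read_observed(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate an observed concentration-time table."""
    df = pd.read_csv(path, comment="#")
    return _validate_observed(df)


def write_observed(df: pd.DataFrame, path: str | Path) -> None:
    """Validate and write an observed table (lossless round trip)."""
    df = _validate_observed(df)
    df.to_csv(path, index=False, columns=list(OBSERVED_COLUMNS))


def read_params(path: str | Path) -> dict:
    """Read a structured (YAML) parameter file to a plain dict."""
    return yaml.safe_load(Path(path).read_text())


def write_result(result, path: str | Path) -> None:
    """Write a simulation result as a long-format CSV with a JSON metadata header."""
    path = Path(path)
    meta = dict(result.metadata)
    meta["regimen"] = {"dose_per_admin": result.regimen.dose_per_admin,
                       "times_days": list(result.regimen.times_days),
                       "route": result.regimen.route}
    header = "# " + json.dumps(meta, sort_keys=True)
    frame = result.to_frame()
    with open(path, "w") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, index=False)
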