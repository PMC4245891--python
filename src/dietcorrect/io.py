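"""CSV/JSON interchange and run logging.

The single tabular format is CSV with the documented person header::

    id,sex,age,weight_kg,height_cm,ei_claimed_kcal,ee_kcal,
    special_diet,atypical_day,nonreporter,race_group

``sex`` accepts 1/2, M/F or male/female and is canonicalised to 1/2;
``age`` maps to the internal ``age_years``.  Optional fields are empty
cells.  Models and distributions travel as JSON documents; every CLI run
emits a RunLog JSON with the effective configuration, master seed, package
version and input/output digests, so identical config + seed reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .metrics import sex_code
from .simulate import SimulationResult

__all__ = [
    "read_person_table",
    "write_person_table",
    "write_results",
    "read_results",
    "RunLog",
]

_REQUIRED = ("sex", "age_years", "weight_kg", "ei_claimed_kcal")
_CSV_ALIASES = {"age": "age_years"}
_BOOL_COLUMNS = ("special_diet", "atypical_day", "nonreporter")
_CSV_ORDER = ["id", "sex", "age", "weight_kg", "height_cm", "ei_claimed_kcal",
              "ee_kcal", "special_diet", "atypical_day", "nonreporter", "race_group"]


def _to_bool(col: pd.Series) -> pd.Series:
    def one(v):
        if pd.isna(v) or v == "":
            return False
        if isinstance(v, str):
            return v.strip().lower() in ("1", "true", "t", "yes", "y")
        return bool(v)
    return col.map(one)


def read_person_table(path) -> pd.DataFrame:
    """Read and validate a person CSV.

    Raises a named error for missing mandatory columns and reports
    unparseable numerics with their row number.  Per-column missingness
    counts are attached as ``df.attrs["missingness"]``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df = df.rename(columns=_CSV_ALIASES)
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{col} required but missing from {path}")
    for col in ("age_years", "weight_kg", "height_cm", "ei_claimed_kcal", "ee_kcal"):
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"unparseable numeric in column {col!r}, row {row}: "
                             f"{df[col].iloc[row]!r}")
        df[col] = parsed
    df["sex"] = sex_code(df["sex"].to_numpy())
    for col in _BOOL_COLUMNS:
        if col in df.columns:
            df[col] = _to_bool(df[col])
    if "race_group" in df.columns:
        df["race_group"] = df["race_group"].fillna("unknown").replace("", "unknown")
    df.attrs["missingness"] = {c: int(df[c].isna().sum()) for c in df.columns}
    return df


def write_person_table(df: pd.DataFrame, path) -> None:
    """Write a person table with the documented header (full precision)."""
    out = df.rename(columns={"age_years": "age"})
    cols = [c for c in _CSV_ORDER if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False)


def write_results(result, path) -> None:
    """Serialise a SimulationResult (JSON) or a table (CSV) to ``path``."""
    path = Path(path)
    if path.is_dir():
        raise ValueError(f"{path} is a directory")
    if isinstance(result, SimulationResult):
        with open(path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
            fh.write("\n")
    elif isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False)
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")


def read_results(path) -> SimulationResult:
    with open(path) as fh:
        return SimulationResult.from_dict(json.load(fh))


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunLog:
    """Provenance record for one CLI run."""

    command: str
    config: dict
    seed: Optional[int] = None
    timestamp: str = field(default_factory=lambda: datetime.datetime.now(
        datetime.timezone.utc).isoformat())
    package_version: str = ""
    input_digests: Dict[str, str] = field(default_factory=dict)
    output_digests: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.package_version:
            from . import __version__
            self.package_version = __version__

    def add_input(self, path):
        self.input_digests[str(path)] = _digest(path)

    def add_output(self, path):
        self.output_digests[str(path)] = _digest(path)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")
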