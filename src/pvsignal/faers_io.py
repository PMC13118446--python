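"""Reading and writing FAERS-dialect quarterly ASCII tables.

FAERS distributes its quarterly data as ``'$'``-delimited, unquoted ASCII
files with a single header line (DEMO, DRUG, REAC, OUTC, INDI, ...).  This
module parses those files into :class:`pandas.DataFrame` objects with a
normalized column set per table kind, handles missing values and age-unit
conversion, and writes files back in the same dialect.

Because the files are unquoted, an embedded ``'$'`` inside a field cannot be
represented; this is a documented limitation of the dialect itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: Mandatory columns per table kind. Extra columns are preserved as-is.
TABLE_COLUMNS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid", "fda_dt", "sex", "age", "age_cod",
             "occp_cod", "reporter_country"],
    "drug": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "indi": ["primaryid", "indi_pt"],
}

#: Columns whose absence is a hard format error (the rest default to missing).
KEY_COLUMNS: dict[str, list[str]] = {
    "demo": ["primaryid", "caseid", "fda_dt"],
    "drug": ["primaryid", "role_cod"],
    "reac": ["primaryid", "pt"],
    "outc": ["primaryid", "outc_cod"],
    "indi": ["primaryid", "indi_pt"],
}

ROLE_CODES = {"PS", "SS", "SC", "C", "I"}
OUTCOME_CODES = {"DE", "LT", "HO", "DS", "CA", "RI", "OT"}

#: Hours per year uses the mean Gregorian year (365.25 d); weeks likewise.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


class FormatError(ValueError):
    """A FAERS table file violates the dialect (e.g. missing mandatory column)."""


@dataclass
class RawReportBundle:
    """Parsed rows of the five FAERS tables for one quarter range, pre-cleaning."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame = field(default_factory=pd.DataFrame)
    indi: pd.DataFrame = field(default_factory=pd.DataFrame)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {"demo": self.demo, "drug": self.drug, "reac": self.reac,
                "outc": self.outc, "indi": self.indi}


def read_table(path: str | Path, table_kind: str) -> pd.DataFrame:
    """Read one ``'$'``-delimited FAERS table into a DataFrame of strings.

    Parameters
    ----------
    path
        File whose first line is the ``'$'``-separated header.
    table_kind
        One of ``demo | drug | reac | outc | indi`` (case-insensitive).

    Returns
    -------
    DataFrame with at least the kind's mandatory columns; blank fields become
    empty strings (the missing marker); unknown extra columns are preserved.

    Raises
    ------
    FormatError
        If a mandatory column is absent from the header.
    """
    kind = table_kind.lower()
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind: {table_kind!r}")
    df = pd.read_csv(path, sep=DELIMITER, dtype=str, keep_default_na=False,
                     engine="python", quoting=3)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in KEY_COLUMNS[kind]:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r} "
                              f"for table kind {kind!r}")
    for col in TABLE_COLUMNS[kind]:
        if col not in df.columns:
            df[col] = ""
    logger.info("read %s: %d rows from %s", kind.upper(), len(df), path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame in the FAERS ASCII dialect (header + '$' rows)."""
    out = df.fillna("").astype(str)
    if out.apply(lambda s: s.str.contains(r"\$").any()).any():
        raise FormatError("field values may not contain the '$' delimiter")
    out.to_csv(path, sep=DELIMITER, index=False, lineterminator="\n")


def read_bundle(directory: str | Path, quarters: list[str] | None = None
                ) -> RawReportBundle:
    """Read DEMO/DRUG/REAC/OUTC/INDI files from *directory*.

    Files are matched by prefix (``DEMO*.txt`` etc.) so both single-quarter
    (``DEMO24Q1.txt``) and concatenated exports are accepted; multiple files
    per kind are concatenated.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for kind in TABLE_COLUMNS:
        paths = sorted(directory.glob(f"{kind.upper()}*.txt"))
        if quarters is not None:
            wanted = {q.upper() for q in quarters}
            paths = [p for p in paths if p.stem[4:].upper() in wanted or not p.stem[4:]]
        if paths:
            frames[kind] = pd.concat([read_table(p, kind) for p in paths],
                                     ignore_index=True)
        else:
            frames[kind] = pd.DataFrame(columns=TABLE_COLUMNS[kind])
    if frames["demo"].empty:
        raise FormatError(f"no DEMO*.txt file found in {directory}")
    return RawReportBundle(**frames)


def write_bundle(bundle: RawReportBundle, directory: str | Path,
                 quarter_tag: str = "14Q3") -> dict[str, Path]:
    """Write all five tables as ``DEMO<tag>.txt`` etc.; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for kind, df in bundle.tables().items():
        p = directory / f"{kind.upper()}{quarter_tag}.txt"
        write_table(df if not df.empty else pd.DataFrame(columns=TABLE_COLUMNS[kind]), p)
        paths[kind] = p
    return paths


def age_in_years(age, age_cod: str) -> float:
    """Convert an (age, unit-code) pair to years; NaN when unconvertible.

    Unit codes: DEC (decades), YR, MON, WK, DY, HR.  A missing unit with a
    nonmissing age is treated as years (the FAERS convention) and flagged via
    a log warning; a negative age is invalid and yields NaN.
    """
    try:
        value = float(age)
    except (TypeError, ValueError):
        return float("nan")
    if np.isnan(value):
        return float("nan")
    if value < 0:
        logger.warning("negative age %r treated as missing", age)
        return float("nan")
    code = (age_cod or "").strip().upper()
    if code == "":
        logger.warning("age %r has no unit code; assuming years", age)
        return value
    if code not in AGE_UNIT_TO_YEARS:
        logger.warning("unknown age unit %r treated as missing", age_cod)
        return float("nan")
    return value * AGE_UNIT_TO_YEARS[code]


def ages_in_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Vectorized :func:`age_in_years` over aligned Series."""
    value = pd.to_numeric(age, errors="coerce")
    code = age_cod.fillna("").str.strip().str.upper().replace("", "YR")
    factor = code.map(AGE_UNIT_TO_YEARS)
    out = value * factor
    out[value < 0] = np.nan
    return out


def parse_fda_dt(raw: pd.Series) -> pd.Series:
    """Parse yyyymmdd date strings to integers; unparseable dates become <NA>.

    Kept as integers (not datetimes): the dedup rule only needs a total order
    and yyyymmdd integers order identically to the calendar.
    """
    as_num = pd.to_numeric(raw, errors="coerce")
    dt = pd.to_datetime(raw, format="%Y%m%d", errors="coerce")
    as_num[dt.isna()] = np.nan
    return as_num.astype("Int64")
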