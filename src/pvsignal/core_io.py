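"""Data model and readers/writers for FAERS-style quarterly relational tables.

A spontaneous-reporting dataset is held as a small bundle of pandas
DataFrames mirroring the FAERS quarterly extract layout:

``demo``
    one row per report: ``primaryid, caseid, fda_dt, event_dt, sex,
    age_yrs, wt_kg, reporter, country``
``drug``
    one row per drug mention: ``primaryid, drugname, role_cod, start_dt``
    with role codes PS (primary suspect), SS, C, I
``reac``
    one row per reported reaction: ``primaryid, pt_code, pt_name``
``outc``
    one row per report outcome: ``primaryid, outc_cod``
``indi``
    optional, one row per reported indication: ``primaryid, indi_name``

Date fields are FAERS ``YYYYMMDD`` text tokens and are kept raw; use
:func:`parse_date` wherever day-resolution arithmetic is needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from datetime import date
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "Dataset",
    "ParsedDate",
    "FormatError",
    "IntegrityError",
    "parse_date",
    "normalize_drug_name",
    "read_quarter",
    "write_table",
    "DEMO_COLUMNS",
    "DRUG_COLUMNS",
    "REAC_COLUMNS",
]

DEMO_COLUMNS = [
    "primaryid", "caseid", "fda_dt", "event_dt",
    "sex", "age_yrs", "wt_kg", "reporter", "country",
]
DRUG_COLUMNS = ["primaryid", "drugname", "role_cod", "start_dt"]
REAC_COLUMNS = ["primaryid", "pt_code", "pt_name"]
OUTC_COLUMNS = ["primaryid", "outc_cod"]
INDI_COLUMNS = ["primaryid", "indi_name"]

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})

OUTCOME_CODES = frozenset(
    {"DE", "LT", "HO", "DS", "CA", "RI", "OT"}
)  # death, life-threatening, hospitalization, disability,
#    congenital anomaly, required intervention, other serious


class FormatError(ValueError):
    """A table is missing a mandatory column or is otherwise malformed."""


class IntegrityError(ValueError):
    """A child row references a primaryid absent from the demographics table."""


@dataclass(frozen=True)
class ParsedDate:
    """Result of parsing a FAERS date token.

    ``kind`` is one of ``full`` (day precision), ``partial`` (year or
    year-month precision), ``invalid`` (impossible value such as month 13
    or the 0000-00-00 / 9999-99-99 sentinels), or ``missing``.
    """

    kind: str
    date: date | None = None
    year: int | None = None
    month: int | None = None

    @property
    def is_full(self) -> bool:
        return self.kind == "full"


_MISSING = ParsedDate("missing")
_INVALID = ParsedDate("invalid")


def parse_date(raw: object) -> ParsedDate:
    """Parse a FAERS ``YYYYMMDD`` / ``YYYYMM`` / ``YYYY`` date token.

    Total over all inputs: every token maps to exactly one of
    full / partial / invalid / missing; nothing raises.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return _MISSING
    s = str(raw).strip()
    if s.endswith(".0"):  # pandas float round-trip of an integer token
        s = s[:-2]
    if s == "" or s.lower() in {"nan", "none"}:
        return _MISSING
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return _INVALID
    year = int(s[:4])
    if year < 1900 or year > 2100:
        return _INVALID
    if len(s) == 4:
        return ParsedDate("partial", year=year)
    month = int(s[4:6])
    if month < 1 or month > 12:
        return _INVALID
    if len(s) == 6:
        return ParsedDate("partial", year=year, month=month)
    day = int(s[6:8])
    try:
        return ParsedDate("full", date=date(year, month, day), year=year, month=month)
    except ValueError:
        return _INVALID


_WS = re.compile(r"\s+")


def normalize_drug_name(name: str) -> str:
    """Trim, case-fold, and collapse internal whitespace.

    No ingredient mapping is attempted: brand and generic names of the same
    product remain distinct, as is conventional in FAERS screens.
    """
    return _WS.sub(" ", str(name).strip()).casefold()


@dataclass
class Dataset:
    """A spontaneous-reporting dataset (demographics + drugs + reactions)."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=OUTC_COLUMNS))
    indi: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=INDI_COLUMNS))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, frame, cols in [
            ("demo", self.demo, DEMO_COLUMNS),
            ("drug", self.drug, DRUG_COLUMNS),
            ("reac", self.reac, REAC_COLUMNS),
            ("outc", self.outc, OUTC_COLUMNS),
            ("indi", self.indi, INDI_COLUMNS),
        ]:
            missing = [c for c in cols if c not in frame.columns]
            if missing:
                raise FormatError(f"{name} table missing column(s): {missing}")
        known = set(self.demo["primaryid"])
        for name, frame in [("drug", self.drug), ("reac", self.reac),
                            ("outc", self.outc), ("indi", self.indi)]:
            orphans = set(frame["primaryid"]) - known
            if orphans:
                raise IntegrityError(
                    f"{name} table references unknown primaryid(s): "
                    f"{sorted(orphans)[:5]}"
                )

    @property
    def n_reports(self) -> int:
        return len(self.demo)

    def subset(self, primary_ids) -> "Dataset":
        """Restrict every table to the given reports."""
        keep = set(primary_ids)
        return Dataset(
            demo=self.demo[self.demo["primaryid"].isin(keep)].reset_index(drop=True),
            drug=self.drug[self.drug["primaryid"].isin(keep)].reset_index(drop=True),
            reac=self.reac[self.reac["primaryid"].isin(keep)].reset_index(drop=True),
            outc=self.outc[self.outc["primaryid"].isin(keep)].reset_index(drop=True),
            indi=self.indi[self.indi["primaryid"].isin(keep)].reset_index(drop=True),
        )


_SEPARATORS = {"faers-ascii": "$", "csv": ","}


def _read_one(path: str | Path, sep: str, required: list[str],
              numeric: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing column(s) {missing}")
    df = df[required].copy()
    df = df.replace("", pd.NA)
    for col in numeric:
        # unparseable numeric fields become missing, never errors
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_quarter(paths: Mapping[str, str | Path],
                 dialect: str = "faers-ascii") -> Dataset:
    """Read one quarter's tables into a :class:`Dataset`.

    ``paths`` maps table roles (``demo``, ``drug``, ``reac`` required;
    ``outc``, ``indi`` optional) to file paths.  ``dialect`` selects the
    delimiter: ``faers-ascii`` uses ``$``, ``csv`` a comma.
    """
    if dialect not in _SEPARATORS:
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _SEPARATORS[dialect]
    for role in ("demo", "drug", "reac"):
        if role not in paths:
            raise FormatError(f"missing required table path: {role}")

    demo = _read_one(paths["demo"], sep, DEMO_COLUMNS,
                     numeric=["primaryid", "caseid", "age_yrs", "wt_kg"])
    drug = _read_one(paths["drug"], sep, DRUG_COLUMNS, numeric=["primaryid"])
    reac = _read_one(paths["reac"], sep, REAC_COLUMNS,
                     numeric=["primaryid", "pt_code"])
    if "outc" in paths:
        outc = _read_one(paths["outc"], sep, OUTC_COLUMNS, numeric=["primaryid"])
    else:
        outc = pd.DataFrame(columns=OUTC_COLUMNS)
    if "indi" in paths:
        indi = _read_one(paths["indi"], sep, INDI_COLUMNS, numeric=["primaryid"])
    else:
        indi = pd.DataFrame(columns=INDI_COLUMNS)

    drug["drugname"] = drug["drugname"].map(normalize_drug_name)
    drug["role_cod"] = drug["role_cod"].astype(str).str.strip().str.upper()
    demo["sex"] = demo["sex"].fillna("unknown").astype(str).str.strip().str.lower()
    demo["reporter"] = demo["reporter"].fillna("unknown").astype(str).str.strip().str.lower()
    demo["country"] = demo["country"].fillna("unknown").astype(str).str.strip()
    return Dataset(demo=demo, drug=drug, reac=reac, outc=outc, indi=indi)


def write_table(records, path: str | Path, fmt: str = "csv") -> Path:
    """Write a result collection (DataFrame or dataclass sequence) as CSV.

    An empty collection yields a header-only file when the element type can
    be inferred (DataFrame) and raises otherwise.  Round-trips through
    ``pd.read_csv``.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported format {fmt!r}")
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows and hasattr(rows[0], "__dataclass_fields__"):
            df = pd.DataFrame(
                [{f.name: getattr(r, f.name) for f in fields(r)} for r in rows]
            )
        else:
            df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return path
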