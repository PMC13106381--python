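"""Descriptive summaries of a curated case series.

Reproduces the conventional spontaneous-report summary table: report year,
sex, age and weight bins, reporter type, country, outcome codes, and
time-to-onset bins, each as count plus percentage to two decimals.

Denominator conventions: outcome and time-to-onset blocks use their own
category totals (a report can carry several outcomes, and the TTO block's
``unknown`` row counts excluded reports); every other block uses the total
case count.
"""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .core_io import Dataset, parse_date

__all__ = ["percent_of", "age_bin", "weight_bin", "summarize",
           "AGE_BIN_LABELS", "WEIGHT_BIN_LABELS"]

AGE_BIN_LABELS = ["<=18", "19-44", "45-64", ">=65", "unknown"]
WEIGHT_BIN_LABELS = ["<50", "50-100", ">100", "unknown"]

OUTCOME_NAMES = {
    "DE": "death", "LT": "life-threatening", "HO": "hospitalization",
    "DS": "disability", "CA": "congenital-anomaly",
    "RI": "required-intervention", "OT": "other-serious",
}


def percent_of(count: int, denom: int):
    """100*count/denom, rounded half-up to two decimals; NaN if denom is 0."""
    if denom == 0:
        return float("nan")
    pct = Decimal(100 * count) / Decimal(denom)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def age_bin(age) -> str:
    """Integer-year bins [0,18], [19,44], [45,64], [65,inf); missing -> unknown."""
    if age is None or (isinstance(age, float) and np.isnan(age)):
        return "unknown"
    if age < 0:
        warnings.warn(f"negative age {age!r} treated as unknown")
        return "unknown"
    if age <= 18:
        return "<=18"
    if age < 45:
        return "19-44"
    if age < 65:
        return "45-64"
    return ">=65"


def weight_bin(w) -> str:
    """Weight bins [0,50), [50,100], (100,inf) kg; missing -> unknown."""
    if w is None or (isinstance(w, float) and np.isnan(w)):
        return "unknown"
    if w < 50:
        return "<50"
    if w <= 100:  # inclusive upper edge of the middle band
        return "50-100"
    return ">100"


def _block(variable, counts: pd.Series, denom: int, kind: str):
    return [
        {"variable": variable, "level": str(lvl), "count": int(n),
         "percent": percent_of(int(n), denom), "denominator_kind": kind}
        for lvl, n in counts.items()
    ]


def summarize(dataset: Dataset, tto_bin_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Summary rows for a (deduplicated) case dataset.

    ``tto_bin_table`` is the output of :func:`pvsignal.tto_weibull.tto_bins`
    pooled over the drugs of interest; when given it is appended with its
    own category-total denominator.
    """
    demo = dataset.demo
    n = len(demo)
    rows: list[dict] = []
    if n == 0:
        return pd.DataFrame(
            columns=["variable", "level", "count", "percent", "denominator_kind"])

    year = demo["fda_dt"].map(lambda s: parse_date(s).year).astype("Int64")
    rows += _block("year", year.value_counts(dropna=False).sort_index(), n, "all-reports")
    rows += _block("sex", demo["sex"].value_counts(), n, "all-reports")
    ages = demo["age_yrs"].map(age_bin)
    rows += _block("age", ages.value_counts().reindex(AGE_BIN_LABELS).dropna().astype(int),
                   n, "all-reports")
    weights = demo["wt_kg"].map(weight_bin)
    rows += _block("weight",
                   weights.value_counts().reindex(WEIGHT_BIN_LABELS).dropna().astype(int),
                   n, "all-reports")
    rows += _block("reporter", demo["reporter"].value_counts(), n, "all-reports")
    rows += _block("country", demo["country"].value_counts(), n, "all-reports")

    if len(dataset.outc):
        oc = dataset.outc["outc_cod"].map(lambda c: OUTCOME_NAMES.get(c, c))
        counts = oc.value_counts()
        rows += _block("outcome", counts, int(counts.sum()), "category-total")

    if tto_bin_table is not None and len(tto_bin_table):
        total = int(tto_bin_table["count"].sum())
        for _, r in tto_bin_table.iterrows():
            rows.append({"variable": "tto", "level": r["bin"],
                         "count": int(r["count"]),
                         "percent": percent_of(int(r["count"]), total),
                         "denominator_kind": "category-total"})
    return pd.DataFrame(rows)
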