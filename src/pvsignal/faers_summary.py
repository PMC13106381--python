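"""Published summary counts of the FAERS cognitive-disorder case series.

These are the printed counts of the 2004-2024 FAERS case series for the
MedDRA preferred term "Cognitive disorder" (41,775 deduplicated reports):
the demographic/temporal/outcome/time-to-onset distribution, and the top
50 primary-suspect drugs with their report counts and whether the FDA
label carries a cognitive-disorder warning.  They serve as fixed inputs
for arithmetic checks (percentage reconstruction, warning-status share);
the underlying raw extract is not redistributable and is not packaged.
"""

from __future__ import annotations

import pandas as pd

from .descriptives import percent_of

__all__ = ["CASE_SERIES_TOTAL", "table1_counts", "table1_percentages",
           "top50_warning_table", "warning_no_share"]

CASE_SERIES_TOTAL = 41_775

YEAR_COUNTS = {
    2004: 299, 2005: 400, 2006: 453, 2007: 540, 2008: 545, 2009: 578,
    2010: 1302, 2011: 1517, 2012: 1670, 2013: 2313, 2014: 2141, 2015: 2600,
    2016: 2593, 2017: 2671, 2018: 3018, 2019: 2811, 2020: 3346, 2021: 3432,
    2022: 3289, 2023: 3042, 2024: 3213,
}
SEX_COUNTS = {"female": 23432, "male": 15389, "unknown": 2952}
AGE_COUNTS = {"<=18": 1087, "19-44": 5958, "45-64": 9426, ">=65": 9643,
              "unknown": 15658}
WEIGHT_COUNTS = {"<50": 895, "50-100": 8637, ">100": 1240, "unknown": 31001}
REPORTER_COUNTS = {"consumer": 20249, "physician": 9054, "pharmacist": 5189,
                   "other-health-professional": 4712, "unknown": 1601,
                   "lawyer": 946, "registered-nurse": 22}
COUNTRY_COUNTS = {"United States": 20655, "Canada": 2423,
                  "United Kingdom": 2316, "France": 1419, "Germany": 1054}
OUTCOME_COUNTS = {"other-serious": 21220, "hospitalization": 13192,
                  "disability": 4434, "life-threatening": 1915,
                  "death": 1658, "congenital-anomaly": 537,
                  "required-intervention": 366}
TTO_COUNTS = {"<2": 2449, "2-5": 443, "5-7": 185, "7-14": 454,
              "14-28": 615, ">=28": 5770, "unknown": 15791}

# top-50 signal drugs: (name, case reports, label carries a warning)
TOP50_WARNINGS: list[tuple[str, int, bool]] = [
    ("finasteride", 1370, False), ("oxcarbazepine", 151, True),
    ("lorlatinib", 115, True), ("diltiazem hydrochloride", 44, False),
    ("valproate sodium", 511, True), ("carbidopa/levodopa", 1245, False),
    ("avapritinib", 192, True), ("diroximel fumarate", 186, False),
    ("natalizumab", 3254, False), ("nitroglycerin", 78, False),
    ("topiramate", 488, True), ("donepezil", 162, False),
    ("divalproex sodium", 210, True), ("haloperidol", 180, True),
    ("dimethyl fumarate", 1440, False), ("teriflunomide", 531, False),
    ("interferon beta-1a", 1984, False),
    ("fingolimod hydrochloride", 1001, False),
    ("peginterferon beta-1a", 140, False), ("rivastigmine", 177, False),
    ("clonazepam", 224, False), ("lansoprazole", 47, False),
    ("carbamazepine", 234, False), ("paroxetine", 38, True),
    ("siponimod", 81, True), ("alemtuzumab", 116, False),
    ("pimavanserin tartrate", 373, False), ("levetiracetam", 471, True),
    ("lacosamide", 40, False), ("lorazepam", 45, True),
    ("oxycodone", 41, False), ("ocrelizumab", 356, False),
    ("dalfampridine", 406, False), ("escitalopram oxalate", 327, False),
    ("tramadol", 40, False), ("olanzapine", 326, False),
    ("lamotrigine", 341, False), ("ofatumumab", 174, False),
    ("gabapentin", 434, False), ("niraparib", 129, False),
    ("ixazomib", 46, False), ("zolpidem", 46, False),
    ("phenytoin", 99, True), ("vimpat", 44, False),
    ("mirtazapine", 109, False), ("sertraline hydrochloride", 295, False),
    ("fluoxetine", 141, True), ("venlafaxine hydrochloride", 265, False),
    ("interferon beta-1b", 128, False),
    ("duloxetine hydrochloride", 252, False),
]


def table1_counts() -> dict[str, dict]:
    """All published count blocks, keyed by variable."""
    return {"year": YEAR_COUNTS, "sex": SEX_COUNTS, "age": AGE_COUNTS,
            "weight": WEIGHT_COUNTS, "reporter": REPORTER_COUNTS,
            "country": COUNTRY_COUNTS, "outcome": OUTCOME_COUNTS,
            "tto": TTO_COUNTS}


def table1_percentages() -> pd.DataFrame:
    """Recompute every published percentage cell from its printed counts.

    The outcome and time-to-onset blocks use their own category totals as
    denominator; every other block uses the 41,775 case total.
    """
    rows = []
    for variable, counts in table1_counts().items():
        if variable in ("outcome", "tto"):
            denom = sum(counts.values())
        else:
            denom = CASE_SERIES_TOTAL
        for level, count in counts.items():
            rows.append({"variable": variable, "level": str(level),
                         "count": count, "percent": percent_of(count, denom)})
    return pd.DataFrame(rows)


def top50_warning_table() -> pd.DataFrame:
    return pd.DataFrame(TOP50_WARNINGS,
                        columns=["drugname", "case_reports", "warning"])


def warning_no_share() -> tuple[int, int, float]:
    """(drugs without a label warning, total drugs, percent without)."""
    tab = top50_warning_table()
    n_no = int((~tab["warning"]).sum())
    return n_no, len(tab), percent_of(n_no, len(tab))
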