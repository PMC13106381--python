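"""Curation of raw spontaneous reports into the analysis set.

Applies the standard FAERS screening sequence: drop duplicate submissions
(same case identifier and receipt date, keep the highest primaryid), tag
reports as cases under a MedDRA preferred-term case definition, keep only
primary-suspect (PS) drug mentions, and apply configurable exclusions
(e.g. overdose-coded reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import Dataset

__all__ = [
    "CaseDefinition",
    "NARROW",
    "BROAD",
    "CurationLog",
    "deduplicate",
    "tag_cases",
    "primary_suspect_drugs",
    "curate",
    "case_pairs",
]

# MedDRA preferred-term codes for the cognitive-disorder endpoints:
# 10057668 Cognitive disorder, 10027175 Memory impairment,
# 10010305 Confusional state, 10013496 Disturbance in attention.
PT_COGNITIVE_DISORDER = 10057668
PT_MEMORY_IMPAIRMENT = 10027175
PT_CONFUSIONAL_STATE = 10010305
PT_DISTURBANCE_IN_ATTENTION = 10013496

PT_OVERDOSE = 10033295  # "Overdose"; the default overdose-exclusion set


@dataclass(frozen=True)
class CaseDefinition:
    """A named set of MedDRA PT codes defining case status."""

    name: str
    pt_codes: frozenset[int]

    def __post_init__(self):
        if not self.pt_codes:
            raise ValueError("case definition requires at least one PT code")


NARROW = CaseDefinition("narrow", frozenset({PT_COGNITIVE_DISORDER}))
BROAD = CaseDefinition(
    "broad",
    frozenset({
        PT_COGNITIVE_DISORDER,
        PT_MEMORY_IMPAIRMENT,
        PT_CONFUSIONAL_STATE,
        PT_DISTURBANCE_IN_ATTENTION,
    }),
)


@dataclass
class CurationLog:
    n_input: int = 0
    n_after_dedup: int = 0
    n_cases: int = 0
    n_noncases: int = 0
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": "input", "count": self.n_input},
            {"step": "after_dedup", "count": self.n_after_dedup},
            {"step": "cases", "count": self.n_cases},
            {"step": "noncases", "count": self.n_noncases},
        ]
        rows += [{"step": f"excluded:{k}", "count": v}
                 for k, v in sorted(self.exclusion_counts.items())]
        return pd.DataFrame(rows)


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Within each (caseid, fda_dt) group keep the row with maximal primaryid.

    Duplicate submissions of the same case routed through multiple senders
    share the case identifier and receipt date; the highest primaryid is the
    most recent version.  Output is sorted by primaryid, so the survivor set
    is independent of input row order.
    """
    survivors = (
        demo.sort_values("primaryid")
        .groupby(["caseid", "fda_dt"], dropna=False, sort=False)
        .tail(1)
        .sort_values("primaryid")
        .reset_index(drop=True)
    )
    return survivors


def tag_cases(dataset: Dataset, defn: CaseDefinition) -> pd.Series:
    """Boolean case flag per report, indexed by primaryid.

    A report is a case iff at least one of its reactions carries a PT code
    in the definition; several qualifying PTs still count once.
    """
    hit = dataset.reac[dataset.reac["pt_code"].isin(defn.pt_codes)]
    case_ids = set(hit["primaryid"])
    flags = dataset.demo["primaryid"].isin(case_ids)
    flags.index = pd.Index(dataset.demo["primaryid"], name="primaryid")
    flags.name = "is_case"
    return flags


def primary_suspect_drugs(dataset: Dataset) -> pd.DataFrame:
    """Distinct (primaryid, drugname) pairs for PS-role drug mentions only.

    Secondary-suspect, concomitant and interacting mentions are excluded; a
    report whose drugs are all non-PS contributes no pair.  A report with k
    distinct PS drugs contributes k pairs.
    """
    ps = dataset.drug[dataset.drug["role_cod"] == "PS"]
    return (
        ps[["primaryid", "drugname"]]
        .drop_duplicates()
        .sort_values(["primaryid", "drugname"])
        .reset_index(drop=True)
    )


def curate(
    dataset: Dataset,
    defn: CaseDefinition = NARROW,
    overdose_pt_codes: frozenset[int] = frozenset({PT_OVERDOSE}),
    manual_exclusions: set | None = None,
) -> tuple[Dataset, pd.Series, CurationLog]:
    """Full curation pipeline: dedup -> exclusions -> case tagging.

    ``manual_exclusions`` is an optional caller-supplied primaryid set for
    filters (non-drug-induced, unassessable) that have no computable field
    definition.  Returns the curated dataset, the per-report case flags, and
    a :class:`CurationLog` accounting for every input report.
    """
    log = CurationLog(n_input=len(dataset.demo))

    deduped = deduplicate(dataset.demo)
    log.exclusion_counts["duplicate"] = log.n_input - len(deduped)
    keep = set(deduped["primaryid"])

    if manual_exclusions:
        dropped = keep & set(manual_exclusions)
        log.exclusion_counts["manual"] = len(dropped)
        keep -= dropped

    if overdose_pt_codes:
        od = dataset.reac[dataset.reac["pt_code"].isin(overdose_pt_codes)]
        dropped = keep & set(od["primaryid"])
        log.exclusion_counts["overdose"] = len(dropped)
        keep -= dropped

    # reports with no reaction rows carry no analyzable event
    with_reac = set(dataset.reac["primaryid"])
    dropped = keep - with_reac
    log.exclusion_counts["missing-reaction"] = len(dropped)
    keep &= with_reac

    curated = dataset.subset(keep)
    log.n_after_dedup = len(curated.demo)
    flags = tag_cases(curated, defn)
    log.n_cases = int(flags.sum())
    log.n_noncases = int((~flags).sum())
    return curated, flags, log


def case_pairs(dataset: Dataset, flags: pd.Series) -> pd.DataFrame:
    """(report, PS-drug) analysis pairs with case flags.

    The unit of disproportionality analysis: columns ``primaryid``,
    ``drugname``, ``is_case``.
    """
    pairs = primary_suspect_drugs(dataset)
    pairs["is_case"] = pairs["primaryid"].map(flags).astype(bool)
    return pairs
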