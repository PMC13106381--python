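"""Subgroup (stratified) signal detection and cross-algorithm concordance.

Re-runs the full disproportionality pipeline inside subgroups defined by
sex, age bin, weight bin, or reporting country, with 2x2 margins
recomputed within the stratum.  Reports with an unknown level for the
stratifying variable are excluded from that stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .case_selection import case_pairs
from .core_io import Dataset
from .descriptives import age_bin, weight_bin
from .disproportionality import MgpsHyperparams, compute_signals

__all__ = ["StratumSpec", "stratum_ids", "stratified_signals",
           "top_countries", "concordance"]

STRATUM_VARIABLES = ("sex", "age_bin", "weight_bin", "country")


@dataclass(frozen=True)
class StratumSpec:
    variable: str
    level: str

    def __post_init__(self):
        if self.variable not in STRATUM_VARIABLES:
            raise ValueError(f"unknown stratification variable {self.variable!r}")


def stratum_ids(dataset: Dataset, spec: StratumSpec) -> set:
    """primaryids of reports belonging to the stratum (unknowns excluded)."""
    demo = dataset.demo
    if spec.variable == "sex":
        level = demo["sex"]
    elif spec.variable == "age_bin":
        level = demo["age_yrs"].map(age_bin)
    elif spec.variable == "weight_bin":
        level = demo["wt_kg"].map(weight_bin)
    else:
        level = demo["country"]
    return set(demo.loc[level == spec.level, "primaryid"])


def stratified_signals(dataset: Dataset, flags: pd.Series, spec: StratumSpec,
                       fallback_prior: MgpsHyperparams | None = None,
                       **params) -> pd.DataFrame:
    """Signal screen restricted to one stratum.

    Identical pipeline to the global run on the stratum's reports.  The
    MGPS prior is re-estimated within the stratum; if that fit fails (tiny
    strata) and ``fallback_prior`` is given, the global prior is used
    instead — both behaviors are surfaced via a warning.
    """
    ids = stratum_ids(dataset, spec)
    if not ids:
        warnings.warn(f"empty stratum {spec}")
        return pd.DataFrame()
    sub = dataset.subset(ids)
    sub_flags = flags.loc[flags.index.isin(ids)]
    pairs = case_pairs(sub, sub_flags)
    if pairs.empty or not pairs["is_case"].any():
        warnings.warn(f"stratum {spec} has no case pairs")
        return pd.DataFrame()
    try:
        out = compute_signals(pairs, **params)
    except (RuntimeError, ValueError):
        if fallback_prior is None:
            raise
        warnings.warn(f"stratum {spec}: MGPS prior fit failed, "
                      "falling back to the global prior")
        out = compute_signals(pairs, prior=fallback_prior, **params)
    if not out.empty:
        out.insert(1, "stratum_variable", spec.variable)
        out.insert(2, "stratum_level", spec.level)
    return out


def top_countries(dataset: Dataset, flags: pd.Series, k: int = 5) -> list[str]:
    """Countries ranked by case-report count, descending; ties lexicographic."""
    if k < 1:
        raise ValueError("k must be >= 1")
    case_ids = set(flags.index[flags])
    demo = dataset.demo
    counts = demo.loc[demo["primaryid"].isin(case_ids), "country"].value_counts()
    counts = counts[counts.index != "unknown"]
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [c for c, _ in ranked[:k]]


def concordance(results: pd.DataFrame,
                stats_cols=("ror", "prr", "ic", "ebgm"),
                flag_cols=("flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps")):
    """Pairwise rank agreement of the four algorithms' drug orderings.

    Returns a dict with ``rank_corr`` (Spearman rho per algorithm pair over
    drugs with all statistics defined) and ``n_discordant_flags`` (drugs
    whose per-algorithm flags are not unanimous).  Returns None with fewer
    than two usable drugs.
    """
    use = results.dropna(subset=list(stats_cols))
    if len(use) < 2:
        return None
    rank_corr = {}
    for x, y in combinations(stats_cols, 2):
        rho = stats.spearmanr(use[x], use[y]).statistic
        rank_corr[f"{x}~{y}"] = float(rho)
    flags = use[list(flag_cols)].to_numpy(dtype=bool)
    discordant = int(np.sum(flags.any(axis=1) & ~flags.all(axis=1)))
    return {"rank_corr": rank_corr, "n_discordant_flags": discordant,
            "n_drugs": int(len(use))}
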