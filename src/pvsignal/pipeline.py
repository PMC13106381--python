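"""End-to-end convenience drivers tying the curation and analysis stages.

These are the entry points the numbered analysis scripts call: dataset ->
curated analysis set -> signal table / time-to-onset fits / stratified
runs / risk-factor regression.
"""

from __future__ import annotations

import pandas as pd

from . import risk_factors as rf
from .case_selection import NARROW, CaseDefinition, case_pairs, curate
from .core_io import Dataset
from .disproportionality import compute_signals
from .tto_weibull import compute_tto_samples, fit_weibull

__all__ = ["run_signal_screen", "run_tto_analysis", "run_risk_factors"]


def run_signal_screen(dataset: Dataset, defn: CaseDefinition = NARROW,
                      **signal_params):
    """Curate and screen: returns (signal table, case flags, curation log)."""
    curated, flags, log = curate(dataset, defn)
    pairs = case_pairs(curated, flags)
    signals = compute_signals(pairs, case_definition_name=defn.name,
                              **signal_params)
    return signals, curated, flags, log


def run_tto_analysis(curated: Dataset, flags, drugs=None,
                     min_n: int = 10) -> pd.DataFrame:
    """Per-drug Weibull time-to-onset fits over case reports."""
    samples = compute_tto_samples(curated, flags, drugs=drugs)
    rows = []
    for name, sample in samples.items():
        fit = fit_weibull(sample.onsets, min_n=min_n)
        rows.append({
            "drugname": name, "n": fit.n,
            "n_excluded": int(sum(sample.n_excluded.values())),
            "median_days": fit.median_days,
            "iqr_lo": fit.iqr_days[0], "iqr_hi": fit.iqr_days[1],
            "alpha": fit.alpha, "alpha_lo": fit.alpha_ci[0],
            "alpha_hi": fit.alpha_ci[1],
            "beta": fit.beta, "beta_lo": fit.beta_ci[0],
            "beta_hi": fit.beta_ci[1],
            "pattern": fit.pattern,
        })
    return pd.DataFrame(rows)


def run_risk_factors(curated: Dataset, flags,
                     demographics=("age", "sex", "weight"),
                     top_indications: int = 20, top_drugs: int = 30,
                     p_enter_stay: float = 0.05):
    """Case/non-case regression over demographics + frequent indications
    and suspect drugs; returns (result table, design info)."""
    indic = rf.top_indications(curated, flags, k=top_indications)
    drugs = rf.top_drugs(curated, flags, k=top_drugs)
    y, X, info = rf.build_design(curated, flags, demographics=demographics,
                                 indications=indic, drugs=drugs)
    table = rf.risk_factor_table(y, X, p_enter_stay=p_enter_stay)
    return table, info
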