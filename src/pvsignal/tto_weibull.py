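"""Time-to-onset (TTO) analysis with Weibull failure-pattern classification.

TTO is the number of days from therapy start to adverse-event onset.
Records with implausible or inconsistent dates are excluded by rule:

1. therapy start after event onset,
2. event onset after the receipt date,
3. birth date after event onset (checked only when a birth date exists),
4. invalid date tokens (0000-00-00 / 9999-99-99 sentinels, month > 12,
   day > 31).

Partial (year / year-month) or missing dates cannot support day
arithmetic and are excluded as ``unknown``.  Same-day onsets (0 days) are
kept and mapped to 0.5 days so the Weibull density, which requires
positive support, applies.

The two-parameter Weibull fit (scale alpha in days, shape beta) yields a
failure-pattern label: shape below 1 with the 95% CI excluding 1 is an
*early failure* pattern (hazard decreasing from the start of therapy), CI
including 1 a *random failure* pattern (constant hazard), shape above 1
with CI excluding 1 a *wear-out* pattern (risk accumulating with
exposure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Dataset, parse_date

__all__ = [
    "TtoSample",
    "WeibullFit",
    "compute_tto",
    "compute_tto_samples",
    "tto_bins",
    "fit_weibull",
    "TTO_BIN_LABELS",
]

TTO_BIN_EDGES = [0.0, 2.0, 5.0, 7.0, 14.0, 28.0, np.inf]
TTO_BIN_LABELS = ["<2", "2-5", "5-7", "7-14", "14-28", ">=28"]

EXCLUSION_RULES = (
    "start-after-event",      # rule 1
    "event-after-receipt",    # rule 2
    "birth-after-event",      # rule 3
    "invalid-date",           # rule 4
    "unknown",                # partial or missing dates
)


@dataclass
class TtoSample:
    """Per-drug onset durations plus an accounting of exclusions."""

    drug_name: str
    onsets: np.ndarray
    n_excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.onsets)


@dataclass
class WeibullFit:
    alpha: float            # scale, days
    beta: float             # shape, dimensionless
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    n: int
    median_days: float      # sample median (descriptive, not the fitted one)
    iqr_days: tuple[float, float]
    pattern: str            # early-failure / random-failure / wear-out / indeterminate


def compute_tto(start_raw, event_raw, fda_raw, birth_raw=None):
    """TTO in days for one (report, drug) pair, or an exclusion reason.

    Returns ``(days, None)`` on success and ``(None, reason)`` otherwise;
    exclusion is a return state, never an exception.
    """
    start = parse_date(start_raw)
    event = parse_date(event_raw)
    fda = parse_date(fda_raw)
    birth = parse_date(birth_raw) if birth_raw is not None else None

    for p in (start, event, fda, birth):
        if p is not None and p.kind == "invalid":
            return None, "invalid-date"
    if not (start.is_full and event.is_full):
        return None, "unknown"
    if start.date > event.date:
        return None, "start-after-event"
    if fda.is_full and event.date > fda.date:
        return None, "event-after-receipt"
    if birth is not None and birth.is_full and birth.date > event.date:
        return None, "birth-after-event"
    days = (event.date - start.date).days
    return (0.5 if days == 0 else float(days)), None


def compute_tto_samples(dataset: Dataset, flags: pd.Series,
                        drugs: list[str] | None = None) -> dict[str, TtoSample]:
    """TTO samples per primary-suspect drug, over case reports only."""
    case_ids = set(flags.index[flags])
    ps = dataset.drug[(dataset.drug["role_cod"] == "PS")
                      & dataset.drug["primaryid"].isin(case_ids)]
    if drugs is not None:
        ps = ps[ps["drugname"].isin(drugs)]
    demo = dataset.demo.set_index("primaryid")
    out: dict[str, TtoSample] = {}
    for name, grp in ps.groupby("drugname", sort=True):
        onsets, excl = [], dict.fromkeys(EXCLUSION_RULES, 0)
        for pid, start_raw in zip(grp["primaryid"], grp["start_dt"]):
            row = demo.loc[pid]
            days, reason = compute_tto(start_raw, row["event_dt"], row["fda_dt"])
            if reason is None:
                onsets.append(days)
            else:
                excl[reason] += 1
        out[name] = TtoSample(name, np.asarray(onsets, dtype=float),
                              {k: v for k, v in excl.items() if v})
    return out


def tto_bins(onsets, n_unknown: int = 0) -> pd.DataFrame:
    """Counts and percentages per onset bin, with an ``unknown`` category.

    Bins are half-open [0,2), [2,5), [5,7), [7,14), [14,28), [28, inf);
    percentages use the total over all seven categories (the excluded-
    unknown reports included) as denominator.
    """
    onsets = np.asarray(onsets, dtype=float)
    counts, _ = np.histogram(onsets, bins=TTO_BIN_EDGES)
    labels = TTO_BIN_LABELS + ["unknown"]
    counts = np.append(counts, n_unknown)
    total = counts.sum()
    pct = np.round(100.0 * counts / total, 2) if total else np.zeros(7)
    return pd.DataFrame({"bin": labels, "count": counts, "percent": pct})


def _weibull_loglik(u: float, v: float, x: np.ndarray) -> float:
    """Log-likelihood at log-scale u = ln(alpha), log-shape v = ln(beta)."""
    alpha, beta = np.exp(u), np.exp(v)
    z = x / alpha
    return float(np.sum(np.log(beta / alpha) + (beta - 1) * np.log(z) - z ** beta))


def _hessian_log_scale(u, v, x, h=1e-4):
    """Observed information of the log-parameterized likelihood (central diff)."""
    def f(du, dv):
        return _weibull_loglik(u + du, v + dv, x)
    fuu = (f(h, 0) - 2 * f(0, 0) + f(-h, 0)) / h ** 2
    fvv = (f(0, h) - 2 * f(0, 0) + f(0, -h)) / h ** 2
    fuv = (f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)) / (4 * h ** 2)
    return -np.array([[fuu, fuv], [fuv, fvv]])


def _summaries(x: np.ndarray):
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), (float(q1), float(q3))


def fit_weibull(onsets, min_n: int = 10) -> WeibullFit:
    """Two-parameter Weibull MLE with CIs from the observed information.

    CIs use the normal approximation on the log-parameter scale (which
    respects positivity).  With fewer than ``min_n`` onsets, or on
    numerical failure, the fit is reported ``indeterminate`` with sample
    summaries only.
    """
    x = np.asarray(onsets, dtype=float)
    if len(x) == 0:
        return WeibullFit(np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan),
                          0, np.nan, (np.nan, np.nan), "indeterminate")
    med, iqr = _summaries(x)
    if len(x) < min_n or np.all(x == x[0]):
        return WeibullFit(np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan),
                          len(x), med, iqr, "indeterminate")
    try:
        beta, _, alpha = stats.weibull_min.fit(x, floc=0)
        info = _hessian_log_scale(np.log(alpha), np.log(beta), x)
        cov = np.linalg.inv(info)
        se_u, se_v = np.sqrt(np.diag(cov))
        if not (np.isfinite(se_u) and np.isfinite(se_v)):
            raise np.linalg.LinAlgError("non-finite standard errors")
    except (RuntimeError, np.linalg.LinAlgError, ValueError):
        return WeibullFit(np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan),
                          len(x), med, iqr, "indeterminate")
    z = 1.959963984540054
    alpha_ci = (alpha * np.exp(-z * se_u), alpha * np.exp(z * se_u))
    beta_ci = (beta * np.exp(-z * se_v), beta * np.exp(z * se_v))
    if beta_ci[1] < 1.0:
        pattern = "early-failure"
    elif beta_ci[0] > 1.0:
        pattern = "wear-out"
    else:
        pattern = "random-failure"
    return WeibullFit(float(alpha), float(beta),
                      (float(alpha_ci[0]), float(alpha_ci[1])),
                      (float(beta_ci[0]), float(beta_ci[1])),
                      len(x), med, iqr, pattern)
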