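"""Synthetic FAERS-like spontaneous reporting system with known ground truth.

Emulates the relational structure a quarterly FAERS extract provides —
demographics, drug mentions with role codes, MedDRA-coded reactions,
outcomes, indications — together with the pathologies a curation pipeline
must handle: duplicate submissions sharing a case identifier, partial and
invalid date tokens, and heavy demographic missingness.

Report-level generative model: each report is assigned one primary-
suspect drug by its marginal exposure probability; case status (the
target event is reported) follows a logistic model whose odds are the
baseline reporting odds times the drug's event-rate multiplier rho
(optionally restricted to one demographic stratum) times exp of any
planted covariate log-odds.  Case reports draw an onset delay from the
drug's Weibull(alpha, beta), so time-to-onset behaviour is plantable per
drug.  Everything is reproducible from the seed, and the returned
GroundTruth suffices to score recall and false-positive rates of any
downstream signal call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .case_selection import PT_COGNITIVE_DISORDER
from .core_io import Dataset

__all__ = ["DrugSpec", "CovariateSpec", "SyntheticConfig", "GroundTruth",
           "generate", "scenario_presets"]

TARGET_PT = PT_COGNITIVE_DISORDER
TARGET_PT_NAME = "cognitive disorder"

# background reaction pool (opaque MedDRA-style codes, not the target)
_BACKGROUND_PTS = [(10019211, "headache"), (10028813, "nausea"),
                   (10012735, "diarrhoea"), (10016256, "fatigue"),
                   (10013968, "dizziness"), (10037844, "rash"),
                   (10047700, "vomiting"), (10003239, "arthralgia")]

_DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    # roughly the composition of the published cognitive-disorder case
    # series: female-predominant, US-heavy, consumer-reported
    "sex": {"female": 0.56, "male": 0.37, "unknown": 0.07},
    "country": {"US": 0.50, "CA": 0.06, "GB": 0.06, "FR": 0.03, "DE": 0.03,
                "JP": 0.02, "NL": 0.02, "OTHER": 0.28},
    "reporter": {"consumer": 0.48, "physician": 0.22, "pharmacist": 0.12,
                 "other-health-professional": 0.11, "unknown": 0.04,
                 "lawyer": 0.02, "registered-nurse": 0.01},
    "outcome": {"OT": 0.49, "HO": 0.30, "DS": 0.10, "LT": 0.05, "DE": 0.04,
                "CA": 0.01, "RI": 0.01},
}


@dataclass(frozen=True)
class DrugSpec:
    """One simulated product: exposure share, planted signal, onset law."""

    name: str
    exposure_prob: float
    rho: float = 1.0                 # event-rate odds multiplier (1 = null)
    weibull_alpha: float = 100.0     # onset scale, days
    weibull_beta: float = 1.0        # onset shape
    stratum: tuple[str, str] | None = None  # e.g. ("sex", "female"): rho
    #                                          applies only inside this stratum

    def __post_init__(self):
        if self.rho < 0 or self.exposure_prob < 0:
            raise ValueError("rho and exposure_prob must be non-negative")
        if self.weibull_alpha <= 0 or self.weibull_beta <= 0:
            raise ValueError("Weibull parameters must be positive")


@dataclass(frozen=True)
class CovariateSpec:
    """A binary report-level covariate (recorded as an indication row)."""

    name: str
    prevalence: float
    log_odds: float = 0.0


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    n_reports: int
    drugs: tuple[DrugSpec, ...]
    baseline_event_prob: float = 0.05
    duplicate_rate: float = 0.0
    invalid_date_rate: float = 0.0
    missing_event_date_rate: float = 0.3
    missing_age_rate: float = 0.37
    missing_weight_rate: float = 0.74
    extra_role_rate: float = 0.2     # chance of an additional SS/C/I mention
    covariates: tuple[CovariateSpec, ...] = ()
    demographics: dict = field(default_factory=lambda: _DEFAULT_DEMOGRAPHICS)

    def __post_init__(self):
        for name in ("baseline_event_prob", "duplicate_rate",
                     "invalid_date_rate", "missing_event_date_rate",
                     "missing_age_rate", "missing_weight_rate",
                     "extra_role_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_reports < 1:
            raise ValueError("n_reports must be positive")
        if not self.drugs:
            raise ValueError("at least one drug is required")


@dataclass
class GroundTruth:
    """Every planted quantity, sufficient to score downstream calls."""

    drugs: pd.DataFrame        # name, rho, weibull_alpha/beta, stratum
    covariates: pd.DataFrame   # name, prevalence, log_odds, true_or
    baseline_event_prob: float
    n_base_reports: int
    n_duplicates: int
    case_flags: pd.Series      # planted case status per base primaryid


def _sample_cat(rng, dist: dict[str, float], n: int) -> np.ndarray:
    keys = list(dist)
    p = np.asarray([dist[k] for k in keys], dtype=float)
    return np.asarray(keys, dtype=object)[rng.choice(len(keys), size=n, p=p / p.sum())]


_EPOCH = date(2005, 1, 1)
_SPAN_DAYS = (date(2023, 12, 31) - _EPOCH).days


def _to_token(days: np.ndarray) -> np.ndarray:
    """Day offsets from the epoch -> YYYYMMDD text tokens."""
    out = np.empty(len(days), dtype=object)
    for i, d in enumerate(days):
        dt = _EPOCH + timedelta(days=int(d))
        out[i] = f"{dt.year:04d}{dt.month:02d}{dt.day:02d}"
    return out


def _corrupt(token: str, pattern: int) -> str:
    # the four invalid-date pathologies seen in raw extracts
    if pattern == 0:
        return "00000000"
    if pattern == 1:
        return "99999999"
    if pattern == 2:
        return token[:4] + "13" + token[6:]   # month > 12
    return token[:6] + "32"                    # day > 31


def generate(config: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Draw one full multi-table dataset plus its ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    pid = np.arange(1, n + 1)

    sex = _sample_cat(rng, config.demographics["sex"], n)
    country = _sample_cat(rng, config.demographics["country"], n)
    reporter = _sample_cat(rng, config.demographics["reporter"], n)
    age = np.clip(rng.normal(55.0, 18.0, n), 0.0, 100.0).round(0)
    age[rng.random(n) < config.missing_age_rate] = np.nan
    weight = np.clip(rng.normal(75.0, 18.0, n), 35.0, 200.0).round(1)
    weight[rng.random(n) < config.missing_weight_rate] = np.nan

    # primary-suspect drug per report
    expo = np.asarray([d.exposure_prob for d in config.drugs], dtype=float)
    drug_ix = rng.choice(len(config.drugs), size=n, p=expo / expo.sum())
    rho = np.asarray([d.rho for d in config.drugs])[drug_ix]
    for j, spec in enumerate(config.drugs):
        if spec.stratum is not None:
            var, level = spec.stratum
            in_stratum = {"sex": sex, "country": country}[var] == level
            rho = np.where((drug_ix == j) & ~in_stratum, 1.0, rho)

    # planted binary covariates
    cov_ind = {}
    cov_logodds = np.zeros(n)
    for cov in config.covariates:
        ind = (rng.random(n) < cov.prevalence).astype(float)
        cov_ind[cov.name] = ind
        cov_logodds += cov.log_odds * ind

    base_odds = config.baseline_event_prob / (1 - config.baseline_event_prob)
    odds = base_odds * rho * np.exp(cov_logodds)
    p_case = odds / (1 + odds)
    is_case = rng.random(n) < p_case

    # dates: therapy start, event onset (Weibull for cases), receipt
    start_days = rng.integers(0, _SPAN_DAYS - 800, size=n)
    alpha = np.asarray([d.weibull_alpha for d in config.drugs])[drug_ix]
    beta = np.asarray([d.weibull_beta for d in config.drugs])[drug_ix]
    onset = np.where(is_case,
                     alpha * rng.weibull(beta, size=n),
                     rng.uniform(0, 365, size=n))
    event_days = start_days + np.floor(onset).astype(int)
    fda_days = event_days + rng.integers(1, 61, size=n)

    start_tok = _to_token(start_days)
    event_tok = _to_token(event_days)
    fda_tok = _to_token(fda_days)

    miss = rng.random(n) < config.missing_event_date_rate
    event_tok = np.where(miss, None, event_tok)
    bad = (~miss) & (rng.random(n) < config.invalid_date_rate)
    patterns = rng.integers(0, 4, size=n)
    event_tok = np.asarray([
        _corrupt(t, p) if b else t
        for t, b, p in zip(event_tok, bad, patterns)], dtype=object)

    demo = pd.DataFrame({
        "primaryid": pid, "caseid": pid,
        "fda_dt": fda_tok, "event_dt": event_tok,
        "sex": sex, "age_yrs": age, "wt_kg": weight,
        "reporter": reporter, "country": country,
    })

    names = np.asarray([d.name for d in config.drugs], dtype=object)
    drug_rows = [pd.DataFrame({
        "primaryid": pid, "drugname": names[drug_ix],
        "role_cod": "PS", "start_dt": start_tok,
    })]
    extra = rng.random(n) < config.extra_role_rate
    if extra.any():
        m = int(extra.sum())
        drug_rows.append(pd.DataFrame({
            "primaryid": pid[extra],
            "drugname": names[rng.integers(0, len(names), size=m)],
            "role_cod": _sample_cat(rng, {"SS": 0.5, "C": 0.3, "I": 0.2}, m),
            "start_dt": None,
        }))
    drug = pd.concat(drug_rows, ignore_index=True)

    bg_ix = rng.integers(0, len(_BACKGROUND_PTS), size=n)
    bg_codes = np.asarray([c for c, _ in _BACKGROUND_PTS])[bg_ix]
    bg_names = np.asarray([s for _, s in _BACKGROUND_PTS], dtype=object)[bg_ix]
    reac = pd.DataFrame({
        "primaryid": pid,
        "pt_code": np.where(is_case, TARGET_PT, bg_codes),
        "pt_name": np.where(is_case, TARGET_PT_NAME, bg_names),
    })
    # cases often report accompanying symptoms too
    accomp = is_case & (rng.random(n) < 0.3)
    if accomp.any():
        m = int(accomp.sum())
        ix2 = rng.integers(0, len(_BACKGROUND_PTS), size=m)
        reac = pd.concat([reac, pd.DataFrame({
            "primaryid": pid[accomp],
            "pt_code": np.asarray([c for c, _ in _BACKGROUND_PTS])[ix2],
            "pt_name": np.asarray([s for _, s in _BACKGROUND_PTS], dtype=object)[ix2],
        })], ignore_index=True)

    outc = pd.DataFrame({
        "primaryid": pid,
        "outc_cod": _sample_cat(rng, config.demographics["outcome"], n),
    })

    indi_frames = [pd.DataFrame({"primaryid": pid[ind.astype(bool)],
                                 "indi_name": name})
                   for name, ind in cov_ind.items()]
    indi = (pd.concat(indi_frames, ignore_index=True) if indi_frames
            else pd.DataFrame({"primaryid": pd.Series(dtype=int),
                               "indi_name": pd.Series(dtype=object)}))

    # duplicate submissions: same caseid and receipt date, higher primaryid
    dup_mask = rng.random(n) < config.duplicate_rate
    n_dup = int(dup_mask.sum())
    if n_dup:
        dup_src = pid[dup_mask]
        new_pid = np.arange(n + 1, n + n_dup + 1)
        remap = dict(zip(dup_src, new_pid))
        dup_demo = demo[dup_mask].copy()
        dup_demo["primaryid"] = new_pid
        demo = pd.concat([demo, dup_demo], ignore_index=True)

        def _with_duplicates(frame: pd.DataFrame) -> pd.DataFrame:
            dup = frame[frame["primaryid"].isin(remap)].copy()
            dup["primaryid"] = dup["primaryid"].map(remap)
            return pd.concat([frame, dup], ignore_index=True)

        drug = _with_duplicates(drug)
        reac = _with_duplicates(reac)
        outc = _with_duplicates(outc)
        indi = _with_duplicates(indi)

    dataset = Dataset(demo=demo, drug=drug, reac=reac, outc=outc, indi=indi)
    truth = GroundTruth(
        drugs=pd.DataFrame([{
            "drugname": d.name, "rho": d.rho,
            "weibull_alpha": d.weibull_alpha, "weibull_beta": d.weibull_beta,
            "stratum_variable": d.stratum[0] if d.stratum else None,
            "stratum_level": d.stratum[1] if d.stratum else None,
        } for d in config.drugs]),
        covariates=pd.DataFrame([{
            "name": c.name, "prevalence": c.prevalence,
            "log_odds": c.log_odds, "true_or": float(np.exp(c.log_odds)),
        } for c in config.covariates]),
        baseline_event_prob=config.baseline_event_prob,
        n_base_reports=n,
        n_duplicates=n_dup,
        case_flags=pd.Series(is_case, index=pd.Index(pid, name="primaryid"),
                             name="is_case"),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

def _null_drugs(k: int) -> tuple[DrugSpec, ...]:
    return tuple(DrugSpec(f"drug{i:03d}", exposure_prob=1.0) for i in range(k))


def scenario_presets(seed: int = 0) -> dict[str, SyntheticConfig]:
    """Named study conditions, stable across calls.

    ``null``: 200 signal-free drugs for false-positive calibration.
    ``five-planted-signals``: 25 null drugs plus five with rho in
    {5, 10, 10, 20, 20}.
    ``stratum-signal``: one drug whose multiplier applies to female
    reports only.
    ``tto-mixture``: drugs with planted Weibull shapes 0.5 (early failure)
    and 1.0 (random failure), with complete onset dates.
    ``riskfactor-recovery``: two true report-level covariates (odds
    ratios 3 and 2) among eight noise covariates, low missingness so the
    complete-case regression retains most reports.
    """
    planted = list(_null_drugs(25)) + [
        DrugSpec("signal_r05", 1.0, rho=5.0, weibull_alpha=60.0, weibull_beta=0.8),
        DrugSpec("signal_r10a", 1.0, rho=10.0, weibull_alpha=90.0, weibull_beta=0.6),
        DrugSpec("signal_r10b", 1.0, rho=10.0, weibull_alpha=120.0, weibull_beta=1.0),
        DrugSpec("signal_r20a", 1.0, rho=20.0, weibull_alpha=45.0, weibull_beta=0.5),
        DrugSpec("signal_r20b", 1.0, rho=20.0, weibull_alpha=150.0, weibull_beta=1.2),
    ]
    tto_drugs = tuple(
        DrugSpec(f"tto_{kind}{i}", 1.0, rho=5.0, weibull_alpha=a, weibull_beta=b)
        for i, (kind, a, b) in enumerate([
            ("early", 60.0, 0.5), ("early", 90.0, 0.5), ("early", 120.0, 0.5),
            ("random", 60.0, 1.0), ("random", 90.0, 1.0), ("random", 120.0, 1.0),
        ])
    )
    rf_covs = (
        CovariateSpec("depression", 0.20, float(np.log(3.0))),
        CovariateSpec("anxiety", 0.15, float(np.log(2.0))),
    ) + tuple(CovariateSpec(f"noise{i:02d}", 0.10, 0.0) for i in range(8))

    return {
        "null": SyntheticConfig(
            seed=seed, n_reports=40_000, drugs=_null_drugs(200),
            baseline_event_prob=0.05, duplicate_rate=0.05,
            invalid_date_rate=0.05),
        "five-planted-signals": SyntheticConfig(
            seed=seed, n_reports=20_000, drugs=tuple(planted),
            baseline_event_prob=0.05, duplicate_rate=0.05,
            invalid_date_rate=0.05),
        "stratum-signal": SyntheticConfig(
            seed=seed, n_reports=20_000,
            drugs=tuple(_null_drugs(19)) + (
                DrugSpec("femaledrug", 2.0, rho=8.0, stratum=("sex", "female")),),
            baseline_event_prob=0.05),
        "tto-mixture": SyntheticConfig(
            seed=seed, n_reports=30_000, drugs=tto_drugs,
            baseline_event_prob=0.05, missing_event_date_rate=0.0,
            invalid_date_rate=0.0),
        "riskfactor-recovery": SyntheticConfig(
            seed=seed, n_reports=20_000, drugs=_null_drugs(10),
            baseline_event_prob=0.08, covariates=rf_covs,
            missing_age_rate=0.05, missing_weight_rate=0.10,
            missing_event_date_rate=0.3),
    }
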