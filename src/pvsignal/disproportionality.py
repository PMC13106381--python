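"""Disproportionality statistics on 2x2 drug-event contingency tables.

For each drug the screen counts, over (report, primary-suspect drug)
analysis pairs:

    a  pairs with the drug and the target event
    b  pairs with the drug, other events
    c  pairs of other drugs with the target event
    d  everything else

and computes four signal statistics with their interval estimates:

ROR
    reporting odds ratio (a*d)/(b*c), Wald CI on the log scale.
PRR
    proportional reporting ratio [a/(a+b)]/[c/(c+d)] with Wald CI and the
    Yates-corrected Pearson chi-square.
BCPNN IC
    the shrunk information component of the Bayesian confidence
    propagation neural network (Bate closed form with canonical priors by
    default; the Noren gamma-posterior variant is available).
MGPS EBGM
    DuMouchel's gamma-Poisson shrinker: counts a ~ Poisson(lambda*E) with
    lambda drawn from a two-component gamma mixture prior whose
    hyperparameters are estimated by marginal maximum likelihood; EBGM is
    the posterior geometric mean of lambda, EB05/EB025 its lower
    posterior quantiles.

A drug-event pair is called signal-positive (``consensus``) only when all
four algorithms pass their conventional thresholds (ROR 95% lower bound
> 1; PRR >= 2 with chi-square >= 4; IC025 > 0; EBGM025 > 2) and the
Bonferroni-adjusted chi-square p-value is below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "MgpsHyperparams",
    "build_tables",
    "ror_ci",
    "prr_chi2",
    "bcpnn_ic",
    "fit_mgps_prior",
    "ebgm_quantiles",
    "consensus_call",
    "compute_signals",
    "THRESHOLDS",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile

THRESHOLDS = {
    "ror_lo": 1.0,       # lower 95% CI bound of the ROR must exceed this
    "prr": 2.0,
    "chi2": 4.0,
    "ic025": 0.0,
    "eb025": 2.0,
    "alpha": 0.05,       # on the Bonferroni-adjusted p-value
}


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def build_tables(pairs: pd.DataFrame, min_count: int = 3,
                 include_untested: bool = False) -> pd.DataFrame:
    """One 2x2 table per drug from (primaryid, drugname, is_case) pairs.

    Margins are conserved: a+b+c+d equals the global pair count for every
    drug.  Tables whose target-event count ``a`` falls below ``min_count``
    are dropped unless ``include_untested`` is set, in which case they are
    kept with ``tested=False`` (they still inform the MGPS prior).  Tables
    with an empty comparator margin (c+d == 0) are flagged ``degenerate``.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    n_pairs = len(pairs)
    n_cases = int(pairs["is_case"].sum())
    per_drug = pairs.groupby("drugname", sort=True)["is_case"].agg(["sum", "count"])
    tab = pd.DataFrame({
        "drugname": per_drug.index,
        "a": per_drug["sum"].astype(int).to_numpy(),
        "b": (per_drug["count"] - per_drug["sum"]).astype(int).to_numpy(),
    })
    tab["c"] = n_cases - tab["a"]
    tab["d"] = n_pairs - n_cases - tab["b"]
    tab["N"] = n_pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        tab["E"] = (tab["a"] + tab["b"]) * (tab["a"] + tab["c"]) / tab["N"]
    tab["degenerate"] = (tab["c"] + tab["d"]) == 0
    tab["tested"] = tab["a"] >= min_count
    if not include_untested:
        tab = tab[tab["tested"]].reset_index(drop=True)
    return tab


def _cells(t, continuity: bool):
    a = np.asarray(t["a"], dtype=float)
    b = np.asarray(t["b"], dtype=float)
    c = np.asarray(t["c"], dtype=float)
    d = np.asarray(t["d"], dtype=float)
    if continuity:
        zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
        a, b, c, d = (x + np.where(zero, 0.5, 0.0) for x in (a, b, c, d))
    return a, b, c, d


# ---------------------------------------------------------------------------
# frequentist statistics
# ---------------------------------------------------------------------------

def ror_ci(t, continuity: bool = False):
    """Reporting odds ratio with 95% Wald CI.

    Returns (ror, lo, hi); NaN triple when a cell is zero and the
    Haldane-Anscombe +0.5 continuity correction is off.
    """
    a, b, c, d = _cells(t, continuity)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        ror = np.where(ok, (a * d) / (b * c), np.nan)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = ror * np.exp(-Z95 * se)
        hi = ror * np.exp(Z95 * se)
    return ror, lo, hi


def prr_chi2(t, continuity: bool = False):
    """PRR with 95% Wald CI, plus the Yates-corrected chi-square and p-value.

    The chi-square (always computed on the uncorrected integer cells) is
    N(|ad-bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)] referred to chi2(1).
    """
    a, b, c, d = _cells(t, continuity)
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = (a > 0) & (c > 0) & (a + b > 0) & (c + d > 0)
        prr = np.where(ok, (a / (a + b)) / (c / (c + d)), np.nan)
        se = np.sqrt(np.clip(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d), 0, None))
        lo = prr * np.exp(-Z95 * se)
        hi = prr * np.exp(Z95 * se)

    a0 = np.asarray(t["a"], dtype=float)
    b0 = np.asarray(t["b"], dtype=float)
    c0 = np.asarray(t["c"], dtype=float)
    d0 = np.asarray(t["d"], dtype=float)
    n = a0 + b0 + c0 + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (a0 + b0) * (c0 + d0) * (a0 + c0) * (b0 + d0)
        num = n * np.clip(np.abs(a0 * d0 - b0 * c0) - n / 2, 0, None) ** 2
        chi2 = np.where(denom > 0, num / denom, np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return prr, lo, hi, chi2, p


# ---------------------------------------------------------------------------
# BCPNN information component
# ---------------------------------------------------------------------------

def bcpnn_ic(t, variant: str = "bate"):
    """Shrunk information component (IC) with its lower bound IC025.

    ``bate`` (default): the closed-form posterior expectation and variance
    with canonical priors gamma11=1, alpha1=beta1=1, alpha=beta=2;
    IC025 = IC - 2*sqrt(V).  ``noren``: IC = log2((a+0.5)/(E+0.5)) with
    IC025 the 2.5% quantile of log2 of a Gamma(a+0.5, rate E+0.5)
    posterior.
    """
    a = np.asarray(t["a"], dtype=float)
    b = np.asarray(t["b"], dtype=float)
    c = np.asarray(t["c"], dtype=float)
    d = np.asarray(t["d"], dtype=float)
    n = a + b + c + d
    if variant == "noren":
        e = (a + b) * (a + c) / n
        ic = np.log2((a + 0.5) / (e + 0.5))
        ic025 = np.log2(stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (e + 0.5)))
        return ic, ic025
    if variant != "bate":
        raise ValueError(f"unknown BCPNN variant {variant!r}")
    g11, a1, b1, al, be = 1.0, 1.0, 1.0, 2.0, 2.0
    row = a + b + a1        # drug margin + prior
    col = a + c + b1        # event margin + prior
    gamma = g11 * (n + al) * (n + be) / (row * col)
    ic = np.log2((a + g11) * (n + al) * (n + be) / ((n + gamma) * row * col))
    v = (1.0 / np.log(2.0) ** 2) * (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + al - a1) / (row * (1 + n + al))
        + (n - (a + c) + be - b1) / (col * (1 + n + be))
    )
    ic025 = ic - 2.0 * np.sqrt(v)
    return ic, ic025


# ---------------------------------------------------------------------------
# MGPS / EBGM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MgpsHyperparams:
    """Two-component gamma mixture prior on the relative reporting rate.

    lambda ~ p_mix * Gamma(alpha1, rate beta1) + (1-p_mix) * Gamma(alpha2,
    rate beta2); the marginal of the count a given baseline E is the
    matching mixture of negative binomials.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p_mix: float

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 < self.p_mix < 1:
            raise ValueError("p_mix must lie in (0, 1)")

    @property
    def prior_mean(self) -> float:
        return (self.p_mix * self.alpha1 / self.beta1
                + (1 - self.p_mix) * self.alpha2 / self.beta2)


# canonical MGPS starting point for the marginal MLE
_MGPS_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _mixture_logpmf(a, e, theta):
    a1, b1, a2, b2, p = theta
    lp1 = stats.nbinom.logpmf(a, a1, b1 / (b1 + e))
    lp2 = stats.nbinom.logpmf(a, a2, b2 / (b2 + e))
    return np.logaddexp(np.log(p) + lp1, np.log1p(-p) + lp2)


def mgps_marginal_loglik(a, e, prior: MgpsHyperparams) -> float:
    """Total log marginal likelihood of counts ``a`` with baselines ``e``."""
    theta = (prior.alpha1, prior.beta1, prior.alpha2, prior.beta2, prior.p_mix)
    return float(np.sum(_mixture_logpmf(np.asarray(a), np.asarray(e), theta)))


def fit_mgps_prior(tables: pd.DataFrame, start=_MGPS_START) -> MgpsHyperparams:
    """Estimate the mixture prior by maximizing the marginal likelihood.

    Optimizes over unconstrained transforms (log for the gamma parameters,
    logit for the mixture weight) with Nelder-Mead from the canonical
    start.  Raises on non-convergence, carrying optimizer diagnostics.
    """
    use = tables[tables["E"] > 0]
    if len(use) < 2:
        raise ValueError("need at least 2 tables with positive E")
    a = use["a"].to_numpy(dtype=float)
    e = use["E"].to_numpy(dtype=float)

    def unpack(z):
        return (np.exp(z[0]), np.exp(z[1]), np.exp(z[2]), np.exp(z[3]),
                special.expit(z[4]))

    def nll(z):
        theta = unpack(z)
        if max(theta[:4]) > 1e8:
            return 1e12
        with np.errstate(all="ignore"):
            ll = np.sum(_mixture_logpmf(a, e, theta))
        return 1e12 if not np.isfinite(ll) else -ll

    z0 = np.array([np.log(start[0]), np.log(start[1]), np.log(start[2]),
                   np.log(start[3]), special.logit(start[4])])
    # The mixture weight is weakly identified on null-like data, leaving a
    # flat likelihood ridge on which the simplex can stall; restart from
    # the terminal point and accept once the objective stops improving.
    opts = {"maxiter": 5000, "maxfev": 8000, "xatol": 1e-5, "fatol": 1e-7}
    res = optimize.minimize(nll, z0, method="Nelder-Mead", options=opts)
    for _ in range(3):
        if res.success:
            break
        prev = res.fun
        res = optimize.minimize(nll, res.x, method="Nelder-Mead", options=opts)
        if prev - res.fun < 1e-6:  # converged in value: flat-ridge stall
            break
    else:
        if not res.success:
            raise RuntimeError(
                f"MGPS prior fit did not converge: {res.message}")
    a1, b1, a2, b2, p = unpack(res.x)
    return MgpsHyperparams(a1, b1, a2, b2, p)


def _posterior_weight(a, e, prior: MgpsHyperparams):
    """Posterior probability that lambda came from the first component."""
    lp1 = stats.nbinom.logpmf(a, prior.alpha1, prior.beta1 / (prior.beta1 + e))
    lp2 = stats.nbinom.logpmf(a, prior.alpha2, prior.beta2 / (prior.beta2 + e))
    l1 = np.log(prior.p_mix) + lp1
    l2 = np.log1p(-prior.p_mix) + lp2
    return np.exp(l1 - np.logaddexp(l1, l2))


def _posterior_cdf(lam, a, e, q, prior: MgpsHyperparams):
    return (q * stats.gamma.cdf(lam, prior.alpha1 + a, scale=1 / (prior.beta1 + e))
            + (1 - q) * stats.gamma.cdf(lam, prior.alpha2 + a,
                                        scale=1 / (prior.beta2 + e)))


def _mixture_ppf(prob, a, e, q, prior: MgpsHyperparams) -> float:
    q1 = stats.gamma.ppf(prob, prior.alpha1 + a, scale=1 / (prior.beta1 + e))
    q2 = stats.gamma.ppf(prob, prior.alpha2 + a, scale=1 / (prior.beta2 + e))
    # effectively single-component posteriors need no root-finding
    if q >= 1 - 1e-12:
        return float(q1)
    if q <= 1e-12:
        return float(q2)
    lo, hi = min(q1, q2), max(q1, q2)
    if np.isclose(lo, hi):
        return float(lo)
    # pad the bracket: the mixture quantile may sit at an endpoint to
    # within floating-point roundoff
    lo, hi = lo * (1 - 1e-9), hi * (1 + 1e-9)
    return float(optimize.brentq(
        lambda lam: _posterior_cdf(lam, a, e, q, prior) - prob, lo, hi,
        xtol=1e-12, rtol=1e-12))


def ebgm_quantiles(tables, prior: MgpsHyperparams):
    """Posterior EBGM (geometric mean) and lower quantiles EB05, EB025.

    The posterior of lambda given count a and baseline E is the gamma
    mixture Q*Gamma(alpha1+a, beta1+E) + (1-Q)*Gamma(alpha2+a, beta2+E)
    with Q the posterior component weight; EBGM = exp(E[ln lambda]) via the
    digamma closed form, the quantiles by root-finding on the mixture CDF.
    """
    a = np.asarray(tables["a"], dtype=float)
    e = np.asarray(tables["E"], dtype=float)
    q = _posterior_weight(a, e, prior)
    mean_ln = (
        q * (special.digamma(prior.alpha1 + a) - np.log(prior.beta1 + e))
        + (1 - q) * (special.digamma(prior.alpha2 + a) - np.log(prior.beta2 + e))
    )
    ebgm = np.exp(mean_ln)
    eb05 = np.array([_mixture_ppf(0.05, ai, ei, qi, prior)
                     for ai, ei, qi in zip(a, e, q)])
    eb025 = np.array([_mixture_ppf(0.025, ai, ei, qi, prior)
                      for ai, ei, qi in zip(a, e, q)])
    return ebgm, eb05, eb025


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_call(results: pd.DataFrame, n_tests: int) -> pd.DataFrame:
    """Per-algorithm flags, Bonferroni adjustment, and the four-way call.

    A pair is consensus-positive only when every algorithm passes its
    threshold and the Bonferroni-adjusted p-value is below 0.05; an
    undefined (NaN) statistic fails its flag.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    r = results.copy()
    thr = THRESHOLDS
    r["p_adj"] = np.minimum(1.0, r["p_value"] * n_tests)
    r["flag_ror"] = (r["ror_lo"] > thr["ror_lo"]).fillna(False)
    r["flag_prr"] = ((r["prr"] >= thr["prr"]) & (r["chi2"] >= thr["chi2"])).fillna(False)
    r["flag_bcpnn"] = (r["ic025"] > thr["ic025"]).fillna(False)
    r["flag_mgps"] = (r["eb025"] > thr["eb025"]).fillna(False)
    r["consensus"] = (
        r["flag_ror"] & r["flag_prr"] & r["flag_bcpnn"] & r["flag_mgps"]
        & (r["p_adj"] < thr["alpha"])
    )
    return r


def compute_signals(
    pairs: pd.DataFrame,
    case_definition_name: str = "narrow",
    min_count: int = 3,
    continuity: bool = False,
    bcpnn_variant: str = "bate",
    include_zeroes: bool = True,
    prior: MgpsHyperparams | None = None,
) -> pd.DataFrame:
    """End-to-end signal screen over (report, PS-drug) analysis pairs.

    Builds contingency tables, fits the MGPS prior (on all tables including
    sub-threshold ones when ``include_zeroes``, matching openEBGM usage),
    computes all four statistics for tables passing ``min_count``, and
    applies the consensus rule with Bonferroni correction over the number
    of tested pairs.  Returns one row per tested drug.
    """
    all_tables = build_tables(pairs, min_count=min_count, include_untested=True)
    tested = all_tables[all_tables["tested"] & ~all_tables["degenerate"]].reset_index(drop=True)
    if tested.empty:
        return pd.DataFrame()
    if prior is None:
        prior_tables = all_tables if include_zeroes else tested
        prior = fit_mgps_prior(prior_tables)

    ror, ror_lo, ror_hi = ror_ci(tested, continuity=continuity)
    prr, prr_lo, prr_hi, chi2, p = prr_chi2(tested, continuity=continuity)
    ic, ic025 = bcpnn_ic(tested, variant=bcpnn_variant)
    ebgm, eb05, eb025 = ebgm_quantiles(tested, prior)

    out = pd.DataFrame({
        "drugname": tested["drugname"],
        "case_definition": case_definition_name,
        "a": tested["a"], "b": tested["b"], "c": tested["c"], "d": tested["d"],
        "E": tested["E"],
        "ror": ror, "ror_lo": ror_lo, "ror_hi": ror_hi,
        "prr": prr, "prr_lo": prr_lo, "prr_hi": prr_hi,
        "chi2": chi2, "p_value": p,
        "ic": ic, "ic025": ic025,
        "ebgm": ebgm, "eb05": eb05, "eb025": eb025,
    })
    return consensus_call(out, n_tests=len(tested))
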