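"""Case/non-case logistic regression for reporting-odds risk factors.

Reports carrying the target event are the cases, every other report a
non-case.  Candidate covariates are demographics (age, sex, weight,
reporter type) plus presence/absence indicators for the most frequently
reported indications and suspect drugs.  Univariate logistic screens are
followed by backward stepwise elimination at P < 0.05, and the retained
model is checked for multicollinearity with variance inflation factors
(VIF < 5 acceptable; tolerance = 1/VIF).

The outputs are reporting associations only — spontaneous-report data
carry no exposure denominators, so odds ratios here are not risks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .core_io import Dataset

__all__ = [
    "build_design",
    "top_indications",
    "top_drugs",
    "univariate_screen",
    "stepwise_multivariate",
    "vif_check",
    "risk_factor_table",
]

Z95 = 1.959963984540054


def top_indications(dataset: Dataset, flags: pd.Series, k: int = 20) -> list[str]:
    """The k indications most frequently reported among cases."""
    case_ids = set(flags.index[flags])
    indi = dataset.indi[dataset.indi["primaryid"].isin(case_ids)]
    return indi["indi_name"].value_counts().head(k).index.tolist()


def top_drugs(dataset: Dataset, flags: pd.Series, k: int = 30) -> list[str]:
    """The k primary-suspect drugs most frequently reported among cases."""
    case_ids = set(flags.index[flags])
    ps = dataset.drug[(dataset.drug["role_cod"] == "PS")
                      & dataset.drug["primaryid"].isin(case_ids)]
    return ps["drugname"].value_counts().head(k).index.tolist()


def build_design(dataset: Dataset, flags: pd.Series,
                 demographics: tuple[str, ...] = ("age", "sex", "weight"),
                 indications: list[str] | None = None,
                 drugs: list[str] | None = None):
    """Outcome vector and covariate matrix for the case/non-case regression.

    Complete-case rule: rows missing any selected demographic are dropped
    (counts logged via the returned dict).  Indication and drug covariates
    are 0/1 presence indicators per report and never create missingness.
    Covariates constant after filtering are dropped with a warning.

    Returns ``(y, X, info)`` with y indexed by primaryid.
    """
    demo = dataset.demo.set_index("primaryid")
    X = pd.DataFrame(index=demo.index)
    if "age" in demographics:
        X["age"] = demo["age_yrs"]
    if "weight" in demographics:
        X["weight"] = demo["wt_kg"]
    if "sex" in demographics:
        sex = demo["sex"].map({"male": 1.0, "female": 0.0})
        X["sex_male"] = sex
    if "reporter" in demographics:
        rep = demo["reporter"]
        X["reporter_hcp"] = np.where(
            rep.isin(["physician", "pharmacist", "other-health-professional",
                      "registered-nurse"]), 1.0,
            np.where(rep == "unknown", np.nan, 0.0))

    for name in indications or []:
        with_ind = set(dataset.indi.loc[dataset.indi["indi_name"] == name,
                                        "primaryid"])
        X[f"indi:{name}"] = demo.index.isin(with_ind).astype(float)
    for name in drugs or []:
        with_drug = set(dataset.drug.loc[
            (dataset.drug["drugname"] == name)
            & (dataset.drug["role_cod"] == "PS"), "primaryid"])
        X[f"drug:{name}"] = demo.index.isin(with_drug).astype(float)

    n_before = len(X)
    keep = X.notna().all(axis=1)
    X = X[keep]
    info = {"n_input": n_before, "n_complete": int(keep.sum()),
            "n_dropped_missing": int(n_before - keep.sum())}

    constant = [c for c in X.columns if X[c].nunique() < 2]
    if constant:
        warnings.warn(f"dropping single-level covariate(s): {constant}")
        X = X.drop(columns=constant)
    y = flags.reindex(X.index).astype(float)
    return y, X, info


def _fit_logit(y, X):
    """Logit fit returning (result, separation_flag)."""
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return None, True
    separated = (not res.mle_retvals.get("converged", False)
                 or not np.all(np.isfinite(res.bse))
                 or np.any(res.bse > 50))
    return res, separated


def univariate_screen(y: pd.Series, X: pd.DataFrame) -> pd.DataFrame:
    """Single-covariate logistic fits: OR, Wald 95% CI and p per variable.

    Perfect separation is flagged and the OR reported as NaN.
    """
    rows = []
    for col in X.columns:
        res, separated = _fit_logit(y, X[[col]])
        if res is None or separated:
            rows.append({"variable": col, "uni_or": np.nan, "uni_lo": np.nan,
                         "uni_hi": np.nan, "uni_p": np.nan, "separation": True})
            continue
        beta, se = res.params[col], res.bse[col]
        rows.append({
            "variable": col,
            "uni_or": float(np.exp(beta)),
            "uni_lo": float(np.exp(beta - Z95 * se)),
            "uni_hi": float(np.exp(beta + Z95 * se)),
            "uni_p": float(res.pvalues[col]),
            "separation": False,
        })
    return pd.DataFrame(rows)


def stepwise_multivariate(y: pd.Series, X: pd.DataFrame,
                          p_enter_stay: float = 0.05):
    """Backward elimination from univariate-significant candidates.

    Starting set: variables with univariate p < ``p_enter_stay`` and no
    separation.  Iteratively refit and remove the variable with the
    largest p >= threshold (ties broken by variable name, so the result is
    invariant to input column/row order) until all retained variables are
    significant.  Returns (final statsmodels result or None, retained
    variable list, univariate screen table).
    """
    uni = univariate_screen(y, X)
    candidates = sorted(
        uni.loc[(uni["uni_p"] < p_enter_stay) & ~uni["separation"], "variable"])
    while candidates:
        res, separated = _fit_logit(y, X[candidates])
        if res is None:
            # drop the (alphabetically) last variable and retry
            candidates = candidates[:-1]
            continue
        pvals = res.pvalues.drop("const")
        worst_p = pvals.max()
        if worst_p < p_enter_stay and not separated:
            return res, candidates, uni
        # remove the largest-p variable; ties broken by name
        worst = sorted(pvals.index[pvals == worst_p])[-1] if not separated \
            else sorted(pvals.index[~np.isfinite(res.bse.drop("const"))]
                        or [pvals.idxmax()])[-1]
        candidates = [c for c in candidates if c != worst]
    return None, [], uni


def vif_check(X: pd.DataFrame) -> pd.DataFrame:
    """Variance inflation factors of the retained covariates.

    VIF_j = 1/(1 - R^2_j) from regressing covariate j on the others (with
    intercept); tolerance is its reciprocal.  A singular design raises,
    naming the collinear columns.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF requires at least 2 covariates")
    Xc = sm.add_constant(X, has_constant="add")
    arr = np.asarray(Xc, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise np.linalg.LinAlgError(
            f"singular design; most collinear pair: "
            f"{corr.index[pair[0]]!r} ~ {corr.columns[pair[1]]!r}")
    cols = list(X.columns)
    vifs = [variance_inflation_factor(arr, i + 1) for i in range(len(cols))]
    return pd.DataFrame({"variable": cols, "vif": vifs,
                         "tolerance": [1.0 / v for v in vifs]})


def risk_factor_table(y: pd.Series, X: pd.DataFrame,
                      p_enter_stay: float = 0.05) -> pd.DataFrame:
    """Combined univariate + stepwise-multivariate + VIF result table."""
    res, retained, uni = stepwise_multivariate(y, X, p_enter_stay)
    out = uni.set_index("variable")
    for col in ("multi_or", "multi_lo", "multi_hi", "multi_p", "vif", "tolerance"):
        out[col] = np.nan
    if res is not None and retained:
        beta = res.params.drop("const")
        se = res.bse.drop("const")
        out.loc[retained, "multi_or"] = np.exp(beta)
        out.loc[retained, "multi_lo"] = np.exp(beta - Z95 * se)
        out.loc[retained, "multi_hi"] = np.exp(beta + Z95 * se)
        out.loc[retained, "multi_p"] = res.pvalues.drop("const")
        if len(retained) >= 2:
            vif = vif_check(X[retained]).set_index("variable")
            out.loc[retained, "vif"] = vif["vif"]
            out.loc[retained, "tolerance"] = vif["tolerance"]
    return out.reset_index()
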