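"""Case/non-case logistic regression: screens, stepwise selection, VIF."""

import numpy as np
import pandas as pd
import pytest

from pvsignal.case_selection import curate
from pvsignal.risk_factors import (build_design, risk_factor_table,
                                   stepwise_multivariate, top_drugs,
                                   top_indications, univariate_screen,
                                   vif_check)
from pvsignal.synthetic import (CovariateSpec, DrugSpec, SyntheticConfig,
                                generate, scenario_presets)


@pytest.fixture(scope="module")
def rf_run():
    ds, truth = generate(scenario_presets(seed=31)["riskfactor-recovery"])
    curated, flags, _ = curate(ds)
    return curated, flags, truth


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def test_build_design_indicator_columns(tiny_dataset):
    curated, flags, _ = curate(tiny_dataset)
    y, X, info = build_design(curated, flags, demographics=(),
                              drugs=["alphadrug"])
    expected = curated.drug.loc[
        curated.drug.role_cod == "PS", ["primaryid", "drugname"]]
    exposed = set(expected.loc[expected.drugname == "alphadrug", "primaryid"])
    assert all(X.loc[pid, "drug:alphadrug"] == (1.0 if pid in exposed else 0.0)
               for pid in X.index)


def test_build_design_complete_case_rule(rf_run):
    curated, flags, _ = rf_run
    y_all, X_all, info_all = build_design(curated, flags, demographics=())
    y, X, info = build_design(curated, flags,
                              demographics=("age", "weight"))
    missing_any = curated.demo[["age_yrs", "wt_kg"]].isna().any(axis=1).sum()
    assert info["n_dropped_missing"] == missing_any
    assert info_all["n_dropped_missing"] == 0
    assert len(y) == len(X) == info["n_complete"]


def test_build_design_drops_constant_covariate(tiny_dataset):
    curated, flags, _ = curate(tiny_dataset)
    with pytest.warns(UserWarning, match="single-level"):
        _, X, _ = build_design(curated, flags, demographics=(),
                               drugs=["nosuchdrug"])
    assert "drug:nosuchdrug" not in X.columns


def test_top_indications_and_drugs_ranked_by_case_frequency(rf_run):
    curated, flags, _ = rf_run
    indic = top_indications(curated, flags, k=3)
    assert len(indic) == 3
    assert len(top_drugs(curated, flags, k=4)) == 4
    # planted prevalent covariates dominate the indication ranking
    assert "depression" in indic


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------

def test_univariate_recovers_planted_odds_ratio():
    cfg = SyntheticConfig(
        seed=101, n_reports=20_000,
        drugs=tuple(DrugSpec(f"d{i}", 1.0) for i in range(5)),
        baseline_event_prob=0.05,
        covariates=(CovariateSpec("exposure", 0.3, float(np.log(5.0))),),
        missing_age_rate=0.0, missing_weight_rate=0.0)
    ds, _ = generate(cfg)
    curated, flags, _ = curate(ds)
    y, X, _ = build_design(curated, flags, demographics=(),
                           indications=["exposure"])
    uni = univariate_screen(y, X).set_index("variable")
    assert 4.0 < uni.loc["indi:exposure", "uni_or"] < 6.0
    assert uni.loc["indi:exposure", "uni_p"] < 1e-10


def test_univariate_type_one_error_controlled():
    """A covariate independent of the outcome exceeds p=0.05 rarely."""
    rng = np.random.default_rng(7)
    rejections = 0
    for _ in range(100):
        y = pd.Series((rng.random(800) < 0.2).astype(float))
        X = pd.DataFrame({"x": (rng.random(800) < 0.3).astype(float)})
        uni = univariate_screen(y, X)
        if uni["uni_p"].iloc[0] < 0.05:
            rejections += 1
    assert rejections <= 10


def test_perfect_separation_flagged():
    y = pd.Series([0.0] * 10 + [1.0] * 10)
    X = pd.DataFrame({"x": [0.0] * 10 + [1.0] * 10})
    uni = univariate_screen(y, X)
    assert uni["separation"].iloc[0]
    assert np.isnan(uni["uni_or"].iloc[0])


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def test_stepwise_retains_planted_predictors(rf_run):
    curated, flags, truth = rf_run
    planted = [c for c in truth.covariates.name
               if truth.covariates.set_index("name").loc[c, "log_odds"] != 0]
    y, X, _ = build_design(curated, flags, demographics=("age", "sex"),
                           indications=list(truth.covariates.name))
    res, retained, _ = stepwise_multivariate(y, X)
    assert {f"indi:{c}" for c in planted} <= set(retained)
    noise = {c for c in retained if c.startswith("indi:noise")}
    assert len(noise) <= 2  # near the nominal false-inclusion rate


def test_stepwise_all_noise_usually_empty():
    rng = np.random.default_rng(9)
    empties = 0
    reps = 20
    for _ in range(reps):
        n = 2000
        y = pd.Series((rng.random(n) < 0.2).astype(float))
        X = pd.DataFrame({f"x{i}": (rng.random(n) < 0.3).astype(float)
                          for i in range(5)})
        _, retained, _ = stepwise_multivariate(y, X)
        empties += not retained
    # five independent screens at alpha=0.05 leave the model empty with
    # probability ~0.95^5 ~ 0.77; a majority of empty replicates suffices
    assert empties >= reps // 2 + 1


def test_stepwise_single_significant_variable():
    rng = np.random.default_rng(12)
    n = 5000
    x = (rng.random(n) < 0.3).astype(float)
    p = 1 / (1 + np.exp(-(-2.0 + 1.5 * x)))
    y = pd.Series((rng.random(n) < p).astype(float))
    X = pd.DataFrame({"x": x, "z": (rng.random(n) < 0.4).astype(float)})
    _, retained, _ = stepwise_multivariate(y, X)
    assert retained == ["x"]


def test_stepwise_invariant_to_row_order(rf_run):
    curated, flags, truth = rf_run
    y, X, _ = build_design(curated, flags, demographics=(),
                           indications=list(truth.covariates.name))
    _, retained1, _ = stepwise_multivariate(y, X)
    perm = np.random.default_rng(0).permutation(len(X))
    _, retained2, _ = stepwise_multivariate(y.iloc[perm], X.iloc[perm])
    assert retained1 == retained2


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def test_vif_orthogonal_covariates_equal_one():
    X = pd.DataFrame({"a": [1, 1, -1, -1, 1, 1, -1, -1.0],
                      "b": [1, -1, 1, -1, 1, -1, 1, -1.0]})
    vif = vif_check(X)
    assert vif["vif"].tolist() == pytest.approx([1.0, 1.0])


def test_vif_duplicated_covariate_raises():
    rng = np.random.default_rng(0)
    x = rng.random(50)
    X = pd.DataFrame({"a": x, "b": x})
    with pytest.raises(np.linalg.LinAlgError, match="'a' ~ 'b'"):
        vif_check(X)


def test_vif_tolerance_product_is_one(rf_run):
    curated, flags, truth = rf_run
    y, X, _ = build_design(curated, flags, demographics=(),
                           indications=list(truth.covariates.name))
    tab = risk_factor_table(y, X)
    with_vif = tab.dropna(subset=["vif"])
    assert len(with_vif) >= 2
    assert np.allclose(with_vif["vif"] * with_vif["tolerance"], 1.0)


def test_multivariate_beats_univariate_under_confounding():
    """With correlated exposures, the adjusted estimates sit closer to the
    planted log-odds than the marginal ones."""
    rng = np.random.default_rng(55)
    n = 30_000
    u = rng.random(n) < 0.3
    x1 = np.where(u, rng.random(n) < 0.7, rng.random(n) < 0.2).astype(float)
    x2 = np.where(u, rng.random(n) < 0.7, rng.random(n) < 0.2).astype(float)
    b1, b2 = np.log(3.0), 0.0
    p = 1 / (1 + np.exp(-(-3.0 + b1 * x1 + b2 * x2)))
    y = pd.Series((rng.random(n) < p).astype(float))
    X = pd.DataFrame({"x1": x1, "x2": x2})
    uni = univariate_screen(y, X).set_index("variable")
    res, retained, _ = stepwise_multivariate(y, X)
    multi_b1 = res.params.get("x1", np.nan)
    err_uni = (np.log(uni.loc["x1", "uni_or"]) - b1) ** 2 \
        + (np.log(uni.loc["x2", "uni_or"]) - b2) ** 2
    multi_b2 = res.params.get("x2", 0.0)
    err_multi = (multi_b1 - b1) ** 2 + (multi_b2 - b2) ** 2
    assert err_multi < err_uni
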