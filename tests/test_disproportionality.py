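"""Contingency-table construction and the four signal statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from pvsignal import disproportionality as dp
from pvsignal.disproportionality import (MgpsHyperparams, bcpnn_ic,
                                         build_tables, consensus_call,
                                         ebgm_quantiles, fit_mgps_prior,
                                         mgps_marginal_loglik, prr_chi2,
                                         ror_ci)

FIXTURE = pd.DataFrame({"a": [10], "b": [90], "c": [100], "d": [9900]})


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def test_build_tables_hand_counted_fixture():
    # drug X: 3 case + 1 non-case pairs; drug Y: 0 case + 2 non-case
    pairs = pd.DataFrame({
        "primaryid": [1, 2, 3, 4, 5, 6],
        "drugname": ["X", "X", "X", "X", "Y", "Y"],
        "is_case": [True, True, True, False, False, False],
    })
    tab = build_tables(pairs, min_count=3).set_index("drugname")
    x = tab.loc["X"]
    assert (x.a, x.b, x.c, x.d) == (3, 1, 0, 2)
    assert "Y" not in tab.index  # a=0 < min_count


def test_build_tables_min_count_drop_and_margin_conservation():
    rng = np.random.default_rng(0)
    pairs = pd.DataFrame({
        "primaryid": np.arange(500),
        "drugname": rng.choice([f"d{i}" for i in range(20)], 500),
        "is_case": rng.random(500) < 0.2,
    })
    tab = build_tables(pairs, min_count=3, include_untested=True)
    assert ((tab.a + tab.b + tab.c + tab.d) == len(pairs)).all()
    assert (tab.loc[~tab.tested, "a"] < 3).all()
    assert (tab.loc[tab.tested, "a"] >= 3).all()


def test_build_tables_single_drug_is_degenerate():
    pairs = pd.DataFrame({"primaryid": [1, 2, 3],
                          "drugname": ["only"] * 3,
                          "is_case": [True, True, True]})
    tab = build_tables(pairs, min_count=3)
    assert tab["degenerate"].all()


def test_build_tables_rejects_min_count_zero():
    with pytest.raises(ValueError):
        build_tables(pd.DataFrame({"primaryid": [], "drugname": [],
                                   "is_case": []}), min_count=0)


# ---------------------------------------------------------------------------
# ROR / PRR / chi2
# ---------------------------------------------------------------------------

def test_ror_fixture_closed_form():
    ror, lo, hi = ror_ci(FIXTURE)
    assert ror[0] == pytest.approx(11.0)
    assert lo[0] == pytest.approx(5.56, abs=0.005)
    assert hi[0] == pytest.approx(21.77, abs=0.01)


def test_prr_chi2_fixture_closed_form():
    prr, lo, hi, chi2, p = prr_chi2(FIXTURE)
    assert prr[0] == pytest.approx(10.0)
    assert chi2[0] == pytest.approx(66.3, abs=0.05)
    assert p[0] == pytest.approx(stats.chi2.sf(chi2[0], 1))


def test_balanced_table_is_null():
    t = pd.DataFrame({"a": [50], "b": [450], "c": [100], "d": [900]})
    ror, *_ = ror_ci(t)
    prr, _, _, chi2, _ = prr_chi2(t)
    assert ror[0] == pytest.approx(1.0)
    assert prr[0] == pytest.approx(1.0)
    assert chi2[0] < 0.5


def test_zero_cell_undefined_without_continuity():
    t = pd.DataFrame({"a": [5], "b": [0], "c": [10], "d": [100]})
    ror, lo, hi = ror_ci(t)
    assert np.isnan(ror[0])
    ror_c, lo_c, _ = ror_ci(t, continuity=True)
    assert np.isfinite(ror_c[0]) and np.isfinite(lo_c[0])


@settings(max_examples=200, derandomize=True)
@given(st.tuples(*[st.integers(1, 500)] * 4))
def test_ror_dominates_prr_above_one(cells):
    """Algebraic identity: ROR >= PRR whenever PRR > 1 on positive cells."""
    a, b, c, d = cells
    t = pd.DataFrame({"a": [a], "b": [b], "c": [c], "d": [d]})
    ror = ror_ci(t)[0][0]
    prr = prr_chi2(t)[0][0]
    if prr > 1:
        assert ror >= prr - 1e-12


# ---------------------------------------------------------------------------
# BCPNN
# ---------------------------------------------------------------------------

def test_ic_fixture_closed_form():
    ic, ic025 = bcpnn_ic(FIXTURE)
    assert ic[0] == pytest.approx(2.38, abs=0.005)
    assert ic025[0] < ic[0]


def test_ic_independence_limit():
    # a equals its expectation exactly on a large balanced table
    t = pd.DataFrame({"a": [100], "b": [9900], "c": [900], "d": [89100]})
    ic, _ = bcpnn_ic(t)
    assert abs(ic[0]) < 0.05


@settings(max_examples=100, derandomize=True)
@given(st.tuples(st.integers(0, 300), st.integers(0, 300),
                 st.integers(0, 300), st.integers(1, 300)))
def test_ic025_below_ic_everywhere(cells):
    a, b, c, d = cells
    t = pd.DataFrame({"a": [a], "b": [b], "c": [c], "d": [d]})
    ic, ic025 = bcpnn_ic(t)
    assert ic025[0] < ic[0]


def test_noren_variant_available():
    ic, ic025 = bcpnn_ic(FIXTURE, variant="noren")
    assert ic025[0] < ic[0]
    assert ic[0] == pytest.approx(np.log2(10.5 / (FIXTURE.eval("(a+b)*(a+c)/(a+b+c+d)")[0] + 0.5)))


# ---------------------------------------------------------------------------
# MGPS
# ---------------------------------------------------------------------------

def _single_gamma_prior():
    # both components identical -> effectively a single Gamma(2, 4) prior
    return MgpsHyperparams(2.0, 4.0, 2.0, 4.0, 0.5)


def test_ebgm_degenerate_prior_digamma_closed_form():
    t = pd.DataFrame({"a": [10], "E": [1.08911]})
    ebgm, eb05, eb025 = ebgm_quantiles(t, _single_gamma_prior())
    expected = np.exp(special.digamma(12) - np.log(5.08911))
    assert ebgm[0] == pytest.approx(expected, rel=1e-12)
    assert ebgm[0] == pytest.approx(2.26, abs=0.005)
    assert eb05[0] == pytest.approx(
        stats.gamma.ppf(0.05, 12, scale=1 / 5.08911), rel=1e-9)
    assert eb05[0] == pytest.approx(1.36, abs=0.005)
    assert eb025[0] <= eb05[0] <= ebgm[0]


def test_ebgm_matches_numeric_integration_oracle():
    from tests.oracles import oracle_posterior
    rng = np.random.default_rng(42)
    prior = MgpsHyperparams(0.7, 0.9, 3.0, 1.5, 0.3)
    for _ in range(15):
        a = int(rng.integers(0, 60))
        e = float(rng.uniform(0.2, 30.0))
        tab = pd.DataFrame({"a": [a], "E": [e]})
        ebgm, eb05, eb025 = ebgm_quantiles(tab, prior)
        o_ebgm, o_05, o_025 = oracle_posterior(a, e, prior)
        assert ebgm[0] == pytest.approx(o_ebgm, rel=1e-6)
        assert eb05[0] == pytest.approx(o_05, rel=1e-6)
        assert eb025[0] == pytest.approx(o_025, rel=1e-6)


def test_mgps_prior_recovery_on_null_tables():
    """Counts simulated with lambda = 1 pull the fitted prior mean to 1."""
    rng = np.random.default_rng(5)
    e = rng.uniform(1.0, 40.0, 5000)
    a = rng.poisson(e)  # lambda identically 1
    tables = pd.DataFrame({"a": a, "E": e})
    prior = fit_mgps_prior(tables)
    assert 0.8 <= prior.prior_mean <= 1.2


def test_mgps_mle_dominates_true_hyperparameters():
    rng = np.random.default_rng(6)
    true = MgpsHyperparams(1.2, 1.5, 4.0, 1.0, 0.4)
    e = rng.uniform(0.5, 20.0, 3000)
    comp = rng.random(3000) < true.p_mix
    lam = np.where(comp, rng.gamma(true.alpha1, 1 / true.beta1, 3000),
                   rng.gamma(true.alpha2, 1 / true.beta2, 3000))
    a = rng.poisson(lam * e)
    tables = pd.DataFrame({"a": a, "E": e})
    fitted = fit_mgps_prior(tables)
    assert (mgps_marginal_loglik(a, e, fitted)
            >= mgps_marginal_loglik(a, e, true) - 1e-6)


def test_mgps_degenerate_repeated_table_converges():
    tables = pd.DataFrame({"a": [7] * 100, "E": [2.0] * 100})
    prior = fit_mgps_prior(tables)
    assert prior.prior_mean > 0


def test_shrinkage_inequality():
    tables = pd.DataFrame({"a": [20], "E": [4.0]})
    prior = MgpsHyperparams(1.0, 1.0, 2.0, 2.0, 0.5)  # mass below a/E = 5
    ebgm, eb05, eb025 = ebgm_quantiles(tables, prior)
    assert 1 < ebgm[0] < 20 / 4.0
    assert eb025[0] <= eb05[0] <= ebgm[0]


def test_ebgm_approaches_relative_rate_asymptotically():
    prior = MgpsHyperparams(1.0, 1.0, 2.0, 2.0, 0.5)
    ratios = []
    for a in (10, 100, 10_000):
        tab = pd.DataFrame({"a": [a], "E": [a / 3.0]})  # a/E fixed at 3
        ebgm, *_ = ebgm_quantiles(tab, prior)
        ratios.append(ebgm[0] / 3.0)
    assert ratios[0] < ratios[1] < ratios[2]
    assert ratios[2] == pytest.approx(1.0, abs=0.01)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _result_row(**kw):
    base = dict(ror=3.0, ror_lo=2.0, ror_hi=4.0, prr=3.0, chi2=10.0,
                p_value=1e-4, ic=1.0, ic025=0.5, ebgm=3.0, eb05=2.8,
                eb025=2.5)
    base.update(kw)
    return pd.DataFrame([base])


def test_consensus_all_thresholds_met():
    out = consensus_call(_result_row(), n_tests=10)
    assert out["consensus"].all()


@pytest.mark.parametrize("kw", [
    {"ror_lo": 1.0},                  # ROR lower bound not above 1
    {"prr": 1.9},                     # PRR below 2
    {"chi2": 3.9},                    # chi-square below 4
    {"ic025": 0.0},                   # IC025 not above 0
    {"eb025": 1.9},                   # EBGM025 not above 2
    {"p_value": 0.04},                # fails after Bonferroni (x10)
])
def test_consensus_single_failure_vetoes(kw):
    out = consensus_call(_result_row(**kw), n_tests=10)
    assert not out["consensus"].any()


def test_bonferroni_capped_at_one():
    out = consensus_call(_result_row(p_value=0.5), n_tests=3)
    assert out["p_adj"].iloc[0] == 1.0


def test_undefined_statistic_fails_consensus():
    out = consensus_call(_result_row(ror_lo=np.nan), n_tests=1)
    assert not out["flag_ror"].any()
    assert not out["consensus"].any()


def test_consensus_requires_positive_n_tests():
    with pytest.raises(ValueError):
        consensus_call(_result_row(), n_tests=0)


# ---------------------------------------------------------------------------
# end-to-end properties on the planted simulation
# ---------------------------------------------------------------------------

def test_signal_table_interval_orderings(planted_run):
    sig = planted_run["signals"]
    ok = sig.dropna(subset=["ror", "prr"])
    assert (ok.ror_lo <= ok.ror + 1e-9).all() and (ok.ror <= ok.ror_hi + 1e-9).all()
    assert (ok.prr_lo <= ok.prr + 1e-9).all() and (ok.prr <= ok.prr_hi + 1e-9).all()
    assert (ok.ic025 <= ok.ic).all()
    assert (ok.eb025 <= ok.eb05 + 1e-12).all()
    assert (ok.eb05 <= ok.ebgm + 1e-12).all()
    assert ((0 <= ok.p_value) & (ok.p_value <= ok.p_adj)
            & (ok.p_adj <= 1)).all()


def test_planted_signals_flagged_nulls_not(planted_run):
    sig = planted_run["signals"]
    strong = sig[sig.drugname.str.startswith(("signal_r10", "signal_r20"))]
    assert strong["consensus"].all()
    nulls = sig[sig.drugname.str.startswith("drug")]
    assert nulls["consensus"].mean() < 0.01
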