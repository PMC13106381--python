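"""Shared fixtures: tiny hand-built datasets and one reusable simulation."""

import pandas as pd
import pytest

from pvsignal.case_selection import PT_COGNITIVE_DISORDER
from pvsignal.core_io import Dataset
from pvsignal.pipeline import run_signal_screen
from pvsignal.synthetic import generate, scenario_presets

OTHER_PT = 10019211  # headache; any non-target code


def make_dataset(demo_rows, drug_rows, reac_rows, outc_rows=(), indi_rows=()):
    demo = pd.DataFrame(demo_rows, columns=[
        "primaryid", "caseid", "fda_dt", "event_dt", "sex", "age_yrs",
        "wt_kg", "reporter", "country"])
    drug = pd.DataFrame(drug_rows, columns=[
        "primaryid", "drugname", "role_cod", "start_dt"])
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt_code", "pt_name"])
    outc = pd.DataFrame(list(outc_rows) or None,
                        columns=["primaryid", "outc_cod"])
    indi = pd.DataFrame(list(indi_rows) or None,
                        columns=["primaryid", "indi_name"])
    return Dataset(demo=demo, drug=drug, reac=reac, outc=outc, indi=indi)


@pytest.fixture
def tiny_dataset():
    """Three reports, one PS drug each, one case (report 2)."""
    demo = [
        (1, 101, "20200115", "20200110", "female", 34.0, 60.0, "consumer", "US"),
        (2, 102, "20200220", "20200210", "male", 67.0, None, "physician", "CA"),
        (3, 103, "20200301", None, "unknown", None, 82.5, "pharmacist", "US"),
    ]
    drug = [
        (1, "alphadrug", "PS", "20200101"),
        (2, "betadrug", "PS", "20200201"),
        (2, "gammadrug", "SS", None),
        (3, "alphadrug", "PS", "20200210"),
    ]
    reac = [
        (1, OTHER_PT, "headache"),
        (2, PT_COGNITIVE_DISORDER, "cognitive disorder"),
        (3, OTHER_PT, "headache"),
    ]
    outc = [(1, "HO"), (2, "OT"), (2, "HO"), (3, "DE")]
    return make_dataset(demo, drug, reac, outc)


@pytest.fixture(scope="session")
def planted_run():
    """One five-planted-signals simulation pushed through the full screen."""
    cfg = scenario_presets(seed=11)["five-planted-signals"]
    dataset, truth = generate(cfg)
    signals, curated, flags, log = run_signal_screen(dataset)
    return {"config": cfg, "dataset": dataset, "truth": truth,
            "signals": signals, "curated": curated, "flags": flags,
            "log": log}
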