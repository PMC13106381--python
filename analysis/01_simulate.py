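#!/usr/bin/env python
"""Generate the study's synthetic reporting-system datasets.

Writes each scenario preset as FAERS-style CSV tables plus the planted
ground truth under results/simulated/<preset>/, so later stages (and any
outside tool) can consume them from disk.
"""

import argparse
from pathlib import Path

from pvsignal.core_io import write_table
from pvsignal.synthetic import generate, scenario_presets

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "simulated")
    args = ap.parse_args()

    for name, cfg in scenario_presets(seed=args.seed).items():
        dataset, truth = generate(cfg)
        outdir = args.out / name
        outdir.mkdir(parents=True, exist_ok=True)
        for table in ("demo", "drug", "reac", "outc", "indi"):
            write_table(getattr(dataset, table), outdir / f"{table}.csv")
        write_table(truth.drugs, outdir / "ground_truth_drugs.csv")
        write_table(truth.covariates, outdir / "ground_truth_covariates.csv")
        print(f"{name}: {dataset.n_reports} reports "
              f"({truth.n_duplicates} duplicates), "
              f"{int(truth.case_flags.sum())} planted cases -> {outdir}")


if __name__ == "__main__":
    main()
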