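# pvsignal

Pharmacovigilance signal detection for spontaneous reporting systems
(SRS), built around the surveillance question: *which drugs are reported
with cognitive-disorder adverse events far more often than the database
background would predict?* The package is aimed at pharmacoepidemiologists
working with FAERS-style quarterly extracts (or any JADER-like relational
SRS) who need a reproducible, tested pipeline from raw tables to consensus
signal calls.

## What it computes

For each drug–event pair the screen builds the 2×2 table
(a = drug & event, b = drug & other events, c = other drugs & event,
d = rest; E = (a+b)(a+c)/N) and evaluates four disproportionality
statistics with their interval estimates:

| statistic | definition | signal threshold |
|---|---|---|
| ROR | ad/bc, Wald CI on log scale | lower 95% bound > 1 |
| PRR | [a/(a+b)]/[c/(c+d)], Yates χ² | PRR ≥ 2 and χ² ≥ 4 |
| BCPNN IC | shrunk log₂(observed/expected), canonical priors | IC025 > 0 |
| MGPS EBGM | empirical-Bayes geometric mean of λ under a 2-gamma mixture prior fitted by marginal ML | EB025 > 2 |

A pair is **consensus-positive** only when all four thresholds pass and
the Bonferroni-adjusted χ² p-value is below 0.05. Around the screen sit
the standard surveillance stages: FAERS-convention deduplication (highest
`primaryid` per case/receipt-date), narrow and broad MedDRA case
definitions, primary-suspect-only filtering, Weibull time-to-onset
modelling with early/random/wear-out failure-pattern classification,
stratified re-screens (sex, age, weight, country), and case/non-case
logistic regression with backward stepwise selection and VIF
diagnostics. A synthetic SRS generator with planted ground truth makes
every stage testable without any data download. See `docs/methods.md`
for the full model descriptions.

## Worked example

```python
from pvsignal.synthetic import scenario_presets, generate
from pvsignal.pipeline import run_signal_screen

config = scenario_presets(seed=1)["five-planted-signals"]
dataset, truth = generate(config)          # 20,976 reports, 976 duplicates
signals, curated, flags, log = run_signal_screen(dataset)
cols = ["drugname", "a", "ror", "prr", "ic025", "ebgm", "eb025", "consensus"]
print(signals.sort_values("ebgm", ascending=False).head(5)[cols]
      .to_string(index=False, float_format="%.3f"))
```

```
   drugname   a   ror   prr  ic025  ebgm  eb025  consensus
signal_r20a 332 9.858 5.442  2.026 4.684  4.208       True
signal_r20b 339 9.635 5.386  2.010 4.627  4.161       True
signal_r10b 230 4.872 3.543  1.464 3.271  2.878       True
signal_r10a 227 4.835 3.524  1.457 3.259  2.864       True
 signal_r05 138 2.319 2.045  0.696 2.039  1.731      False
```

The four drugs planted with rate multipliers of 10 and 20 are called
consensus-positive; the ρ = 5 drug shows elevated statistics but its
EB025 of 1.73 sits below the EBGM025 > 2 threshold; all 25 signal-free
drugs are negative. `a` is the drug's case-report count, `E`-relative
measures (`ebgm`) are shrunk toward 1 by the empirical-Bayes prior, so
they sit below the raw ROR — the expected behaviour of the gamma-Poisson
shrinker.

The numbered scripts under `analysis/` run each stage as a narrative
driver and write their tables under `results/`:

```sh
python analysis/01_simulate.py --seed 1       # datasets + ground truth
python analysis/02_signal_screen.py --seed 1  # consensus signal table
python analysis/03_time_to_onset.py --seed 1  # Weibull fits and onset bins
python analysis/04_descriptives.py --seed 1   # summary tables
python analysis/05_stratified.py --seed 1     # per-stratum screens
python analysis/06_risk_factors.py --seed 1   # logistic regression + VIF
```

FAERS-style `$`-delimited quarterly tables (or CSV) are read with
`pvsignal.read_quarter({"demo": ..., "drug": ..., "reac": ...})` and flow
through the identical pipeline.

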