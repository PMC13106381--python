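# Methods

`pvsignal` implements the standard post-marketing surveillance workflow for
a spontaneous reporting system (SRS) such as FAERS: curate raw quarterly
tables into a case/non-case analysis set, screen drug–event pairs with four
disproportionality algorithms under a consensus rule, characterize onset
timing with a Weibull model, repeat the screen inside demographic strata,
and model reporting odds with case/non-case logistic regression. Because no
raw FAERS extract can be redistributed, the package ships a synthetic SRS
generator with planted ground truth; every stage is validated against it
and against closed-form oracles.

## Case curation

Duplicate submissions are removed by the FAERS convention: within each
(case identifier, receipt date) group only the row with the highest
`primaryid` survives. Survivors are emitted sorted by `primaryid`, so the
result is independent of input row order. A report is a **case** when at
least one of its reactions carries a MedDRA preferred term (PT) from the
active case definition; the narrow definition is the single PT
*Cognitive disorder* (10057668), the broad (sensitivity) definition adds
*Memory impairment* (10027175), *Confusional state* (10010305) and
*Disturbance in attention* (10013496). PT codes are treated as opaque
integers — no MedDRA hierarchy traversal is attempted, which keeps the
package free of dictionary licensing.

Only **primary-suspect (PS)** drug mentions enter the analysis; secondary
suspect, concomitant and interacting mentions are dropped. The unit of
analysis is the (report, PS-drug) pair: a report with *k* distinct PS drugs
contributes *k* pairs, each inheriting the report's case status. This is
the common choice in FAERS screens and makes the margin-conservation
invariant (every drug's 2×2 table sums to the global pair count) hold
exactly. Reports whose reactions include a configurable overdose PT set
are excluded; filters with no computable field definition (non-drug-induced,
unassessable) are supported as a caller-supplied exclusion list. Every
exclusion is counted in a curation log whose entries plus survivors sum to
the input count.

Drug names are normalized only by trimming, case-folding and whitespace
collapse. No brand→generic or ingredient mapping is attempted: real FAERS
screens of this kind report e.g. a brand name and its generic as separate
rows, and any merging rule would be an invention.

## Disproportionality statistics

For a drug with cells (a, b, c, d), N = a+b+c+d and baseline expectation
E = (a+b)(a+c)/N:

- **ROR** = ad/bc with a Wald 95% CI on the log scale,
  exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
- **PRR** = [a/(a+b)]/[c/(c+d)] with the analogous Wald CI, accompanied by
  the Yates-corrected Pearson χ², N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)],
  referred to χ²(1). The continuity-corrected form is the conventional one
  in PRR screening.
- **BCPNN IC**: the closed-form shrunk information component with the
  canonical priors (γ₁₁ = 1, α₁ = β₁ = 1, α = β = 2) and
  IC025 = IC − 2√V(IC) from the matching variance expression. The
  alternative gamma-posterior formulation, IC = log₂((a+½)/(E+½)) with
  IC025 the 2.5% quantile of log₂ Gamma(a+½, rate E+½), is available as
  `variant="noren"`; the closed form is the default because the screen's
  thresholds were established with it.
- **MGPS EBGM**: counts follow a ~ Poisson(λE) with the relative reporting
  rate λ drawn from a two-component gamma mixture prior. Hyperparameters
  are estimated by maximizing the marginal likelihood — a mixture of
  negative binomials — over all tables, including sub-threshold ones
  (`include_zeroes`, on by default, mirroring how openEBGM-style fits use
  the full table set). The optimizer is Nelder-Mead over log/logit
  transforms from the canonical start (0.2, 0.1, 2, 4, 1/3). On null-like
  data the mixture weight is only weakly identified, leaving a flat
  likelihood ridge; the fit restarts from its terminal point and accepts
  when the objective stops improving, and it raises with diagnostics if
  the value is still moving after three restarts. The posterior is the
  conjugate gamma mixture; EBGM = exp E[ln λ] via the digamma closed form,
  and EB05/EB025 are found by Brent root-finding on the mixture CDF
  bracketed by the component quantiles (with a 1e-9 relative pad, since
  the mixture quantile can sit at a bracket end to within roundoff).
  Closed-form results agree with brute-force numeric integration of the
  unnormalized posterior to better than 1e-6 relative error.

**Zero cells.** ROR and PRR are undefined when b or c is 0; the undefined
state propagates as NaN and fails the corresponding flag. A
Haldane–Anscombe +0.5 continuity option exists but is off by default, so a
spurious signal can never be manufactured from an empty comparator cell.

**Consensus.** A pair is signal-positive only if all four algorithms pass
their conventional thresholds — ROR 95% lower bound > 1; PRR ≥ 2 with
χ² ≥ 4; IC025 > 0; EBGM025 > 2 — *and* the Bonferroni-adjusted χ² p-value
(multiplied by the number of drug–event pairs passing the minimum-count
filter, capped at 1) is below 0.05. The minimum count defaults to 3 case
reports, inclusive. Both EB05 and EB025 are reported because screening
conventions vary in which lower quantile they print.

## Time-to-onset

TTO is event onset minus therapy start in whole days, computed only when
both dates are full-precision and four validity rules pass: start not
after onset; onset not after the receipt date; birth date (when present)
not after onset; no invalid tokens (0000-00-00 / 9999-99-99 sentinels,
month > 12, day > 31). Partial or missing dates are excluded as unknown.
Same-day onsets are mapped to 0.5 days rather than dropped — the "<2 days"
descriptive bin clearly contains them, and the Weibull density needs
positive support. Onset bins are half-open, [0,2), [2,5), [5,7), [7,14),
[14,28), [28,∞), with exactly-28-day onsets in the last bin; this boundary
convention reproduces the published case-series percentages from their
printed counts. Bin percentages use the total over all seven categories
(unknown included).

The two-parameter Weibull is fitted by maximum likelihood
(`scipy.stats.weibull_min` with the location fixed at zero); 95% CIs come
from the observed information of the log-parameterized likelihood
(central-difference Hessian), which respects positivity. Profile
likelihood would be more accurate in small samples but the normal
approximation covers the true shape ≥ 90% of the time at n = 500, the
regime the analysis targets; below 10 onsets the fit is declared
indeterminate. The failure pattern is **early** when the shape CI lies
below 1, **wear-out** when above, **random** when it includes 1. Reported
medians and IQRs are the *sample* statistics, not the fitted
distribution's, matching the descriptive convention of published SRS
tables.

## Descriptives and strata

Percentages are rounded half-up to two decimals. Age bins are ≤18, 19–44,
45–64, ≥65 in integer years; weight bins are <50, 50–100 (upper edge
inclusive), >100 kg. Outcome percentages use the outcome-record total as
denominator (a report can carry several outcomes); that convention — never
stated in published tables but required to reproduce them — is exposed via
the `denominator_kind` column. Report year comes from the receipt date.

Stratified screens re-run the identical pipeline on the stratum's reports
with 2×2 margins recomputed within the stratum; reports with an unknown
level are excluded from that stratification. The MGPS prior is
re-estimated within each stratum; tiny strata can defeat the fit, in which
case the caller may supply the global prior as a fallback (both paths
warn). Countries are ranked by case-report count with lexicographic
tie-breaks. Cross-algorithm concordance is summarized by pairwise Spearman
correlation of the drugs' point estimates plus the count of drugs with
non-unanimous flags.

## Case/non-case regression

Cases are regressed against demographics (age, sex, weight, reporter
type) and presence/absence indicators for the most frequently reported
indications and PS drugs among cases. Rows missing any selected
demographic are dropped (complete-case; counts reported), indicators never
create missingness. Screening is univariate logistic per covariate;
"stepwise" selection is implemented as backward elimination from the
univariate-significant set, removing the largest-p covariate at each
refit until all retained p < 0.05 — backward was chosen because the
direction is conventionally unstated in SRS analyses and elimination from
a screened candidate set is the common practice. Ties break on variable
name, making the result invariant to row and column order. Perfect
separation is flagged, not silently estimated. VIFs for the retained model
come from `statsmodels`; tolerance = 1/VIF identically, and a singular
design raises naming the most collinear pair. Outputs are reporting
associations only: an SRS has no exposure denominator, so no absolute risk
is ever derived.

## Synthetic reporting system

The generator emulates what the pipeline consumes: multi-table reports
keyed by `primaryid`/`caseid`, PS/SS/C/I role codes, MedDRA-style PT codes,
duplicate submissions (same case and receipt date, higher `primaryid`),
YYYYMMDD date tokens corrupted with the four invalid patterns in equal
shares, and FAERS-like demographic structure — female-predominant (56%),
US-heavy, consumer-reported, with heavy age (37%) and weight (74%)
missingness by default, matching the published case-series composition.
Case status follows a logistic model: baseline reporting odds (default
case probability 0.05) multiplied by the PS drug's rate multiplier ρ
(optionally restricted to one stratum) and by exp of planted covariate
log-odds. Case onsets are drawn from the drug's Weibull(α, β). Identical
seed and configuration give byte-identical tables.

Scenario presets fix the study conditions used throughout testing:
`null` (200 signal-free drugs, 40,000 reports), `five-planted-signals`
(25 null + ρ ∈ {5, 10, 10, 20, 20} among 30 drugs, 20,000 reports),
`stratum-signal` (ρ = 8 for female reports only), `tto-mixture` (shapes
0.5 and 1.0 with complete onset dates, 30,000 reports) and
`riskfactor-recovery` (planted odds ratios 3.0 and 2.0 among eight noise
covariates, 20,000 reports, reduced missingness so the complete-case
regression retains most reports). These sizes give each null drug ~10
expected case pairs (comfortably past the minimum-count filter), planted
drugs 130–340 case reports, and per-drug onset samples of ~1,000 — large
enough for stable parameter recovery while a full simulation-plus-screen
replicate completes in about two seconds.

What the generator does **not** emulate: the 20,000+ product vocabulary
and their wildly skewed marginal frequencies, indication-channeling
(confounding by indication), reporting waves after media coverage,
multi-event reports with correlated PTs, or drifting reporting rates over
calendar time. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under a faithful generative model of
the *data structure* — not that real-world signals are causal, which no
disproportionality method can show.

## Known limitations

- Disproportionality measures reporting behaviour; consensus-positive
  means "reported disproportionately", never "causes the event".
- The Bonferroni correction is deliberately conservative; with few tested
  pairs it leaves the screen essentially driven by the four thresholds.
- The Weibull CIs are asymptotic; at n close to the minimum of 10 their
  coverage degrades.
- Stepwise selection inherits its known post-selection-inference caveats;
  reported multivariate p-values are not adjusted for the selection path.
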