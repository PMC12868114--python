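# Methods

This note documents the statistical model, the conventions, the
synthetic data-generating process, and the numerical choices behind
faerskit, in enough detail to judge what its tests do and do not show.

## Data model and preprocessing

A *report* is one spontaneous submission: demographics (DEMO), drug
rows with role codes PS/SS/C/I (DRUG), MedDRA-coded reactions (REAC),
outcome codes DE/LT/HO/DS/CA/RI/OT (OUTC) and therapy dates (THER),
joined on PRIMARYID. Spontaneous reports are not incidence data: all
statistics here compare reporting proportions within the same database,
never population risks.

**Deduplication.** Multiple submissions of one case share a CASEID.
Per CASEID the row with the highest FDA_DT (receipt date) survives;
ties break to the highest PRIMARYID. The rule is a pure argmax, so the
result is independent of input row order and idempotent — both are
asserted by tests on permuted duplicate-laden fixtures.

**Dates.** FAERS dates are digit strings of length 8, 6 or 4. They are
parsed with an explicit precision tag (day/month/year) and partial
dates are never completed to an invented day for analysis purposes:
time-to-onset requires day precision on both ends, and anything less is
rejected into a categorised tally (missing event date, missing start,
partial event, partial start, event before start). Onset is the day
difference plus one, so a same-day event is day 1 and onset is always a
positive integer. When the target drug appears on several rows, the
earliest day-precision start is used: first exposure defines latency.

**Ages** are normalised to years from the unit code (decade ×10, year
×1, month ÷12, week ÷52.18, day ÷365.25, hour ÷8766). Implausible ages
(unit-entry artifacts reaching five digits) are *retained* by default so
that summaries reproduce what raw spontaneous data actually look like;
`clean_ages=True` excludes ages above 120 years from the quantitative
summary while still tabulating them in the categorical bins.

**Drug matching** is case-insensitive exact matching after trimming and
whitespace collapsing over a user-supplied synonym list (generic and
brand names). There is deliberately no substring matching: a congener
sharing a name stem must not match. The analysis universe for 2×2
tables is *all* deduplicated reports; the exposed margin is the reports
naming the target as primary suspect.

## Disproportionality statistics

With a, b, c, d as in the README and E = (a+b)(a+c)/N:

- **ROR** ad/bc with the log-normal CI. Any zero cell makes the
  estimate or its variance undefined; such tables are returned as
  non-estimable with a reason rather than patched with a Haldane +0.5,
  because the signal rule's n ≥ 3 floor makes corrected zero-cell
  estimates pointless for screening. (A continuity-corrected variant
  would only matter for tables the criteria already exclude.)
- **PRR** with its log CI. a = 0 yields a degenerate zero estimate
  (estimable, never a signal); c = 0 is non-estimable.
- **χ²** is Yates-corrected Pearson, each |O−E| deviation reduced by
  0.5 and clamped at zero. This matches the generic
  continuity-corrected contingency test (asserted against an
  independent implementation); a flag switches to uncorrected Pearson.
- **IC** uses the shrunk closed form log₂((a+0.5)/(E+0.5)) with
  delta-method variance (1/(a+0.5))/ln²2 and IC025 = IC − 1.96σ. The
  original Dirichlet moment construction is available
  (`variant="moment"`). The two agree within 0.1 bit for a ≥ 10
  *provided the observed-to-expected ratio is moderate* (≲2 at a = 10,
  ≲4 at a ≥ 30); at extreme ratios with tiny E the moment variant
  shrinks harder. The sign of the shrunk IC is exactly the sign of
  a − E, which is also exactly the sign of ROR−1 and PRR−1 — so the
  three-way concordance invariant is algebraic, not approximate.
- **MGPS/EBGM.** a ~ Poisson(λE) with the two-component gamma mixture
  prior on λ. The five hyperparameters are fitted by maximising the
  negative-binomial mixture marginal likelihood over the (a, E) counts
  of *all* suspect-drug/PT pairs in the universe (not only the target
  drug's), by L-BFGS-B on log-transformed shapes/rates and a
  logit-transformed weight, from the canonical start
  (α₁=0.2, β₁=0.1, α₂=2, β₂=4, w=1/3). The fit is deterministic — no
  stochastic restarts. Fewer than 100 pairs with a ≥ 1 cannot identify
  a mixture; the fit then refuses and falls back to the fixed diffuse
  starting prior, with a logged warning. A boundary-pinned mixture
  weight is clamped into (0,1) and warned about.

  The posterior of λ is again a two-component gamma mixture
  (α_j + a, β_j + E) with weights proportional to prior weight ×
  negative-binomial evidence. EBGM = exp(E[ln λ]) via digamma; EBGM05
  solves the posterior CDF = 0.05 by bracketed Brent root-finding to
  1e-10. Tests check both against brute-force quadrature of
  prior × Poisson likelihood (no conjugacy) to 4 significant digits.
  The vectorised all-pairs screen evaluates the EBGM05 > 2 flag as
  posterior CDF(2) < 0.05, which is algebraically the same condition
  without per-pair root-finding.

## Signal criteria and tables

The four flags are: ROR — n ≥ 3 and CI lower bound > 1; PRR — n ≥ 3,
PRR ≥ 2 and χ² ≥ 4 (the Evans rule; the χ² companion is standard in
this literature and can be switched off); IC — IC025 > 0; EBGM —
EBGM05 > 2. The conservative default for ranked tables is the
conjunction of all four. Frequency ranking sorts by n (ties: EBGM,
then PT); intensity ranking by EBGM (ties: n, then PT).

Subgroup analysis restricts the universe to one stratum and recomputes
everything inside it, including a re-fitted MGPS prior (small strata
fall back to the diffuse prior). Age bins default to <18, 18–44,
45–64, >64 — the scheme used in published results tables — with a
<18/18–60/>60 alternative selectable. Missing values form an
`Unknown` stratum that is carried through counting (stratum n values
sum to the pooled n) but is not meant for hypothesis generation.
Region stratification is country-level and requires an explicit level
list; there is no canonical country set.

## Summary conventions

Published FAERS tabulations give each block its own denominator, and
faerskit reproduces exactly those conventions so printed percentages
are recoverable from printed counts:

- sex, age bins, reporting year, reporter class: all reports;
- outcome categories: the block's own total of outcome mentions (one
  report can carry several codes; this is the only convention under
  which the block sums to 100%);
- top-k countries: the top-k subtotal, *not* all reports — this
  differs from what a casual reader might assume and is flagged here
  deliberately;
- onset bins: reports with a computable onset;
- death/non-death cross-tables: the block's grand total.

Quantitative summaries use the n−1 standard deviation and
linear-interpolation quartiles; a single observation reports SD 0 with
a degenerate flag. Every block re-checks that its percentages sum to
100 ± rounding.

## The synthetic generator

The generator emulates the *structure* of spontaneous reporting data
with known ground truth. Per case: one primary-suspect drug from a
long-tailed popularity distribution (1/(g+25) over 50 drugs; the
target drug receives ≈3.6% of reports); a distinct PT set drawn from
long-tailed background weights (1/(j+5) over 150 PTs), 1 + Poisson(1.5)
draws; sex F/M/unknown at 62/27/11%; lognormal ages (median 45 y) with
implausible five-digit artifacts at rate 0.001; lognormal weights;
outcome codes at fixed marginal rates; reporter occupation and country
codes; onset drawn from a two-component lognormal mixture (short
component median 7 days, long component median 350 days, weight 0.45
on short) that produces the early-peak/late-tail bimodal onset shape
seen in spontaneous data; therapy start, event and receipt dates
consistent with that onset; per-field missingness; month-precision
event dates at rate 0.08; and duplicate re-submission at rate 0.05
with a strictly later FDA_DT and a new PRIMARYID (optionally filling a
previously missing sex, to exercise the most-current-information rule).

Signals are injected multiplicatively: PT j's weight is multiplied by
λ(g, j) and the row renormalised, keeping the per-case PT count
rate-stable. Three mechanisms attenuate the *realised*
observed/expected ratio below the injected λ: renormalisation itself
(÷(1+(λ−1)w)), saturation of the per-case inclusion probability under
multiple draws, and the target drug's own contribution to the pooled
PT margin from which E is computed. At the default weights the
measured attenuation is ≈4.9 for λ = 8 and ≈3.2 for λ = 4 — the
recovery tests therefore check EBGM against the band
[0.5λ, 1.5λ] rather than λ itself, and `realized_rates` reports what
the data actually contain, with a Poisson standard error.

What the generator does *not* emulate: real MedDRA vocabulary and its
versioning, drug co-prescription structure, country-specific reporting
cultures, secular reporting trends, duplicated cases with conflicting
content, or free-text name misspellings. Passing tests demonstrate
correctness of the pipeline's arithmetic and calibration under a known
data-generating process — not that any particular real-world signal is
causal, nor that name matching would survive real FAERS spelling noise.

## Problem sizes and calibration checks

The replicated checks use 20 universes of 20,000 cases each, a size at
which the injected pairs reach expected counts ≥ 50 while a full
generate-and-screen cycle stays at a few seconds: (i) with all λ = 1,
at most 1% of (drug, PT) pairs with n ≥ 3 may clear all four criteria
(measured: 0 of ≈100,000 eligible pairs — the EBGM05 > 2 bar is very
conservative under the null); (ii) pairs injected at λ ∈ {4, 8} must
be flagged by all four criteria in ≥95% of replicates (measured:
100%), with mean EBGM inside [0.5λ, 1.5λ].

## Numerical notes

- Likelihood evaluations use `np.exp` and return −∞ on overflow so the
  optimiser's line search backtracks instead of raising.
- The EBGM05 bracket is [min ppf(0.001), max ppf(0.5)] of the two
  posterior components, which provably brackets the 5th percentile of
  the mixture.
- The quadrature oracle in the tests integrates in u = ln λ (the
  lower gamma tail for shape < 1 decays only like λ^shape, so a naive
  lower cutoff biases E[ln λ]) with breakpoints at the posterior mode
  (width ~1/√a inside a ~90-unit log interval) and relative tolerance
  1e-10.
- Ranked-table tie-breaks (EBGM, then PT lexicographic) make output
  byte-deterministic for a fixed seed.

## Known limitations

- The comparator is "all other drugs in the universe"; no
  Mantel–Haenszel stratified expectation is offered (listed as a
  config extension point).
- ROR's zero-cell policy (non-estimable, no Haldane correction) means
  ROR-flag counts are not comparable to tools that apply +0.5.
- The MGPS fit maximises the exact pair-level marginal likelihood; it
  does not implement the historical squashing/stratification
  heuristics of large-scale MGPS deployments, which matter only at
  database scales far beyond these tests.
- Multiplicity is handled the way the field handles it — shrinkage
  plus fixed thresholds — not by formal corrections; flagged PTs are
  hypotheses, not established risks.
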