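# Methods

This note documents the statistical model behind `uretox`, the
conventions it fixes where the underlying study leaves choices open,
and what its synthetic-data tests do and do not demonstrate.

## Cohort model and stratification

A subject carries group (ASD/control), sex, age in years, an optional
CARS severity score (ASD only), and the five-toxin panel either as raw
µmol/L plus urinary creatinine (mmol/L) or as pre-normalized µmol/mmol
values. Analyses are complete-case: missing values are never imputed,
and subjects lacking a measurement route for a toxin fail validation.

Age bands are half-open intervals, by default [2, 6) and [6, 18),
labelled `2-5.9y`/`6-17y` after the clinical convention of printing the
last tenth inside the band; half-open intervals guarantee every age has
exactly one band (5.95 is "younger", 6.0 "older"). CARS classes are
mild/moderate for scores ≤ 36.0 and severe for scores ≥ 36.5. The
half-point granularity of CARS makes the open gap (36.0, 36.5) empty in
practice, but the classifier is total: a score strictly inside the gap,
or a missing score, puts the subject in `cars_unclassified`, which is
reported (and logged subject by subject in the CLI) but excluded from
severity contrasts. This mirrors the study cohort, where only 92 of the
161 ASD children carry a severity class.

## Normalization and descriptives

Normalization is the plain dilution correction raw/creatinine
(µmol/L ÷ mmol/L → µmol/mmol creatinine); creatinine must be strictly
positive. Summaries report n, mean, the n−1 sample SD (undefined for a
singleton and reported as missing), median, quartiles, and range.
Quartiles use linear interpolation between order statistics
(`numpy.quantile` method "linear"), the common scientific-software
default; the rule is configurable among the standard methods because
the source tables do not state theirs and raw data are unavailable to
reverse-engineer it. Group ratio columns are case median / reference
median and case mean / reference mean. All statistics are held at full
precision; rounding (2 decimals for concentrations and ratios, 1 for
percentages) happens only in renderers.

One published ratio cell is not reproducible from its own printed
inputs: the ADMA median ratio prints 1.15 while 14.72/12.70 = 1.159
rounds to 1.16 under any convention. The package always reports the
recomputed value.

## Inference

The pipeline is unconditionally non-parametric. The Shapiro–Wilk screen
(3 ≤ n ≤ 5000, non-constant input) documents the non-normality of the
toxin distributions; it never switches the method. Group contrasts use
the two-sided Wilcoxon rank-sum (Mann–Whitney U) test — the source
describes a "Wilcoxon signed-rank test", but with independent groups of
unequal size (71 vs 161) only the rank-sum form is defined, so that is
what is implemented and recorded. The exact U null distribution is used
when the smaller group has ≤ 8 subjects and the pooled sample is
tie-free; the exact path refuses ties and falls back to the normal
approximation with midranks, tie-corrected variance, and continuity
correction. Every result records which path was taken.

Multiplicity is controlled by the Benjamini–Hochberg step-up procedure
at α = 0.05, applied within one stratified comparison's five-toxin
family (not pooled across strata), matching the per-table presentation
of such panels. Both raw and adjusted p-values are always reported,
since published toxin-panel tables rarely state which they print. Note
that BH is order-preserving and never decreases a p-value, but it is
*not* idempotent in general (re-adjusting an adjusted non-constant
sequence can inflate it further); constant families are fixed points.

## Composite burden metrics

All composite metrics are functions of the five stratum medians only:
total burden (their sum), percent contributions (each median over the
total, summing to exactly 100 with the default denominator), and the
functional ratios IS/PCS, PCS/TMAO, IS/ADMA, and SDMA/ADMA (the last
is included because the arginine-metabolism balance is of interest even
where not tabulated; arbitrary numerator/denominator pairs are
accepted). A zero denominator yields a missing value with a warning.
Per-subject ratio distributions are available as an explicit
exploratory function but are not the default statistic — the composite
profile is deliberately a ratio of medians.

Composite metrics are always recomputed from full-precision medians.
The published derived tables are internally inconsistent at the second
decimal (a control total burden of 148.65 vs 149.39 = the sum of the
printed control medians; an SDMA contribution of 21.1% vs 21.6% =
32.06/148.65): such printed derived values are used as *inputs* when
reproducing a specific printed cell (e.g. contributions against the
printed 148.65 denominator) but are never hard-coded as outputs.

## Synthetic cohort generator

The generator emulates the study conditions so every downstream stage
is testable without access to the raw data:

- **Composition.** Group sizes default to 161 ASD / 71 controls. The
  joint sex × age-band counts (ASD 23/12 younger and 101/25 older
  boys/girls; controls 10/4 and 27/30) and the per-sex CARS classes
  (45+13 mild/moderate, 27+7 severe, remainder unclassified) are
  allocated by largest-remainder scaling, which reproduces the
  published counts exactly at the default sizes and proportionally
  otherwise. Ages are uniform within their band and CARS scores uniform
  within [30, 36] (mild/moderate) or [36.5, 60] (severe) — conventions,
  not published distributions.
- **Marginals.** Each (group, toxin) is log-normal with
  µ = ln(median) and σ = ln(Q3/Q1)/(2·0.67449) fitted from the
  published median and quartiles. This matches the theoretical median
  exactly and the quartile *ratio* Q3/Q1 exactly. It cannot also match
  both quartile *endpoints* unless the published quartiles are
  log-symmetric about the median (median = √(Q1·Q3)); for the most
  skew-asymmetric cells (ASD PCS, ASD TMAO) the implied endpoints
  differ from the published ones by ~20%. Recovery tests therefore
  target the printed median and the fitted distribution's own
  quartiles. Means and SDs are not matched at all — a log-normal fitted
  to median/IQR generally has a heavier mean than the data.
- **Dependence.** Toxins are independent by default; a Gaussian-copula
  correlation matrix can be supplied, but no inter-toxin correlations
  are published to calibrate it.
- **Raw values.** Creatinine is a log-normal stand-in (default median
  1.0 mmol/L, log-sd 0.4 — a plausible pediatric spot-urine spread; no
  distribution is published) and raw = normalized × creatinine, so
  re-normalizing recovers the draws to round-off. An optional
  truncation switch clips draws to the published [min, max] per cell
  (approximating the zero-valued minima in the published ranges); it is
  off by default because no group statistic divides by a per-subject
  toxin value.
- **Determinism.** A fixed seed makes the cohort byte-identical across
  runs; the seed is recorded in the output metadata.

Consequently, passing tests show that the *pipeline* recovers what the
generator encodes (quantiles, composition, null behaviour); they cannot
show anything about features the generator does not model — inter-toxin
correlation, measurement error, batch effects, diet, or the true
mean/tail behaviour of the clinical distributions.

### Effect injection

`inject_effect` shifts one cell's log-location, multiplying its implied
median by e^shift while leaving its shape untouched — the natural
location alternative for a rank test on a log-scale family. A ln 2
shift on PCS doubles its median, which flips the control IS/PCS ratio
(1.69) below 1 and makes PCS the dominant contributor, the algebraic
form of the phenolic-dominance pattern; the type-I simulations use a
zero shift.

## Numerical and rendering choices

- Quantile rule, SD denominator, and rounding as above; renderers use
  Python's `format` (round-half-even at the printed precision).
- PCS/TMAO is rendered at 1 decimal (its magnitude is ~10–20), the
  other ratios at 2, percentages at 1, burdens and concentrations at 2.
- Exact-vs-asymptotic rank-sum switching is at smaller-group size 8;
  beyond that the exact distribution gains nothing at the tolerances
  used while enumeration cost grows combinatorially.
- Degenerate inputs: empty strata are omitted with a logged note rather
  than raising; empty groups and constant Shapiro–Wilk inputs raise.

## Problem sizes used in tests

Convergence checks draw 50,000–100,000 subjects per group (sampling
error of a log-normal sample median at n = 10⁵ with σ ≈ 1.24 is ≈ 0.5%
relative, comfortably inside the 1% target); the type-I simulation uses
1,000 cohort pairs at the study sizes (binomial ±2σ ≈ ±0.014 around
0.05); the exact-test oracle enumerates all rank assignments for group
sizes ≤ 7 over 1,000 random instances. These sizes were chosen so each
check's Monte-Carlo error is small against its tolerance.

## Known limitations

- The generator matches median/IQR-ratio only (see above); it is a
  distributional stand-in, not a reconstruction of the cohort.
- Bristol stool scores are stored and validated but never analyzed (no
  results are published for them).
- No covariate adjustment, no effect sizes beyond the ratio columns, no
  confidence intervals on composite metrics (none are published; the
  composite metrics are descriptive). Bootstrap CIs are deliberately
  out of scope for the default pipeline.
- LC-MS/MS acquisition is out of scope; the pipeline starts at
  concentrations.
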