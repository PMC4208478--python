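# Methods

## The composite index

TEASE-16 summarizes a jurisdiction's alcohol-control framework as a single
calibrated score in [0, 100]. Sixteen policy topics in five regulatory
domains are each coded on an ordinal stringency scale (2–6 levels, least →
most stringent) and a three-level enforcement scale (poor / moderate /
strong). Continuous quantities behind some topics — beer/wine/spirit price
indices, blood-alcohol limits, breath-testing frequency — are banded into
ordinal levels and treated purely ordinally thereafter; a convenience
converter (`band_for_value`) maps a number to its band using half-open
intervals closed on the printed bound. Because the blood-alcohol bands are
ordinal, the unit of the printed limits (mg/dL vs g/dL is ambiguous in
common tabulations) has no effect on scoring. The six penalty levels for
drink-driving are ordered as listed, with "Other" last; a custom codebook
can re-map that ordering if a user disagrees, since no principled ordering
of "Other" exists.

**Stringency fraction.** Level *i* of *k* (1-based) maps to
σ = (i−1)/(k−1). This linear ordinal map anchors the least stringent level
at 0 and the most stringent at 1; intermediate levels are treated as
equally spaced because the scales carry no metric information.

**Enforcement fraction.** The additive rules use ε ∈ {0, 0.5, 1} for poor /
moderate / strong — poor enforcement earns nothing beyond stringency's own
share. The multiplicative rule instead multiplies σ by a third of the raw
1/2/3 rating, so a stringent but poorly enforced policy retains a third of
its points. The two conventions are deliberate: the additive grid is the
unique 3-point mapping consistent with published per-domain scores, while
the multiplicative rule follows the stated "third of the raw enforcement
rating".

**Topic maxima and calibration.** Topic *j* with weight `w_j` can earn at
most `100·w_j/Σw`. Calibration divides an area's raw score by the maximum
attainable under the active (weighting, combination) pair and rescales to
100; with the fraction conventions above the maximum attainable is exactly
100 for every pair, so calibration is the identity — but it is always
computed, never assumed, so user-supplied conventions stay correctly
calibrated. Scores are therefore invariant to rescaling all weights by a
positive constant.

**Ranking.** Competition ranking on descending totals (ties share the
minimum rank; rank 1 = strongest framework). A deterministic secondary sort
by area name stabilizes output order only and never affects rank values.
Display values are rounded to one decimal, half away from zero; internal
arithmetic is unrounded.

## Area-specific weights by DEA

The fourth weighting scheme lets each area choose the weights most
favourable to itself. With weight-free topic attainments
a_j ∈ [0, 1] (the combined σ/ε fraction), the score is
100·Σw_j a_j / Σw_j. For a focal area the solver maximizes this ratio
subject to:

* **star ordering** — every 3-star weight strictly above every 2-star
  weight, and 2-star above 1-star. Strictness is realized as a gap
  constraint `w_hi ≥ w_lo + ε` with ε = 1e-6 (configurable) on the
  normalized scale, since linear programs cannot express strict
  inequalities;
* **ratio bound** — `max(w) ≤ 12·min(w)`, implemented non-strictly (LPs
  need closed feasible sets; the boundary is measure-zero). Together with
  the normalization this keeps every weight strictly positive, preventing
  perfect ratings obtained by zeroing out weak topics;
* **feasibility of all areas** — no area's score under the focal weights
  may exceed 100.

The ratio of linear forms is linearized Charnes–Cooper style by fixing
Σw = 1, after which everything is a linear program solved exactly with
HiGHS (`scipy.optimize.linprog`), tolerance ~1e-8. One structural remark:
under the Σw = 1 normalization a score is a weighted average of
attainments ≤ 1, so the "no area exceeds 100" constraints can never bind;
they are retained in the program because they are part of the stated
constraint set, at negligible cost. Two useful consequences, both tested:
the DEA score dominates the calibrated score under any fixed admissible
scheme (baseline and heavy both satisfy the ordering and ratio bound; equal
weighting violates the strict ordering and is not admissible), and raising
any attainment never lowers the optimum. LP optima are verified against an
exhaustive brute-force search: by degree-zero homogeneity, enumerating all
integer weight vectors in {1..12}^n covers every rational vertex of the
constrained region, so the oracle agrees with the LP to ~1e-4 points on
small instances.

## Sensitivity analysis

All 12 assumption sets (4 weightings × 3 combination rules) are scored and
ranked; the area-specific cells use each area's own DEA weights under the
cell's combination rule. Per area the summary reports the baseline value
(baseline weights + 50:50, the first-listed configuration), the median of
the 12 values, and the (min, max) range. Rank medians over an even count
can land on .5; they are reported as integers with .5 rounded toward the
better (smaller) rank, which is how integer medians arise from 12 values —
a configurable choice. Medians are taken over per-assumption *calibrated*
scores.

Correlations against baseline use Pearson for scores and tie-corrected
Spearman (average ranks, then Pearson on ranks) for ranks; p-values use the
t approximation on n−2 degrees of freedom, displayed as "<0.0001" below
1e-4. The "extreme" correlation takes, per area, the range endpoint
farthest from its baseline value and correlates those extremes against
baseline — one reading of an ambiguous summary statistic, documented as
such. Degenerate grids (e.g. identical areas) have undefined correlations;
`correlate` raises, and the grid summary reports NaN for those entries
rather than failing the whole summary.

## Consumption link

Pure alcohol per capita (litres/person/year) = volume sold (millions of
litres/year) × mean ABV fraction × 1e6 / (population in millions × 1e6);
the explicit million factors mirror the conventional bookkeeping and
cancel. Income adjustment divides by GDP per capita (PPP international
dollars) and reports litres per 1000 I$ — a homogeneity-checked unit
convention, monotone decreasing in GDP. ABV must be a fraction in (0, 1];
values above 1 are rejected to catch percent-as-number mistakes.

Both a linear and a log-linear OLS of adjusted consumption on policy score
are provided. The log-linear model is the default for percent
interpretations and predictions because a constant-percent effect is only
coherent on the log scale: slope b implies a semi-elasticity of
100·(1−e^b) percent per point, and a Δ-point score increase at baseline
consumption c reduces consumption by c·(1−e^{bΔ}). `predict_change`
refuses linear-model input, where that arithmetic would be invalid. The
fits are simple regressions at small n; the package makes no causal claim.

## Synthetic data generator

The generator emulates the assumed data structure: per-area ordinal policy
codings plus consumption inputs whose income-adjusted values are
log-linear in the baseline policy score with Gaussian noise on the log
scale.

* Stringency: a k-level topic's 0-based level index is Binomial(k−1, p)
  with p = bias^{exp(−z)}, where bias is the per-domain propensity
  (default 0.5, neutral) and z ~ Normal(0, 0.8) is a per-area quality
  tilt. The exponential-tilt form pins p at 0 or 1 when the bias is 0 or 1
  (degenerate configurations used as anchors in tests) and gives
  between-area total-score dispersion of roughly 25–75 points at the
  defaults, comparable to observed cross-national spreads.
* Enforcement: i.i.d. over topics with probabilities (0.25, 0.40, 0.35)
  for poor/moderate/strong.
* Consumption: adjusted = exp(0.9 − 0.018·score + Normal(0, 0.15)). The
  slope is the reference semi-elasticity (1.8%/point) and the intercept
  places adjusted consumption in a realistic 0.2–1.6 L per 1000 I$ band.
  The intended adjusted value is back-converted into a (volume, ABV,
  population, GDP) tuple drawn from plausible ranges (ABV 4–12%,
  population 1–150 million, GDP 3 000–60 000 I$), constructed so the
  forward conversion reproduces it to 1e-9.

What the generator does **not** emulate: within-country policy
heterogeneity, correlated enforcement and stringency, measurement error in
codings, non-log-linear consumption responses, or the cultural/religious
covariates that shape real consumption. Tests passing on synthetic data
therefore validate the arithmetic and the statistical machinery, not the
empirical claims about any real jurisdiction.

Packaged fixtures expose the published nine-area score and sensitivity
tables (domain points, totals, ranks; baseline/median/range summaries) so
that downstream arithmetic — medians, ranges, rank correlations — can be
checked against printed values without any external data. The underlying
raw per-area codings were never published and are deliberately not
reconstructed.

## Numerical and scope choices

* LP solver tolerance ~1e-8; DEA scores reported to one decimal.
* Score conservation (topics → domains → total) holds to 1e-9 because all
  three are scaled jointly.
* Problem sizes: property tests run 9 synthetic areas (16 topics); DEA
  oracle comparisons use 2–6 topic instances where exhaustive enumeration
  is cheap; slope-recovery uses 500 replicates of n = 9.
* Published correlation coefficients tied to the unpublished 2011
  consumption inputs (e.g. score–consumption r values) are out of scope;
  the package recomputes only quantities derivable from shipped inputs,
  plus property-based checks of everything else.
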