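# Methods

## Dose–response model

Percent inhibition of root growth is defined against the concurrent water
control, `I(c) = 100·(1 − x̄_c/x̄_0)`; it can be negative when a treatment
stimulates growth. The EC50 is estimated by ordinary least squares of `I`
on concentration and inversion at 50 %, `EC50 = (50 − intercept)/slope`.
This linear-inhibition model is the estimator this bioassay traditionally
uses; no four-parameter log-logistic alternative is provided because the
tested ranges are narrow and approximately linear. A non-positive fitted
slope leaves the EC50 undefined (flagged, not an error): the substance does
not inhibit growth over the range. A regression-based `ec(x)` solver is
exposed for users who want true EC_x quantiles rather than the multiplicative
(0.5, 1, 1.5) × EC50 design concentrations.

Two fitting modes exist because raw study data typically arrive either way:
per-replicate (every root is a point; the default, more efficient) and
group-means (one point per concentration; used when only summary tables
survive). Both share the same control mean.

## Cytogenetic endpoints

Per slide: `MI = 100·TCD/TCC`, `CA% = 100·ΣTA/TCC`, `MF = CA%/MI`. The MF
numerator ("cells with abnormal division") is taken as the aberrant-cell
count, which makes `MF ≡ CA%/MI` an exact identity; this is asserted in
tests and holds for the published dose-series table to ±0.01. Aberrant cells
are tallied in six categories (micronucleus, c-metaphase, disturbance,
vagrant, stickiness, bridge) disjoint from the dividing-cell count.

Group aggregation defaults to per-slide endpoints summarised as mean ±
sample SD (n−1) across slides; a pooled-count mode (sum counts, then one
endpoint) is also available. A single-slide group reports SD as missing,
never zero.

Mutagenicity inhibition of a co-treatment uses the standard antimutagenicity
formula `100·(a − b)/(a − c)` with a/b/c the positive-control, co-treatment
and negative-control CA%. It requires `a > c` (a mutagenic signal); the
classification boundaries 25 and 40 are inclusive to "moderate". This
formula reproduces the bundled study's printed 48 h inhibition column to
≤0.03; its 24 h / 43 mg/mL entry does not follow from the printed means
(recomputed ≈27.5 vs printed 24.37) and is carried as a documented
discrepancy (`published.KNOWN_DISCREPANCIES`) rather than matched.

## ISSR polymorphism

Band profiles are binary loci × samples matrices with one negative-control
lane. Per-sample polymorphism is `100·(|lost| + |gained|)/|control ∪ sample|`
— 100 × the Jaccard distance between band sets. This definition was adopted
because it reproduces every per-sample percentage printed in the bundled
study tables (28 values, worst deviation 0.008; the tables themselves mix
truncation and rounding at 2 dp, hence comparisons at ±0.02). Total
polymorphism is the percentage of non-monomorphic loci. Band classification
is definitional: monomorphic = present in every lane, unique = present in
exactly one, polymorphic otherwise, absent = no lane (flagged). Two printed
single-lane bands labelled "P" in the source tables are classified unique
here, and the UBC-811 printed total (83.83 %) is flagged as a typo for the
matrix-derived 83.33 % (10/12 loci); fixtures encode the matrices verbatim
and never the internally inconsistent per-column totals.

Sample distances support Jaccard (default, consistent with the polymorphism
statistic), Dice, and simple matching (Hamming proportion). UPGMA is
average linkage on the distance matrix (scipy's implementation), with each
merge placed at half its cophenetic distance, so the tree is exactly
ultrametric up to floating point; Newick output carries branch lengths.
Tie-breaking among equal merge heights follows the linkage implementation's
deterministic order, so output is reproducible for a given input matrix.
The source study's printed clade distance ranges are not reproduced: the
software and metric behind them are unspecified, so the metric is left
configurable instead.

## Statistics layer

The endpoint model is a two-factor fixed-effects ANOVA, duration ×
concentration with interaction (the study describes its model as one-way but
includes the interaction; the two-factor form matches the substance).
Empty factorial cells trigger a fall back to the additive model with a
warning. Pairwise comparisons are Tukey HSD across the crossed cells;
letters come from a Piepho-style insert-and-absorb compact letter display,
which guarantees that two cells share a letter iff their adjusted difference
is not significant. Assumption checks are Levene (homogeneity across
groups) and Shapiro–Wilk on group-mean residuals; constant inputs are
flagged rather than tested.

Endpoint correlations are Pearson r with two-tailed p, BH-FDR adjusted over
the family of pairs within a treatment grouping (single vs combined are
separate families, mirroring how the endpoints are grouped). With
concentrations as replicates, n is typically 3; a low-power warning is
issued for n < 5 and these correlations are exploratory by construction —
they are property-tested (affine invariance, BH monotonicity, FDR control
under the null), not value-matched to any published coefficient, whose input
vectors are not available.

## Synthetic-data generator

The generator's defaults are the study conditions: concentrations
(0, 21.5, 43, 64.5) mg/mL, exposures (24, 48, 72) h, 40 roots per group,
3 slides × 1000 cells (group totals of 3000 cells, matching how the study
reports both per-slide and per-treatment totals), control mean lengths
40.43/49.33/60.5 mm, control MI 20.93/25.20/31.00 % and control CA
0.20/0.53/1.03 % per exposure.

* **Root growth** — mean `x̄_0(t)·(1 − min(1, slope·c))` with Gaussian noise
  clamped at 0 mm. The clamp (rather than resampling) is the simplest model
  consistent with reported means ± SD; at default parameters (means ≥ 20 mm,
  sd = 4 mm ≈ 10 % of the 24 h control) its bias is negligible. The default
  slope 0.5/43 per mg/mL puts the true EC50 at 43 mg/mL. Slopes that reach
  full inhibition inside the range clamp the mean at zero and set a
  `clamped` flag in the ground truth rather than failing.
* **Cell counts** — each slide is one multinomial draw over
  {non-dividing, dividing, six aberration categories}; the dividing
  probability is the true MI, the aberrant mass is the true CA split
  uniformly over the six categories (the real category mixture is unknown;
  uniform is the stated default and configurable). The multinomial is itself
  an assumption — the study reports only mean ± SD across slides, no count
  variance model. Defaults for the dose effects, `mi_decay = 0.074` and
  `ca_slope = 0.0764` %/(mg/mL), were fitted once to the 24 h dose series.
* **Band matrices** — a pool of `band_pool_size` loci with log-uniform
  weights in [193, 3076] bp sorted descending; the control lane carries
  `control_band_count` random pool loci; each control band is lost with
  `p = 1 − exp(−λ_l·c·m)` and each non-control locus gained with
  `p = 1 − exp(−λ_g·c·m)`. `m = 1` for single and combined lanes and
  `positive_control_multiplier` (default 40) for the positive-control lane —
  the reference mutagen acts at a low nominal concentration (4 mg/mL) but
  with strong genomic effect, and giving only that lane the multiplier keeps
  the stated single-treatment process untouched. Defaults (pool 13,
  control 7, λ_l = 0.0052, λ_g = 0.0028 per mg/mL) were chosen once to mimic
  the bundled tables' lost/gained counts.

Determinism: one integer seed; the three generators use independent
`default_rng([seed, k])` streams (k = 0 roots, 1 cells, 2 bands), so each
stage is bit-reproducible on its own. What passing recovery tests show is
that the estimators are unbiased and consistent *under these generating
assumptions* — linear inhibition, multinomial scoring, independent Bernoulli
band changes. Real assay data add features the generator omits: between-root
and between-bulb heterogeneity, scorer effects, non-linear dose–response at
the range edges, correlated band changes along the gel, and band-calling
error; agreement here does not certify behaviour under those.

## Problem sizes and numerical choices

The recovery studies use the sizes of the study design itself: EC50
recovery on the determination design (six concentrations 0–50 mg/mL, 40
roots each; noiseless, then 200 replicates at 10 %-of-control noise), MI
recovery over 500 replicate 3 × 1000-cell simulations, property suites on
1000 random matrices / 1000 null simulations. The full test suite and the
acceptance script each complete in well under a minute on one CPU.

Display rounding is round-half-up to 2 dp; all comparisons against printed
values use full-precision computation with tolerances of one printed ulp
(±0.01 on 2-dp endpoints, ±0.02 on polymorphism percentages, ±0.05 on the
inhibition column whose inputs are themselves rounded means), since the
source tables mix truncation and rounding.

## Known limitations

* The bundled tables are transcriptions of printed summaries, not raw data;
  raw root lengths and correlation input vectors are unavailable, so EC50
  from raw data and correlation coefficients are validated by synthetic
  recovery only.
* `n = 3` correlations have almost no power; they are reported with a
  warning and should be treated as exploratory.
* UPGMA topology is deterministic but tie-breaks follow the linkage
  library's order; trees from other software may resolve ties differently.
* The generator does not simulate gels, densitometry, or PCR chemistry;
  band matrices are generated at the scoring level.
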