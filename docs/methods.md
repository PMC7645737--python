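# Methods

This note documents the statistical model behind `foodsust`, the choices
made where the procedure was genuinely open, and what the synthetic-data
harness does and does not demonstrate.

## Ordinal rating

Indicator measurements reach the 0–4 Likert scale by one of three routes.

* **Benchmark normalisation** — attainment `p = min(value/benchmark, 1)`,
  for indicators with an official reference value (minimum wage being the
  canonical case). Attainment is capped at 100%: exceeding a benchmark is
  not more desirable than meeting it.
* **Max-in-context normalisation** — `p = min(value/context_max, 1)`, for
  indicators without official benchmarks (e.g. crop and breed diversity);
  the largest value observed in the study context defines 100%. Downstream
  uses are therefore invariant to the measurement's absolute scale.
* **Qualitative mapping** — an explicit category → score table agreed per
  indicator; unmapped categories become missing with a warning rather than
  an error, so a stray label cannot silently corrupt or abort an import.

The fraction-to-score map is linear with half-up rounding,
`score = ⌊4p + 0.5⌋`. The equivalence of the 0–4 scale with 0–100% implies
equal spacing of the grid; linear binning is the only map consistent with
that reading that is also monotone, surjective onto {0..4}, and symmetric
under direction reversal (`score(p, lower-is-better) =
score(1−p, higher-is-better)`, a property the tests enforce). Per-indicator
bespoke cut-points can be expressed by pre-transforming `p` before calling
the rating engine.

Household food insecurity is flagged by the lightest item of the
experience-based scales (worry about having enough food in the past four
weeks); the full multi-item severity scoring of those instruments is out of
scope.

## Aggregation

Scores are ordinal, so dimensions and activities are summarised by
**medians** of their non-missing indicator scores; means of raw scores are
never taken. Conventions:

* even counts use the midpoint of the two central order statistics, which
  produces the half-point medians visible in dimension profiles;
* missing scores are excluded, not imputed as zero — an activity a food
  system genuinely performs at "very low" level must be *rated* 0, while an
  activity with no usable evidence contributes nothing and is flagged;
* a dimension with no non-missing score raises: an overall score computed
  over four dimensions would not be comparable with one over five;
* an activity category with no non-missing score contributes 0 to the
  cumulative (max 20) score and is reported in `empty_activities`;
* quartiles use linear interpolation between closest order statistics
  (numpy's `method="linear"`), checked in the tests against a brute-force
  order-statistic oracle;
* display rounding is one decimal, half-up, applied only at reporting;
  internal arithmetic is unrounded.

The overall score is the unweighted arithmetic mean of the five dimension
medians. No weighting across dimensions or activities is applied anywhere.

## Key-lever (deviation) analysis

The reference baseline for each food system is the **median over all its
indicator scores** (not per-dimension, not cross-system): each indicator is
then counted as below / above / equal across systems. Equal-to-median
scores count as neither weakness nor strength. Rankings break ties on the
below-count by fewer above-counts, then lexicographically by indicator id,
giving a deterministic total order; indicators that never score above any
reference median carry a `no_positive_score` flag. Counts conserve:
below + above + equal + missing = number of systems, asserted as a property
over randomly generated matrices.

## Polychoric correlation and ordinal PCA

Pearson correlations of ordinal codes are attenuated; the polychoric model
treats each observed variable as a standard normal latent variable cut at
unknown thresholds. Estimation is **two-step ML**: thresholds are fixed at
`τ_k = Φ⁻¹(cumulative proportion through category k)` from the margins, and
the latent correlation maximises the multinomial log-likelihood whose cell
probabilities are bivariate-normal rectangle probabilities over the
threshold grid. Numerical choices:

* the bivariate normal CDF uses Owen's T-function identity
  (`scipy.special.owens_t`), exact to well below the 1e−7 accuracy target
  and fully vectorised over the threshold grid; the implementation is
  cross-checked in tests against `scipy.stats.multivariate_normal`;
* the correlation is optimised by bounded scalar search on
  (−0.999, 0.999) with tolerance 1e−6; cell probabilities are floored at
  1e−12 to keep the log-likelihood finite on sparse tables;
* variables with a single observed category are degenerate and dropped
  with a warning entry; indicators with *any* missing score are removed
  before the analysis (pairwise-complete estimation would give each pair a
  different sample, untenable with a handful of observations);
* a pairwise-assembled matrix need not be positive semi-definite — with
  six observations it usually is not; it is repaired by clipping
  eigenvalues at 1e−6 and rescaling to unit diagonal, and the result is
  flagged `smoothed`.

PCA is a plain eigendecomposition of the (repaired) correlation matrix:
loadings are eigenvectors scaled by the square root of their eigenvalue,
components are ordered by descending eigenvalue, and each eigenvector's
sign is fixed so its largest-magnitude loading is positive (signs are
otherwise arbitrary). Component extraction is used, not a factor model and
not rotation. Retention is the Kaiser criterion (eigenvalue > 1) capped at
n_observations − 1 — the rank bound of centred data — with a floor of one
component. Influence lists keep indicators with |loading| above a cutoff,
0.45 by default, sorted by |loading|.

## Environmental metrics

ASC/ASCI follows `ASC_i = ((S_i + N_i)/2)·A_i`, `ASCI = Σ ASC_i` over the
land-cover classes of an agroecosystem, with `N_i ≤ 23` (the service
catalogue) and at most 99 classes. Area shares are fractions in [0, 1];
percent-scale tables are divided by 100 on import. `S_i` is taken as the
mean strength over the services a class provides (when derived from a
class × service strength table, `N_i` counts the positive entries and
`S_i` averages them); its absolute scale is not rescaled, because the ASCI
indicator is rated by max-in-context normalisation, which is
scale-invariant. ASCI is additive under splitting a class into parts with
equal `N`, `S` and is monotone in each argument — both are property-tested.

Shannon diversity is `H = −Σ p_i ln p_i` (natural log) over labels with
positive counts.

## Synthetic-data harness

`simulate_scores` draws ordinal matrices for six food-system archetypes.
The default dimension targets (0–4, half-point grid) encode the qualitative
contrast the assessment is designed to expose: agroecological and local
systems high and balanced, the regional system intermediate, the
domestic–indigenous system strongest environmentally but weak on poverty
and inequality, and the agro-industrial systems weak on environment and
right to food yet medium-to-high on social-ecological resilience. Scores
are normal draws centred on the dimension target (default sd 0.8, a
plausible between-indicator spread within one dimension), rounded half-up
and clipped to {0..4}; missingness defaults (2% background, 50% within the
three wage indicators) put roughly 5% of cells to N/A, concentrated where
the original dataset had them. With sd 0 the generator is an identity
check: every score equals its discretised dimension target, so medians must
recover the targets end-to-end (targets are compared after discretisation
onto the Likert grid, since a half-point target cannot be an individual
rating).

`simulate_ordinal` draws latent multivariate normals and discretises at
known thresholds — the ground truth for polychoric recovery
(MAE < 0.07 at n = 500 across ρ ∈ {−0.8…0.8} is enforced in the tests).
`simulate_landscape` draws Dirichlet area shares with random service counts
and strengths. All generators use numpy's PCG64 with an explicit seed;
identical seeds give bit-identical outputs.

What the harness does **not** emulate: real rating workshops (consensus
dynamics, bespoke per-indicator cut-points), correlation structure between
indicators within a dimension beyond the shared target, systematically
skewed missingness outside the wage indicators, and any survey microdata.
Passing tests therefore demonstrate that the arithmetic of the pipeline is
correct and stable under the stated conditions, not that any particular
real-world food system scores as the archetypes do.

## Problem sizes

The test suite and the acceptance script run the full 56-indicator,
six-system pipeline (≈1 400 polychoric pairs, a few seconds), 200 simulated
pairs at n = 500 for polychoric recovery, 1 000 random matrices for
deviation-count conservation, and 200 random landscapes for the ASCI
properties — sizes chosen so the entire suite completes in well under a
minute of numerics while keeping Monte-Carlo noise far from the asserted
margins.

## Known limitations

* Two-step (not full-information) polychoric ML: thresholds are not
  re-estimated jointly with ρ; at the sample sizes involved the difference
  is far below the recovery tolerances.
* With six observations the polychoric matrix is heavily smoothed; retained
  components and loadings should be read as descriptive, not inferential.
* The XLSX importer is heuristic by necessity (supplementary workbook
  layouts vary); anything it cannot recognise is ignored, and the CSV
  dialect is the canonical interchange.
* No weighting, no significance testing, no factor rotation — deliberate
  non-goals of the assessment design.
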