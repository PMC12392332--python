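# Methods

## Study model

The package models a three-arm rat cohort — untreated controls, sham-operated
dams, and intrauterine-hypoperfusion dams — whose pups are classified as
growth-restricted from birth weight, profiled for CSF protein abundance on
postnatal days 4 and 5, followed longitudinally for candidate biomarkers, and
tested behaviorally. Every analysis stage is implemented against tabular
inputs only; mass-spectrometric acquisition, image segmentation and
annotation retrieval are out of scope and enter as already-quantified tables.

## FGR threshold

Birth weights are treated as normal within group. The threshold is
`mean − k·SD` of the reference (untreated) group with `k = 1.5` by default;
with the reference statistics 7.01 ± 0.55 g this is 6.185 g. Classification
uses strict `<` — a pup at exactly the threshold is non-FGR — because the
rule is phrased as "below" the threshold. Quantiles are evaluated in full
double precision; two-decimal rounding is display only.

## Synthetic cohort generator

Each generator draws from its own `numpy` PCG64 stream seeded by
`(fixed offset, master seed)`, so outputs are bit-reproducible and adding a
generator never perturbs another. Defaults are the modelled study's
conditions: 10 pups per group per day, 601 proteins with 15 responders,
and group weight laws control (7.01, 0.55), sham (6.87, 0.74),
hypoperfusion (5.727, 0.74) g. The hypoperfusion mean is chosen so that
P(weight < 6.185) = 0.73 at σ = 0.74 — the generator is calibrated to the
reported fraction of FGR-classified offspring, since the group mean itself
is not a reported statistic. Litters are filled round-robin (10 pups/dam);
litter random effects exist but default to zero variance, as litter
clustering is not part of the modelled analysis.

### Proteome model

Reporter intensities are log-normal: positive and right-skewed, as isobaric
reporter intensities are. For responder *j* with direction d_j ∈ {±1},

    log A_ij = log(baseline_j) + d_j · β · z_i + ε_ij,   ε ~ N(0, σ²),

with z_i the birth-weight z-score within the profiled cohort (so the planted
correlation is scale-free) and σ = `noise_sd` = 0.5 by default. β is set by
inverting the bivariate-normal identity ρ_s = (6/π)·asin(r/2),
r = β/√(β²+σ²), so the population Spearman correlation equals
`target_abs_rho` (0.8 by default, the magnitude typical of the strongest
reported candidates). Null proteins are independent of weight. Day-5 uses
the same responders and directions with probability `concordance_prob`
(default 1; a non-concordant responder has its day-5 direction flipped). By
default the two days profile **independent** pup cohorts (n = 10/group/day);
a `same_pups_both_days` flag covers the paired design, since the profiling
design is ambiguous in the modelled study.

### Timecourse and behavior generators

The timecourse generator emits raw band/albumin densities whose ratio is the
configured relative level (sham 1, FGR-vehicle `tc_elevation` = 2, MSC arm
pulled back toward 1 by `tc_attenuation` from day 5 on) times log-normal
noise (`tc_noise_sd` = 0.3, a typical densitometry CV). The behavior
generator plants deficits in the FGR-vehicle arm (longer geotaxis latency,
shorter rota-rod latency with reduced trial-2 learning, reduced Y-maze
alternation bias, weaker novel-object preference), with the MSC arm
recovering a configurable fraction (default 0.8). Distribution shapes and
magnitudes are invented plumbing: they make downstream statistics exercisable,
but passing tests on them says nothing about real effect sizes — only that
the scoring rules and tests behave correctly on data with this structure.
The generators do not emulate missing values, batch effects, or
litter-correlated noise; real data would carry all three.

## Screen statistics

Spearman ρ is the Pearson correlation of midranks. The default p-value is
the t-approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df, which reproduces the
reference panel's printed p-magnitudes from its printed 2-dp correlations
(e.g. ρ = −0.87, n = 20 → 6.2×10⁻⁷ against a printed 6×10⁻⁷); an exact
permutation mode (P(|ρ*| ≥ |ρ|) over all n! rank permutations) is available
for n ≤ 9. With n = 20 per day the t-approximation is within 0.02 of the
exact permutation mid-p (asserted at n = 8, where enumeration is feasible).

Storey q-values use the step-down minimum q(i) = min_{j≥i} π0·m·p(j)/j,
capped at 1; with π0 = 1 this is exactly Benjamini–Hochberg (oracle-tested
against statsmodels). π0 is estimated by Storey's smoother — π0(λ) on the
grid 0.05…0.95 fitted with a cubic polynomial and evaluated at λ = 0.95 —
clamped to [1/m, 1]; a fixed-π0 mode gives strict-BH reproducibility. With
fewer than 10 p-values the smoother falls back to fixed π0 with a warning.
q-values are computed within each day's full quantified protein set;
proteins with fewer than 4 complete abundance/weight pairs are excluded from
the q-value pool and flagged.

Concordance requires per-day significance (p < 0.05 ∧ q < 0.1) on both days
plus equal nonzero sign of ρ; ρ = 0 carries no direction. The
brain-expression rule retains candidates with ≥ Medium expression in a
neuronal, glial or Purkinje class in any region. The rule is configuration,
not hard-code: it is the operationalization of "highly expressed in brain
cells" that exactly reproduces the reference panel's 15 → 6 split, and both
the level floor and the allowed cell classes are arguments.

## Nonparametric tests

Steel–Dwass: pooled midranks per pair; W the rank-sum of the second group,
E[W] = n_b(N+1)/2, tie-corrected Var[W] = n_a n_b/(N(N−1))·(Σr² − N(N+1)²/4);
p = P(Q_{k,∞} ≥ √2|t|) with the studentized-range tail computed by numerical
integration of 1 − k∫φ(z)[Φ(z) − Φ(z−q)]^{k−1} dz (cross-checked against
scipy's studentized-range distribution to 1e-6). The infinite-df reference
is standard for rank statistics; small-sample exactness is delegated to the
permutation oracle used in the tests, where agreement is measured against
the exact mid-p because the n = 4 permutation null is so discrete that
single atoms carry ~0.15 probability. Zero-variance pairs (all observations
tied) report t = 0, p = 1 rather than erroring, so degenerate simulated
inputs cannot crash a pipeline.

Wilcoxon signed-rank: zero differences dropped; exact null distribution of
the positive-rank sum for n ≤ 25 via polynomial counting over doubled
midranks (ties supported); beyond that, the normal approximation with tie
correction. The modelled study applies this paired test to an apparently
unpaired weight-gain comparison; how pairs were formed is not stated, so the
package exposes both the signed-rank path and the k = 2 rank-sum
(Steel–Dwass) path and takes no guess.

## Normalization conventions

Blot densitometry: band/albumin, then divided by the reference-group mean
ratio — either the sham group at the first day globally, or the sham group
per time point; both conventions are offered because the two longitudinal
designs being modelled use one each. Immunofluorescence: affine map sending
a per-panel background to 1 and the panel maximum to 100, with out-of-range
values clamped to the anchors and counted (per-image maxima can exceed the
panel-wide display maximum). Per-panel background is the default; a
per-image background is a caller decision.

## Behavioral scoring choices

The climb-up latency bins overlap at their printed boundaries (15 s is both
"0–15" and "15–30"); left-closed/right-open bins are adopted, so 15 s scores
4. The Y-maze alternation denominator is implemented as printed
(entries − 1), making the attainable maximum (entries−2)/(entries−1)·100
rather than 100; the conventional (entries − 2) denominator is available via
an argument, default off, because the printed formula is followed rather
than second-guessed. Rota-rod latencies are capped at the 300 s protocol
limit with a warning.

## Problem sizes and numerical choices

The test suite's simulation-based assertions use: 10,000 weights for
generator calibration; m = 5,000 null proteins for p-value uniformity;
50 replicate studies (601 proteins, 15 responders, n = 20/day) for
planted-responder recovery (≥ 70%) and realized FDR (≤ 0.10); 2,000
three-group null simulations (n = 15) for Steel–Dwass family-wise error
(within [0.03, 0.07] at nominal 0.05); and full enumeration (34,650
relabelings) for the n = 4 exact Steel–Dwass oracle. These sizes make Monte
Carlo error small relative to each asserted band while the full suite runs
in well under a minute. All randomness flows from explicit seeds; reruns are
byte-identical (the pipeline asserts its own funnel-count invariants as
postconditions on every run).

## Known limitations

- The generators produce clean, complete, batch-free tables; conclusions
  about robustness to missingness or batch structure cannot be drawn from
  them.
- The asymptotic Steel–Dwass p-value is approximate for very small groups
  (n ≤ 5); deviations from the exact permutation mid-p reach ~0.04 on the
  largest atoms of a fully null n = 4 configuration.
- π0-smoother estimates are noisy for m below a few hundred; the fixed-π0
  mode is preferable there.
- The brain-expression filter is only as good as its annotation table;
  un-annotated candidates are routed to a needs-review list rather than
  silently dropped or kept.
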