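# Methods

## Data model

The analysis operates on a complete compounds × residues matrix E of
per-residue binding-energy contributions (kJ/mol; negative = favorable, the
sign convention of MM-PBSA decomposition output) and an activity vector of
pIC50 values paired **by compound identifier**, never by row position.
Missing cells are an error on read; an explicit `fill_missing` option exists
because decomposition tools omit residues with no contact, and silently
zero-filling would distort correlations toward whatever the zero happens to
mean relative to the column's scale. Per-frame contribution files are
aggregated by the arithmetic mean over frames (the usual convention of
averaging MM-PBSA snapshots); a median option is available for
outlier-heavy trajectories.

The packaged study dataset is transcribed at the printed 2-decimal
precision. Whether the original correlations were computed on full-precision
or rounded energies is unknowable from the publication; the reproduce
tolerances (±0.03 on residue/cluster correlations, ±0.02 on component
correlations) absorb exactly that rounding uncertainty, and all 18
juxtaposed values agree within it. One printed pIC50 (DuP-697) is ambiguous
in the energy table's header and is taken from the component table, where it
is printed unambiguously as 8.04.

## Statistics

**Correlation** is the Pearson product-moment coefficient. The choice is
forced empirically: Pearson reproduces every printed correlation within
rounding; Spearman does not (it is available behind `method="spearman"` for
robustness checks). The implementation computes cov/√(v_x·v_y) in a form
that is bit-symmetric in its arguments; degenerate inputs (n < 3, length
mismatch, zero variance) raise rather than returning 0 or NaN, and
zero-variance residue columns are flagged undefined and excluded from
selection instead of being coerced to r = 0. At least 3 paired observations
are required; correlations on so few compounds are reported but carry very
wide sampling error (see *Limitations*).

**Cluster score.** A cluster's score for compound c is the cumulative
binding energy S_c = Σ_{i∈cluster} E_{ci}; the cluster statistic is
r = corr(S, pIC50). Summation makes the score invariant to residue order
and additive over disjoint subsets, both asserted by property tests.

**Selection rule.** The published procedure keeps residues with negative
correlation, then narrows them per SAR site. Applied as stated to the
packaged data it yields six residues — Gln178, Ser339, Tyr341, Arg499,
Phe504, Ala513 (cumulative-energy r = −0.650) — whereas the published
7-residue cluster additionally contains Val509, whose printed correlation
is +0.20. Both behaviors are first-class: the default pipeline applies the
rule as written, and the published cluster ships as an explicit override
constant (`CANONICAL_CLUSTER`, r = −0.592 ≈ the published −0.60). The
package deliberately takes no position on which the original authors
intended.

**Subset search.** The exhaustive search enumerates all subsets of sizes
[k_min, k_max] (vectorized per size), subject to an enumeration budget
(default 10⁶) and an optional requirement of ≥ 1 residue per SAR site.
Objectives: `most_negative_r` (default, matching the favorable-binding sign
convention) and `max_abs_r`. Ranking ties break toward smaller clusters,
then the canonical residue order (alphabetical code, ascending number), so
output is deterministic and column-order invariant; retained results are
re-scored through the scalar correlation path so their r is bit-identical
to `cluster_correlation` on the same subset. Greedy forward selection
offers an O(n·k) alternative with the same tie-break; it can be
arbitrarily suboptimal in principle, and tests assert only that it never
beats the exhaustive optimum at equal k. Raw subset counts are reported
with search results; no multiplicity correction is applied across the
enumerated subsets — the ranking is exploratory, and any single highlighted
subset should be judged by the permutation test, not by its rank.

**Permutation test.** Activity labels are permuted n_perm times (default
999) and the cluster correlation recomputed; the two-sided p-value is
(#{|r_perm| ≥ |r_obs|} + 1)/(n_perm + 1). The +1 smoothing keeps the test
valid (never reports 0) at the cost of a floor of 1/(n_perm+1). One-sided
alternatives are supported. A comparison tolerance of 1e−15 guards the ≥
against float noise in ties. Simulated on 1,000 null datasets at the study's
own scale (8 compounds, 199 permutations) the rejection rate at α = 0.05 is
0.05 — the test is exactly calibrated under exchangeability.

**Bootstrap.** Percentile CI (default 95%) over compound-level resamples;
resamples in which either vector is constant have no defined correlation
and are redrawn (count logged). With n = 8 compounds the percentile CI is
crude — it is reported as a stability indicator, not an exact interval —
and ≥ 4 compounds are required.

**Cross-validation.** Leave-one-out: for each held-out compound a
univariate least-squares line pIC50 ~ S is fitted on the rest;
q² = 1 − PRESS/SS_tot with SS_tot about the overall activity mean, and RMSE
is over held-out predictions. q² ≤ 0 means the cluster score predicts no
better than the mean. On the packaged data the canonical cluster gives
q² = −0.39, RMSE = 0.79 pIC50 units — a caveat the correlation alone hides.

**Randomness.** All stochastic operations use numpy's seeded `default_rng`;
experiment replicates derive child seeds from a single parent seed, and
every CLI report records the seed, config echo and input checksums.
Cross-version bit-stability of numpy's generator is best-effort.

## Synthetic-data generator

The generator emulates only the statistical structure the analysis
consumes: activities i.i.d. normal (default mean 7.8, sd 0.7 — the scale of
the packaged pIC50s, which span 6.30–8.57; a matched-moment uniform option
exists), and residue energies

    e_ij = μ_E + σ_E · (ρ_j z_i + √(1 − ρ_j²) ε_ij),

with z the standardized activity vector, ε i.i.d. standard normal, and
defaults μ_E = −8, σ_E = 3 kJ/mol (the scale of the packaged decomposition
energies). Conditioning on z, the population correlation of column j with
activity is exactly ρ_j, so recovery tests have an analytic target: the
asymptotic bound |mean r̂ − ρ| < 2(1 − ρ²)/√(n − 1) is asserted directly.
Each dataset embeds its generating spec for provenance. The generator does
**not** emulate inter-residue energy covariance, frame-to-frame
autocorrelation, heavy-tailed energy distributions, or measurement error in
IC50s — passing recovery tests therefore demonstrate correctness of the
estimation machinery, not robustness of the method on real decomposition
data.

## What the recovery experiment shows

With seven residues at ρ = −0.6 and five null residues:

* at the study's own n = 8, sign-rule sensitivity is well below 1 —
  single-study residue selections at this scale are unstable;
* at n = 500, mean estimated r recovers −0.6 within ±0.005 and sensitivity
  reaches 1.0, but **specificity plateaus at ~0.5 at every n**: a true-zero
  residue's sample correlation is symmetric about zero, so a pure sign rule
  admits it with probability ½ regardless of sample size. Sign-only
  selection has no specificity against null residues; screening out
  irrelevant residues requires a magnitude or significance threshold on top
  of the sign. This is the central statistical caveat about sign-selected
  residue clusters, and the package surfaces it rather than papering over
  it.

## Problem sizes in the test suite

The suite's simulation sizes are chosen as the smallest that make each
statistical assertion sharp: 1,000 null datasets bound the type-I-error
estimate's binomial error at ±0.014 (2 sd) inside the asserted [0.03, 0.07]
band; 200 replicates at n = 500 pin mean recovered r to ±0.004; 500
replicates suffice for the sign of the mean null q². Exhaustive-search
oracle checks run on ≤ 10 residues where full enumeration is trivial.

## Limitations

* With 8 compounds the sampling sd of r is ≈ 0.35 under the null; none of
  the individual printed residue correlations except the strongest would
  survive a formal significance screen, and the canonical cluster's
  permutation p is 0.12. The package reproduces the published numbers and
  simultaneously quantifies their fragility.
* The published study extends the cluster score to 18 further inhibitors
  and a pooled 26-compound set (reported correlations −0.47 and −0.70);
  their per-residue energies are not published, so those analyses are
  documented here but cannot be recomputed from shipped data.
* Site membership is as named in the original narrative (Site-1:
  Tyr371/Phe504/Val509; Site-2: Gln178/Ser339/Arg499; Site-3:
  Tyr341/Ala513); the full membership of each site was never enumerated.
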