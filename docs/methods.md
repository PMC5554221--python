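# Methods

This note records the models, conventions and design choices behind
`coregulon`, in the spirit of a statistical-software methods appendix. It
documents what the code computes and why; every number quoted here is
produced by the test suite or `scripts/acceptance.py` at run time.

## Discretization

Inference consumes a ternary matrix. Each gene is centered on its mean
across samples (a config switch allows centering on designated reference
samples instead; which centering the original analyses used is not
documented, so gene-mean is the default) and thresholded at ±*k*·σ with a
*closed* boundary (≥ / ≤), where σ is the standard deviation of the full
centered matrix. A single global σ, rather than per-gene scaling, preserves
the relative dynamic range of genes: strongly regulated genes yield more
nonzero states. Default *k* = 1. A zero-σ (all-constant) matrix produces
all-zero states with a warning rather than an error, since downstream
stages handle empty state sets.

## Co-regulator mining

The *collective state* of a TF set in a sample is its unanimous nonzero
state, else 0 — the strictest cooperative reading, chosen because it is
permutation-invariant and makes support anti-monotone in set size, so a
classic Apriori levelwise search is exact. Support is the fraction of
samples with nonzero collective state; sets with support ≥
`min_coreg_support` up to `max_coreg` members are kept. The default support
threshold is 0.2 and the default `max_coreg` is 4. The miner is implemented
in-package (it is ~60 lines against an incremental collective-state
update) and is verified against exhaustive enumeration in the tests.

## Candidate selection and the discrete prediction rule

For a gene with states g, a candidate program (A, I) predicts per sample
p = sign(a − i), where a and i are the collective states of A and I (empty
set → 0). The rule is monotone increasing in a, decreasing in i, and
symmetric under (A, I, g) → (I, A, −g); the discrete score is
mean(|g − p|)/2 ∈ [0, 1]. Candidates are all disjoint pairs drawn from the
mined sets plus the empty set on one side, restricted to score ≤
`search_thresh` (default 0.5) and to genes whose states are nonzero in ≥
`min_gene_support` (default 0.1) of samples; the same row filter applies to
TFs acting as regulators.

Ternary patterns collapse within phases of similar activity, so many
candidate programs tie at the best discrete score. Truncating the candidate
list aggressively before regression would discard exact-fitting programs;
the default `max_candidates` is therefore 20 000 — effectively "score
everything that passes the screen" at the package's default scale — and the
regression stage is computed from per-set sufficient statistics
(batched 3×3 normal equations) so the cost of scoring all survivors is
negligible.

## Sign-constrained regression and model selection

Gene expression is regressed on an intercept, the mean expression of A
(coefficient ≥ 0) and the mean expression of I (coefficient ≤ 0). With at
most two regressors the active-set method is exact: fit unconstrained, drop
the worst violating term, refit, re-check. The fit score is the adjusted
R², 1 − (1 − R²)(n − 1)/(n − p − 1), with p the number of retained
non-intercept terms. The batched normal-equations path and the reference
per-candidate least-squares path are cross-checked against each other in
the tests (they agree to ~1e-10 on well-conditioned data).

For selection, negative adjusted R² is clamped to 0 so both component
scores live on [0, 1]; the merged score is the unweighted mean of the
clamped fit score and, when evidence is used, the evidence score. Ties are
broken by fewer regulators, then lexicographic member lists — every
ordering in the package has a deterministic total order so repeated runs
are byte-identical.

By default only non-regulator rows are modeled as targets. Selection is an
argmax with no fit threshold, so every eligible row receives a model;
modeling the regulator rows themselves would therefore force TF→TF edges of
no better-than-chance quality. A config switch (`include_tf_targets`)
restores TF targets for users who want them (self-regulation is always
excluded).

## Evidence integration

The evidence score of a model is the fraction of its *within-side*
unordered TF pairs (co-activators, co-inhibitors) present in the PPI
evidence — the quantity a physical interaction can support. Cross-side
pairs are excluded as they mix activation and repression. Models with no
pair score 0 by default; a `no_pair_evidence_neutral` switch excludes the
evidence term from their mean instead (the default avoids systematically
favoring single-regulator models when evidence is on). Network-level
enrichment is the one-sided hypergeometric tail of the overlap between the
realized cooperative pairs and the evidence pairs within the C(|TF|, 2)
pair universe.

## Cooperativity network

Two TFs are linked when they co-occur on the same side of at least
`min_common_genes` selected models (default 5) *and* the shared count is
hypergeometrically significant at `alpha` (default 0.01), with the marginal
counts taken over genes whose model contains each TF. The count threshold
alone admits promiscuous regulators with large regulons; the significance
gate corrects for regulon size.

## Influence

The influence of regulator r in a sample is the Welch statistic comparing
the expression of its activated and repressed targets, with per-set sample
variance (ddof = 1) divided by set size. Conventions for small regulons: a
singleton side contributes variance 0 (keeping small regulons computable
above `min_target`); an empty side contributes mean 0 and no variance term,
so single-sided regulons compare their targets against a zero baseline; the
statistic is undefined only when both sides are empty, or when the
denominator vanishes with unequal means (equal means give 0). Influence is
computed on replicate means, for TFs with ≥ `min_target` = 10 targets, and
undefined entries are serialized as `NA`.

## Phase segmentation

The influence heatmap is segmented by exact dynamic programming minimizing
within-segment squared deviation from segment means across all TF rows
(rows with undefined entries are dropped). For a fixed number of segments
the optimum is exact (verified against exhaustive search for small n). The
number of phases is chosen by penalized cost over 1..`max_phases` with
default penalty 2·d·log(n)·s², where s² is half the median across TFs of
the variance of the first differences — a robust estimate of the fast
within-phase fluctuation scale. The data-scale factor makes the criterion
invariant to the units of the influence values; with an unscaled penalty
the criterion would be meaningless for t-statistic-scale data. The
segmentation operation itself is analysis plumbing: it automates a call
that practitioners usually make by eye on the heatmap.

## Robust rank aggregation

Within a phase, TFs are ranked per sample by signed influence (a regulator
is considered active when its activated targets sit above its repressed
ones); over the whole course, by absolute influence (impact of either
sign). For each TF the normalized rank vector r(1) ≤ … ≤ r(n) over its n
lists yields ρ = min_k P(U(k) ≤ r(k)) under the uniform order-statistic
null, i.e. the Beta(k, n−k+1) lower tail; the implementation is checked
against an independent binomial-sum tail. The corrected score is
min(1, ρ·m) with m the number of ranked items. A TF with undefined
influence in a sample is dropped from that sample's list and its n
adjusted. Final ordering: ρ ascending, then mean normalized rank, then id.

## Master regulators

Enrichment of a TF's regulon (union of activated and repressed targets by
default; a `side` option restricts it) in a user gene list is the one-sided
hypergeometric tail, with the universe defaulting to the genes carrying
selected models. Raw p-values order the output; a Benjamini–Hochberg column
is reported but not used for selection. Under a simulated null the
(discreteness-smoothed) p-values are uniform by a Kolmogorov–Smirnov check.

## Synthetic data generator

The generator emulates the structure the analysis assumes, at the study
scale: 26 time points × 3 replicates, 4 phases, 20 TFs, 200 genes, with a
monotonically increasing C/N covariate (7.89 → 31) and times spanning
110–170 h in the metadata.

* **TF activity** is piecewise: each TF is active (expression step +3 log2
  units) in exactly one phase and inactive elsewhere, plus a private smooth
  drift. The drift is a Gaussian-smoothed noise process (correlation length
  1.5 time points) squashed through tanh — a near-telegraph waveform that
  maximizes drift energy under a hard amplitude bound (peak drawn from
  0.4–0.7). The bound keeps drift from crossing the discretization
  thresholds on its own; independent draws make every TF's profile
  distinguishable from every other's, which is what renders the planted
  programs identifiable.
* **Co-regulator sets** are drawn per phase from that phase's TFs (sizes
  2–3 by default, every TF covered) and shared across genes, planting the
  cooperativity structure.
* **Genes** are α + β_A·mean(activators) + β_I·mean(inhibitors) with
  β magnitudes in 0.6–0.8 and opposite signs, plus N(0, noise_sd²)
  biological noise per time point; replicates share the biology and add
  N(0, replicate_sd²) technical noise (defaults 0.1 and 0.05). A
  "noiseless" run sets both to 0.
* **Evidence** includes each planted within-side TF pair with probability
  `coverage` and adds `round(false_rate · n_planted)` spurious pairs.

What the generator does **not** emulate: probe/batch effects, missing
values, non-additive (e.g. multiplicative or saturating) regulation,
TF-on-TF regulation, autocorrelated noise, and regulons that change sign
across conditions. Passing recovery tests on these data therefore
demonstrates algorithmic correctness under the model's own assumptions, not
performance on real arrays.

On this design, the full pipeline recovers all planted signed edges exactly
at zero noise, keeps signed-edge F1 above 0.8 at noise 0.1 (typically
0.85–0.91 across seeds), finds the planted 4-phase structure exactly at
both noise levels, and ranks each phase's five planted active TFs as that
phase's top five — all recomputed by `scripts/acceptance.py`.

## Determinism

All randomness flows through `numpy.random.default_rng` seeded from the
user seed (with fixed stream offsets per purpose); all orderings have
lexicographic fallbacks; writers format numbers at 6 significant digits.
Two runs with the same seed produce byte-identical outputs, which the
acceptance script verifies.

## Known limitations

* The discrete screen collapses within-phase structure, so candidate
  discrimination rests entirely on the regression; data whose regulators
  are collinear (e.g. perfectly co-expressed TFs) yield arbitrary—though
  deterministic—choices among equivalent programs.
* Adjusted R² penalizes regression *terms* (at most two), not regulator
  count, so supersets of the true sets are rejected only via their worse
  fit; at high noise this inflates regulon sizes somewhat.
* The influence statistic assumes the regulon's sign structure is correct;
  errors in inferred edge signs propagate to influence, phases and ranks.
* Hypergeometric p-values are reported raw in Table-style outputs; use the
  BH column when scanning many gene lists.
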