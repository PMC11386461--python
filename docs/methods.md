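# Methods

## Problem setting

Two bulk RNA-seq datasets X and Y — typically from different species and
different studies — each profile the same two conditions C1 and C2. After
preprocessing (library-size normalization to counts per million, zeros
replaced by 1, log2 transform) and restriction to shared genes (same
species) or one-to-one orthologs (cross species), the goal is a
transformation of both matrices that removes study-specific technical
structure while preserving (a) each dataset's internal C1-vs-C2 contrast
and (b) genuine species differences.

## Evaluation model

All quality measures derive from six DEG lists between the four groups
H_C1, H_C2, M_C1, M_C2 (H = X's role, M = Y's role), in fixed positional
order: two condition lists (1–2), two cross lists (3–4), two species lists
(5–6). DEG calling: noise filter (a gene needs ≥ n samples with log2 value
≥ 4, n = size of the smaller group, counted pooled across both groups),
Welch two-sample t-test with Welch–Satterthwaite degrees of freedom,
Benjamini–Hochberg FDR over the noise-passing genes, then FDR ≤ 0.05 and
|LFC| ≥ 1. Direction is the sign of the LFC (first-named group minus
second).

With P_ij/i = |L_i ∩ L_j| / |L_i| (defined as 0 for empty L_i):

- CCA = mean of the 12 ordered P_ij/i over lists 1–4, i ≠ j.
- SA = Σ_{i=1..4, j=5,6} (P_ij/i + P_ij/j) / 16. The species–species
  intersection L5 ∩ L6 deliberately does not enter; the divisor is the
  number of terms actually summed.
- CSC = CCA / SA, with SA floored at 1e-6 (a warning is emitted when the
  floor activates; CCA = 0 yields CSC = 0 regardless).
- IOU(dataset) = |before ∩ after| / |before ∪ after| of its condition
  list across a normalization; two empty lists give 1.

## The CSN transform

1. **Clustering.** Gene vectors of the row-aligned pair are concatenated
   (samples of X then Y) and clustered with fuzzy c-means (Euclidean,
   fuzziness exponent 2.0, seeded random membership init, tolerance 1e-6).
   Genes are hard-assigned by maximal membership (ties to the lowest
   index) because the displacement formula addresses exactly one cluster
   per gene. Default k = 50; the parameter count is 4k + 4.
2. **Weighted standardization.** Target moments are weighted blends, e.g.
   μ_x_st = (w_xx μ_x + w_yx μ_y) / (w_xx + w_yx) and likewise for σ and
   for Y with (w_yy, w_xy). Each entry is mapped
   x → ((x − μ_x)/σ_x)·σ_x_st + μ_x_st using sample (ddof = 1) standard
   deviations, σ floored at 1e-8 so constant genes are shifted to the
   blended mean only.
3. **Per-cluster affine displacement.** x → x·α_i + β_i per dataset, with
   cluster-specific (α, β).

Loss (minimized):
F = −CSC − IOU(X) − IOU(Y) + m·(max(t−IOU(X),0)² + max(t−IOU(Y),0)²),
recomputing the six lists on each candidate's displaced pair; the IOU
baselines are the condition lists of the *input* pair, computed once.
t = 0 makes the penalty identically zero. m defaults to 100: an IOU
shortfall of 0.05 then costs 0.25 per dataset, which dominates the CSC
gains we observe on synthetic pairs (order 0.1–3), so the floor binds in
practice without being a hard constraint.

### Optimization

CMA-ES (standard (μ/μ_w, λ) formulation with rank-one + rank-μ covariance
updates and cumulative step-size adaptation) searches the space of
*offsets* from the identity centers (α = 1, β = 0, w_xx = w_yy = 1,
w_yx = w_xy = 0), bounded in [−2, 2]. Initial step size
σ⁰ = 0.01·(2 − (−2)) = 0.04; population 4 + ⌊3 ln N⌋ (19 for N = 204);
50 generations by default. Candidates are clipped to the box before
evaluation and the clipped vectors are used in the distribution update —
the simplest of the standard bound-handling schemes, adequate here because
the optimum lies well inside the box. Decoded weights are additionally
clipped to ≥ 0, and if a blend denominator falls below 1e-3 the dataset's
own weight is raised to restore it (negative weight sums would invert
moments meaninglessly). The identity point is evaluated first, so the
best-ever solution is never worse than doing nothing; this also makes
"final CSC ≥ initial CSC" structurally guaranteed whenever t ≤ 1, because
at identity both IOUs equal 1 (their maximum) and the penalty vanishes,
so any accepted improvement in F must come from CSC. Loss values are
cached by parameter-vector hash within a run.

### Numerical choices

- ((x−μ)/σ)·σ + μ is not bitwise x in floating point, so when the blended
  moments equal a dataset's own moments exactly (true at the identity
  weights) standardization returns the input unchanged; the identity
  transform is therefore bit-for-bit.
- Welch test is vectorized over genes; rows where both groups are constant
  and equal get t = 0, p = 1. Zero variance with unequal means raises by
  default; inside the CSN loss the variance is floored at 1e-12 instead,
  since displaced synthetic data can create degenerate rows
  mid-optimization.
- BH q-values come from statsmodels' `multipletests`; a fixed-λ (0.5)
  Storey variant is available as an option.

## Baseline normalizer

The rank baseline defines a scale = sorted gene-wise mean sample of a
reference dataset; every sample of every other dataset is rewritten so its
r-th smallest entry takes scale[r]. Ties are resolved ordinally by gene
row order (deterministic; relevant because many entries equal log2(1) = 0).
The reference itself is not transformed, which is why its condition-list
IOU is exactly 1. This differs from quantile normalization only in how the
common value set is chosen (reference mean sample vs mean of sorted
samples).

## Synthetic data generator

Emulates the two-species, two-study, two-condition design on the log2
scale: gene baselines μ_g ~ N(6, 2); 10% of genes carry a condition effect
(magnitude U(1.5, 3), random sign, shared across species except a 5%
discordant minority whose sign flips in species 2); a disjoint 10% carry a
species effect of the same magnitude law; each study then applies a global
affine distortion (scale U(0.8, 1.2), shift U(−1, 1)), gene-wise offsets
N(0, 1), and i.i.d. noise N(0, 0.5). Five samples per group by default.
The per-study gene-wise offsets are what inflates cross and species lists
before normalization; the distortion is affine, so the affine-per-cluster
CSN model can undo it in principle.

What the generator does **not** emulate: count-level sampling noise
(values are Gaussian on the log2 scale, not negative-binomial counts),
gene–gene correlation, library composition effects, and nonlinear
platform distortions. Passing tests therefore demonstrate correct
mechanics and recoverability under affine batch structure, not performance
on real cross-platform data.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline at desk
scale: 1000 genes, 5 samples per group, k = 50, 25 CMA-ES generations for
the IOU-floor study (five seeds); 600 genes, k = 20, 15 generations for
the optimizer-sanity study; smaller sizes for unit tests. These sizes keep
a full run in tens of seconds while leaving the method's behavior
qualitatively unchanged (as with the cluster count, results are not
sensitive to moderate changes).

## Known limitations

- Exactly two datasets; extending to > 2 studies or species would require
  a joint loss and is out of scope.
- The displacement model is affine per cluster; nonlinear batch effects
  are only approximated.
- The loss is piecewise constant in regions where no DEG list changes, so
  the optimizer relies on population spread rather than gradients;
  small populations can stall on plateaus.
- DEG calling assumes two unpaired groups with ≥ 2 samples each; no
  covariates, pairing, or count-model inference.
- Storey's q-value uses a single fixed λ rather than the spline-fitted π0
  of the original procedure.
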