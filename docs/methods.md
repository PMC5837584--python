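# Methods

## Model

A rooted binary tree `T` with non-negative edge lengths (expected
substitutions per site) and a reversible Markov substitution model `θ`
induce a distribution `p` on characters `s ∈ Ω^n`: a state evolves from
the stationary distribution `π` at the root along each edge with
transition matrix `P = exp(Q·t·r)`, where `t` is the edge length and `r`
the relative rate of the character's rate class. Two model families are
shipped:

- **CFN** (two-state symmetric): `Q = [[−1,1],[1,−1]]`, `π = (½,½)`, no
  free parameters;
- **GTR(+Γ)(+I)**: `q_ij = s_ij π_j` from six exchangeabilities (order
  AC, AG, AT, CG, CT, GT) and frequencies (order A, C, G, T), with
  discrete-Gamma across-site rate variation and an optional
  invariant-sites class.

Conventions that make edge lengths comparable across models:
`−Σ_i π_i Q_ii = 1` (unit expected rate) and the rate mixture has mean
exactly 1, the invariant class included (Gamma-class rates are scaled by
`1/(1−p_inv)`).

All character probabilities come from Felsenstein's pruning algorithm,
vectorized across characters with per-node rescaling of the
partial-likelihood arrays and a final log-sum-exp over rate classes; a
hundred-taxon tree evaluates without underflow. Rate classes follow
across-site semantics: one class per character, applied to the whole
tree. Under these reversible stationary models the likelihood is
invariant to root placement (pulley principle) — this is tested, not
assumed — so arbitrary rootings of the same unrooted tree give identical
distributions.

## Distances and estimators

Exact mode enumerates `Ω^n` (default cap 65,536 outcomes: 16 binary or 8
DNA taxa) and evaluates the definitions directly; it serves as the
oracle for every estimator test. Monte Carlo mode simulates `m`
characters from each distribution and evaluates:

- Hellinger: `R_m = 1 − (1/2m) Σ [√(q/p)(s_p,i) + √(p/q)(s_q,i)]`,
  unbiased for `d_H²`; reported distance `√max(R_m, 0)`.
- KL: mean of `log(p/q)` over draws from `p` (the displayed one-sample
  form; no reverse-sample term is averaged in).
- JS: each KL-to-mixture term from its own sample, with the mixture
  probability `(p+q)/2` computed by log-sum-exp from both models. Each
  per-draw term is bounded by `log 2`, so the estimate respects the
  `√log 2` bound by construction.
- TV: `½[mean |1 − q/p| over s_p + mean |1 − p/q| over s_q]`; each half
  is unbiased for `Σ|p−q|` since `E_p|1 − q/p| = Σ_s|p(s) − q(s)|`.

Numerical conventions:

- every ratio is the exponential of a log-probability difference;
  probabilities are never divided;
- raw (possibly negative) estimates are preserved in the estimate record
  so unbiasedness stays testable; the reported metric clamps at 0;
- a simulated character with probability 0 under the opposite model
  (possible only with zero-length edges) raises an error naming the
  character rather than returning −∞;
- exact mode snaps |raw| < 1e-12 to 0, so identical inputs report an
  exactly zero distance despite enumeration round-off;
- standard errors are plug-in: sample variances of the per-draw terms,
  the two samples treated as independent;
- the two sample streams are spawned as independent child generators of
  the caller's seeded generator, so runs are reproducible and the
  (pair1, pair2) / (pair2, pair1) comparisons are meaningful.

**Control variates.** The likelihood ratios `q/p` (under the `p` sample)
and `p/q` (under the `q` sample) have known mean 1 and are used as
regression-adjusted control variates for the Hellinger terms. The
regression coefficient is cross-fitted on two half-samples — each half is
adjusted with the coefficient estimated from the other — because the
ratios are heavy-tailed enough that a same-sample coefficient visibly
biases the mean at small `m`; cross-fitting keeps the estimator exactly
unbiased. The variance reduction is real but varies strongly between
tree pairs (and can vanish at small `m`, where the coefficient estimate
is noisy); the package treats it as an opt-in flag (`use_cv`).

## Sample-size planning

The per-draw terms `R₁` have mean `μ₀ = d_H²` and variance `σ₀²`; a
pilot run of `m₀` draws (default 1000, configurable — the choice is not
prescribed by the method) estimates both by the sample mean and the
`m₀ − 1`-denominator sample variance. For an absolute tolerance `τ` on
the *distance* scale with failure probability `β`,

    m ≥ z²_{β/2} σ₀² / (τ² (2√μ₀ − τ)²),

rounded up, minimum 1. The factor `(2√μ₀ − τ)²` is the delta-method
conversion of the tolerance from the distance to the squared scale on
which `R_m` is asymptotically normal; a relative tolerance `α` is the
special case `τ = α√μ₀`. Requirements: `0 < τ < 2√μ₀` (otherwise the
tolerance is unachievable in this approximation) and `μ₀ > 0`. A pilot
estimate `μ₀ < 1e-12` means the pair is indistinguishable at pilot
precision; auto mode then reports distance 0 with `m = m₀` and a warning
instead of dividing by zero.

The same machinery extends beyond its Hellinger derivation: JS shares
the square-root structure and uses the identical bound on its squared
scale; KL and TV are reported on their own scale, so the plain normal
bound `m ≥ z²σ²/τ²` applies. This extension is a design choice of this
package.

Auto mode achieves approximately the nominal `1 − β` probability of
landing within the tolerance: at `α = 5%`, `β = 20%` the measured
coverage over replicate runs sits near the nominal 80% (76–85% across
seeds in the shipped checks), the spread being normal-approximation and
pilot-estimation slack.

## Missing taxa

For taxon sets `A ≠ B` with `A ∩ B ≠ ∅`:

- **common-taxa**: both trees are cropped to `A ∩ B`; cropping preserves
  all pairwise path lengths among kept taxa and sums the edge lengths of
  suppressed degree-2 nodes. With only one shared taxon the cropped
  distributions depend only on `π` (a warning is raised).
- **augmentation**: `p` is extended to `A ∪ B` by
  `p_{A∪B}(s) = p(s_A) / |Ω|^{|B∖A|}` — uniform, maximal-uncertainty
  marginals for the taxa missing from a tree. The augmented object
  implements the same simulate/log-probability protocol as a plain
  tree-model pair, so every estimator and the exact mode work unchanged.
  With `A = B` the wrapper is the identity and reproduces plain
  distances draw for draw.

Model parameters are carried over unchanged by both methods; nothing is
re-estimated after cropping. In the deletion experiments the same
*number* of taxa is deleted from each tree but the taxa are chosen
independently per tree (seed-controlled).

## Synthetic data generator

The generator emulates the synthetic study conditions: Yule (pure-birth)
topologies realized by successive uniform joins; iid Gamma edge lengths
with mean 0.1 and variance 0.005 (shape 2, scale 0.05) unless stated
otherwise; SPR perturbations that prune a uniform non-root subtree and
regraft it onto a uniform edge of the remainder (attachment point bisects
the target edge, the suppressed node's edges are summed); and the
4-taxon Felsenstein/Farris-zone pair with two long pendant edges placed
non-sister / sister (default short edge 0.1, configurable). Trees are
generated rooted and binary (2n−2 edges); readers accept polytomies.

What the generator does **not** emulate: real alignments and their
estimation noise, model misspecification, non-iid sites, indels/gaps,
and posterior or bootstrap tree samples from real data. Passing tests
therefore demonstrate correctness of the distances, estimators, and
planning arithmetic under the assumed models — not robustness of the
measures on empirical data.

## Experiment drivers and scale choices

The scripted experiments run at desk scale: edge scaling uses 16-taxon
pairs with `m = 2000` per grid point; the deletion experiment uses
20-taxon pairs, 50 replicate deletions and `m = 1000`; distance-matrix
demonstrations use 6–8 taxa where enumeration is exact. These sizes keep
every property measurable with comfortable Monte Carlo margins.

Distance matrices derive one seed per unordered pair from the master
seed and the sorted pair labels (SHA-256, reduced below 2³¹), and orient
each pair by label before estimation, so matrices are exactly symmetric,
independent of item order, and parallelizable without changing results.
MDS is classical (Torgerson) scaling: double-centering of the squared
distance matrix and a spectral embedding on the positive eigenvalues;
Euclidean inputs are reproduced exactly, and rank-deficient inputs
return fewer columns with a warning.

## Known limitations

- Discrete-Gamma categories default to `K = 4` with the bin **mean** as
  the category rate; likelihoods differ in the third decimal from
  median-based implementations.
- The KL estimator requires `q > 0` on every `p`-draw; trees containing
  zero-length edges can violate this and raise an error rather than
  return an infinite estimate.
- Monotone trend of the augmented-Hellinger deletion experiment holds in
  the low-deletion regime but turns over once roughly a third to half of
  the taxa are deleted (verified by exact enumeration at 10 taxa): with
  heavy deletion the shrinking tree-structured intersection and the
  shrinking union outweigh the uniform-augmentation mismatch, so the
  mean distance decreases again. On 20-taxon trees the turnover sits
  between 6 and 10 deletions.
- Amino-acid and codon alphabets are not shipped (the architecture does
  not hard-code the alphabet size, but only binary and DNA models are
  constructed); non-reversible models are rejected at construction.
- Geometric/topological baselines (BHV, Robinson–Foulds, SPR distance,
  Kendall–Colijn) are out of scope.
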