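# Methods

## Model

Each read is reduced to a k-mer frequency profile **x** ∈ ℝ₊^{4ᵏ}:
overlapping windows of length k on the given strand, ambiguous windows
skipped, counts normalized to sum one. Under a mixture model in which a
read originates from taxon C_m with probability p(C_m), the expected
profile decomposes as E[**x**] = Σ_m p(C_m) E[**x** | C_m], so the sample
mean μ carries information about the composition and can be deconvolved
against a matrix A of reference profiles.

ARK refines this by partitioning feature space into Q Voronoi regions.
Conditioning on a region preserves the same structure,
E[**x** | **x** ∈ R_q] = Σ_m p(C_m | **x** ∈ R_q) E[**x** | C_m, **x** ∈ R_q],
so any mean-profile estimator can be applied per region and the results
fused by the law of total probability,
p(C_m) = Σ_q P_q · p(C_m | **x** ∈ R_q), with P_q the fraction of reads in
region q. Fusion is exact algebra, not a heuristic: if clustering
captures real heterogeneity the conditional means are more informative
than μ; if it does not, per-cluster estimates coincide and the fused
result equals the Q = 1 estimate.

Assumptions worth keeping in mind: reads and references are co-oriented
(no reverse-complement canonicalization); per-read frequency normalization
makes reads of unequal length contribute equally (a `use_counts` switch
averages raw counts instead); estimation quality is bounded by how well
reference profiles span the reads' profiles.

## Clustering

The deterministic strategy is LBG codebook growth: start from the global
mean; to go from Q to Q+1, split one centroid into a perturbed pair and
refine all centroids with Lloyd iterations (nearest-neighbor assignment
under squared Euclidean distance, then mean update) until the relative
distortion decrease falls below 1e-6 or 100 iterations. The cluster to
split is the one contributing the largest within-cluster sum of squares
(policy `distortion`, the default; `probability` splits the most populated
one instead).

The split perturbs the centroid along the cluster's leading principal
direction, c ± ε·s·v with ε = 1e-3, v the principal unit vector (deterministic
power iteration) and s the mean absolute spread along it. The direction
matters: the first Lloyd assignment after a split cuts the cluster with a
hyperplane through the centroid perpendicular to the perturbation, so
splitting along the direction of maximal variance cuts the cluster where
it is widest. A coordinate-scaling perturbation (direction ≈ the centroid
itself) was evaluated and rejected: on small instances checkable by
exhaustive enumeration it routinely landed in local optima, because its
cut plane is nearly independent of the cluster's shape. Zero-variance
clusters fall back to coordinate scaling. Empty clusters arising during
Lloyd iterations are re-seeded with the point farthest from its centroid
(never stealing from a singleton).

The random strategy samples Q distinct reads' profiles as representation
vectors, assigns every read once, and recomputes centroids as subset
means; representation vectors attracting no reads are dropped with a
warning and Q shrinks. It trades optimality for a single pass over the
data, which is the sensible default at very large read counts.

The adaptive loop grows Q one at a time (each level refined from the
previous codebook) and stops when Σ_m |p(C_m)|_Q − p(C_m)|_{Q−1}| < η or
Q = Q_max, returning the estimate at the stopping Q — the later, more
refined of the two levels the rule compares.

## Estimators

`estimate_nnls` solves min_{x≥0} ‖[A; λ·1ᵀ]x − [μ; λ]‖₂ via
`scipy.optimize.nnls`. The λ-weighted row enforces Σx = 1 softly; at the
default λ = 10⁴ the constraint is effectively hard while keeping the
problem an ordinary NNLS. `estimate_nn_omp` grows an active set greedily
by the largest positive norm-scaled correlation with the residual,
refits the active set by NNLS each step, and stops at `max_support`
columns (default min(M, 100)), residual norm < 1e-6, or when no column
correlates positively. Both normalize the raw column weights to the
simplex and then sum weights per taxon, which matters in split-reference
mode where a taxon owns several columns. A cluster on which an estimator
degenerates to the zero solution contributes the uniform composition with
its P_q (logged); this keeps fusion mass-conserving.

## Reference construction

`whole` mode profiles each reference sequence into one column. `split`
mode reproduces the SEK-style design: sequences longer than 700 bp are cut
into 400 bp windows overlapping by 100 bp (trailing remainders are kept
when at least as long as the overlap); shorter sequences are excluded.
Split references are the setting in which clustering pays off — reads are
local windows of their source gene, so cluster means align with window
columns while the global mean blurs them. Genus-level evaluation
truncates lineages to the genus rank and re-sums.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| k | 6 | k-mer order; 4ᵏ = 4096 features |
| Q (random strategy) | 75 | fixed cluster count |
| η | 0.01 | adaptive stopping threshold, scaled VD in (0, 1] |
| Q_max | 64 | adaptive cap (powers of two conventional, 16–256) |
| λ | 10⁴ | NNLS sum-to-one row weight |
| max_support | min(M, 100) | OMP sparsity cap |
| split window / overlap / min length | 400 / 100 / 700 bp | reference splitting |
| Lloyd tol / max iterations | 1e-6 / 100 | convergence of each refinement |
| split perturbation ε | 1e-3 | relative offset along the principal direction |

## Simulator

`simulate` emulates an amplicon experiment with known truth: M random
reference sequences (default 1500 bp, i.i.d. uniform bases; optionally
grouped into families sharing 80% of a common backbone to mimic the
strong conservation of real 16S genes — family members then show ≈ 73%
pairwise identity, and families define a genus rank); abundances from a
power law (p_m ∝ m^(−α), α = 1), uniform, or linear law; reads of fixed
length (250 bp) or Normal(450, σ² = 50) truncated to the reference (the
variance-vs-sd ambiguity of "450 ± 50 variance" is resolved as σ² = 50,
with σ = 50 available); per-base substitution errors to a uniformly chosen
different base; and two-parent single-breakpoint chimeras at a configurable
rate (5% or 35% are the conventional settings). The recorded truth is the
realized pre-chimera draw frequency, which is what depth-limited reads can
at best reveal.

What the simulator does **not** model: 454-style homopolymer (flowgram)
noise, PCR copy-number and length bias, primer-targeted variable-region
extraction, quality scores, and real phylogenetic covariance structure.
Passing tests therefore demonstrate the estimator's statistical machinery
— featurization, clustering, deconvolution, fusion, stopping — under
controlled heterogeneity, not performance on any particular real
sequencing platform.

## Numerical choices

Distances in the nearest-neighbor rule drop the per-point ‖x‖² term
(constant across centroids); ties go to the lowest centroid index.
Distortion of converged codebooks uses the exact-means identity
WCSS = Σ‖x‖² − Σ_q n_q‖c_q‖², clipped at zero against roundoff.
Centroid updates use an indicator matmul so the whole Lloyd pass is BLAS.
Featurization batches all reads into one coded array separated by invalid
sentinels, so counting is a single vectorized pass; reads with no valid
k-mer window are dropped with a warning. PCoA double-centers −½D²,
eigendecomposes symmetrically, drops negative eigenvalues with a warning,
and reports explained fractions over the positive spectrum. JSD uses log
base 2 so its maximum is exactly 1. All randomness flows from explicit
integer seeds recorded in outputs; LBG is deterministic and the seed is
provenance only.

## Problem sizes in the shipped experiments

The test suite and `scripts/acceptance.py` run at desk scale, chosen as
the package's own operating points: clean-recovery runs use 20 taxa at
depth 10,000; heterogeneity studies use 50 taxa in families of 5 at depth
2,000 with 5% chimeras and 1% substitution errors against split
references, 20 seeds in the suite and 6 in the acceptance script; the
fixed-Q operating point is Q = 75 and the clustering-gain comparisons use
Q = 16 versus Q = 1. Larger depths change runtimes, not conclusions: the
estimators see only per-cluster means.

## Known limitations

Accuracy at Q > 1 is not guaranteed to improve monotonically — k-means
minimizes distortion, not estimation error; the improvement claim is
statistical (median over seeds), and the shipped tests assert it that
way. Very small clusters yield noisy conditional means (a
`min_cluster_size` knob exists, default 1 = no filtering). The random
strategy can return fewer than Q clusters on degenerate data. The NN-OMP
pursuit is a faithful-in-spirit greedy method, not a re-implementation of
any specific published solver's internals.
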