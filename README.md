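# ark16s — Aggregation of Reads by K-means

Estimate the taxonomic composition of a bacterial community from 16S rRNA
amplicon reads, fast and without per-read classification.

## The problem and the method

Given millions of 16S reads from one sample, we want the relative
abundances p(C₁), …, p(C_M) of M taxa represented in a reference database.
Composition estimators in the Quikr/SEK family avoid per-read alignment by
summarizing a whole read set as a single **mean k-mer profile**: each read
becomes a frequency vector **x** ∈ ℝ₊^{4ᵏ} over all 4ᵏ k-mers (k = 6 by
default), and the sample mean **μ** ≈ E[**x**] is deconvolved against the
reference profiles A by a sparse nonnegative fit, μ ≈ A·p.

A single mean discards a lot of information: reference k-mer profiles are
far from linearly independent (16S is highly conserved, and split
references give each taxon several columns), so different mixtures can
produce nearly the same μ. ARK restores information by **vector
quantization**: partition the reads' feature vectors into Q Voronoi
regions R₁, …, R_Q with k-means, compute each region's occupancy
probability and conditional mean

    P_q = (#reads in R_q) / N,      μ_q = mean of profiles in R_q,

run the base estimator on every μ_q, and fuse the per-cluster compositions
as a mixture:

    p(C_m) = Σ_q  P_q · p(C_m | x ∈ R_q).

With Q = 1 this is exactly the unmodified base method. Two clustering
strategies are provided: a **deterministic** one (Linde-Buzo-Gray codebook
growth, Q increased by one until the fused estimate moves by less than a
threshold η in scaled variational distance, capped at Q_max) and a cheap
**random** one (Q fixed, e.g. 75; representation vectors sampled from the
data, one nearest-neighbor pass).

Two base estimators ship behind one pluggable contract:

- `estimate_nnls` — nonnegative least squares with a λ-weighted
  sum-to-one row (Quikr-style),
- `estimate_nn_omp` — nonnegative orthogonal matching pursuit with an
  active-set NNLS refit (SEK-style).

Accuracy is scored by **variational distance** VD = ½‖p − p̂‖₁ ∈ [0, 1];
sample-to-sample comparisons use Jensen-Shannon divergence and PCoA.
A built-in simulator (power-law/uniform/linear abundances, fixed or
normally distributed read lengths, substitution errors, two-parent
chimeras) provides ground truth for every experiment, so the whole method
is testable offline.

## Worked example

`examples/01_simulate_and_estimate.py` simulates 5,000 clean 250 bp reads
from 15 taxa with power-law abundances and runs the full pipeline:

```
reads: 5000, taxa: 15, Q used: 16
VD(truth, estimate) = 0.0223
top taxa (estimated vs true):
  taxon_0005: 0.3000 vs 0.3064
  taxon_0013: 0.1480 vs 0.1506
  taxon_0010: 0.1001 vs 0.0972
  taxon_0004: 0.0756 vs 0.0788
  taxon_0011: 0.0597 vs 0.0582
```

A VD of 0.022 means the estimated and true compositions disagree on about
2% of total probability mass. `examples/03_clustering_gain.py` shows the
point of the method — on a harder sample (correlated taxa, 5% chimeras,
1% substitution errors, split references) clustering reduces the error of
both base estimators:

```
nnls_regularized: VD at Q=1 0.0756 -> VD at Q=16 0.0619
nn_omp: VD at Q=1 0.1724 -> VD at Q=16 0.0760
```

The other examples demonstrate the adaptive-Q loop and JSD+PCoA
ordination of many samples.

## Command line

The same pipeline is available as a thin CLI:

```sh
ark16s simulate --taxa 50 --depth 10000 --law power_law --chimera 0.05 \
    --seed 1 --out sim/
ark16s build-ref --fasta sim/reference.fasta --taxonomy sim/taxonomy.tsv \
    --mode split --out ref.npz
ark16s estimate --reads sim/reads.fasta --ref ref.npz --estimator nnls \
    --strategy random --Q 75 --seed 1 --out profile.tsv
ark16s evaluate --truth sim/truth.tsv --estimate profile.tsv
ark16s ordinate profile1.tsv profile2.tsv ... --out coords.tsv
```

Every estimate writes a JSON sidecar (seed, strategy, Q used, cluster
probabilities, convergence trace) sufficient to reproduce the run.

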