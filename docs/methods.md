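# Methods

## Model

The generative model couples three layers.

**Cluster layer.** Cells arrive pre-grouped into Q clusters (in the
motivating application, sets of B cells with identical BCR heavy chains).
The corrected membership of cell *j* is a categorical variable
T<sub>j</sub> with prior p<sub>j,q</sub> ∝ exp(−c·G<sub>j,q</sub>), the
row-wise softmax of the negative cell-to-cluster distance matrix G scaled
by a strength constant c ≥ 0. G counts differing BCR mutations (symmetric
difference of mutation sets, or Hamming distance on aligned heavy-chain
sequences; both are supported, as the number-of-differing-mutations notion
admits either reading). Cells without a sequenced BCR form their own
singleton cluster; their distance to it is 0 and to every other cluster
the mean of all known cell-to-cluster distances. G is fixed during
inference; cluster representatives are not recomputed when cells move.

**Genotype layer.** The input clone genotypes Ω (N mutations × K clones,
binary, from an upstream phylogeny tool such as Canopy) are treated as a
noisy observation of the true genotypes C at error rate ξ:
P(C<sub>i,k</sub>=1 | Ω, ξ) = |Ω<sub>i,k</sub> − ξ|, with
ξ ~ Beta(κ₀, κ₁). Each cluster's clone I<sub>q</sub> has a uniform prior
over the K clones (clone prevalences from the phylogeny are deliberately
not used).

**Count layer.** At covered positions the alternative-allele UMI count is
binomial: A<sub>i,j</sub> ~ Binom(D<sub>i,j</sub>, θ<sub>i</sub>) if the
clone assigned to cell j's cluster carries mutation i, else
Binom(D<sub>i,j</sub>, θ₀). Entries with D = 0 contribute a likelihood
factor of exactly 1 and are never materialized. θ₀ ~ Beta(α₀, β₀) and
θ<sub>i</sub> ~ Beta(α₁, β₁) i.i.d.

## Inference

A systematic-scan Gibbs sampler updates, per sweep and in this order: all
I<sub>q</sub>, then (θ₀, θ) by beta-binomial conjugacy, then all
T<sub>j</sub>, then all C<sub>i,k</sub>, then ξ by beta-Bernoulli
conjugacy. Cells enter the conditional of I<sub>q</sub> through their
*corrected* membership T (the graphical model routes the counts through
T); an empty cluster's conditional falls back to the uniform prior. All
categorical conditionals are evaluated in log space with max-subtraction;
log-odds for C are clipped at ±700 before the logistic transform so that
extreme likelihood ratios saturate at 0/1 without overflow; degenerate
priors (ξ exactly 0 or 1) short-circuit to their exact point mass.

Multiple chains differ only in the random initialization of I (uniform per
cluster); T starts at the input clustering, C at Ω, and continuous
parameters at their prior means. Each chain is a pure function of
(master seed, chain index). After discarding a burn-in fraction (default
50%), the chain with the highest mean post-burn-in log joint is reported —
pooling is avoided because unmixed chains would blur the posterior — and
the maximum cross-chain disagreement in the cluster-to-clone posterior
(after genotype-based label alignment) is emitted as a convergence
diagnostic. Defaults follow a full-scale run: 20,000 iterations and 10
chains; the large T and C matrices may be recorded thinned. MAP ties break
toward the lowest clone index.

Cell-level posteriors marginalize over the corrected clustering:
P(cell j → clone k) is the fraction of retained iterations in which
I<sub>T_j</sub> = k. Corrected prevalences are the MAP-assignment
histogram over cells.

Two corrected-genotype sets are put on a common labeling by the
permutation minimizing total column-wise L1 distance — exhaustive search
for K ≤ 8 (lexicographically smallest optimum on ties), Hungarian
assignment above.

## Hyperparameter defaults

| parameter | default | prior mean | rationale |
|---|---|---|---|
| c | 2 | — | cluster-prior strength used in the motivating analysis |
| κ (ξ) | (1, 9) | 0.10 | weak prior, genotype errors expected rare |
| v₀ (θ₀) | (0.3, 29.7) | 0.01 | sequencing-error scale in non-carrying cells |
| v₁ (θᵢ) | (2.25, 2.65) | 0.46 | allelic imbalance and dropout in carrying cells; matches the predecessor per-cell model's published defaults |

All are exposed on the estimator and the CLI.

## Input filtering

Mutations are restricted to those present in both Ω and the count
matrices with at least one variant read in at least one cell; cells must
carry at least one variant read at a retained mutation. "Contains a
mutation" is read as variant evidence (≥1 alternative read), not mere
coverage; a `require_alt_read=False` switch gives the coverage reading.
Clusters emptied by the cell filter are dropped and indices re-densified;
a filter report records all before/after counts.

## Synthetic data

The generator emulates the model's assumed structure end to end and is the
basis of all simulation checks:

- **Genotypes:** clones on a random tree rooted at an all-zero base clone;
  each non-base clone owns ≥1 private mutation and inherits its ancestors'
  (N ≥ K−1 required); Ω flips each entry of the truth independently with
  probability ξ_true (default 0.05).
- **Clusters:** the default conditions place half the cells (multiplet
  fraction 0.5) into `n_multiplet_clusters` clusters (default 50) with
  sizes 1 + Zipf(2), producing the skewed, singleton-dominated size
  distributions seen in BCR clonotype data; every remaining cell is its
  own singleton cluster. A stated multiplet-cell budget cannot coexist
  with an arbitrary fixed total cluster count (each singleton cell is a
  cluster), so the total Q follows from M and the multiplet fraction.
  Explicit size lists are accepted.
- **Counts:** D = 0 with probability 1 − coverage (default coverage 0.15),
  else 1 + Poisson(depth_mean − 1) (default mean 2) — chosen over a
  negative binomial for simplicity; A binomial with θ₀ = 0.01 or
  θᵢ ~ Beta(2.25, 2.65) per the carrying status of the cell's true clone.
- **Misclustering:** a fraction of cells (default 0.05) is moved to a
  random wrong cluster; moves that would empty a cluster are skipped, so
  singleton-cluster cells are never misclustered. Distances keep
  misclustered cells close (distance 1) to their true cluster so the
  correction is identifiable.

What the generator does **not** emulate: overdispersed (beta-binomial)
counts, position- or cell-specific coverage structure, doublets, BCR
sequence evolution within lineages, or expression phenotypes. Passing
recovery checks on these simulations therefore demonstrates correctness
of the inference under the model's own assumptions, not robustness to the
full noise structure of real scRNA-seq.

## Verification design

- **Conjugate updates** are checked exactly against the closed-form beta
  posteriors on hand-computed sufficient statistics.
- **Exact enumeration:** on a 3-mutation / 4-cell / 3-cluster / 2-clone
  instance with θ and ξ clamped, Gibbs frequencies (50,000 sweeps, half
  burn-in) match marginals obtained by summing the joint over all 2^(NK)
  genotype matrices and K^Q cluster assignments (the sum over T
  factorizes per cell) within total variation 0.02 per variable. A second,
  independently coded triple-loop enumerator validates the first on an
  even smaller instance to 1e−10.
- **Reduction to per-cell assignment:** with singleton clusters whose
  distinct BCRs place every other cluster far away, the cluster layer is
  uninformative and the model collapses to the per-cell (cardelino-style)
  model; posteriors match an independently coded per-cell sampler within
  0.05 per entry (40,000 sweeps, 6,000 burn-in on both sides — sizes set
  by the Monte Carlo error of slow-mixing bimodal cells). With a *flat*
  switch prior instead, cells can co-occupy clusters and couple, and the
  collapse is only approximate — measured discrepancies up to ~0.1 on
  ambiguous cells — which is why the check uses the distant-singleton
  construction.
- **Recovery** at the default conditions (K=4, N=80, M=400, coverage
  0.15): MAP accuracy ≥ 0.90 on multiplet-cluster cells and posterior
  mean ξ within 0.03 of truth, with 600 sweeps × 2 chains (accuracy and
  ξ stabilize well before this budget).
- **Confidence effect:** across 10 paired replicates (M=200, a size at
  which the effect is already unambiguous), mean normalized entropy and
  Gini of cell posteriors are lower under the true multiplet clustering
  than under all-singleton clusters — the information added by the
  clustering prior.
- **Geweke check:** a successive-conditional chain (regenerate counts,
  then one Gibbs sweep) reproduces the prior means of ξ and θ₀ from
  forward simulation within 3 standard errors (batch-means SE for the
  chain), exercising every conditional jointly.
- **Determinism:** identical seeds and configuration produce
  byte-identical outputs, both at the estimator level and through the CLI.

## Evaluation metrics

Assignment confidence: normalized entropy (−Σp log p / log K) and a Gini
impurity rescaled by K/(K−1) so that both score 0 at a point mass and 1 at
uniform regardless of K — the rescaling makes values comparable across
clone counts and accommodates near-uniform 4-clone distributions scoring
close to 1 (raw impurity is available via a flag). Partition agreement:
Hubert–Arabie adjusted Rand index. Embedding-based validity of a grouping:
Dunn index, pooled within-group RMSSTD, Calinski–Harabasz, and k-NN
connectivity (default k=10); singleton groups contribute zero diameter
(with a warning). Pielou evenness quantifies cluster-size skew. Expression
preprocessing (normalization, PCA/UMAP, graph clustering) is the caller's
responsibility — the metrics consume any embedding plus labels.

## Limitations

- The clone tree itself is taken as input and never re-inferred; errors in
  the tree topology can only be absorbed into genotype corrections.
- Chain selection by best mean log joint reports a single mode; with
  genuinely multimodal posteriors the cross-chain disagreement diagnostic
  should be inspected and more chains run.
- The binomial count model ignores overdispersion; strongly overdispersed
  data will yield overconfident posteriors.
- The distance matrix is static; a clustering correction that should also
  update distances (e.g., after large cluster rearrangements) is out of
  scope.
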