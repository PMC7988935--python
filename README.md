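# cactus-assign

Assignment of single tumor cells to evolutionary clones from allele-specific
scRNA-seq transcript counts, with joint Bayesian correction of the input
clone genotypes and of the input cell clustering.

## The problem

Bulk DNA sequencing of a tumor, combined with a phylogenetic
reconstruction, yields a set of *K* clones, each described by a binary
genotype over *N* somatic mutations (matrix **Ω**, mutations × clones).
Single-cell RNA-seq of the same tumor measures, at each mutated position
*i* and cell *j*, the number of UMIs carrying the alternative allele
(*A*<sub>*i,j*</sub>) out of the total covering UMIs (*D*<sub>*i,j*</sub>).
These counts are extremely sparse — most positions are not expressed in
most cells — so assigning each cell to a clone on its own reads is noisy.

When the cells carry an additional, independent grouping signal — in B-cell
lymphoma, cells with identical B-cell-receptor (BCR) heavy chains belong to
the same clonal lineage — clusters of cells can be assigned jointly,
pooling their reads. This package implements that joint model: cell
clusters are mapped to clones, while the clone genotypes (which contain
errors at unknown rate ξ) and the clustering itself (imperfect) are
corrected during inference.

## The model

Hidden variables, sampled by a systematic-scan Gibbs sampler:

- *I*<sub>*q*</sub> ∈ {1..K} — clone of cluster *q*, uniform prior;
- *T*<sub>*j*</sub> ∈ {1..Q} — corrected cluster of cell *j*, categorical
  prior *p*<sub>*j,q*</sub> = e<sup>−c·G(j,q)</sup> / Σ<sub>q′</sub>
  e<sup>−c·G(j,q′)</sup>, where *G*(*j,q*) is the number of BCR mutations
  separating cell *j* from the representative sequence of cluster *q* and
  *c* ≥ 0 (default 2) sets the prior strength;
- *C*<sub>*i,k*</sub> — corrected genotype, with
  P(*C*=1 | Ω, ξ) = |Ω − ξ| and ξ ~ Beta(κ₀, κ₁);
- θ₀, θ<sub>*i*</sub> — binomial success probabilities of observing the
  alternative allele in a non-carrying / carrying cell, with beta priors.

Read counts follow *A* ~ Binom(*D*, θ<sub>*i*</sub>) when the assigned
clone carries mutation *i* and Binom(*D*, θ₀) otherwise; beta-binomial and
beta-Bernoulli conjugacy give closed-form updates for θ and ξ. With
singleton clusters and an uninformative cluster prior the model collapses
to per-cell assignment (the cardelino model).

## Worked example

```python
import numpy as np
from cactus import SimConfig, simulate_dataset, CactusGibbs, confidence_report

cfg = SimConfig(K=4, N=60, M=300, n_multiplet_clusters=40, seed=0)
data, truth = simulate_dataset(cfg)

est = CactusGibbs(n_iters=1000, n_chains=4, thin=2, random_state=1).fit(data)

accuracy = (est.map_clone_of_cell_ == truth.clone_of_cell).mean()
print(f"MAP cell-to-clone accuracy: {accuracy:.3f}")
print(f"posterior mean xi: {est.xi_samples_.mean():.4f}  (simulated: {cfg.xi_true})")
print("corrected prevalences:", np.round(est.corrected_prevalence_, 3))
rep = confidence_report(est.cell_clone_prob_)
print(f"mean normalized entropy: {rep.mean_normalized_entropy:.3f}")
```

prints

```
MAP cell-to-clone accuracy: 0.917
posterior mean xi: 0.0399  (simulated: 0.05)
corrected prevalences: [0.227 0.287 0.317 0.17 ]
mean normalized entropy: 0.135
```

91.7% of the 300 simulated cells are MAP-assigned to their true clone, the
genotype error rate (simulated at 5%) is recovered at 4%, the corrected
prevalences are the fractions of cells assigned to each of the four clones,
and the low mean normalized entropy (0 = every cell assigned with
certainty, 1 = uniform over clones) indicates confident assignments.

The fitted estimator exposes `cluster_clone_prob_` (Q × K),
`cell_clone_prob_` (M × K), `cell_cluster_prob_` (M × Q),
`genotype_prob_` (N × K posterior of the corrected genotypes), posterior
traces of ξ and θ₀, and MAP summaries; `predict()` / `predict_proba()`
follow the scikit-learn convention.

## Command line

```bash
cactus simulate --config sim.yaml --seed 4 --out simdir/
cactus run --genotypes genotypes.tsv --alt alt.mtx --total total.mtx \
    --mutations mutations.txt --barcodes barcodes.txt \
    --clusters clusters.tsv --distances distances.tsv \
    --iters 20000 --chains 10 --seed 1 --out outdir/
cactus evaluate --assignments outdir/cell_clone_prob.tsv --out report.json
```

`run` accepts MatrixMarket or dense-TSV count matrices, filters to
mutations with variant evidence and cells carrying at least one common
mutation, and writes posterior tables, MAP assignments, traces, and a run
summary with convergence diagnostics.

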