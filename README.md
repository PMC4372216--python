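# ican-net

Integrated multi-omics co-alteration network analysis for cancer gene
prioritization.

Tumor genomes alter genes on several molecular levels at once — copy-number
gain or loss, promoter methylation change, and expression change — and genes
that are *co-altered* across these levels tend to act together in disease.
`ican-net` turns matched gene-level copy-number, methylation and expression
matrices plus curated interaction data (pathway SIF files, PPI edge lists)
into a weighted **integrated co-alteration network** (ICan), then uses that
network to rank candidate disease genes, score functional modules, and screen
discretized alteration features for survival impact. It is aimed at
computational biologists working with GISTIC-style copy-number calls,
Illumina methylation beta values and matched expression data (e.g. TCGA-style
cohorts).

## The method

**Edge weighting by canonical correlation.** Each gene *g* carries a 3 × *n*
profile over samples: expression, copy number, methylation. For two
interacting genes with profiles G₁, G₂ the canonical correlations ρ₁ ≥ ρ₂ ≥ ρ₃
are the square roots of the eigenvalues λₖ of the Rayleigh quotient matrix

    R = Σ₁₁^(−1/2) Σ₁₂ Σ₂₂^(−1) Σ₂₁ Σ₁₁^(−1/2)

built from the sample covariance blocks of the stacked 6-variate profile.
A sequential Bartlett chi-squared screen tests H₀: λₖ = … = λ₃ = 0 via

    Tₖ = −[n − (p + q + 3)/2] Σᵢ₌ₖ..₃ log(1 − λᵢ),   Tₖ ~ χ²((p−k+1)(q−k+1)),

and the edge weight is the significance-weighted mean eigenvalue

    ω = Σₖ λₖ I(pₖ) / Σₖ I(pₖ),   I(p) = −log p if p ≤ 0.05 else 0,

with ω = 0 when no component is significant. ω ∈ [0, 1] measures how strongly
the pair co-alters across all three levels; single-layer baseline networks
(GCE/GCC/GCM) use the absolute Pearson correlation of one layer instead.

**Prioritization by random walk with restart.** With W the column-stochastic
weighted adjacency and P₀ uniform over known disease (seed) genes, iterate
P_{t+1} = (1−r) W P_t + r P₀ (r = 0.7, L1 tolerance 1e-10) to a steady state
that ranks every gene by proximity to the seeds. Permutations of random seed
sets give empirical p-values (Benjamini–Hochberg adjusted), and 5-fold
cross-validation measures recovery of held-out known genes by AUC.

**Downstream screens.** Modules are scored by M = Σω / E, the mean weight of
their induced edges; discretized alteration features (amplified, homozygously
deleted, over-/under-expressed at mean ± SD, hypo-/hyper-methylated at beta
0.2/0.8) are screened per candidate gene by Kaplan–Meier curves and the
log-rank test at the joint cutoff p < 0.05, FDR < 0.25.

## Worked example

A synthetic cohort with a planted disease module whose edges are co-altered
across the three layers (target canonical correlation 0.7):

```python
import numpy as np
from ican import (generate_network, generate_multiomics, build_ican,
                  candidate_significance, cv_auc)

hbn, truth = generate_network(n_genes=300, module_size=20,
                              seeds_fraction=0.5, rng=7)
module_edges = [(a, b) for a, b in hbn.graph.edges
                if a in truth.module_members and b in truth.module_members]
seen, pairs = set(), []
for a, b in module_edges:
    if a not in seen and b not in seen:
        pairs.append(((a, b), 0.7)); seen |= {a, b}
profiles, _ = generate_multiomics(n_samples=200, planted_pairs=pairs,
                                  genes=sorted(hbn.graph.nodes), rng=8)

ican = build_ican(hbn, profiles)
print(f"ICan: {ican.n_nodes} nodes, {ican.n_edges} edges")
```

prints

```
ICan: 300 nodes, 710 edges
mean omega, planted co-altered edges: 0.520
mean omega, background edges:        0.005
```

so co-altered pairs get two orders of magnitude more weight than background
edges (a planted canonical correlation of 0.7 puts the leading eigenvalue
λ₁ ≈ 0.49, which dominates ω). Prioritization from half the module as seeds:

```python
table = candidate_significance(ican, truth.seed_genes, n_perm=1000, rng=17)
auc = cv_auc(ican, truth.module_members, folds=5, rng=17)
print(f"5-fold CV: mean AUC {auc['mean_auc']:.3f}, max AUC {auc['max_auc']:.3f}")
```

```
5-fold CV: mean AUC 1.000, max AUC 1.000
```

Held-out module members are recovered perfectly on this fixture because the
module is densely wired to the seeds while the scale-free background is not.

The same steps are available as a shell pipeline:

```sh
ican simulate --preset network --rng 3 -o sim/
ican build-hbn --sif pathways.sif --tsv ppi.tsv -o hbn.tsv
ican weight --profiles profiles/ --network hbn.tsv --method cca -o ican.tsv
ican prioritize --network ican.tsv --seeds seeds.txt --perms 1000 --rng 17 -o ranks.tsv
ican run --config run.cfg          # full seven-stage pipeline with manifest
```

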