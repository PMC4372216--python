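# Methods

## Model and procedure

The framework treats a gene as a 3-variate random vector over tumor samples
— expression, continuous copy number, promoter-methylation beta value — and
asks, for every pair of genes known to interact, how strongly the two
vectors are linearly related *jointly across the three levels*. Canonical
correlation analysis (CCA) answers this: with sample covariance blocks
Σ₁₁, Σ₁₂, Σ₂₂ (1/(n−1) normalization) the eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of
R = Σ₁₁^{−1/2} Σ₁₂ Σ₂₂^{−1} Σ₂₁ Σ₁₁^{−1/2} are the squared canonical
correlations. CCA is invariant to invertible linear maps of either block, so
the units of the three layers (log2 expression, copy-number ratio, beta
value) do not matter; this invariance is tested.

Significance of each component uses the classical sequential Bartlett
approximation: the k-th test addresses H₀: λₖ = … = λ₃ = 0 with statistic
Tₖ = −[n − (p+q+3)/2] Σ_{i=k..p} log(1 − λ̂ᵢ) referred to χ² on
(p−k+1)(q−k+1) degrees of freedom (p = q = 3). Two presentation variants of
the multiplier, n − (p+q+3)/2 and n − 1 − (p+q+1)/2, are algebraically
identical and both accepted via `bartlett_form`. The test indexing is chosen
so that the first test covers all components (df 9) and the last covers only
λ₃ (df 1); the chi-squared tail area is one-sided upper. Calibration is part
of the acceptance surface: under independent Gaussian blocks at n = 200 the
first test rejects at ~5%.

The edge weight ω averages λₖ over significant components with weights
−log pₖ (components with pₖ > 0.05 contribute nothing; ω = 0 when none is
significant, so a non-significant pair carries no co-alteration evidence).
By default ω averages the eigenvalues λₖ; `weight_basis="rho"` averages the
canonical correlations instead, exposing an ambiguity in how such weights
are often written.

Single-layer baseline networks (GCE, GCC, GCM) weight the identical
node/edge skeleton with the absolute Pearson correlation of one layer, so
the four networks differ only in edge weight and comparisons are like for
like. The signed correlation is retained in the output for inspection.

## Random-walk prioritization

The walk P_{t+1} = (1−r) W P_t + r P₀ uses the column-stochastic
normalization of the weighted adjacency: only a stochastic W preserves
probability mass under this recursion, and the power iteration then equals
the direct solve r(I − (1−r)W)^{−1}P₀ (an oracle-equivalence test). Columns
with zero weighted degree are replaced by a uniform column. P₀ is uniform
over the seed genes present in the network; r defaults to 0.7 and the
iteration stops when the L1 change drops below 1e-10. Nodes in components
without a seed receive probability → 0 and rank below all reachable nodes,
ties broken by gene symbol.

Permutation significance redraws uniform random seed sets of the observed
cardinality. The empirical p-value of a non-seed gene is
(1 + exceedances)/(1 + usable permutations), counting only permutations in
which that gene was **not** itself drawn as a seed. The conditioning matters:
a restarting walker concentrates roughly r/|seeds| of its mass on each seed,
which no non-seed probability can exceed, so unconditional permutations
would floor every p-value near |seeds|/|nodes| and the screen could never
reject. Conditioned on non-seed status the observed and permuted
probabilities are exchangeable under the null, so the p-values are uniform —
a property the acceptance suite checks by Kolmogorov–Smirnov distance.
Benjamini–Hochberg adjustment runs across non-seed genes; candidates are
those with adjusted p < 0.05. Degree-matched seed resampling is deliberately
not the default (uniform sampling mirrors the simple "random genes" null)
and can be layered on by passing a custom permutation set.

Cross-validated evaluation partitions the known genes into 5 seeded folds;
each fold's training 80% seeds the walk and the AUC ranks the held-out 20%
against all non-known, non-seed nodes. Both the mean and the max fold AUC
are reported, since headline figures are sometimes quoted as the maximum.

## Differential screens and discretization

Expression tumor-vs-normal analysis is a moderated two-sample statistic
d = (mean difference)/(pooled SE + s₀) with s₀ the median per-gene pooled
SE, and a permutation FDR (group labels permuted, default 200 rounds,
tail-count estimate monotonized along the ranking). This is a deliberate,
documented stand-in for the SAM workflow — the ranked-d-statistic/Δ-threshold
machinery is out of scope, and only the significant gene lists feed
downstream counting. Significance requires linear-scale fold change ≥ 2
(direction-aware; `log2_input` switches to a difference-of-means ≥ 1) and
q < 0.05. Methylation uses the Mann–Whitney U test (exact for small groups,
normal approximation with tie correction otherwise) with BH FDR < 0.005.
Wherever "FDR" appears without a named method, BH is used.

Alteration discretization follows oncogene/tumor-suppressor logic with
strict inequalities, ties falling in the unaltered class: amplified ⟺ call
∈ {1, 2}; homozygous deletion ⟺ call = −2; over/under-expressed ⟺ strictly
beyond the per-gene mean ± SD computed over tumor samples (sample SD,
ddof = 1, configurable); hypo-/hyper-methylated ⟺ beta strictly below 0.2 /
above 0.8. Zero-variance expression genes get no expression calls.

KNN imputation fills a missing entry from the k nearest rows by Euclidean
distance over mutually observed columns; a neighbor is skipped when fewer
than 3 columns are shared or when it lacks the target column, and the column
mean is the fallback when no usable donor exists. Probe-level methylation is
collapsed to genes by the arithmetic mean of surviving probes.

## Module scoring and survival screen

A module's score M is Σωᵢⱼ/E over member pairs that are network edges — the
mean induced edge weight. Pairs that are not edges contribute zero to the
numerator; this is the only reading under which dividing by the edge count E
yields a bounded score comparable across modules. Modules with no induced
edge are unscoreable and flagged rather than scored 0. Module membership is
a pluggable input (any density-based finder's TSV output); a
connected-components fallback keeps the pipeline self-contained, and the
cutoff-stability table (best-Jaccard matching of modules across detector
cutoffs, size deviation per module) supports choosing a detector operating
point. Cross-network comparison pools induced edge weights per network over
the shared module membership and applies a two-sided Mann–Whitney test of
the integrated network against each baseline; per-module average weights are
also emitted so a paired per-module comparison can be made instead.

The survival screen splits samples by presence of each of the six alteration
features per candidate gene, requires ≥ 5 feature-positive samples, and
applies the log-rank test (lifelines) with BH adjustment over the actually
tested features only; a feature is significant at the joint cutoff p < 0.05
and FDR < 0.25. Direction is "risk" when the feature-positive group's
restricted mean survival (area under its Kaplan–Meier curve up to the common
follow-up horizon) is lower. Ties of events and censorings at the same time
follow the standard convention: events first.

## Synthetic-data generator

`generate_multiomics` drives each gene's three layers from independent
standard normal latent values; a planted pair shares one latent factor z
across all six coordinates with per-layer loading α, giving population first
canonical correlation ρ₁ = 3α²/(1 + 2α²), inverted in closed form as
α² = r/(3 − 2r). The methylation layer is squashed into [0, 1] by a logistic
map (near-linear in the bulk, so the planted correlation survives), and
discrete copy-number calls come from symmetric per-gene quantile thresholds
(defaults: 10% amplified with the outer 5% as call 2, 2% deleted with the
outer 1% as call −2). `generate_network` plants a clique-like module (pair
wiring probability 0.6 by default) on a Barabási–Albert preferential-
attachment background (m = 2) and designates a random half of the module as
seeds. `generate_survival` draws exponential event times whose hazard is a
baseline (1/1000 per day) times the product of planted hazard ratios for
carried features, with independent exponential censoring tuned to the target
censoring fraction (default 0.3). All generators are pure functions of their
parameters and RNG seed.

What the generator does *not* emulate: batch effects, platform noise,
copy-number segment structure, methylation probe correlation, non-linear
dosage effects, or realistic degree-alteration confounding. Passing tests
therefore demonstrate correctness and calibration of the machinery under
clean planted effects, not performance on real tumor cohorts.

## Problem sizes and numerical choices

The test and acceptance experiments use deliberately compact problem sizes —
200-sample profiles, 200–500-node networks, 500–3000 permutations, 1000
log-rank replicates — chosen so the full suite characterizes calibration
and recovery while remaining quick to run end to end. Numerical safeguards:
covariance blocks are ridge-regularized (ε = 1e-8 · trace/3) only when
near-singular, e.g. a constant copy-number row, and the pair is flagged
degenerate; λ is clipped to [0, 1] and 1 − λ floored at 1e-12 before logs;
empirical p-values use the (1 + x)/(1 + n) correction so no p is exactly 0;
p-values in ω's −log weights are floored at 1e-300. Edges whose CCA fails
outright (both genes constant) are dropped with a logged count rather than
kept at weight 0, because zero-weight edges would still dilute the walk's
column normalization.

## Known limitations

CCA here is limited to the 3 × 3 case (no regularized or kernel variants);
interaction sources are matched by case-sensitive gene symbol with no alias
resolution; the expression differential screen approximates rather than
reproduces SAM; module discovery itself (MCODE-style density clustering) is
external; and published cohort-scale figures (network sizes, candidate
counts, AUCs on TCGA ovarian data) depend on specific database versions and
are not reproduction targets of this package.
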