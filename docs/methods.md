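# Methods

This note documents the statistical procedures implemented in `t2di`, the
assumptions behind the synthetic-study generator, the defaults of every
consequential parameter, and the numerical choices made where the design
was genuinely open.

## 1. Interactome model

Genes are identified by upper-cased symbol strings; no alias resolution is
attempted (symbol harmonization across interaction databases is out of
scope and must happen upstream). The graph is undirected and simple:
self-loops are dropped at parse time with a logged count, duplicate rows
collapse. Edges carry *source tags* (`physical`, `coexpression`); merging
two networks takes the union of nodes and edges, an edge present in both
inputs accumulating both tags, so
`|E_merged| = |E_phys| + |E_coexpr| − |E_shared|` holds by construction.
For module discovery the graph is treated as unweighted — mutual
information survives only as edge metadata.

**Degree-distribution fit.** The scale-free character of an interactome is
summarized by the continuous maximum-likelihood power-law exponent
`α̂ = 1 + n_tail / Σ ln(k_i/(x_min − 0.5))` over degrees `k_i ≥ x_min`.
`x_min` defaults to 2 and is configurable; when every tail degree equals
`x_min` the MLE diverges and a degenerate-input error is raised instead.
This continuous estimator applied to discrete degrees carries a small
downward bias at low `x_min` (a few percent at α = 2.5, `x_min` = 2); for
preferential-attachment graphs the fit is made at `x_min = m` (the
attachment count), where the tail actually begins.

## 2. Co-expression network

Pairwise dependence is measured by plug-in mutual information on an
equal-frequency (rank-based) discretization into `B × B` cells, in nats.
`B = max(2, ⌊√n⌋)` by default; rank ties break by original sample index,
making the estimate deterministic. Expression is log2(x+1)-transformed
first (the ranks are invariant to the monotone transform; the transform is
kept so exported intermediate values match the documented pipeline).
Identical vectors give MI = ln B exactly when B divides n; constant
vectors give MI = 0 with a warning.

The network is built in two steps: (1) keep pairs with MI ≥ a threshold —
default 1.0 nats, deliberately stringent; the threshold's unit and value
are configuration, not dogma; (2) prune with the **data processing
inequality**: in every triangle the edge with the *strictly* smallest MI
is marked when `MI_weakest < (1 − tolerance)·min(other two)` (default
tolerance 0), marks being taken against the original edge set and applied
simultaneously, so the result cannot depend on edge iteration order and a
three-way tie removes nothing.

With 20 samples and B = 4 the plug-in estimator's null bias is about
`(B−1)²/(2n) ≈ 0.2` nats with substantial variance, so a 1.0-nat threshold
admits a small number of spurious pairs; the co-expression layer is
therefore treated as an *augmentation* of the physical network, never as
evidence on its own. Permutation calibration of MI and bootstrapped
consensus networks are intentionally out of scope.

## 3. Differential expression

The built-in test is a deliberately simple two-group negative-binomial
Wald test, not a reimplementation of shrinkage-based tools: libraries are
normalized by median-of-ratios (genes expressed in all samples form the
geometric-mean reference); `log2FC = log2((mean_case + ½)/(mean_ctrl + ½))`
on normalized counts (pseudocount ½ stabilizes low counts); the NB
dispersion φ is method-of-moments per gene, averaged across groups and
floored at 1e-8; the Wald statistic uses the delta-method variance
`(1/μ + φ)/n` per group and is referred to a **t distribution with
n₁+n₂−2 df** — the small-sample correction for the estimated dispersion,
which brings the null type-I error to its nominal level at n = 10 + 10
(the normal reference is measurably anticonservative there). All-zero
genes get p = 1. Any external per-gene table (gene, log2fc, p) can be
substituted, and that is the recommended route when DESeq2/edgeR output
is available.

Benjamini–Hochberg adjustment is the exact step-up
`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1, returned in input order.
The significance gate is `padj < 0.05` **and** `|log2FC| > 0.75`, both
strict, applied after adjustment over all tested genes (no independent
filtering). Up/down counts and per-direction median log2FC are reported
alongside.

## 4. Module discovery

**Diffusion expansion.** With N network genes and a current set of size s,
a candidate of degree k with ks links into the set scores the
hypergeometric upper tail `P(X ≥ ks)`; the smallest p is added each
iteration, ties broken by larger ks then lexicographically smaller
symbol (the tie rule is fixed for determinism). The seed weight is 1 —
seeds and added genes count equally when s grows. Default 200 iterations.
The frontier emptying ends the run early with a logged notice.

**Active subnetworks.** Gene p-values are clamped to [1e-12, 1−1e-12]
before z-scoring (genes without a p get p = 1, i.e. the clamp floor). The
aggregate score of k genes is `z_A = Σz/√k`; its null moments under
uniform k-gene sampling are `μ_k = √k·z̄` and
`σ_k² = Var(z)·(N−k)/(N−1)` (finite-population sampling without
replacement). `calibrate_score` estimates these by Monte Carlo (default
2,000 samples per k, cached); the annealer itself uses the closed-form
moments — the infinite-sample limit of the same calibration — because the
search visits hundreds of distinct component sizes per run and per-size
resampling would dominate the runtime. The two agree to sampling error and
a test asserts it.

The annealing state is a node in/out vector, initialized active with
probability ½. Each iteration toggles one uniformly random node; the state
score is the sum of the top-`n_modules` (default 5) component scores s_A;
improvements are always accepted, worsenings with probability
exp(Δ/T) under geometric cooling `T_i = T_start·(T_end/T_start)^(i/I)`
(defaults 1.0 → 0.01 over 10⁶ iterations; the test profile uses 10⁴ and
stamps its reports as scaled down). No regional/local score adjustment is
applied. The best-seen state's components are reported in descending s_A,
greedily filtered to pairwise Jaccard overlap ≤ 0.1. The search is run
twice — the second pass on the subgraph induced by the first pass's genes
— and the second-pass output (HSN2) is what feeds the signature set;
HSN2 ⊆ HSN1 by construction.

**Signatures.** `signatures = (diffusion ∪ HSN2) ∩ DE-significant`, with
per-gene provenance (`diamond`, `jactivemodules`, `both`). Because
intersection distributes over union, filtering before or after the union
is equivalent; counts are reported per method post-filter, so
`total = n_diamond + n_jam − n_both` exactly.

## 5. Module topology

`S` is the size of the largest connected component of the disease genes'
induced subgraph (genes absent from the network count as isolated
singletons; ties in component size break toward the lexicographically
smallest member). The null resamples Nd genes uniformly from all network
nodes (a degree-binned mode — resampling within log2-degree bins — is
available for degree-matched nulls); z = (S − mean)/sd with the one-sided
normal tail p, plus the empirical `p = (#{S_rand ≥ S}+1)/(n_rand+1)`,
which can never be 0. A zero null sd is flagged degenerate and only the
empirical p is reported. The separation `d_s` is the mean distance from
each disease gene to its nearest other disease gene (unreachable genes
excluded with a logged count); Glass' Δ is
`(mean_treat − mean_ctrl)/sd_ctrl` with the n−1 sd.

## 6. GWAS integration

**Binning.** A SNP enters a gene's bin if it lies inside the annotated
interval (1-based inclusive; no promoter padding by default — padding is a
knob), or is in LD at r² ≥ 0.8 with a genotyped SNP inside the interval —
one hop only, no transitive chaining. A SNP may serve several bins.
**Gene-level p** is the Šidák-corrected minimum, `1 − (1 − p_min)^m`,
computed via `log1p/expm1`; Simes combination is available as an
alternative flag. **λ_GC** is the median association χ²₁ quantile divided
by 0.4549. **Fraction curves** compare, on a log-spaced threshold grid,
each query set's fraction of genes below p against the mean ± sd band of
100 uniform size-matched control sets. **Fisher enrichment** is the
one-sided (greater) hypergeometric tail on the 2×2 table, with
OR = ad/bc (∞ when bc = 0 and ad > 0).

**Monte-Carlo SNP-set enrichment** counts flagged query SNPs against
size-matched background draws without replacement. Such a count is
exactly hypergeometric, so the null is sampled from
Hypergeometric(N, K, n) directly — distribution-identical to explicit
permutation (a permutation oracle cross-checks this in tests) and fast
enough for the production 10⁶ draws; background matching is by size only.
The empirical p uses (k+1)/(N+1) everywhere, so its floor at 10⁶ draws is
1.00e-6. **Perfect-LD expansion** treats r² = 1 ∧ D′ = 1 as the
equivalence relation it is and returns the transitive closure.

**eQTL/GWAS concordance ("sherlock-lite").** Each eSNP contributes the
Wakefield-form approximate log Bayes factor
`LBF = ½·ln(V/(V+W)) + z²W/(2(V+W))` (GWAS z, effect variance V, prior
effect variance W, default 0.04): negative near z = 0, positive for large
|z|, zero contribution for SNPs that are not eSNPs of the gene. A gene's
score is the sum over its eSNPs; significance comes from permutations
that redraw the gene's eSNP z-scores from the full GWAS z pool, with the
plus-one convention. This is an intentional simplification of exact
Bayes-factor colocalization scoring, adequate for ranking and calibrated
under the null (tested).

## 7. Comorbidity and symptoms

Relative risks are input metadata; the filter keeps RR ≥ 1.5 with the
lower 99% confidence bound strictly above 1.0. Signature enrichment in a
comorbid disease's gene set is the one-sided Fisher test over a declared
gene universe (genes outside it are ignored with a log note). Symptom
similarity is the cosine of TF-IDF vectors, `w(t,d) = tf·ln(N/n_t)` with
natural log and no smoothing (a +1-smoothing flag exists); a term present
in every disease gets weight 0, and a disease whose entire vector
vanishes is flagged and assigned similarity 0, including to itself.

## 8. The synthetic-study generator

The generator exists so every downstream statistic can be tested with
known ground truth; its distributions are the standard minimal models the
downstream tests assume, not fits to any real cohort.

* **Interactome**: preferential attachment (`n_genes` = 1000, `m` = 3 by
  default), giving the heavy-tailed degree distribution expected of
  interactomes. The planted module is a connected induced subgraph of 30
  nodes collected by random walk, densified by adding each absent
  module-pair edge with probability 0.2 — disease modules are by
  definition locally dense neighborhoods, and a bare random-walk sample of
  a sparse graph is nearly a tree, which no diffusion method could
  meaningfully recover from 10 seeds. 10 seed genes are drawn uniformly
  from the module.
* **Expression**: a 10-case / 10-control cohort. Control counts are
  NB(μ_g, φ = 0.1) with μ_g log-normal (σ = 1) around a base mean of 100;
  cases multiply μ_g by 2^lfc for effect genes (planted lfc = 2 on module
  genes; each first neighbor of the module receives the effect with
  probability 0.05, keeping spillover clearly smaller than the module
  itself). Module genes share one latent log-normal factor across samples
  (σ = 0.6), inducing the positive co-expression the MI network should
  recover. All planted effects are positive; direction is not part of any
  downstream contract. Note that the latent factor, being shared by all
  module genes and independent of condition, also injects module-wide
  between-group noise (sd ≈ 0.39 on the log2FC scale at n = 10 + 10), so
  the *effective* module fold change varies around its planted value from
  seed to seed — single-study recovery therefore fluctuates, and recovery
  guarantees are stated as means over 25 seeds.
* **GWAS**: single synthetic chromosome, 2 kb genes with 2 kb gaps; SNP
  counts per gene body and per gap are Poisson(3); z ~ N(0,1) with +5
  added at causal SNPs (all SNPs inside module genes); p = 2Φ(−|z|). LD
  is emitted for all pairs within blocks of 5 consecutive SNPs, r² ~
  U(0.7, 1) with 15% of pairs at exactly r² = 1, D′ = 1, and no LD across
  blocks.
* **Annotations/eQTL**: three cell-type flags at base rate 0.1, odds
  multiplied by 8 at causal SNPs; eQTL records target each gene's own
  SNPs, module genes drawing more eSNPs.
* **Comorbidity**: 20 diseases of size ~Poisson(25)+5, a Binomial(size,
  ρ = 0.3) share of members from module/effect genes; RR ~ U(1, 2.5) with
  a lower CI bound RR − U(0.1, 0.6); symptom vectors overlap the focal
  disease's 30-term vector with the same ρ.

One master seed drives everything through fixed per-stage substreams
(`default_rng([seed, offset])`), so regenerating one stage never perturbs
another and written files are byte-identical across reruns.

**What the generator does not emulate**: realistic LD from a reference
panel, allele frequencies, read-level sequencing noise, batch effects,
correlated null genes outside the module, real MeSH vocabularies, or
epidemiological RR estimation. Passing tests therefore demonstrate
*internal correctness and calibration* of the statistics, not performance
on real cohorts.

## 9. Test and calibration design

Null-calibration checks zero all planted effects and verify nominal
behavior: the expression test's type-I error at α = 0.05 (20 seeds × 2,000
genes), λ_GC on ~10⁵ null SNPs (the ±0.02 acceptance band is ≈2.7 sampling
sd at that size), and uniformity (KS) of the Monte-Carlo, Fisher,
permutation and module-size empirical p-values. Because one-sided p-values
on discrete statistics are exactly uniform only on their support, the
uniformity checks use dimensions with enough support spread for the KS
distance to be dominated by sampling noise: Fisher calibration uses
300- and 400-gene sets over a 2,000-gene universe, and module-size
calibration uses 120 genes on a 400-node Erdős–Rényi graph at mean degree
4 (near-critical induced subgraphs give the component size a wide
distribution). These dimensions were fixed by pilot design of the
calibration experiment, before any assertion was frozen.

Planted-module recovery runs the full discovery stack on 25 seeded
default studies in the scaled-down profile (10⁴ annealing iterations) and
asserts mean signature precision ≥ 0.6 and recall ≥ 0.5 against the
planted module, and ≥ 60% mean recovery of non-seed module genes within
the first 40 diffusion iterations.

## 10. Known limitations

* The NB Wald test is approximate; shrinkage estimators, covariate
  adjustment and outlier handling are absent by design — use an external
  table for production differential expression.
* The annealer's scaled-down profile (10⁴ iterations) is far from
  converged on 1,000-node graphs; its contribution there leans on the
  DE gate for precision. The production profile (10⁶) matches the
  published tool settings.
* MI thresholding at small n is noisy (Section 2); the co-expression
  network should be read as hypothesis augmentation.
* Gene-level p by Šidák-corrected minimum ignores intra-bin LD
  correlation and is conservative for large, tightly linked bins.
* Perfect-LD transitivity assumes exact r² = 1 records; floating r²
  values just below 1 are deliberately not chained.
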