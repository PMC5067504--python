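# t2di — disease-module signatures from an integrated interactome

`t2di` is a Python toolkit for finding **disease-module signatures**: genes
that sit together in a molecular interaction network *and* are
transcriptionally dysregulated in a case–control cohort. It is aimed at
systems-biology researchers who have (i) a curated physical interaction
network, (ii) an expression matrix from cases and controls, and optionally
(iii) GWAS summary statistics, eQTL/regulatory annotations and comorbidity
gene sets, and who want a reproducible, testable pipeline from those inputs
to a ranked signature set with enrichment evidence.

## What it computes

1. **Interactome construction.** A de novo co-expression network is built
   from expression profiles by pairwise mutual information (equal-frequency
   binning, nats), thresholded (default MI ≥ 1.0) and pruned with the data
   processing inequality (in any triangle the weakest edge is presumed
   indirect). It is merged with the physical network; edges carry source
   tags (`physical`, `coexpression`, or both).

2. **Dual module discovery.**
   * *Diffusion expansion* from known disease (seed) genes: at each of
     `n_iter` (default 200) steps the non-member gene with the most
     significant hypergeometric connectivity p,
     `p = Σ_{i≥ks} C(s,i)·C(N−s,k−i)/C(N,k)`,
     joins the module. Scoring by significance rather than raw link count
     penalizes hubs.
   * *Active-subnetwork search*: per-gene differential-expression p-values
     map to z-scores `z = Φ⁻¹(1−p)`; a connected subnetwork of size k is
     scored `z_A = Σz_i/√k`, calibrated to `s_A = (z_A − μ_k)/σ_k` against
     random k-gene sets, and high-scoring subnetworks are found by
     simulated annealing (start/end temperature 1.0/0.01, 10⁶ iterations,
     5 modules, pairwise Jaccard overlap ≤ 0.1), run recursively
     (HSN1 → HSN2).

3. **Signature gating.** Genes found by either method must be
   differentially expressed (BH-adjusted p < 0.05 **and** |log2FC| > 0.75)
   to become signatures; provenance per gene is kept.

4. **Evaluation layers.** Module-topology statistics (largest-component
   size S vs its randomized null, z-score and empirical p, separation d_s,
   Glass' Δ); GWAS integration (positional + LD SNP-to-gene binning at
   r² ≥ 0.8, Šidák gene-level p, genomic inflation λ_GC, fraction curves
   vs 100 size-matched control gene sets, Fisher 2×2 enrichment,
   Monte-Carlo SNP-set annotation enrichment with the (k+1)/(N+1)
   convention, perfect-LD expansion, and a simplified Bayes-factor
   eQTL/GWAS concordance score); comorbidity (relative-risk filtering at
   RR ≥ 1.5 with 99% CI lower bound > 1.0, Fisher gene-set enrichment,
   TF-IDF cosine symptom similarity).

A fully parameterized synthetic-study generator (`t2di.synthetic`) plants a
known disease module in a scale-free interactome and emulates the cohort,
GWAS, annotation and comorbidity inputs, so the entire pipeline is testable
offline with ground truth.

## Worked example

```python
from t2di.config import SimConfig, DiscoveryParams
from t2di.pipeline import run_all

result = run_all(SimConfig(seed=1), params=DiscoveryParams.test_profile())
print(result.signatures.counts())
print({k: round(v, 3) for k, v in result.report["signatures"].items()
       if k.startswith(("precision", "recall"))})
print("module z =", round(result.report["topology"]["z"], 2),
      " lambda_GC =", round(result.report["gwas"]["lambda_gc"], 3))
```

prints

```
{'diamond': 26, 'jactivemodules': 2, 'both': 1, 'total': 27}
{'precision_vs_module': 0.704, 'recall_vs_module': 0.633}
module z = 19.87  lambda_GC = 1.037
```

Here 27 signatures were discovered on a synthetic study with a planted
30-gene module: 26 supported by diffusion expansion, 2 by the (scaled-down)
annealing search, 1 by both, all differentially expressed. 70.4% of the
signatures are genuine module genes and 63.3% of the module was recovered.
The module z-score says the recovered gene set is far more connected than
same-sized random sets, and λ_GC slightly above 1 reflects the planted
association signal in the simulated GWAS.

The same stages are exposed as a CLI:
`t2di simulate|build-network|dge|discover|topology|gwas-bin|gwas-qq|enrich-mc|sherlock|comorbidity|run-all`.

## Documentation

`docs/methods.md` describes the statistical model behind every stage, the
synthetic-data generator's assumptions, all tunable parameters with their
defaults, and known limitations.
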