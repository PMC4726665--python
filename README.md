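# metamodule

Network-based meta-analysis of multi-study two-group gene expression data.

Individual expression studies of a phenotype contrast (the motivating case:
women with high versus low bone mineral density, profiled in blood monocytes,
B cells and bone biopsies) are small and inconsistent. `metamodule` combines
the per-gene evidence of k such studies and projects it onto a
protein–protein interaction (PPI) network to find a *consensus functional
module*: a connected subnetwork of genes whose differential expression is
jointly significant and reproducible under resampling.

The pipeline:

1. **Preprocessing** — collapse probes to gene symbols keeping the probe with
   the largest interquartile range; screen outlier samples by robust z on the
   first two principal components; intersect the studies' gene universes.
2. **Per-study differential expression (SAM)** — the relative-difference
   score `d_g = (x̄_high − x̄_low) / (s_g + s0)` with a pooled permutation
   null across genes; p-values use plus-one smoothing, so they never reach 0.
3. **Meta-analysis** — Fisher's combined statistic `χ² = −2·Σ ln pᵢ`
   (χ² with 2k df), and pooled standardized mean differences (Hedges' g)
   under a fixed-effects model, switching to DerSimonian–Laird random effects
   when Cochran's Q has p < 0.05 or I² > 50%; z = pooled SMD / SE;
   Benjamini–Hochberg FDR on both p-value families.
4. **Module detection** — a beta-uniform mixture (BUM)
   `f(p) = λ + (1−λ)·a·p^{a−1}` fitted to the combined p-values converts each
   gene into an additive node score at a chosen FDR; the maximum-scoring
   connected subnetwork is found exactly (branch-and-bound after safe graph
   reductions) or heuristically on large graphs; repeating detection on
   bootstrap-resampled data and re-solving on node-frequency scores
   (frequency − φ) yields the consensus module.
5. **Downstream** — hypergeometric pathway enrichment (Bonferroni), candidate
   genes passing both meta-analysis gates inside the module, and gene-level
   GWAS replication via each gene's most significant SNP.

A first-class synthetic-data generator (`metamodule.simulate`) emulates the
multi-study setting — unequal sample sizes, two partially overlapping
platform gene universes, between-study heterogeneity on the SMD scale, and a
connected module planted in a scale-free network — so the entire pipeline is
testable without any external downloads.

## Worked example

```python
from metamodule import (SimulationConfig, simulate_studies, simulate_network,
                        network_graph, sam_test, meta_analyze,
                        consensus_module, select_candidates)

config = SimulationConfig(
    k_studies=4, n_high=30, n_low=30, n_genes=2000, deg_fraction=12 / 2000,
    smd_range=(0.8, 0.8), heterogeneity_tau2=0.02, network_nodes=500,
    network_attach=2, planted_module_size=12, seed=1,
)
datasets, truth = simulate_studies(config)
graph = network_graph(simulate_network(config, truth))

sam_results = {ds.study_id: sam_test(ds, n_perm=1000, seed=i)[0]
               for i, ds in enumerate(datasets)}
meta = meta_analyze(sam_results, datasets)
print("genes with Fisher q < 0.05:", int((meta["fisher_q"] < 0.05).sum()))

module = consensus_module(datasets, graph, n_iter=20, fdr=0.001, seed=1)
print("consensus module: %d nodes, %d edges" % (len(module.nodes), len(module.edges)))

candidates = select_candidates(meta, module)
top = meta.loc[candidates[0]]
print("top candidate: pooled SMD %.2f (SE %.2f), z = %.2f, Fisher p = %.2e"
      % (top["pooled_smd"], top["pooled_se"], top["z"], top["fisher_p"]))
```

Output:

```
genes with Fisher q < 0.05: 14
consensus module: 11 nodes, 10 edges
top candidate: pooled SMD 1.15 (SE 0.14), z = 8.32, Fisher p = 3.41e-12
```

The 14 genes surviving FDR correction include the 12 planted ones; the
consensus module recovers 11 of the 12 planted genes with no off-module
nodes, and the top candidate's pooled effect (true SMD 0.8, inflated here by
selection) is highly significant by both combiners.

The same stages are available from the shell:

```sh
metamodule simulate --out sim/ --seed 1
metamodule all --config config.yaml --out results/
```

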