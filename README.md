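# lrnet

Community-regularized inference of ligand–receptor cross-talk networks from
cell-type-resolved expression data.

## The problem

Cell–cell interactions in a tissue are mediated by ligands secreted or
displayed by a sending cell type binding cognate receptors on a receiving
cell type. Correlation-based screens over a curated ligand–receptor (LR)
reference call many false interactions, because a single strong interaction
induces indirect correlations across every pair that shares a gene with it.
The principled fix — conditioning each pair on all others via partial
correlations — is ill-posed when the number of candidate LR variables *p*
far exceeds the cohort size *n*, the usual regime for flow-sorted bulk
RNA-seq with tens of patients.

`lrnet` resolves this with a graph decomposition. It

1. builds a weighted bipartite candidate graph: nodes are
   (cell type, gene, role) triples, edges are reference-supported LR pairs
   weighted by the Pearson correlation of their `log2(TPM+1)`, z-scaled
   expression across paired samples;
2. partitions the graph by seeded Louvain modularity maximization into
   *within-communities* capped at the sample size (recursively re-split
   when too large), plus *between-communities* collecting the edges that
   cross two within-communities, so every candidate edge is regularized in
   exactly one context;
3. fits, per community, an L1-penalized Gaussian precision matrix
   maximizing `log det Θ − tr(SΘ) − Σ P_ij |Θ_ij|`, where the entrywise
   penalty matrix puts a very large penalty (a structural zero) on
   ligand–ligand, receptor–receptor and non-candidate entries and a lasso
   level λ — selected per community by BIC over 20 log-spaced values on
   [0.01, 0.9] — on candidate LR entries;
4. keeps candidate edges with strictly positive estimated partial
   correlation `−Θ_ij/√(Θ_ii Θ_jj)` and unions the communities into a
   global interactome with full provenance.

An optional resampling test assigns each edge a per-community p-value, and
downstream modules project a coarse interactome onto single-cell
subpopulations, score subpopulation prognosis from survival z-scores,
compute sender-standardized cross-talk matrices, and measure a receptor's
influence on its correlated signaling neighborhood by eigenvector
centrality.

Because real flow-sorted cohorts are large downloads, the package ships a
first-class synthetic generator: sparse bipartite ground-truth precision
matrices with positive partial correlations, sampled into Gaussian cohorts
of any size, so the entire pipeline is testable against a known edge set.

## Worked example

```python
from lrnet import (generate_truth, sample_cohort, infer_interactome,
                   confusion_metrics)

truth = generate_truth(seed=0)            # 3 cell types, 60 variables
cohort = sample_cohort(truth, n=200, seed=1)
inter = infer_interactome(cohort, truth.reference, truth.retained, seed=0)

universe = {e for e in truth.candidate_edges
            if not (e[0].cell_type == e[1].cell_type and e[0].gene == e[1].gene)}
sens, spec = confusion_metrics(inter.edge_set & universe,
                               set(truth.truth_edges), universe)
print(f"edges inferred: {len(inter.edges)}")
print(f"sensitivity {sens:.2f}, specificity {spec:.2f}")
```

```
edges inferred: 64
sensitivity 1.00, specificity 0.72
```

All 37 generated interactions (true partial correlations in [0.3, 0.6])
are recovered from a 200-sample cohort; 27 of the 98 null candidate edges
are also called, the expected trade-off for a BIC-selected lasso support
filtered to positive partials.

The same pipeline is exposed as a CLI:

```sh
lrnet simulate --out sim --cohort-size 200 --seed 0
lrnet fit --expr-dir sim/expression --reference sim/reference_pairs.tsv \
      --out interactome.tsv
lrnet benchmark --expr-dir sim/expression --reference sim/reference_pairs.tsv \
      --sizes 15,25,50,100,200 --reps 50 --seed 0 --out bench/
```

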