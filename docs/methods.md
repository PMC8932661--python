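# Methods

## Model

The data are cell-type-resolved expression tables over a shared patient
cohort: for each cell type *c*, a genes × samples matrix of TPM values,
log-transformed as `log2(TPM + 1)` and z-scaled per gene (sample SD,
ddof = 1). After scaling, every (cell type, gene) pair is one standardized
variable, and the sample covariance of any variable set equals its sample
correlation.

The inferential target is the set of conditionally dependent
ligand–receptor (LR) pairs: in a Gaussian graphical model over the
candidate variables, an LR pair interacts exactly when its precision
(inverse covariance) entry is nonzero, equivalently when its partial
correlation `ρ_ij·rest = −Θ_ij/√(Θ_ii Θ_jj)` is nonzero. Only positive
partial correlations are interpreted as interactions — a ligand inducing
its receptor's pathway is expected to co-vary positively once confounders
are removed — so the binarization keeps candidate edges with strictly
positive estimated partials.

## Candidate graph

A curated two-column LR reference defines which gene pairs may interact.
For every reference pair and every ordered cell-type pair (autocrine pairs
included), an edge is added when the ligand is retained in the sender and
the receptor in the receiver; the weight is the Pearson correlation over
paired samples. Degenerate self-edges (identical variable on both ends)
are dropped: the correlation of a variable with itself carries no
information. Constant genes are excluded before any correlation. Two gene
filters are provided: a mean-TPM threshold (default 10, evaluated on the
raw scale), and a two-step dispersion filter on log values — tertile genes
by mean expression and drop the lowest tertile, then z-normalize the
dispersion ratio (variance/mean, ddof = 1) within each surviving
expression tertile and drop the lowest tertile of the pooled normalized
dispersions. Equal-frequency binning uses `np.array_split` over a
deterministic (value, gene name) ordering; whether the original procedure
re-bins dispersion globally or within expression bins is not decidable
from its description, so this variant is fixed and documented rather than
asserted as the original rule.

## Community decomposition

Estimating one joint precision matrix is hopeless when candidate variables
far outnumber samples, so the graph is partitioned by Louvain modularity
maximization (networkx implementation, fixed seed; modularity itself is
re-implemented and cross-checked against a brute-force double loop in the
tests). Louvain needs nonnegative weights; the default weight is
|Pearson r|, with |Spearman| available as a switch. Communities larger
than the sample size are recursively re-partitioned on their induced
subgraph (depth cap 10); a community Louvain refuses to split is kept and
flagged `unsplittable` rather than broken arbitrarily. Edges crossing two
within-communities are collected into between-community pseudocommunities
containing exactly the endpoints of the crossing edges; consequently every
candidate edge is fitted in exactly one community, an invariant the test
suite fuzzes.

## Penalized precision with structural zeros

Each community is fitted by maximizing
`log det Θ − tr(SΘ) − Σ_ij P_ij |Θ_ij|` with a block coordinate-descent
graphical lasso written for this package (numba-compiled), because the
standard scalar-penalty implementations cannot express an entrywise
penalty matrix. `P` carries λ on candidate LR entries and 10⁶ on
everything else off-diagonal (ligand–ligand, receptor–receptor, and LR
pairs absent from the reference — the stricter choice prevents dependence
from routing through non-cognate pairs and is switchable). The
soft-threshold update zeroes structurally penalized coefficients exactly,
so structural zeros hold to machine precision. Convergence is declared
when the covariance sweep changes by less than `tol × mean |off-diag S|`
(tol = 1e-4, max 500 sweeps); failures raise with the community id and λ.
At λ → 0 and without structural constraints the estimate reproduces the
directly inverted partial-correlation matrix (tested at 1e-3 for a
10-variable, n = 200 community).

λ is selected per community by BIC over 20 logarithmically spaced values
on [0.01, 0.9], fitted descending with warm starts:
`BIC(λ) = −2·(n/2)(log det Θ̂ − tr(SΘ̂)) + log(n)·df`, with df the number
of nonzero upper-triangle off-diagonal entries (|Θ̂_ij| > 1e-8) and n the
number of shared samples. Ties resolve to the larger λ (sparser model).
Size-1 communities are skipped; size-2 communities run through the same
solver, which reduces to the closed-form 2×2 soft-threshold solution.

A note on support recovery: BIC-selected lasso support is not an exact
support recoverer — when strong edges are present the selected λ is small
and near-zero noise partials can remain positive. The tests therefore
assert full recovery of truth edges plus clear separation of partial
magnitudes, not exact set equality; the benchmark quantifies the
sensitivity/specificity trade-off explicitly.

## Edge significance

The per-edge test asks how surprising the observed correlation `r_obs` is
among correlation values that would make the pipeline call the edge at
all, within its community. The pair's correlation entry is replaced by
draws `u_t ~ Uniform(−1, 1)` (with eigenvalue-clipped projection back to
the PD cone, floor 1e-8), the community fit (BIC selection + binarization)
is re-run per draw, and a depth-3 regression tree is fitted to the binary
calls, giving a call function f(u). The depth cap keeps f a coarse step
function and avoids interpolation artifacts.

The null for chance correlations at sample size n is taken from a Wishart
distribution with identity scale and df = n: its correlation-normalized
off-diagonal entries are exactly the sample correlations of independent
Gaussians at that sample size (SD ≈ 1/√n). Broad Gaussian draws
`g_s ~ N(0, sd(u))` — matched to the proposal so the tree is evaluated
where it was trained — are importance-reweighted to the Wishart-derived
null scale, and

```
p_one = Σ_s f(g_s)·w_s·1[g_s > r_obs] / Σ_s f(g_s)·w_s ,   p_two = 2·min(p_one, 1−p_one)
```

with `w_s` the density ratio between the null-scale and proposal-scale
Gaussians at `g_s`. The comparison `g_s > r_obs` is signed. If the call
never varies across substitutions the test is uninformative and returns
p_two = 1 with a degeneracy flag; zero total null call mass is an error.
This null construction is this package's own: the originating description
lists the same ingredients (uniform proposal, regression tree, Gaussian,
Wishart multiplication) but does not pin their composition, and the
composition chosen here is the one that makes the statistic a proper
finite-sample tail probability. Everything is seeded; the test is
deterministic per seed. It recomputes only the community's regularization,
not the global partition, so partition stochasticity is deliberately
outside the null.

## Synthetic study conditions

The generator emulates a flow-sorted cohort: by default 3 cell types ×
(10 ligand + 10 receptor) genes = 60 variables, a reference pair list
sampled at density 0.15 over the ligand × receptor gene grid, candidate
edges enumerated across all ordered cell-type pairs, truth edges kept with
probability 0.25, and target partial correlations drawn uniformly from
[0.3, 0.6] — moderate effect sizes typical of co-regulated transcripts.
Precision entries are set to −ρ (positive partials under the −Θ
convention); positive definiteness is enforced by uniform diagonal
inflation to a minimum eigenvalue of 0.05, which preserves the zero
pattern exactly while shrinking effect sizes, so the reported per-edge
ρ_true values are recomputed after the repair. The implied covariance is
rescaled to correlation form and cohorts are i.i.d. Gaussian draws,
re-z-scaled per gene.

What this does and does not emulate: the generator produces exactly the
Gaussian, linearly dependent, paired-sample world the model assumes. It
does not emulate RNA-seq count noise, dropout, compositional effects,
unpaired cohorts, or protein-level regulation — passing tests demonstrate
correct inference under the model, not robustness to those violations.

Benchmark problem sizes were chosen to keep the full suite and the
acceptance script comfortably reproducible on one core: recovery uses 20
seeds at n = 200; the downsampling contrast uses one truth, a n = 1000
population whose single whole-graph fit is the gold standard, and 20
replicates at each cohort size, comparing the community pipeline against
the same single-fit estimator run on the small cohort. The universe for
specificity is the population candidate graph, fixed across arms;
non-predicted edges rank below every predicted edge in the ROC;
downsampling is without replacement; Jaccard of two empty sets is defined
as 1.

## Downstream scoring

Projection relabels each coarse edge by every (sender subpopulation,
receiver subpopulation) combination where the ligand is DE-flagged with
average expression above the threshold (default 0.4) and the receptor
exceeds the same threshold; DE flags, secretion annotations, and an
optional receptor-expression cutoff are inputs, not computed. The
prognostic score of a subpopulation is the expression-weighted mean
`Σ e_L z_L / Σ e_L` of survival z-scores over its secreted DE ligands
(positive = poor prognosis); subpopulations with fewer than three
qualifying ligands are excluded for power. Among projected edges sharing a
gene pair, the (sender, receiver) combination minimizing the prognostic
score gap is kept, ties retained. Cross-talk counts are standardized per
sender row by z-scoring with sample SD (a proportion-of-sent mode is
available); constant rows map to zeros and are flagged. The downstream
influence of a receptor is its eigenvector centrality — power iteration on
the |Pearson|-weighted protein-interaction graph over expressed signaling
genes, restricted to the receptor's connected component, shifted by a
diagonal constant to guarantee convergence on bipartite components,
normalized to unit maximum — transformed by `log2(1 + c)`, mapping [0, 1]
onto [0, 1]. The log transform is this package's reading of an
"influence score ranging from 0 to 1"; it compresses differences among
high-centrality receptors.

## Known limitations

- Interactions are assumed to manifest as positive linear transcript
  co-variation; secreted factors acting at a distance, protein complexes,
  and spatially or temporally modulated signaling fall outside the model.
- The per-community significance test does not account for partition
  stochasticity, and no multiple-testing correction is applied across the
  interactome.
- BIC-selected lasso support overcalls weak positive partials; users
  wanting a harder guarantee should filter kept edges by partial magnitude
  or the significance test.
- λ selection is per community; no information is shared across
  communities.
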