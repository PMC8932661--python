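"""Global interactome assembly, benchmark metrics and the downsampling harness.

The per-community kept edges are unioned into a single bipartite network
with full provenance, classified as autocrine/paracrine, and compared to a
gold-standard network with confusion metrics, ROC AUC and Jaccard overlap.
The harness repeatedly downsamples a large population cohort to emulate
small studies and contrasts the community-regularized pipeline with a
single whole-graph penalized fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .communities import (Community, WITHIN, build_between_communities,
                          detect_within_communities)
from .graph import EdgeKey, LRGraph, LRNode, build_lr_graph
from .ingest import ExpressionMatrix, LRReference
from .precision import (KeptEdge, RegularizedCommunity, fit_community,
                        lambda_grid)

logger = logging.getLogger(__name__)


class EdgeRecord(NamedTuple):
    pearson_r: float
    partial_r: float
    community_id: str
    kind: str
    p_two: float | None = None


@dataclass
class Interactome:
    """Assembled binary LR network with per-edge provenance."""

    edges: dict[EdgeKey, EdgeRecord]
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[LRNode]:
        out: set[LRNode] = set()
        for lig, rec in self.edges:
            out.add(lig)
            out.add(rec)
        return out

    @property
    def edge_set(self) -> set[EdgeKey]:
        return set(self.edges)

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ligand_celltype\tligand_gene\treceptor_celltype\t"
                     "receptor_gene\tpearson_r\tpartial_r\tcommunity_id\tkind\tp_two\n")
            for (lig, rec), rec_ in sorted(self.edges.items()):
                p = "" if rec_.p_two is None else f"{rec_.p_two:.6g}"
                fh.write(f"{lig.cell_type}\t{lig.gene}\t{rec.cell_type}\t{rec.gene}\t"
                         f"{rec_.pearson_r:.6g}\t{rec_.partial_r:.6g}\t"
                         f"{rec_.community_id}\t{rec_.kind}\t{p}\n")


def assemble_interactome(
    regularized: Iterable[RegularizedCommunity | None],
    provenance: dict | None = None,
) -> Interactome:
    """Union of kept edges across communities; duplicates prefer the WC record."""
    edges: dict[EdgeKey, EdgeRecord] = {}
    lambdas: dict[str, float] = {}
    for reg in regularized:
        if reg is None:
            continue
        lambdas[reg.community.id] = reg.lambda_star
        for ke in reg.kept_edges:
            record = EdgeRecord(pearson_r=ke.pearson_r, partial_r=ke.partial_r,
                                community_id=ke.community_id, kind=ke.kind)
            if ke.edge in edges and edges[ke.edge].kind == WITHIN:
                continue
            edges[ke.edge] = record
    prov = dict(provenance or {})
    prov["lambda_per_community"] = lambdas
    return Interactome(edges=edges, provenance=prov)


def classify_edges(interactome: Interactome) -> tuple[dict[EdgeKey, str], pd.DataFrame]:
    """Label each edge autocrine/paracrine and summarize per cell-type pair."""
    labels: dict[EdgeKey, str] = {}
    rows = []
    for lig, rec in interactome.edges:
        label = "autocrine" if lig.cell_type == rec.cell_type else "paracrine"
        labels[(lig, rec)] = label
        rows.append((lig.cell_type, rec.cell_type, label))
    if rows:
        df = pd.DataFrame(rows, columns=["sender", "receiver", "label"])
        summary = (df.groupby(["sender", "receiver", "label"]).size()
                   .rename("count").reset_index())
        summary["fraction"] = summary["count"] / summary["count"].sum()
    else:
        summary = pd.DataFrame(columns=["sender", "receiver", "label", "count", "fraction"])
    return labels, summary


def confusion_metrics(predicted: set, gold: set, universe: set) -> tuple[float, float]:
    """Sensitivity (recall on gold edges) and specificity (TN rate)."""
    if not gold:
        raise ValueError("empty gold standard: sensitivity undefined")
    if not predicted <= universe or not gold <= universe:
        raise ValueError("predicted and gold must be subsets of the universe")
    negatives = universe - gold
    if not negatives:
        raise ValueError("gold equals universe: specificity undefined")
    sens = len(predicted & gold) / len(gold)
    spec = len(negatives - predicted) / len(negatives)
    return sens, spec


def roc_auc(scores: dict, gold: set, universe: set) -> float:
    """AUC of |score|-thresholded calls against the gold edge set.

    Edges never predicted receive a score below every predicted edge, so
    they are not called at any threshold; ties average (Mann-Whitney).
    """
    if not gold:
        raise ValueError("empty gold standard")
    if set(gold) >= set(universe):
        raise ValueError("gold equals universe: AUC undefined")
    universe_list = sorted(universe)
    called = {e: abs(s) for e, s in scores.items() if e in universe}
    floor = (min(called.values()) if called else 0.0) - 1.0
    y = np.array([e in gold for e in universe_list], dtype=int)
    s = np.array([called.get(e, floor) for e in universe_list], dtype=float)
    return float(roc_auc_score(y, s))


def jaccard(a: set, b: set) -> float:
    """|A & B| / |A | B|; defined as 1.0 when both sets are empty."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def build_gold_standard(
    expr: ExpressionMatrix,
    ref: LRReference,
    retained: dict[str, list[str]] | None = None,
    grid: np.ndarray | None = None,
    max_variables: int = 500,
    provenance_label: str = "gold",
) -> tuple[Interactome, LRGraph]:
    """Single whole-graph penalized fit (no community decomposition).

    Intended for large cohorts where the full candidate graph is estimable;
    also serves as the no-community baseline arm in the benchmark.
    """
    graph = build_lr_graph(expr, ref, retained)
    community = Community(
        id=provenance_label, kind=WITHIN,
        nodes=frozenset(graph.nodes),
        candidate_edges=frozenset(graph.edges),
    )
    n_vars = len({(n.cell_type, n.gene) for n in community.nodes})
    if n_vars > max_variables:
        raise ValueError(
            f"candidate graph has {n_vars} variables (> {max_variables}); "
            "chunk the gene list or raise max_variables explicitly"
        )
    reg = fit_community(community, expr, grid=grid)
    inter = assemble_interactome([reg], provenance={"mode": "single_fit",
                                                    "label": provenance_label})
    return inter, graph


def infer_interactome(
    expr: ExpressionMatrix,
    ref: LRReference,
    retained: dict[str, list[str]] | None = None,
    seed: int = 0,
    max_community_size: int | None = None,
    grid: np.ndarray | None = None,
    weight_mode: str = "abs_pearson",
) -> Interactome:
    """End-to-end pipeline: graph, communities, per-community fits, union."""
    graph = build_lr_graph(expr, ref, retained)
    partition = detect_within_communities(
        graph, max_size=max_community_size, seed=seed, weight_mode=weight_mode)
    between = build_between_communities(graph, partition)
    regs = [fit_community(c, expr, grid=grid)
            for c in list(partition.communities) + between]
    return assemble_interactome(regs, provenance={
        "mode": "community", "seed": seed,
        "n_within": len(partition.communities), "n_between": len(between),
        "n_samples": expr.n_samples,
    })


@dataclass
class BenchmarkResult:
    records: pd.DataFrame   # tidy: size, rep, arm, metric, value
    summary: pd.DataFrame   # size, arm, metric, mean, sd
    gold_edges: set
    universe: set


def _rescale(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Re-z-scale rows of an already log-scaled cohort subset."""
    values = {}
    constant: dict[str, list[str]] = {}
    for ct, df in expr.values.items():
        arr = df.to_numpy(dtype=float)
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        const = (sd[:, 0] == 0)
        sd[const] = 1.0
        z = (arr - mu) / sd
        z[const, :] = 0.0
        values[ct] = pd.DataFrame(z, index=df.index, columns=df.columns)
        constant[ct] = [g for g, c in zip(df.index, const) if c]
    return ExpressionMatrix(values=values, scale_state=expr.scale_state,
                            constant_genes=constant)


def _arm_metrics(inter: Interactome, gold: set, universe: set) -> dict[str, float]:
    pred = inter.edge_set & universe
    sens, spec = confusion_metrics(pred, gold, universe)
    scores = {e: r.pearson_r for e, r in inter.edges.items() if e in universe}
    auc = roc_auc(scores, gold, universe)
    return {"sensitivity": sens, "specificity": spec, "auc": auc,
            "jaccard": jaccard(pred, gold), "n_edges": float(len(pred))}


def run_downsampling_benchmark(
    population: ExpressionMatrix,
    ref: LRReference,
    sizes: Sequence[int] = (15, 25, 50, 100, 200),
    reps: int = 50,
    seed: int = 0,
    retained: dict[str, list[str]] | None = None,
    gold: Interactome | None = None,
    grid: np.ndarray | None = None,
) -> BenchmarkResult:
    """Downsample the population and score both arms against the gold network.

    For each (size, replicate): draw a sample subset without replacement,
    re-scale it, run both the community pipeline ("remi" arm) and the
    single whole-graph fit ("baseline" arm), and record sensitivity,
    specificity, AUC and Jaccard against the gold standard.  Fully seeded.
    """
    if min(sizes) < 3:
        raise ValueError("cohort sizes below 3 are not supported")
    if max(sizes) > population.n_samples:
        raise ValueError("cohort size exceeds the population")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if grid is None:
        grid = lambda_grid()
    if gold is None:
        gold, pop_graph = build_gold_standard(population, ref, retained, grid=grid)
    else:
        pop_graph = build_lr_graph(population, ref, retained)
    universe = set(pop_graph.edges)
    gold_edges = gold.edge_set & universe

    rng = np.random.default_rng(seed)
    samples = np.asarray(population.samples)
    rows = []
    for size in sizes:
        for rep in range(reps):
            cohort_ids = list(rng.choice(samples, size=size, replace=False))
            cohort = _rescale(population.subset_samples(cohort_ids))
            arm_seed = int(rng.integers(2 ** 31))
            arms = {
                "remi": infer_interactome(cohort, ref, retained,
                                          seed=arm_seed, grid=grid),
                "baseline": build_gold_standard(cohort, ref, retained,
                                                grid=grid,
                                                provenance_label="baseline")[0],
            }
            for arm, inter in arms.items():
                for metric, value in _arm_metrics(inter, gold_edges, universe).items():
                    rows.append((size, rep, arm, metric, value))
    records = pd.DataFrame(rows, columns=["size", "rep", "arm", "metric", "value"])
    summary = (records.groupby(["size", "arm", "metric"])["value"]
               .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
               .reset_index())
    return BenchmarkResult(records=records, summary=summary,
                           gold_edges=gold_edges, universe=universe)
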