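"""Weighted bipartite ligand-receptor candidate graph and partial correlations.

Nodes are (cell type, gene, role) triples; an edge connects a ligand node to
a receptor node whenever the gene pair appears in the reference list and both
genes survive expression filtering in their respective cell types.  Edge
weights are Pearson correlations over the paired samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
from scipy import stats

from .ingest import ExpressionMatrix, LRReference, LOG_SCALED

logger = logging.getLogger(__name__)

LIGAND = "ligand"
RECEPTOR = "receptor"


class LRNode(NamedTuple):
    cell_type: str
    gene: str
    role: str

    def label(self) -> str:
        return f"{self.cell_type}|{self.gene}|{self.role}"


EdgeKey = tuple[LRNode, LRNode]  # (ligand node, receptor node)


@dataclass
class LRGraph:
    """Bipartite candidate interaction graph.

    ``edges`` maps (ligand node, receptor node) -> Pearson r.  ``spearman``
    optionally carries Spearman correlations for the alternative community
    weighting mode.
    """

    edges: dict[EdgeKey, float]
    n_samples: int
    spearman: dict[EdgeKey, float] | None = None

    def __post_init__(self) -> None:
        for (lig, rec), w in self.edges.items():
            if lig.role != LIGAND or rec.role != RECEPTOR:
                raise ValueError(f"edge {lig} -> {rec} violates bipartite roles")
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight on edge {lig} -> {rec}")

    @property
    def nodes(self) -> set[LRNode]:
        out: set[LRNode] = set()
        for lig, rec in self.edges:
            out.add(lig)
            out.add(rec)
        return out

    def to_networkx(self, weight_mode: str = "abs_pearson") -> nx.Graph:
        """Undirected view with nonnegative weights for community detection."""
        g = nx.Graph()
        source = self.edges if weight_mode in ("abs_pearson", "pearson") else self.spearman
        if weight_mode in ("abs_spearman", "spearman") and self.spearman is None:
            raise ValueError("graph was built without Spearman correlations")
        for key, w in self.edges.items():
            lig, rec = key
            r = source[key]
            g.add_edge(lig, rec, weight=abs(r) if weight_mode.startswith("abs") else r,
                       pearson=w)
        return g

    def write_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ligand_celltype\tligand_gene\treceptor_celltype\treceptor_gene\tweight\n")
            for (lig, rec), w in sorted(self.edges.items()):
                fh.write(f"{lig.cell_type}\t{lig.gene}\t{rec.cell_type}\t{rec.gene}\t{w:.10g}\n")

    @classmethod
    def read_edgelist(cls, path: str | Path, n_samples: int = 0) -> "LRGraph":
        edges: dict[EdgeKey, float] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("ligand_celltype"):
                raise ValueError(f"{path} is not an edge-list TSV")
            for line in fh:
                lct, lg, rct, rg, w = line.rstrip("\n").split("\t")
                edges[(LRNode(lct, lg, LIGAND), LRNode(rct, rg, RECEPTOR))] = float(w)
        return cls(edges=edges, n_samples=n_samples)

    def write_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        for (lig, rec), w in self.edges.items():
            for node in (lig, rec):
                g.add_node(node.label(), cell_type=node.cell_type,
                           gene=node.gene, role=node.role)
            g.add_edge(lig.label(), rec.label(), weight=w)
        nx.write_graphml(g, path)


def build_lr_graph(
    expr: ExpressionMatrix,
    ref: LRReference,
    retained: dict[str, Iterable[str]] | None = None,
    min_samples: int = 3,
    force: bool = False,
    compute_spearman: bool = False,
) -> LRGraph:
    """Enumerate reference-supported LR edges across all cell-type pairs.

    For each reference pair (ligand gene, receptor gene) and each ordered
    cell-type pair (including autocrine, sender == receiver), an edge is
    created when the ligand is retained in the sender and the receptor in
    the receiver.  Degenerate self-edges (identical (cell type, gene)
    variable on both ends) are dropped with a warning.  Genes flagged as
    constant are excluded (their correlation is undefined).
    """
    if expr.scale_state != LOG_SCALED:
        raise ValueError("build_lr_graph expects log_scaled expression")
    n = expr.n_samples
    if n < min_samples and not force:
        raise ValueError(f"only {n} samples; correlations are unstable below "
                         f"{min_samples} (pass force=True to override)")
    if retained is None:
        retained = {ct: expr.genes(ct) for ct in expr.cell_types}
    retained_sets = {
        ct: {g for g in genes
             if expr.has_gene(ct, g) and not expr.is_constant(ct, g)}
        for ct, genes in retained.items()
    }
    cell_types = [ct for ct in expr.cell_types if ct in retained_sets]

    edges: dict[EdgeKey, float] = {}
    spearman: dict[EdgeKey, float] | None = {} if compute_spearman else None
    n_degenerate = 0
    for lig_gene, rec_gene in sorted(ref.pairs):
        for ca in cell_types:
            if lig_gene not in retained_sets[ca]:
                continue
            x = expr.row(ca, lig_gene)
            for cb in cell_types:
                if rec_gene not in retained_sets[cb]:
                    continue
                if ca == cb and lig_gene == rec_gene:
                    n_degenerate += 1
                    continue
                y = expr.row(cb, rec_gene)
                r = float(np.corrcoef(x, y)[0, 1])
                key = (LRNode(ca, lig_gene, LIGAND), LRNode(cb, rec_gene, RECEPTOR))
                edges[key] = r
                if spearman is not None:
                    spearman[key] = float(stats.spearmanr(x, y).statistic)
    if n_degenerate:
        logger.warning("dropped %d degenerate self-pair edge(s) "
                       "(same gene, same cell type)", n_degenerate)
    logger.info("built LR graph: %d edges over %d candidate cell types (n=%d)",
                len(edges), len(cell_types), n)
    return LRGraph(edges=edges, n_samples=n, spearman=spearman)


def partial_correlation_triplet(r_ab: float, r_ac: float, r_bc: float) -> float:
    """First-order partial correlation of A and B controlling for C."""
    for name, r in (("r_ab", r_ab), ("r_ac", r_ac), ("r_bc", r_bc)):
        if not -1.0 < r < 1.0:
            if name == "r_ab" and abs(r) == 1.0:
                # |r_ab| = 1 is allowed by the formula itself
                continue
            raise ValueError(f"{name}={r} outside (-1, 1); partial correlation undefined")
    denom = np.sqrt((1.0 - r_ac ** 2) * (1.0 - r_bc ** 2))
    return float((r_ab - r_ac * r_bc) / denom)


def partial_correlation_matrix(R: np.ndarray, cond_tol: float = 1e-10) -> np.ndarray:
    """Full-order partial correlations from a correlation matrix.

    P_ij = -Theta_ij / sqrt(Theta_ii Theta_jj) with Theta = R^-1; the
    diagonal is set to 1.  Rejects asymmetric, non-unit-diagonal or
    numerically singular input.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have unit diagonal")
    w = np.linalg.eigvalsh(R)
    if w[0] <= cond_tol * w[-1]:
        raise np.linalg.LinAlgError("R is singular or ill-conditioned")
    theta = np.linalg.inv(R)
    d = np.sqrt(np.diag(theta))
    P = -theta / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P
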