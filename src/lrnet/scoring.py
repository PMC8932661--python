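"""Subpopulation projection, prognostic scoring and signaling influence.

A coarse interactome inferred on flow-sorted cell types can be refined with
single-cell subpopulation profiles: each coarse edge is re-labeled by every
(sender subpopulation, receiver subpopulation) combination in which the
ligand is differentially expressed above an expression floor and the
receptor is expressed above the same floor.  The refined network supports
three scores: a prognostic score per subpopulation (expression-weighted
mean of survival z-scores over its secreted DE ligands), a sender-
standardized cross-talk score between subpopulation pairs, and a
downstream-influence score per receptor from eigenvector centrality on a
correlation-weighted signaling network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .graph import EdgeKey, LIGAND, LRNode, RECEPTOR
from .interactome import Interactome

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = ["subpop", "parent", "gene", "avg_expr", "scaled_avg",
                   "de_flag", "secreted"]


@dataclass
class SubpopulationProfile:
    """Tidy per-(subpopulation, gene) summary of a single-cell dataset.

    ``table`` columns: subpop, parent, gene, avg_expr (normalized log-scale
    mean, nonnegative), scaled_avg (z-scaled mean), de_flag (bool),
    secreted (bool, ligand annotation).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROFILE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"profile table missing columns: {missing}")
        if (self.table["avg_expr"] < 0).any():
            raise ValueError("avg_expr must be nonnegative")
        parents = self.table.groupby("subpop")["parent"].nunique()
        if (parents > 1).any():
            bad = parents[parents > 1].index.tolist()
            raise ValueError(f"subpopulations with multiple parents: {bad}")

    @property
    def parent_map(self) -> dict[str, str]:
        return dict(self.table.drop_duplicates("subpop")
                    .set_index("subpop")["parent"])

    def lookup(self, subpop: str, gene: str) -> pd.Series | None:
        hit = self.table[(self.table["subpop"] == subpop)
                         & (self.table["gene"] == gene)]
        return None if hit.empty else hit.iloc[0]


def average_by_subpopulation(
    cells: pd.DataFrame,
    labels: pd.Series | dict,
    patients: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Mean expression per subpopulation (rows) x gene (columns).

    ``cells`` is cell x gene.  With ``patients`` given, averaging is
    patient-balanced: per-(patient, subpopulation) means are averaged over
    patients, so patients with many cells do not dominate.
    """
    labels = pd.Series(labels).reindex(cells.index)
    if labels.isna().any():
        raise ValueError("every cell must carry a subpopulation label")
    counts = labels.value_counts()
    if (counts == 0).any():  # pragma: no cover - value_counts drops zeros
        raise ValueError("subpopulation with zero cells")
    if patients is None:
        return cells.groupby(labels).mean()
    patients = pd.Series(patients).reindex(cells.index)
    per_patient = cells.groupby([labels, patients]).mean()
    return per_patient.groupby(level=0).mean()


class ProjectedEdge(NamedTuple):
    edge: EdgeKey            # subpopulation-resolved
    parent_edge: EdgeKey     # coarse interactome edge


@dataclass
class ProjectedInteractome:
    edges: list[ProjectedEdge]
    expr_threshold: float
    flags: dict = field(default_factory=dict)

    @property
    def edge_set(self) -> set[EdgeKey]:
        return {pe.edge for pe in self.edges}

    def by_parent(self) -> dict[EdgeKey, list[ProjectedEdge]]:
        out: dict[EdgeKey, list[ProjectedEdge]] = {}
        for pe in self.edges:
            out.setdefault(pe.parent_edge, []).append(pe)
        return out


def project_to_subpopulations(
    interactome: Interactome,
    profile: SubpopulationProfile,
    expr_threshold: float = 0.4,
) -> ProjectedInteractome:
    """Re-label coarse edges by qualifying subpopulation combinations.

    A sender subpopulation qualifies when the ligand is DE-flagged with
    avg_expr above the threshold there; a receiver qualifies when the
    receptor's avg_expr exceeds the threshold.  One projected edge is
    emitted per qualifying (sender, receiver) combination (product rule).
    """
    parent_map = profile.parent_map
    coarse_cts = {n.cell_type for n in interactome.nodes}
    orphan = sorted(set(parent_map.values()) - coarse_cts)
    if orphan:
        raise ValueError(f"subpopulation parents absent from interactome: {orphan}")

    t = profile.table
    projected: list[ProjectedEdge] = []
    for edge in sorted(interactome.edges):
        lig, rec = edge
        senders = t[(t["parent"] == lig.cell_type) & (t["gene"] == lig.gene)
                    & t["de_flag"] & (t["avg_expr"] > expr_threshold)]["subpop"]
        receivers = t[(t["parent"] == rec.cell_type) & (t["gene"] == rec.gene)
                      & (t["avg_expr"] > expr_threshold)]["subpop"]
        for s in senders:
            for r in receivers:
                sub_edge = (LRNode(s, lig.gene, LIGAND), LRNode(r, rec.gene, RECEPTOR))
                projected.append(ProjectedEdge(edge=sub_edge, parent_edge=edge))
    logger.info("projected %d coarse edges into %d subpopulation edges",
                len(interactome.edges), len(projected))
    return ProjectedInteractome(edges=projected, expr_threshold=expr_threshold)


def autocrine_conversion_stats(
    interactome: Interactome, projected: ProjectedInteractome
) -> dict[str, float]:
    """Fraction of coarse autocrine edges projecting across subpopulations.

    ``any``: at least one projected edge joins distinct subpopulations;
    ``all``: every projected edge does.  Coarse autocrine edges with no
    projection are excluded from the denominators.
    """
    by_parent = projected.by_parent()
    n_auto = n_any = n_all = 0
    for edge, record in interactome.edges.items():
        lig, rec = edge
        if lig.cell_type != rec.cell_type:
            continue
        children = by_parent.get(edge, [])
        if not children:
            continue
        n_auto += 1
        cross = [pe.edge[0].cell_type != pe.edge[1].cell_type for pe in children]
        n_any += any(cross)
        n_all += all(cross)
    if n_auto == 0:
        return {"any": float("nan"), "all": float("nan"), "n_autocrine": 0}
    return {"any": n_any / n_auto, "all": n_all / n_auto, "n_autocrine": n_auto}


@dataclass
class PrognosticTable:
    scores: dict[str, float]              # subpop -> weighted z-score
    excluded: dict[str, str]              # subpop -> reason
    n_ligands: dict[str, int] = field(default_factory=dict)


def prognostic_score(
    profile: SubpopulationProfile,
    z_scores: dict[str, float],
    secreted_ligands: set[str] | None = None,
    min_ligands: int = 3,
) -> PrognosticTable:
    """Expression-weighted survival score per subpopulation.

    Over qualifying ligands L (DE-flagged, annotated secreted, covered by
    the z-score table): a = sum_L e_L * z_L and b = sum_L e_L, score = a/b.
    Subpopulations with fewer than ``min_ligands`` qualifying secreted DE
    ligands are excluded with reason ``min_ligands``.  The score is a convex
    combination of the ligand z-scores, hence bounded by their range.
    """
    t = profile.table
    scores: dict[str, float] = {}
    excluded: dict[str, str] = {}
    n_used: dict[str, int] = {}
    for subpop, sub in t.groupby("subpop"):
        de = sub[sub["de_flag"]]
        rows = []
        n_secreted_de = 0
        for _, row in de.iterrows():
            gene = row["gene"]
            is_secreted = bool(row["secreted"]) if secreted_ligands is None \
                else gene in secreted_ligands
            if not is_secreted:
                continue
            n_secreted_de += 1
            if gene not in z_scores:
                logger.warning("ligand %s lacks a prognostic z-score; skipped", gene)
                continue
            rows.append((float(row["avg_expr"]), float(z_scores[gene])))
        if len(rows) < min_ligands or n_secreted_de < min_ligands:
            excluded[subpop] = "min_ligands"
            continue
        b = sum(e for e, _ in rows)
        if b == 0:
            raise ValueError(f"zero total ligand expression in {subpop}")
        a = sum(e * z for e, z in rows)
        scores[subpop] = a / b
        n_used[subpop] = len(rows)
    return PrognosticTable(scores=scores, excluded=excluded, n_ligands=n_used)


def filter_pairs_by_prognosis(
    projected: ProjectedInteractome,
    table: PrognosticTable,
    profile: SubpopulationProfile,
) -> tuple[list[ProjectedEdge], dict[str, int]]:
    """Prognosis-guided edge filter.

    Drops edges whose receptor has scaled average expression below zero,
    and edges touching subpopulations excluded from scoring; among edges
    sharing the same (ligand gene, receptor gene) the pair with the closest
    sender/receiver prognostic scores is kept (all tied minimizers kept).
    """
    dropped = {"receptor_expression": 0, "unscored_subpop": 0, "not_argmin": 0}
    survivors: list[ProjectedEdge] = []
    for pe in projected.edges:
        lig, rec = pe.edge
        if lig.cell_type not in table.scores or rec.cell_type not in table.scores:
            dropped["unscored_subpop"] += 1
            continue
        hit = profile.lookup(rec.cell_type, rec.gene)
        if hit is None or float(hit["scaled_avg"]) < 0.0:
            dropped["receptor_expression"] += 1
            continue
        survivors.append(pe)

    groups: dict[tuple[str, str], list[ProjectedEdge]] = {}
    for pe in survivors:
        lig, rec = pe.edge
        groups.setdefault((lig.gene, rec.gene), []).append(pe)
    kept: list[ProjectedEdge] = []
    for members in groups.values():
        gaps = [abs(table.scores[pe.edge[0].cell_type]
                    - table.scores[pe.edge[1].cell_type]) for pe in members]
        best = min(gaps)
        winners = [pe for pe, gap in zip(members, gaps) if gap == best]
        if len(winners) > 1:
            logger.info("tie on prognostic gap for %s: keeping %d edges",
                        members[0].edge[0].gene, len(winners))
        dropped["not_argmin"] += len(members) - len(winners)
        kept.extend(winners)
    return kept, dropped


@dataclass
class CrosstalkMatrix:
    counts: pd.DataFrame       # sender x receiver integer counts
    standardized: pd.DataFrame  # per-sender z-scored rows
    constant_senders: list[str] = field(default_factory=list)


def crosstalk_matrix(
    edges: Iterable[EdgeKey | ProjectedEdge], mode: str = "zscore"
) -> CrosstalkMatrix:
    """Sender x receiver interaction counts with per-sender standardization.

    ``zscore`` mode z-scores each sender row (sample SD); constant rows map
    to zeros and are flagged.  ``proportion`` mode divides each row by its
    total instead.
    """
    keys = [(pe.edge if isinstance(pe, ProjectedEdge) else pe) for pe in edges]
    senders = sorted({lig.cell_type for lig, _ in keys})
    receivers = sorted({rec.cell_type for _, rec in keys})
    if len(receivers) < 2:
        raise ValueError("cross-talk standardization needs >= 2 receivers")
    counts = pd.DataFrame(0, index=senders, columns=receivers, dtype=int)
    for lig, rec in keys:
        counts.loc[lig.cell_type, rec.cell_type] += 1

    arr = counts.to_numpy(dtype=float)
    constant: list[str] = []
    if mode == "zscore":
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        const = (sd[:, 0] == 0)
        sd[const] = 1.0
        std = (arr - mu) / sd
        std[const, :] = 0.0
        constant = [s for s, c in zip(senders, const) if c]
    elif mode == "proportion":
        totals = arr.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        std = arr / totals
    else:
        raise ValueError(f"unknown mode {mode!r}")
    standardized = pd.DataFrame(std, index=senders, columns=receivers)
    return CrosstalkMatrix(counts=counts, standardized=standardized,
                           constant_senders=constant)


def _power_iteration(A: np.ndarray, tol: float = 1e-10,
                     max_iter: int = 10000) -> np.ndarray:
    # iterate on A + cI: same eigenvectors, and the shift guarantees a
    # dominant eigenvalue even on bipartite graphs (lambda_min = -lambda_max)
    if A.sum() == 0:
        raise ValueError("zero adjacency; centrality undefined")
    shift = float(A.sum(axis=1).max())
    M = A + shift * np.eye(A.shape[0])
    x = np.ones(A.shape[0])
    x /= np.linalg.norm(x)
    for _ in range(max_iter):
        y = M @ x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            return y
        x = y
    raise RuntimeError("eigenvector centrality power iteration did not converge")


def downstream_influence(
    receptor_gene: str,
    signaling_genes: Iterable[str],
    ppi_edges: Iterable[tuple[str, str]],
    expr: pd.DataFrame,
) -> tuple[float, dict]:
    """Influence of a receptor on its correlated signaling neighborhood.

    The signaling graph has nodes = signaling genes present (non-constant)
    in the expression table and edges = protein-protein interaction pairs
    among them, weighted by |Pearson r|.  Eigenvector centrality is computed
    by power iteration on the connected component containing the receptor,
    normalized to unit maximum; the influence score is log2(1 + c) for the
    receptor's normalized centrality c, mapping [0, 1] onto [0, 1].
    Receptors absent from the graph score 0 with a flag.
    """
    arr = expr.to_numpy(dtype=float)
    variable = arr.std(axis=1) > 0
    present = {g for g, ok in zip(expr.index, variable) if ok}
    nodes = sorted(set(signaling_genes) & present)
    node_ix = {g: k for k, g in enumerate(nodes)}
    p = len(nodes)
    A = np.zeros((p, p))
    X = expr.loc[nodes].to_numpy(dtype=float) if nodes else np.empty((0, 0))
    for a, bgene in ppi_edges:
        if a in node_ix and bgene in node_ix and a != bgene:
            i, j = node_ix[a], node_ix[bgene]
            if A[i, j] == 0.0:
                r = np.corrcoef(X[i], X[j])[0, 1]
                A[i, j] = A[j, i] = abs(float(r))

    if receptor_gene not in node_ix or A[node_ix[receptor_gene]].sum() == 0:
        return 0.0, {"flag": "receptor_absent"}

    # connected component containing the receptor
    comp = {node_ix[receptor_gene]}
    frontier = [node_ix[receptor_gene]]
    while frontier:
        nxt = []
        for i in frontier:
            for j in np.nonzero(A[i])[0]:
                if j not in comp:
                    comp.add(int(j))
                    nxt.append(int(j))
        frontier = nxt
    idx = sorted(comp)
    sub = A[np.ix_(idx, idx)]
    cent = _power_iteration(sub)
    cent = np.abs(cent)
    cent /= cent.max()
    c = float(cent[idx.index(node_ix[receptor_gene])])
    return float(np.log2(1.0 + c)), {"flag": None, "component_size": len(idx),
                                     "centrality": c}
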