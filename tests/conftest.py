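"""Shared fixtures: tiny expression cohorts, toy references, graph builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lrnet.communities import BETWEEN, WITHIN, Community
from lrnet.graph import LIGAND, LRGraph, LRNode, RECEPTOR
from lrnet.ingest import ExpressionMatrix, LRReference, LOG_SCALED, RAW_TPM


def make_expr(arrays: dict[str, dict[str, np.ndarray]],
              scale_state: str = LOG_SCALED) -> ExpressionMatrix:
    """ExpressionMatrix from {cell type: {gene: vector}} literals."""
    n = len(next(iter(next(iter(arrays.values())).values())))
    samples = [f"s{i + 1}" for i in range(n)]
    values = {
        ct: pd.DataFrame(np.vstack([np.asarray(v, dtype=float)
                                    for v in genes.values()]),
                         index=list(genes), columns=samples)
        for ct, genes in arrays.items()
    }
    return ExpressionMatrix(values=values, scale_state=scale_state)


def zscore_rows(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force rows to z-scores so correlation machinery contracts hold."""
    values = {}
    for ct, df in expr.values.items():
        arr = df.to_numpy(dtype=float)
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        values[ct] = pd.DataFrame((arr - mu) / sd, index=df.index, columns=df.columns)
    return ExpressionMatrix(values=values, scale_state=LOG_SCALED)


def expr_from_covariance(cov: np.ndarray, genes_by_ct: dict[str, list[str]],
                         n: int, seed: int) -> ExpressionMatrix:
    """Gaussian cohort with the given variable covariance, z-rescaled.

    Variables are ordered cell type by cell type, gene by gene, matching
    the row order of ``cov``.
    """
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n).T
    arrays: dict[str, dict[str, np.ndarray]] = {}
    k = 0
    for ct, genes in genes_by_ct.items():
        arrays[ct] = {}
        for g in genes:
            arrays[ct][g] = X[k]
            k += 1
    return zscore_rows(make_expr(arrays))


def make_graph(edge_specs: list[tuple[str, str, str, str, float]],
               n_samples: int = 50) -> LRGraph:
    """LRGraph from (lig_ct, lig_gene, rec_ct, rec_gene, weight) tuples."""
    edges = {
        (LRNode(lct, lg, LIGAND), LRNode(rct, rg, RECEPTOR)): w
        for lct, lg, rct, rg, w in edge_specs
    }
    return LRGraph(edges=edges, n_samples=n_samples)


def make_community(edges, kind: str = WITHIN, cid: str = "wc0") -> Community:
    nodes = frozenset(n for e in edges for n in e)
    return Community(id=cid, kind=kind, nodes=nodes,
                     candidate_edges=frozenset(edges))


def pair_community(rho: float, n: int, seed: int,
                   gene_l: str = "L1", gene_r: str = "R1"):
    """Two-variable community whose single edge has population correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    expr = expr_from_covariance(cov, {"ct1": [gene_l, gene_r]}, n=n, seed=seed)
    edge = (LRNode("ct1", gene_l, LIGAND), LRNode("ct1", gene_r, RECEPTOR))
    return make_community([edge]), expr, edge


def random_bipartite_graph(rng: np.random.Generator, n_lig: int = 6,
                           n_rec: int = 6, n_ct: int = 2,
                           edge_prob: float = 0.3) -> LRGraph:
    specs = []
    cts = [f"ct{i + 1}" for i in range(n_ct)]
    for li in range(n_lig):
        for ri in range(n_rec):
            for ca in cts:
                for cb in cts:
                    if rng.random() < edge_prob:
                        specs.append((ca, f"L{li}", cb, f"R{ri}",
                                      float(rng.uniform(-1, 1))))
    if not specs:
        specs.append(("ct1", "L0", "ct1", "R0", 0.5))
    return make_graph(specs)


@pytest.fixture
def toy_reference() -> LRReference:
    pairs = frozenset((f"L{i:02d}", f"R{i:02d}") for i in range(20))
    return LRReference(pairs=pairs)


@pytest.fixture
def raw_expr() -> ExpressionMatrix:
    return make_expr(
        {"m": {"g1": [1, 1, 3, 3], "g2": [0, 0, 0, 0], "g3": [5, 2, 8, 1]},
         "f": {"g1": [2, 2, 2, 4], "g3": [1, 9, 3, 3]}},
        scale_state=RAW_TPM,
    )
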