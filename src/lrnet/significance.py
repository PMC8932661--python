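"""Per-edge, per-community significance via correlation resampling.

The test asks: given the community context, how surprising is the observed
correlation of an LR pair among correlation values that would make the
pipeline call the edge at all?  Procedure:

1. Replace the pair's entry in the community correlation matrix with draws
   from a uniform proposal on (-1, 1) (projecting back to the positive
   definite cone when needed), re-run the community fit for each draw, and
   record whether the edge is kept.
2. Fit a shallow regression tree mapping the substituted correlation to the
   binary call, giving a smooth call function f(u).
3. Build a finite-sample null for chance correlations from a Wishart
   distribution with identity scale and df = n: its correlation-normalized
   off-diagonal entries have the spread of sample correlations between
   independent genes at the study's sample size.  Broad Gaussian draws
   (SD matched to the uniform proposal) are importance-reweighted to that
   null scale, so the null is evaluated wherever the tree was trained.
4. The one-sided p is the null-weighted call mass above the observed
   correlation over the total null-weighted call mass; it is then folded to
   a two-sided p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .communities import Community
from .graph import EdgeKey
from .ingest import ExpressionMatrix
from .precision import (candidate_mask, community_correlation,
                        precision_to_partials, select_lambda)

logger = logging.getLogger(__name__)


@dataclass
class EdgeSignificance:
    edge: EdgeKey
    community_id: str
    r_obs: float
    p_one: float
    p_two: float
    n_reps: int
    seed: int
    degenerate: bool = False


def two_sided(p_one: float) -> float:
    """Fold a one-sided p-value into a two-sided one: 2 * min(p, 1 - p)."""
    if not 0.0 <= p_one <= 1.0:
        raise ValueError(f"p_one={p_one} outside [0, 1]")
    return 2.0 * min(p_one, 1.0 - p_one)


def nearest_pd_correlation(S: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped projection back to a PD correlation matrix."""
    w, V = np.linalg.eigh(S)
    if w[0] >= eig_floor:
        return S
    w = np.clip(w, eig_floor, None)
    out = (V * w) @ V.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return 0.5 * (out + out.T)


def _norm_pdf(x: np.ndarray, sd: float) -> np.ndarray:
    return np.exp(-0.5 * (x / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def edge_pvalue(
    community: Community,
    expr: ExpressionMatrix,
    edge: EdgeKey,
    n_reps: int = 1000,
    seed: int = 0,
    tree_depth: int = 3,
    grid: np.ndarray | None = None,
    structural_penalty: float = 1e6,
) -> EdgeSignificance:
    """Significance of one candidate edge within its community.

    Deterministic for a fixed seed.  If the edge call never varies across
    the resampled correlations the test is uninformative: the result is
    flagged degenerate with p_two = 1.
    """
    if edge not in community.candidate_edges:
        raise ValueError(f"edge {edge} is not a candidate edge of {community.id}")
    S, variables = community_correlation(community, expr)
    index = {v: k for k, v in enumerate(variables)}
    lig, rec = edge
    i = index[(lig.cell_type, lig.gene)]
    j = index[(rec.cell_type, rec.gene)]
    r_obs = float(S[i, j])
    mask = candidate_mask(community, variables)
    n = expr.n_samples
    rng = np.random.default_rng(seed)

    # (1) uniform correlation substitution and pipeline re-calls
    u = rng.uniform(-1.0, 1.0, n_reps)
    b = np.zeros(n_reps)
    for t in range(n_reps):
        S_t = S.copy()
        S_t[i, j] = S_t[j, i] = u[t]
        S_t = nearest_pd_correlation(S_t)
        _, _, theta = select_lambda(S_t, mask, n=n, grid=grid,
                                    structural_penalty=structural_penalty,
                                    context=f"significance {community.id}")
        b[t] = 1.0 if precision_to_partials(theta)[i, j] > 0.0 else 0.0

    if b.min() == b.max():
        logger.info("edge %s call never varies across %d substitutions", edge, n_reps)
        return EdgeSignificance(edge=edge, community_id=community.id,
                                r_obs=r_obs, p_one=0.5, p_two=1.0,
                                n_reps=n_reps, seed=seed, degenerate=True)

    # (2) call function from a depth-limited regression tree
    tree = DecisionTreeRegressor(max_depth=tree_depth, random_state=0)
    tree.fit(u.reshape(-1, 1), b)

    # (3) Wishart finite-sample null scale + importance reweighting
    sd_u = float(u.std(ddof=1))
    g = rng.normal(0.0, sd_u, n_reps)
    z = rng.standard_normal((n_reps, n, 2))  # Wishart(I2, df=n) via outer products
    w11 = np.sum(z[:, :, 0] ** 2, axis=1)
    w22 = np.sum(z[:, :, 1] ** 2, axis=1)
    w12 = np.sum(z[:, :, 0] * z[:, :, 1], axis=1)
    omega = w12 / np.sqrt(w11 * w22)  # correlation-normalized entries
    sd_null = float(omega.std(ddof=1))
    f = tree.predict(g.reshape(-1, 1))
    weights = f * _norm_pdf(g, sd_null) / _norm_pdf(g, sd_u)
    total = float(weights.sum())
    if total <= 0.0:
        raise ValueError("null call mass is zero; cannot form a p-value")

    # (4) one-sided tail mass, folded two-sided
    p_one = float(weights[g > r_obs].sum() / total)
    return EdgeSignificance(edge=edge, community_id=community.id, r_obs=r_obs,
                            p_one=p_one, p_two=two_sided(p_one),
                            n_reps=n_reps, seed=seed)


def write_significance(results: list[EdgeSignificance], path) -> None:
    with open(path, "w") as fh:
        fh.write("ligand_celltype\tligand_gene\treceptor_celltype\treceptor_gene\t"
                 "community_id\tr_obs\tp_one\tp_two\tdegenerate\n")
        for r in results:
            lig, rec = r.edge
            fh.write(f"{lig.cell_type}\t{lig.gene}\t{rec.cell_type}\t{rec.gene}\t"
                     f"{r.community_id}\t{r.r_obs:.6g}\t{r.p_one:.6g}\t"
                     f"{r.p_two:.6g}\t{int(r.degenerate)}\n")
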