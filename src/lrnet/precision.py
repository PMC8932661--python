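"""Per-community penalized precision estimation with structural bipartite zeros.

Each community of candidate LR edges is modeled as a Gaussian Markov random
field over its (cell type, gene) expression variables.  The inverse
correlation matrix is estimated by an L1-penalized maximum-likelihood
(graphical lasso) solver that supports an entrywise penalty matrix:

    maximize  log det(Theta) - tr(S Theta) - sum_ij P_ij |Theta_ij|

Ligand-ligand, receptor-receptor and non-candidate ligand-receptor entries
carry a very large penalty (structural zeros), so conditional dependence can
only be expressed along reference-supported LR pairs.  The lasso level on
candidate entries, lambda, is selected per community by BIC over a fixed
logarithmic grid.  Candidate edges whose estimated partial correlation
-Theta_ij/sqrt(Theta_ii Theta_jj) is strictly positive are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numba import njit

from .communities import Community
from .graph import EdgeKey
from .ingest import ExpressionMatrix, LOG_SCALED

logger = logging.getLogger(__name__)

DEFAULT_STRUCTURAL_PENALTY = 1e6
DEFAULT_GRID = (0.01, 0.9, 20)
NONZERO_TOL = 1e-8

Variable = tuple[str, str]  # (cell type, gene)


class ConvergenceError(RuntimeError):
    """Raised when the penalized solver fails to converge."""


def lambda_grid(low: float = DEFAULT_GRID[0], high: float = DEFAULT_GRID[1],
                num: int = DEFAULT_GRID[2]) -> np.ndarray:
    """Logarithmically spaced lasso grid (default 20 points on [0.01, 0.9])."""
    return np.geomspace(low, high, num)


@dataclass
class PenaltySpec:
    """Entrywise penalties for one community fit.

    ``candidate_mask`` marks entries penalized at ``lam``; every other
    off-diagonal entry receives ``structural_penalty``.  The diagonal is
    unpenalized.
    """

    lam: float
    candidate_mask: np.ndarray  # boolean, symmetric, zero diagonal
    structural_penalty: float = DEFAULT_STRUCTURAL_PENALTY

    @property
    def penalty_matrix(self) -> np.ndarray:
        p = self.candidate_mask.shape[0]
        P = np.full((p, p), self.structural_penalty, dtype=float)
        P[self.candidate_mask] = self.lam
        np.fill_diagonal(P, 0.0)
        return P


class KeptEdge(NamedTuple):
    edge: EdgeKey
    pearson_r: float
    partial_r: float
    community_id: str
    kind: str


@dataclass
class RegularizedCommunity:
    community: Community
    variables: list[Variable]
    S: np.ndarray
    theta: np.ndarray
    partials: np.ndarray
    lambda_star: float
    bic_trace: list[tuple[float, float]]
    kept_edges: list[KeptEdge]


def community_variables(community: Community) -> list[Variable]:
    """Unique (cell type, gene) variables of a community, sorted.

    A gene acting as both ligand and receptor in the same cell type maps to
    a single expression variable.
    """
    return sorted({(n.cell_type, n.gene) for n in community.nodes})


def community_correlation(
    community: Community, expr: ExpressionMatrix
) -> tuple[np.ndarray, list[Variable]]:
    """Sample correlation matrix over the community's expression variables."""
    if expr.scale_state != LOG_SCALED:
        raise ValueError("community_correlation expects log_scaled expression")
    variables = community_variables(community)
    rows = []
    for ct, gene in variables:
        if expr.is_constant(ct, gene):
            raise ValueError(f"variable ({ct}, {gene}) is constant; correlation undefined")
        rows.append(expr.row(ct, gene))
    X = np.vstack(rows)
    if X.shape[0] == 1:
        return np.ones((1, 1)), variables
    S = np.corrcoef(X)
    np.fill_diagonal(S, 1.0)
    return S, variables


def candidate_mask(community: Community, variables: list[Variable]) -> np.ndarray:
    """Boolean mask of variable pairs carried by candidate LR edges."""
    index = {v: i for i, v in enumerate(variables)}
    p = len(variables)
    mask = np.zeros((p, p), dtype=bool)
    for lig, rec in community.candidate_edges:
        i = index[(lig.cell_type, lig.gene)]
        j = index[(rec.cell_type, rec.gene)]
        if i != j:
            mask[i, j] = mask[j, i] = True
    return mask


@njit(cache=True)
def _glasso_cd(S, P, B, tol, max_iter, inner_tol, inner_max):  # pragma: no cover
    """Block coordinate-descent graphical lasso with entrywise penalties.

    Returns (W, B, iterations); iterations == -1 signals non-convergence.
    B holds per-column lasso coefficients and may carry a warm start.
    """
    p = S.shape[0]
    W = S.copy()
    # restore warm-started covariance columns from B
    for j in range(p):
        has = False
        for k in range(p):
            if B[k, j] != 0.0:
                has = True
        if has:
            for i in range(p):
                if i != j:
                    acc = 0.0
                    for l in range(p):
                        if l != j:
                            acc += W[i, l] * B[l, j]
                    W[i, j] = acc
                    W[j, i] = acc
    # relative tolerance scale: mean |off-diagonal S|
    scale = 0.0
    cnt = 0
    for i in range(p):
        for j in range(p):
            if i != j:
                scale += abs(S[i, j])
                cnt += 1
    scale = scale / cnt if cnt > 0 else 0.0
    thr = tol * scale if scale > 0 else tol

    v = np.zeros(p)
    for it in range(max_iter):
        delta = 0.0
        for j in range(p):
            # v[i] = sum_{l != j} W[i, l] * B[l, j]
            for i in range(p):
                v[i] = 0.0
            for l in range(p):
                if l != j and B[l, j] != 0.0:
                    bl = B[l, j]
                    for i in range(p):
                        v[i] += W[i, l] * bl
            for inner in range(inner_max):
                maxd = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j] - (v[k] - W[k, k] * B[k, j])
                    pen = P[k, j]
                    if r > pen:
                        nb = (r - pen) / W[k, k]
                    elif r < -pen:
                        nb = (r + pen) / W[k, k]
                    else:
                        nb = 0.0
                    d = nb - B[k, j]
                    if d != 0.0:
                        ad = abs(d)
                        if ad > maxd:
                            maxd = ad
                        for i in range(p):
                            v[i] += W[i, k] * d
                        B[k, j] = nb
                if maxd < inner_tol:
                    break
            for i in range(p):
                if i != j:
                    ch = abs(W[i, j] - v[i])
                    if ch > delta:
                        delta = ch
                    W[i, j] = v[i]
                    W[j, i] = v[i]
        if delta < thr:
            return W, B, it + 1
    return W, B, -1


def fit_penalized_precision(
    S: np.ndarray,
    penalty: PenaltySpec | np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 500,
    warm_B: np.ndarray | None = None,
    context: str = "",
) -> np.ndarray:
    """Estimate a sparse precision matrix under entrywise L1 penalties.

    Entries with very large penalties are driven exactly to zero by the
    soft-thresholding updates, realizing structural zeros.  Raises
    :class:`ConvergenceError` if the covariance sweep does not stabilize
    within ``max_iter`` sweeps.
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    if S.shape != (p, p) or not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be a symmetric square matrix")
    P = penalty.penalty_matrix if isinstance(penalty, PenaltySpec) else np.asarray(penalty, float)
    if P.shape != S.shape:
        raise ValueError("penalty matrix shape mismatch")
    if p == 1:
        return np.array([[1.0 / S[0, 0]]])
    B = np.zeros((p, p)) if warm_B is None else warm_B
    W, B, iters = _glasso_cd(S, P, B, tol, max_iter, min(tol * 1e-2, 1e-6), 200)
    if iters < 0:
        raise ConvergenceError(f"penalized precision fit did not converge "
                               f"in {max_iter} sweeps ({context})")
    theta = np.zeros((p, p))
    for j in range(p):
        beta = B[:, j].copy()
        beta[j] = 0.0
        denom = W[j, j] - float(W[:, j] @ beta)
        if denom <= 0:
            raise ConvergenceError(f"non-positive conditional variance ({context})")
        theta[j, j] = 1.0 / denom
        theta[:, j] -= beta / denom
        theta[j, j] = 1.0 / denom
    theta = 0.5 * (theta + theta.T)
    return theta


def precision_to_partials(theta: np.ndarray) -> np.ndarray:
    """Partial correlations -Theta_ij / sqrt(Theta_ii Theta_jj), unit diagonal."""
    d = np.sqrt(np.diag(theta))
    P = -theta / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def _gaussian_loglik(theta: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - float(np.trace(S @ theta)))


def model_df(theta: np.ndarray) -> int:
    """Estimated degrees of freedom: nonzero upper-triangle off-diagonals."""
    iu = np.triu_indices_from(theta, k=1)
    return int(np.sum(np.abs(theta[iu]) > NONZERO_TOL))


def select_lambda(
    S: np.ndarray,
    mask: np.ndarray,
    n: int,
    grid: np.ndarray | None = None,
    structural_penalty: float = DEFAULT_STRUCTURAL_PENALTY,
    tol: float = 1e-4,
    max_iter: int = 500,
    context: str = "",
) -> tuple[float, list[tuple[float, float]], np.ndarray]:
    """BIC selection of the candidate-entry lasso level.

    Fits the penalized precision at each grid value (descending, with warm
    starts) and scores BIC = -2 * loglik + log(n) * df, where the
    log-likelihood is (n/2)(log det Theta - tr(S Theta)) and df counts
    estimated nonzero off-diagonal entries.  Ties resolve to the larger
    lambda (the sparser model).
    """
    if grid is None:
        grid = lambda_grid()
    grid = np.sort(np.asarray(grid, dtype=float))
    p = S.shape[0]
    trace: list[tuple[float, float]] = []
    fits: dict[float, np.ndarray] = {}
    B = np.zeros((p, p))
    for lam in grid[::-1]:
        spec = PenaltySpec(lam=lam, candidate_mask=mask,
                           structural_penalty=structural_penalty)
        try:
            theta = fit_penalized_precision(S, spec, tol=tol, max_iter=max_iter,
                                            warm_B=B, context=f"{context} lambda={lam:.4g}")
        except ConvergenceError as exc:
            logger.warning("fit failed: %s", exc)
            B = np.zeros((p, p))
            continue
        bic = -2.0 * _gaussian_loglik(theta, S, n) + np.log(n) * model_df(theta)
        trace.append((float(lam), float(bic)))
        fits[float(lam)] = theta
    if not fits:
        raise ConvergenceError(f"all lambda fits failed ({context})")
    trace.sort(key=lambda t: t[0])
    # argmin BIC; ties -> larger lambda
    best_lam, best_bic = trace[0]
    for lam, bic in trace[1:]:
        if bic <= best_bic + 1e-12:
            best_lam, best_bic = lam, bic
    return best_lam, trace, fits[best_lam]


def binarize_community(reg: RegularizedCommunity) -> list[KeptEdge]:
    """Candidate edges with strictly positive estimated partial correlation."""
    index = {v: i for i, v in enumerate(reg.variables)}
    kept: list[KeptEdge] = []
    for edge in sorted(reg.community.candidate_edges):
        lig, rec = edge
        i = index[(lig.cell_type, lig.gene)]
        j = index[(rec.cell_type, rec.gene)]
        partial = float(reg.partials[i, j])
        if partial > 0.0:
            kept.append(KeptEdge(edge=edge, pearson_r=float(reg.S[i, j]),
                                 partial_r=partial,
                                 community_id=reg.community.id,
                                 kind=reg.community.kind))
    return kept


def fit_community(
    community: Community,
    expr: ExpressionMatrix,
    grid: np.ndarray | None = None,
    structural_penalty: float = DEFAULT_STRUCTURAL_PENALTY,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> RegularizedCommunity | None:
    """Full community pipeline: correlation, lambda selection, binarization.

    Communities with fewer than two expression variables (or no candidate
    edges) are skipped and return None.
    """
    if not community.candidate_edges:
        return None
    S, variables = community_correlation(community, expr)
    if len(variables) < 2:
        return None
    mask = candidate_mask(community, variables)
    lam, trace, theta = select_lambda(
        S, mask, n=expr.n_samples, grid=grid,
        structural_penalty=structural_penalty, tol=tol, max_iter=max_iter,
        context=f"community {community.id}",
    )
    reg = RegularizedCommunity(
        community=community, variables=variables, S=S, theta=theta,
        partials=precision_to_partials(theta), lambda_star=lam,
        bic_trace=trace, kept_edges=[],
    )
    reg.kept_edges = binarize_community(reg)
    return reg
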