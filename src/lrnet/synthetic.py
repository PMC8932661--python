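"""Ground-truth bipartite Gaussian graphical models and sampled cohorts.

The generator emulates a flow-sorted expression study: a roster of ligand
and receptor genes shared by several cell types, a curated reference of
cognate LR pairs, and a sparse precision matrix whose only off-diagonal
entries sit on a random subset of candidate LR edges (positive partial
correlations).  Cohorts of any sample size are drawn i.i.d. from the implied
multivariate Gaussian, so every stage of the inference pipeline can be
tested against a known edge set without external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import EdgeKey, LIGAND, LRNode, RECEPTOR, partial_correlation_matrix
from .ingest import ExpressionMatrix, LRReference, LOG_SCALED

logger = logging.getLogger(__name__)

MIN_EIGENVALUE = 0.05


@dataclass
class SyntheticTruth:
    cell_types: list[str]
    ligand_genes: list[str]
    receptor_genes: list[str]
    reference: LRReference
    variables: list[tuple[str, str]]  # (cell type, gene), matrix order
    truth_edges: dict[EdgeKey, float]  # edge -> true partial correlation
    Theta_true: np.ndarray
    Sigma_true: np.ndarray  # inverse of Theta, rescaled to unit diagonal
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def var_index(self) -> dict[tuple[str, str], int]:
        return {v: i for i, v in enumerate(self.variables)}

    @property
    def candidate_edges(self) -> set[EdgeKey]:
        """All reference-supported edges across ordered cell-type pairs."""
        out: set[EdgeKey] = set()
        for lig_gene, rec_gene in self.reference.pairs:
            for ca in self.cell_types:
                for cb in self.cell_types:
                    out.add((LRNode(ca, lig_gene, LIGAND),
                             LRNode(cb, rec_gene, RECEPTOR)))
        return out

    @property
    def retained(self) -> dict[str, list[str]]:
        genes = self.ligand_genes + self.receptor_genes
        return {ct: list(genes) for ct in self.cell_types}

    def edge_to_vars(self, edge: EdgeKey) -> tuple[int, int]:
        lig, rec = edge
        idx = self.var_index
        return idx[(lig.cell_type, lig.gene)], idx[(rec.cell_type, rec.gene)]


def generate_truth(
    n_celltypes: int = 3,
    ligands_per_type: int = 10,
    receptors_per_type: int = 10,
    reference_density: float = 0.15,
    edge_prob: float = 0.25,
    rho_range: tuple[float, float] = (0.3, 0.6),
    seed: int = 0,
) -> SyntheticTruth:
    """Build a random sparse bipartite precision structure.

    Steps: sample the reference pair list over the gene roster, enumerate
    candidate edges across all ordered cell-type pairs, keep each with
    probability ``edge_prob``, assign each kept edge a target partial
    correlation drawn uniformly from ``rho_range`` (entered as
    Theta_ij = -rho so partials are positive under the -Theta convention),
    inflate the diagonal uniformly until the smallest eigenvalue reaches
    0.05, and rescale the implied covariance to correlation form.  The
    per-edge partial correlations reported in ``truth_edges`` are recomputed
    after the repair, so they match the final matrices exactly.
    """
    lo, hi = rho_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("rho_range must lie inside (0, 1)")
    if not 0.0 <= edge_prob <= 1.0:
        raise ValueError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    cell_types = [f"ct{i + 1}" for i in range(n_celltypes)]
    ligand_genes = [f"L{i + 1:03d}" for i in range(ligands_per_type)]
    receptor_genes = [f"R{i + 1:03d}" for i in range(receptors_per_type)]

    # reference pairs over the gene roster
    pairs: set[tuple[str, str]] = set()
    for lg in ligand_genes:
        for rg in receptor_genes:
            if rng.random() < reference_density:
                pairs.add((lg, rg))
    if not pairs:  # guarantee a non-empty reference
        lg = ligand_genes[int(rng.integers(len(ligand_genes)))]
        rg = receptor_genes[int(rng.integers(len(receptor_genes)))]
        pairs.add((lg, rg))
    reference = LRReference(pairs=frozenset(pairs))

    variables = [(ct, g) for ct in cell_types for g in ligand_genes + receptor_genes]
    index = {v: i for i, v in enumerate(variables)}
    p = len(variables)

    theta = np.eye(p)
    chosen: list[tuple[EdgeKey, int, int]] = []
    for lig_gene, rec_gene in sorted(pairs):
        for ca in cell_types:
            for cb in cell_types:
                if rng.random() >= edge_prob:
                    continue
                i = index[(ca, lig_gene)]
                j = index[(cb, rec_gene)]
                if i == j or theta[i, j] != 0.0:
                    continue
                rho = float(rng.uniform(lo, hi))
                theta[i, j] = theta[j, i] = -rho
                chosen.append(((LRNode(ca, lig_gene, LIGAND),
                                LRNode(cb, rec_gene, RECEPTOR)), i, j))

    # uniform diagonal inflation to enforce positive definiteness
    min_eig = float(np.linalg.eigvalsh(theta)[0])
    inflation = 0.0
    if min_eig < MIN_EIGENVALUE:
        inflation = MIN_EIGENVALUE - min_eig
        theta = theta + inflation * np.eye(p)
    if inflation > 5.0:
        raise ValueError(
            f"cannot reach positive definiteness without extreme shrinkage "
            f"(diagonal inflation {inflation:.2f}); lower edge_prob or rho_range"
        )
    if inflation > 1.0:
        logger.warning("diagonal inflation %.2f substantially shrinks the "
                       "effective partial correlations", inflation)

    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    sigma_corr = sigma / np.outer(d, d)
    np.fill_diagonal(sigma_corr, 1.0)
    theta_corr = np.linalg.inv(sigma_corr)
    # exact zero pattern preserved by diagonal scaling; clean numerical dust
    zero_mask = theta == 0.0
    np.fill_diagonal(zero_mask, False)
    theta_corr[zero_mask] = 0.0

    partials = partial_correlation_matrix(sigma_corr)
    truth_edges = {edge: float(partials[i, j]) for edge, i, j in chosen}
    if any(v <= 0 for v in truth_edges.values()):
        raise AssertionError("truth partial correlations must stay positive")

    logger.info("synthetic truth: %d variables, %d reference pairs, %d truth "
                "edges (inflation %.3f)", p, len(pairs), len(truth_edges), inflation)
    return SyntheticTruth(
        cell_types=cell_types, ligand_genes=ligand_genes,
        receptor_genes=receptor_genes, reference=reference,
        variables=variables, truth_edges=truth_edges,
        Theta_true=theta_corr, Sigma_true=sigma_corr, seed=seed,
        config=dict(n_celltypes=n_celltypes, ligands_per_type=ligands_per_type,
                    receptors_per_type=receptors_per_type,
                    reference_density=reference_density, edge_prob=edge_prob,
                    rho_range=list(rho_range), seed=seed,
                    diagonal_inflation=inflation),
    )


def sample_cohort(truth: SyntheticTruth, n: int, seed: int = 0) -> ExpressionMatrix:
    """Draw an n-sample cohort from the truth covariance.

    Rows are re-z-scaled per gene (sample SD), matching the ``log_scaled``
    state the inference pipeline expects.
    """
    if n < 3:
        raise ValueError("cohort size must be at least 3")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(truth.Sigma_true)
    X = rng.standard_normal((n, len(truth.variables))) @ chol.T  # n x p
    X = X.T  # p x n
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd

    samples = [f"s{i + 1:04d}" for i in range(n)]
    genes = truth.ligand_genes + truth.receptor_genes
    values: dict[str, pd.DataFrame] = {}
    for ct in truth.cell_types:
        rows = [X[truth.var_index[(ct, g)]] for g in genes]
        values[ct] = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)
    return ExpressionMatrix(values=values, scale_state=LOG_SCALED,
                            constant_genes={ct: [] for ct in truth.cell_types})


def write_truth(truth: SyntheticTruth, out_dir: str | Path) -> None:
    """Persist the truth edge list and configuration echo as text."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "truth_edges.tsv", "w") as fh:
        fh.write("ligand_celltype\tligand_gene\treceptor_celltype\t"
                 "receptor_gene\trho_true\n")
        for (lig, rec), rho in sorted(truth.truth_edges.items()):
            fh.write(f"{lig.cell_type}\t{lig.gene}\t{rec.cell_type}\t"
                     f"{rec.gene}\t{rho:.6f}\n")
    with open(out_dir / "reference_pairs.tsv", "w") as fh:
        fh.write("ligand\treceptor\n")
        for lg, rg in sorted(truth.reference.pairs):
            fh.write(f"{lg}\t{rg}\n")
    with open(out_dir / "config.json", "w") as fh:
        json.dump(truth.config, fh, indent=2)
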