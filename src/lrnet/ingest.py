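"""Reading, normalization and filtering of cell-type-resolved expression data.

The expected input is one tabular file per flow-sorted cell type, rows =
genes, columns = shared sample (patient) identifiers, values in TPM.  All
downstream correlation machinery operates on ``log2(TPM + 1)`` values that
have been z-scaled per gene within each cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RAW_TPM = "raw_tpm"
LOG = "log"
LOG_SCALED = "log_scaled"

_SCALE_STATES = (RAW_TPM, LOG, LOG_SCALED)


@dataclass
class ExpressionMatrix:
    """Per-cell-type gene x sample expression tables over a shared cohort.

    Attributes
    ----------
    values
        Mapping of cell-type label -> DataFrame (genes x samples).  Every
        DataFrame shares the identical ordered sample columns.
    scale_state
        One of ``raw_tpm``, ``log`` (log2(TPM+1)) or ``log_scaled``
        (log-transformed then z-scaled per gene row).
    constant_genes
        Per cell type, genes whose row was constant at scaling time; their
        scaled rows are all zeros and they are excluded from correlations.
    dropped_samples
        Sample IDs discarded because they were absent from at least one
        cell type.
    """

    values: dict[str, pd.DataFrame]
    scale_state: str = RAW_TPM
    constant_genes: dict[str, list[str]] = field(default_factory=dict)
    dropped_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale_state not in _SCALE_STATES:
            raise ValueError(f"unknown scale_state {self.scale_state!r}")
        samples = None
        for ct, df in self.values.items():
            if df.index.has_duplicates:
                dup = df.index[df.index.duplicated()][0]
                raise ValueError(f"duplicate gene {dup!r} in cell type {ct!r}")
            if samples is None:
                samples = list(df.columns)
            elif list(df.columns) != samples:
                raise ValueError("cell types do not share an identical sample list")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values)

    @property
    def samples(self) -> list[str]:
        first = next(iter(self.values.values()))
        return list(first.columns)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def genes(self, cell_type: str) -> list[str]:
        return list(self.values[cell_type].index)

    def row(self, cell_type: str, gene: str) -> np.ndarray:
        """Expression vector of one (cell type, gene) variable."""
        return self.values[cell_type].loc[gene].to_numpy(dtype=float)

    def has_gene(self, cell_type: str, gene: str) -> bool:
        return gene in self.values[cell_type].index

    def is_constant(self, cell_type: str, gene: str) -> bool:
        return gene in self.constant_genes.get(cell_type, [])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        """Restrict to a sample subset (columns), keeping the scale state."""
        vals = {ct: df.loc[:, list(samples)].copy() for ct, df in self.values.items()}
        return ExpressionMatrix(
            values=vals,
            scale_state=self.scale_state,
            constant_genes={ct: list(g) for ct, g in self.constant_genes.items()},
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - message wrapper
        raise ValueError(f"could not read expression table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"expression table {path} has no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def load_expression(
    paths: dict[str, str | Path] | list[str | Path],
    cell_type_labels: list[str] | None = None,
    scale_state: str = RAW_TPM,
) -> ExpressionMatrix:
    """Load one gene x sample table per cell type and pair the cohorts.

    Samples are intersected across cell types (order taken from the first
    table); dropped sample IDs are logged and recorded.  Duplicate gene rows
    within a table are rejected.
    """
    if isinstance(paths, dict):
        items = list(paths.items())
    else:
        if cell_type_labels is None or len(cell_type_labels) != len(paths):
            raise ValueError("cell_type_labels must match the number of paths")
        items = list(zip(cell_type_labels, paths))
    if not items:
        raise ValueError("no expression tables given")

    tables: dict[str, pd.DataFrame] = {}
    for ct, path in items:
        df = _read_table(path)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene row {dup!r} in table for {ct!r}")
        tables[ct] = df

    shared = list(next(iter(tables.values())).columns)
    all_samples: set[str] = set()
    for df in tables.values():
        all_samples.update(df.columns)
        shared = [s for s in shared if s in set(df.columns)]
    if not shared:
        raise ValueError("zero shared samples across cell types")
    dropped = sorted(all_samples - set(shared))
    if dropped:
        logger.warning(
            "dropping %d sample(s) absent from at least one cell type: %s",
            len(dropped), ", ".join(dropped),
        )
    values = {ct: df.loc[:, shared] for ct, df in tables.items()}
    return ExpressionMatrix(values=values, scale_state=scale_state, dropped_samples=dropped)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform; requires raw TPM input."""
    if expr.scale_state != RAW_TPM:
        raise ValueError(f"log_transform expects raw_tpm input, got {expr.scale_state}")
    for ct, df in expr.values.items():
        if (df.to_numpy() < 0).any():
            raise ValueError(f"negative expression values in cell type {ct!r}")
    values = {ct: np.log2(df + 1.0) for ct, df in expr.values.items()}
    return ExpressionMatrix(values=values, scale_state=LOG,
                            dropped_samples=list(expr.dropped_samples))


def scale_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-scale each gene row (sample SD, ddof=1); constant rows -> zeros, flagged."""
    if expr.scale_state != LOG:
        raise ValueError(f"scale_genes expects log input, got {expr.scale_state}")
    values: dict[str, pd.DataFrame] = {}
    constant: dict[str, list[str]] = {}
    for ct, df in expr.values.items():
        arr = df.to_numpy(dtype=float)
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        const_mask = (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
        sd[const_mask] = 1.0
        z = (arr - mu) / sd
        z[const_mask, :] = 0.0
        values[ct] = pd.DataFrame(z, index=df.index, columns=df.columns)
        constant[ct] = [g for g, c in zip(df.index, const_mask) if c]
    return ExpressionMatrix(values=values, scale_state=LOG_SCALED,
                            constant_genes=constant,
                            dropped_samples=list(expr.dropped_samples))


def normalize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Full normalization: log2(TPM+1) then per-gene z-scaling.

    Calling this on already-normalized data is a contract violation and
    raises rather than silently double-transforming.
    """
    return scale_genes(log_transform(expr))


def _equal_frequency_bins(order: list[str], n_bins: int = 3) -> dict[str, int]:
    """Assign ordered items to ``n_bins`` near-equal groups (0 = lowest)."""
    assignment: dict[str, int] = {}
    for b, chunk in enumerate(np.array_split(np.asarray(order, dtype=object), n_bins)):
        for g in chunk:
            assignment[g] = b
    return assignment


def _ranked(values: dict[str, float]) -> list[str]:
    # ties broken deterministically by gene name
    return [g for g, _ in sorted(values.items(), key=lambda kv: (kv[1], kv[0]))]


def filter_genes(
    expr: ExpressionMatrix,
    mode: str = "tpm_threshold",
    threshold: float = 10.0,
    n_bins: int = 3,
) -> dict[str, list[str]]:
    """Per-cell-type gene retention.

    ``tpm_threshold``
        Keep genes whose mean raw TPM exceeds ``threshold`` (default 10).
        Accepts raw TPM input directly, or log input (inverted to the raw
        scale before thresholding).
    ``dispersion_bins``
        On log (unscaled) values: (1) split genes into three equal-frequency
        bins by mean expression and drop the lowest bin; (2) compute the
        dispersion ratio variance/mean per remaining gene, z-normalize it
        within each surviving expression bin, re-bin all survivors into
        three equal-frequency groups by normalized dispersion and drop the
        lowest group.
    """
    retained: dict[str, list[str]] = {}
    if mode == "tpm_threshold":
        for ct, df in expr.values.items():
            if expr.scale_state == RAW_TPM:
                raw = df.to_numpy(dtype=float)
            elif expr.scale_state == LOG:
                raw = np.power(2.0, df.to_numpy(dtype=float)) - 1.0
            else:
                raise ValueError("tpm_threshold needs raw_tpm or log values")
            keep = raw.mean(axis=1) > threshold
            retained[ct] = [g for g, k in zip(df.index, keep) if k]
        return retained

    if mode == "dispersion_bins":
        if expr.scale_state != LOG:
            raise ValueError("dispersion_bins needs log (unscaled) values")
        for ct, df in expr.values.items():
            genes = list(df.index)
            if len(genes) < n_bins:
                raise ValueError(
                    f"cell type {ct!r} has {len(genes)} genes; "
                    f"need at least {n_bins} for binning"
                )
            arr = df.to_numpy(dtype=float)
            means = dict(zip(genes, arr.mean(axis=1)))
            expr_bin = _equal_frequency_bins(_ranked(means), n_bins)
            survivors = [g for g in genes if expr_bin[g] > 0]
            if len(survivors) < n_bins:
                retained[ct] = sorted(survivors)
                continue
            variances = dict(zip(genes, arr.var(axis=1, ddof=1)))
            disp = {}
            for g in survivors:
                m = means[g]
                disp[g] = variances[g] / m if m > 0 else -np.inf
            # z-normalize dispersion within each surviving expression bin
            z_disp: dict[str, float] = {}
            for b in range(1, n_bins):
                members = [g for g in survivors if expr_bin[g] == b]
                vals = np.array([disp[g] for g in members], dtype=float)
                finite = np.isfinite(vals)
                mu = vals[finite].mean() if finite.any() else 0.0
                sd = vals[finite].std(ddof=1) if finite.sum() > 1 else 0.0
                for g, v in zip(members, vals):
                    if not np.isfinite(v):
                        z_disp[g] = -np.inf
                    elif sd > 0:
                        z_disp[g] = (v - mu) / sd
                    else:
                        z_disp[g] = 0.0
            disp_bin = _equal_frequency_bins(_ranked(z_disp), n_bins)
            retained[ct] = [g for g in genes if disp_bin.get(g, 0) > 0]
        return retained

    raise ValueError(f"unknown filter mode {mode!r}")


@dataclass(frozen=True)
class LRReference:
    """Curated ligand-receptor pair list (e.g. FANTOM5-derived)."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("LR reference contains no pairs")

    @property
    def ligand_set(self) -> frozenset[str]:
        return frozenset(l for l, _ in self.pairs)

    @property
    def receptor_set(self) -> frozenset[str]:
        return frozenset(r for _, r in self.pairs)


def load_lr_reference(path: str | Path) -> LRReference:
    """Read a two-column (ligand, receptor) table; duplicates are merged.

    A single header row reading 'ligand<TAB>receptor' (any case) is skipped.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split(sep)
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"malformed LR reference row {lineno} in {path}: {line!r}")
            lig, rec = fields[0].strip(), fields[1].strip()
            if lineno == 1 and (lig.lower(), rec.lower()) == ("ligand", "receptor"):
                continue
            pairs.add((lig, rec))
    if not pairs:
        raise ValueError(f"LR reference {path} is empty")
    ref = LRReference(pairs=frozenset(pairs))
    logger.info(
        "loaded %d LR pairs (%d ligands, %d receptors) from %s",
        len(ref.pairs), len(ref.ligand_set), len(ref.receptor_set), path,
    )
    return ref


def write_expression(expr: ExpressionMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write one TSV per cell type in the same layout ``load_expression`` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ct, df in expr.values.items():
        p = out_dir / f"{ct}.tsv"
        df.to_csv(p, sep="\t", index_label="gene")
        paths[ct] = p
    return paths
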