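"""Quality control and depth normalization of raw counts."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import scipy.sparse as sp

from ._utils import ConfigError

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level filters.

    Defaults are the conventional scRNA-seq choices (no thresholds are
    reported for the emulated study): cells keep 200-6000 detected genes and
    at most 20% mitochondrial counts; genes must be detected in >= 3 cells.
    Mitochondrial genes are identified by the ``MT-`` symbol prefix.
    """

    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 6000
    max_mito_fraction: float = 0.2
    min_cells_per_gene: int = 3

    def validate(self) -> None:
        if self.min_genes_per_cell > self.max_genes_per_cell:
            raise ConfigError("min_genes_per_cell exceeds max_genes_per_cell")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ConfigError("max_mito_fraction must lie in [0, 1]")
        if self.min_cells_per_gene < 0:
            raise ConfigError("min_cells_per_gene must be non-negative")


def filter_cells(adata: ad.AnnData, thresholds: QCThresholds = QCThresholds()) -> tuple[ad.AnnData, dict]:
    """Apply QC filters; returns the filtered view (copied) and a rule report.

    Cells are kept when their detected-gene count lies in
    [min_genes_per_cell, max_genes_per_cell] and their mitochondrial count
    fraction is <= max_mito_fraction; genes are then kept when detected in at
    least min_cells_per_gene of the retained cells.  Cell and gene order is
    preserved.  Raises if nothing survives.
    """
    thresholds.validate()
    X = sp.csr_matrix(adata.X)
    n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_cols = np.array([g.upper().startswith(MITO_PREFIX) for g in adata.var_names])
    if mito_cols.any():
        mito = np.asarray(X[:, mito_cols].sum(axis=1)).ravel()
    else:
        mito = np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)

    low = n_genes < thresholds.min_genes_per_cell
    high = n_genes > thresholds.max_genes_per_cell
    mito_bad = mito_frac > thresholds.max_mito_fraction
    keep_cells = ~(low | high | mito_bad)
    if not keep_cells.any():
        raise ValueError("empty after QC: all cells removed by the cell filters")

    kept = adata[keep_cells].copy()
    detected = np.asarray((sp.csr_matrix(kept.X) > 0).sum(axis=0)).ravel()
    keep_genes = detected >= thresholds.min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("empty after QC: all genes removed by the gene filter")
    out = kept[:, keep_genes].copy()

    report = {
        "n_cells_in": int(adata.n_obs),
        "removed_low_genes": int(low.sum()),
        "removed_high_genes": int(high.sum()),
        "removed_high_mito": int(mito_bad.sum()),
        "n_cells_out": int(out.n_obs),
        "n_genes_in": int(adata.n_vars),
        "removed_genes": int((~keep_genes).sum()),
        "n_genes_out": int(out.n_vars),
    }
    logger.info(
        "QC: %d/%d cells kept (low-gene %d, high-gene %d, mito %d); %d/%d genes kept",
        report["n_cells_out"], report["n_cells_in"], report["removed_low_genes"],
        report["removed_high_genes"], report["removed_high_mito"],
        report["n_genes_out"], report["n_genes_in"],
    )
    return out, report


def normalize_log(adata: ad.AnnData, target_sum: float = 10_000.0) -> ad.AnnData:
    """Scale each cell to ``target_sum`` total counts, then log(1+x).

    Natural log; output stays sparse and non-negative.  A zero-total cell is
    an error (QC is expected to have removed it) and is named in the message.
    """
    if target_sum <= 0:
        raise ConfigError("target_sum must be positive")
    X = sp.csr_matrix(adata.X, dtype=np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = adata.obs_names[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"cannot normalize zero-total cell {bad!r}")
    scale = sp.diags(target_sum / totals)
    X = scale @ X
    X.data = np.log1p(X.data)
    out = adata.copy()
    out.X = sp.csr_matrix(X)
    return out
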