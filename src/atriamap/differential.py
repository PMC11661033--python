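"""Wilcoxon rank-sum differential expression with BH FDR control.

Two entry points mirror the two biological questions: ``rank_markers`` builds
the one-vs-rest marker catalogue per cluster (the union of significant,
upregulated genes across clusters is the pipeline's DEG universe), and
``condition_deg`` contrasts AF against SR within one subcluster.

The scalar test uses the exact rank-sum distribution when the pooled sample
is small (<= 12 values) and tie-free, and the normal approximation with tie
correction and continuity correction otherwise.  The table-level routines use
a vectorised implementation of the same asymptotic test.
"""

from __future__ import annotations

import logging
import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12

DEG_COLUMNS = ("gene", "cluster", "log2fc", "p", "q", "direction")


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (U statistic of x, p-value).

    Exact enumeration when len(x)+len(y) <= 12 with no ties; normal
    approximation with midrank tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    exact = pooled.size <= EXACT_MAX_N and np.unique(pooled).size == pooled.size
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    p = min(max(float(res.pvalue), np.nextafter(0.0, 1.0)), 1.0)
    return float(res.statistic), p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# vectorised rank-sum machinery
# ---------------------------------------------------------------------------

def _tie_terms(X: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tied groups, per column."""
    Xs = np.sort(X, axis=0)
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = Xs[:, j]
        boundaries = np.flatnonzero(np.r_[True, col[1:] != col[:-1], True])
        t = np.diff(boundaries).astype(float)
        out[j] = float((t**3 - t).sum())
    return out


def _rank_sum_block(X: np.ndarray, masks: list[np.ndarray]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Asymptotic rank-sum test of each mask-group vs the rest, per gene.

    ``X`` is cells x genes dense; ranks and tie terms are computed once and
    reused across groups.  Returns per mask the (U, two-sided p) arrays.
    Matches scipy's asymptotic Mann-Whitney with continuity correction.
    """
    n = X.shape[0]
    ranks = scipy.stats.rankdata(X, axis=0)
    ties = _tie_terms(X)
    results = []
    for mask in masks:
        n1 = int(mask.sum())
        n2 = n - n1
        R1 = ranks[mask].sum(axis=0)
        U1 = R1 - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
        sigma = np.sqrt(np.maximum(sigma2, 0.0))
        diff = U1 - mu
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (diff - 0.5 * np.sign(diff)) / sigma
        z[sigma == 0] = 0.0
        p = np.clip(2.0 * scipy.stats.norm.sf(np.abs(z)), np.nextafter(0.0, 1.0), 1.0)
        results.append((U1, p))
    return results


def _log2fc(mean_log_a: np.ndarray, mean_log_b: np.ndarray) -> np.ndarray:
    """Expression-space log2 fold change from mean log1p values, pseudocount 1."""
    return np.log2((np.expm1(mean_log_a) + 1.0) / (np.expm1(mean_log_b) + 1.0))


def _group_tests(adata: ad.AnnData, masks: dict, chunk: int = 512) -> dict[str, pd.DataFrame]:
    """Run every mask-group vs rest over all genes, chunked over genes."""
    X = sp.csr_matrix(adata.X)
    genes = np.asarray(adata.var_names)
    keys = list(masks)
    mask_list = [np.asarray(masks[k], dtype=bool) for k in keys]
    parts: dict[str, list[pd.DataFrame]] = {k: [] for k in keys}
    for start in range(0, X.shape[1], chunk):
        sl = slice(start, min(start + chunk, X.shape[1]))
        block = np.asarray(X[:, sl].todense(), dtype=np.float64)
        stats = _rank_sum_block(block, mask_list)
        for key, mask, (U, p) in zip(keys, mask_list, stats):
            m1 = block[mask].mean(axis=0)
            m0 = block[~mask].mean(axis=0)
            parts[key].append(pd.DataFrame({
                "gene": genes[sl],
                "U": U,
                "p": p,
                "log2fc": _log2fc(m1, m0),
            }))
    return {k: pd.concat(v, ignore_index=True) for k, v in parts.items()}


def rank_markers(adata: ad.AnnData, labels, q_max: float = 0.05, lfc_min: float = 0.25,
                 up_only: bool = True, min_cells: int = 3) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers per cluster on log-normalized values.

    Every gene is tested in every cluster against all other cells; BH
    adjustment is applied within each cluster's gene vector.  Records are
    filtered to q < q_max and log2fc > lfc_min (upregulated only when
    ``up_only``); the union of genes over clusters is the DEG universe.
    Clusters with fewer than ``min_cells`` cells are skipped with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    clusters = sorted(pd.unique(pd.Series(labels)).tolist(), key=str)
    if len(clusters) < 2:
        raise ValueError("rank_markers requires at least 2 clusters")
    masks = {}
    for c in clusters:
        mask = labels == c
        if mask.sum() < min_cells:
            warnings.warn(f"cluster {c!r} has fewer than {min_cells} cells; skipped")
            continue
        masks[c] = mask
    tables = _group_tests(adata, masks)
    records = []
    for c, tab in tables.items():
        tab = tab.assign(cluster=c, q=bh_adjust(tab["p"].to_numpy()))
        tab["direction"] = np.where(tab["log2fc"] > 0, "up", "down")
        keep = (tab["q"] < q_max) & (tab["log2fc"].abs() > lfc_min)
        if up_only:
            keep &= tab["direction"] == "up"
        records.append(tab.loc[keep, list(DEG_COLUMNS)])
    out = pd.concat(records, ignore_index=True) if records else pd.DataFrame(columns=DEG_COLUMNS)
    return out.sort_values(["cluster", "log2fc"], ascending=[True, False], ignore_index=True)


def deg_universe(markers: pd.DataFrame) -> list[str]:
    """Sorted unique genes across all marker records."""
    return sorted(markers["gene"].unique().tolist())


def condition_deg(adata: ad.AnnData, sub_labels, subcluster: str, conditions,
                  min_cells: int = 3) -> pd.DataFrame:
    """SR-vs-AF Wilcoxon test within one subcluster; "up" means higher in AF.

    Returns the full per-gene table (gene, cluster, log2fc, p, q, direction);
    callers filter by q as needed.
    """
    sub_labels = np.asarray(sub_labels, dtype=object)
    conditions = np.asarray(conditions, dtype=object)
    cells = sub_labels == subcluster
    if not cells.any():
        raise ValueError(f"no cells labelled {subcluster!r}")
    cond = conditions[cells]
    for level in ("SR", "AF"):
        if (cond == level).sum() < min_cells:
            raise ValueError(f"subcluster {subcluster!r} has <{min_cells} {level} cells")
    sub = adata[cells]
    af_mask = cond == "AF"
    tab = _group_tests(sub, {"AF": af_mask})["AF"]
    tab = tab.assign(cluster=subcluster, q=bh_adjust(tab["p"].to_numpy()))
    tab["direction"] = np.where(tab["log2fc"] > 0, "up", "down")
    return tab[list(DEG_COLUMNS)]
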