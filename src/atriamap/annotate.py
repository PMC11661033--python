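"""Clustering and marker-panel-based cell-type / subcluster assignment.

The annotation strategy is the transparent, deterministic one: PCA followed by
seeded k-means, over-partitioning the cells relative to the number of major
types, then labelling every cluster by the marker panel whose z-scored mean
expression it maximises.  Subclusters are obtained by re-running the same
procedure within each major type against that type's sub-panel.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from ._utils import derive_seed
from .profiles import MarkerPanel

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 30
DEFAULT_K_MAJOR = 30  # over-partition, then label clusters by marker score


def _matrix(data) -> sp.csr_matrix:
    if isinstance(data, ad.AnnData):
        return sp.csr_matrix(data.X)
    return sp.csr_matrix(data)


def cluster_cells(data, n_components: int = DEFAULT_N_COMPONENTS, k: int = DEFAULT_K_MAJOR,
                  seed: int = 0) -> np.ndarray:
    """PCA + seeded k-means partition of cells into ``k`` clusters.

    Returns an integer cluster id per cell.  Deterministic given ``seed``;
    k=1 trivially assigns everything to cluster 0.
    """
    X = _matrix(data)
    n_cells = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the number of cells ({n_cells})")
    if k == 1:
        return np.zeros(n_cells, dtype=int)
    n_components = max(1, min(n_components, n_cells - 1, X.shape[1]))
    dense = np.asarray(X.todense(), dtype=np.float32)
    pcs = PCA(n_components=n_components, svd_solver="auto", random_state=seed).fit_transform(dense)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(pcs.astype(np.float64))


def _cluster_means(X: sp.csr_matrix, labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Mean expression per cluster (clusters x genes) and the cluster keys."""
    keys = sorted(pd.unique(pd.Series(labels)).tolist(), key=str)
    means = np.empty((len(keys), X.shape[1]))
    for i, key in enumerate(keys):
        mask = np.asarray(labels == key)
        means[i] = np.asarray(X[mask].mean(axis=0)).ravel()
    return means, keys


def _zscore_rows_across_clusters(means: np.ndarray) -> np.ndarray:
    """z-score each gene (column) across clusters; zero-variance genes -> 0."""
    mu = means.mean(axis=0)
    sd = means.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (means - mu) / sd
    z[:, sd == 0] = 0.0
    return z


def score_markers(data, labels, panel: dict[str, tuple[str, ...]] | MarkerPanel,
                  var_names=None) -> pd.DataFrame:
    """Marker score table: clusters x types.

    score(cluster, type) = mean over the type's present marker genes of the
    cluster-mean expression z-scored across clusters.  Panel genes absent
    from the matrix are logged and skipped; if no panel gene is present at
    all, this is an error.  ``var_names`` is required when ``data`` is a bare
    matrix rather than AnnData.
    """
    if isinstance(panel, MarkerPanel):
        panel = {t: g for t, g in panel.major.items()}
    if var_names is None:
        if not isinstance(data, ad.AnnData):
            raise ValueError("var_names must be given for a bare matrix")
        var_names = data.var_names
    X = _matrix(data)
    gene_index = {g: i for i, g in enumerate(var_names)}
    labels = np.asarray(labels)
    means, keys = _cluster_means(X, labels)
    z = _zscore_rows_across_clusters(means)

    scores = {}
    any_present = False
    for typ, genes in panel.items():
        cols = [gene_index[g] for g in genes if g in gene_index]
        missing = [g for g in genes if g not in gene_index]
        if missing:
            logger.warning("markers absent from matrix for %s: %s", typ, ",".join(missing))
        if not cols:
            scores[typ] = np.zeros(len(keys))
            continue
        any_present = True
        scores[typ] = z[:, cols].mean(axis=1)
    if not any_present:
        raise ValueError("no marker-panel gene is present in the matrix")
    return pd.DataFrame(scores, index=pd.Index(keys, name="cluster"))


def assign_types(scores: pd.DataFrame) -> tuple[dict, list]:
    """Argmax type per cluster; exact ties break to the first panel column.

    Returns (cluster -> type, list of tie-flagged clusters).
    """
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("score table contains non-finite values")
    assignment: dict = {}
    ties: list = []
    for cluster, row in scores.iterrows():
        best = row.max()
        winners = [t for t in scores.columns if row[t] == best]
        assignment[cluster] = winners[0]
        if len(winners) > 1:
            ties.append(cluster)
    return assignment, ties


def _name_subclusters(scores: pd.DataFrame) -> dict:
    """Cluster -> subcluster name; one-to-one (Hungarian) when sizes match."""
    if len(scores.index) == len(scores.columns):
        rows, cols = linear_sum_assignment(-scores.to_numpy())
        return {scores.index[r]: scores.columns[c] for r, c in zip(rows, cols)}
    assignment, _ = assign_types(scores)
    return assignment


def subcluster(data: ad.AnnData, major_labels, panel: MarkerPanel,
               k_map: dict[str, int] | None = None,
               n_components: int = DEFAULT_N_COMPONENTS, seed: int = 0) -> np.ndarray:
    """Re-cluster within each major type and name clusters by the sub-panel.

    ``k_map`` maps major type -> number of subclusters (default: the number
    of sub-panel entries for the type).  A type with k=1 and no (or a single)
    sub-panel entry keeps the major name (or that entry's name).
    """
    major_labels = np.asarray(major_labels, dtype=object)
    if k_map is None:
        k_map = panel.k_map()
    out = np.empty(data.n_obs, dtype=object)
    for major in pd.unique(major_labels):
        mask = major_labels == major
        n_cells = int(mask.sum())
        k = int(k_map.get(major, 1))
        if k > n_cells:
            raise ValueError(f"major type {major!r} has {n_cells} cells, fewer than k={k}")
        sub_panel = dict(panel.sub.get(major, {}))
        if k == 1 or len(sub_panel) <= 1:
            name = next(iter(sub_panel)) if len(sub_panel) == 1 else str(major)
            out[mask] = name
            continue
        sub = data[mask]
        ids = cluster_cells(sub, n_components=n_components, k=k,
                            seed=derive_seed(seed, f"subcluster|{major}"))
        scores = score_markers(sub, ids, sub_panel)
        naming = _name_subclusters(scores)
        out[mask] = np.array([naming[i] for i in ids], dtype=object)
    return out


def annotate_cells(data: ad.AnnData, panel: MarkerPanel,
                   k_major: int = DEFAULT_K_MAJOR,
                   k_map: dict[str, int] | None = None,
                   n_components: int = DEFAULT_N_COMPONENTS,
                   seed: int = 0) -> pd.DataFrame:
    """Full annotation: over-cluster, label major types, then subcluster.

    Returns a per-cell DataFrame with columns cluster_id, major_type,
    subcluster (indexed like ``data.obs``).
    """
    k_major = min(k_major, data.n_obs)
    ids = cluster_cells(data, n_components=n_components, k=k_major,
                        seed=derive_seed(seed, "major-clustering"))
    scores = score_markers(data, ids, panel)
    types, ties = assign_types(scores)
    if ties:
        logger.warning("tied marker scores for clusters: %s", ties)
    major = np.array([types[i] for i in ids], dtype=object)
    sub = subcluster(data, major, panel, k_map=k_map, n_components=n_components, seed=seed)
    return pd.DataFrame(
        {"cluster_id": ids, "major_type": major, "subcluster": sub},
        index=data.obs_names,
    )
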