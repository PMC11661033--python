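"""Expression patterns: partition the DEG universe by cluster-level profile.

Each DEG gets a profile of mean expression per cluster, z-scored within the
gene across clusters; k-means on these profiles groups genes into K patterns
(default K=14, the number of patterns the emulated study reports).  A
pattern's signature is the ordered set of clusters whose centroid value
exceeds the signature threshold (default z > 1) — the clusters the pattern
"belongs to".  Pattern ids are ordered by the cluster index of the centroid
argmax so that reports are stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans

DEFAULT_K = 14
DEFAULT_SIGNATURE_Z = 1.0


def pattern_matrix(adata: ad.AnnData, labels, genes) -> pd.DataFrame:
    """Gene x cluster matrix of cluster-mean expression, z-scored per gene.

    All requested genes must be present; a gene constant across clusters
    yields an all-zero row (never NaN).
    """
    genes = list(genes)
    missing = [g for g in genes if g not in set(adata.var_names)]
    if missing:
        raise ValueError(f"genes absent from matrix: {','.join(missing)}")
    labels = np.asarray(labels, dtype=object)
    clusters = sorted(pd.unique(pd.Series(labels)).tolist(), key=str)
    if len(clusters) < 2:
        raise ValueError("pattern_matrix requires at least 2 clusters")
    X = sp.csr_matrix(adata[:, genes].X)
    means = np.empty((len(genes), len(clusters)))
    for j, c in enumerate(clusters):
        mask = labels == c
        means[:, j] = np.asarray(X[mask].mean(axis=0)).ravel()
    mu = means.mean(axis=1, keepdims=True)
    sd = means.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (means - mu) / sd
    z[np.repeat(sd == 0, len(clusters), axis=1)] = 0.0
    return pd.DataFrame(z, index=pd.Index(genes, name="gene"),
                        columns=pd.Index(clusters, name="cluster"))


@dataclass
class PatternModel:
    """K expression patterns over a DEG universe.

    ``assignment`` maps gene -> pattern id (1..K); ``centroid`` is the
    pattern x cluster matrix of mean z-scored expression;
    ``signature`` lists, per pattern, the clusters with centroid value above
    the signature threshold, strongest first.
    """

    K: int
    assignment: pd.Series
    centroid: pd.DataFrame
    signature: dict[int, list]
    signature_threshold: float = DEFAULT_SIGNATURE_Z

    def genes_of(self, pattern: int) -> list[str]:
        return self.assignment.index[self.assignment == pattern].tolist()

    @property
    def genes(self) -> list[str]:
        return self.assignment.index.tolist()

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().reindex(range(1, self.K + 1), fill_value=0)

    def to_tsv(self, assignment_path: str | Path, centroid_path: str | Path) -> None:
        self.assignment.rename_axis("gene").rename("pattern").to_frame().reset_index().to_csv(
            assignment_path, sep="\t", index=False, lineterminator="\n")
        self.centroid.to_csv(centroid_path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, assignment_path: str | Path, centroid_path: str | Path,
                 signature_threshold: float = DEFAULT_SIGNATURE_Z) -> "PatternModel":
        assign = pd.read_csv(assignment_path, sep="\t").set_index("gene")["pattern"]
        centroid = pd.read_csv(centroid_path, sep="\t", index_col=0)
        centroid.index = centroid.index.astype(int)
        sig = _signatures(centroid, signature_threshold)
        return cls(K=len(centroid), assignment=assign, centroid=centroid,
                   signature=sig, signature_threshold=signature_threshold)


def _signatures(centroid: pd.DataFrame, threshold: float) -> dict[int, list]:
    sig = {}
    for pid, row in centroid.iterrows():
        above = row[row > threshold].sort_values(ascending=False)
        sig[int(pid)] = above.index.tolist()
    return sig


def assign_patterns(matrix: pd.DataFrame, K: int = DEFAULT_K, seed: int = 0,
                    signature_threshold: float = DEFAULT_SIGNATURE_Z,
                    max_restarts: int = 10) -> PatternModel:
    """Seeded k-means partition of gene profiles into K non-empty patterns.

    Pattern ids are relabelled 1..K by the cluster index of the centroid
    argmax (ties by descending peak height).  An empty pattern triggers a
    reseeded restart, bounded by ``max_restarts``.
    """
    n_genes = len(matrix)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_genes:
        raise ValueError(f"K={K} exceeds the number of genes ({n_genes})")
    values = matrix.to_numpy()
    for attempt in range(max_restarts):
        km = KMeans(n_clusters=K, n_init=10, random_state=seed + attempt)
        raw = km.fit_predict(values)
        counts = np.bincount(raw, minlength=K)
        if (counts > 0).all():
            break
    else:
        raise RuntimeError(f"could not produce {K} non-empty patterns in {max_restarts} restarts")

    centroids = km.cluster_centers_
    order = sorted(
        range(K),
        key=lambda i: (int(np.argmax(centroids[i])), -float(centroids[i].max())),
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignment = pd.Series([relabel[r] for r in raw], index=matrix.index, name="pattern")
    centroid = pd.DataFrame(
        centroids[order], index=pd.Index(range(1, K + 1), name="pattern"),
        columns=matrix.columns,
    )
    return PatternModel(
        K=K,
        assignment=assignment,
        centroid=centroid,
        signature=_signatures(centroid, signature_threshold),
        signature_threshold=signature_threshold,
    )
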