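"""Per-sample cluster composition and SR-vs-AF proportion comparisons.

Composition is tabulated per sample as counts and fractions; between-condition
comparisons use the two-sided unpaired Student's t-test on per-sample
fractions (Welch optional), with the conventional asterisk annotation
(* p<0.05, ** p<0.01).  With 3 samples per condition, p-values are a coarse
instrument — effect sizes (group means) are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

LEVELS = {"major": "major_type", "subcluster": "subcluster"}


@dataclass
class CompositionTable:
    """Sample x cluster composition: counts, fractions, per-sample condition."""

    counts: pd.DataFrame
    fractions: pd.DataFrame
    condition: pd.Series

    def pooled_fractions(self, condition: str | None = None) -> pd.Series:
        """Cluster fractions pooled over all cells (optionally one condition)."""
        counts = self.counts
        if condition is not None:
            counts = counts.loc[self.condition == condition]
        totals = counts.sum(axis=0)
        return totals / totals.sum()

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.add_suffix(":count").join(self.fractions.add_suffix(":fraction"))
        out.insert(0, "condition", self.condition)
        out.to_csv(path, sep="\t", lineterminator="\n")


def tabulate_composition(meta: pd.DataFrame, level: str = "major") -> CompositionTable:
    """Exact per-sample counts and fractions at the major or subcluster level.

    ``meta`` needs columns sample_id, condition and the level's label column;
    unlabeled cells are an error (their count is reported).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {sorted(LEVELS)}")
    label_col = LEVELS[level]
    for col in ("sample_id", "condition", label_col):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    unlabeled = meta[label_col].isna() | (meta[label_col].astype(str) == "")
    if unlabeled.any():
        raise ValueError(f"{int(unlabeled.sum())} cells lack a {label_col!r} label")

    counts = (
        meta.groupby(["sample_id", label_col], observed=True).size().unstack(fill_value=0)
    )
    counts = counts.sort_index().sort_index(axis=1)
    fractions = counts.div(counts.sum(axis=1), axis=0)
    condition = (
        meta.drop_duplicates("sample_id").set_index("sample_id")["condition"].reindex(counts.index)
    )
    return CompositionTable(counts=counts, fractions=fractions, condition=condition)


@dataclass(frozen=True)
class ProportionTest:
    cluster: str
    t: float
    p: float
    mean_sr: float
    mean_af: float
    stars: str
    flagged: bool


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_proportions(table: CompositionTable, cluster, welch: bool = False) -> ProportionTest:
    """Two-sided unpaired t-test of SR vs AF per-sample fractions for a cluster.

    Pooled-variance Student's test by default (``welch=True`` for the Welch
    variant).  Degenerate inputs (zero variance in both groups) report p = 1
    when the means agree, p -> 0 flagged when they differ.
    """
    if cluster not in table.fractions.columns:
        raise ValueError(f"unknown cluster {cluster!r}")
    sr = table.fractions.loc[table.condition == "SR", cluster].to_numpy(dtype=float)
    af = table.fractions.loc[table.condition == "AF", cluster].to_numpy(dtype=float)
    for name, grp in (("SR", sr), ("AF", af)):
        if grp.size < 2:
            raise ValueError(f"condition {name} has fewer than 2 samples")
    if sr.std() == 0 and af.std() == 0:
        equal = float(sr.mean()) == float(af.mean())
        return ProportionTest(str(cluster), 0.0 if equal else np.inf,
                              1.0 if equal else np.nextafter(0.0, 1.0),
                              float(sr.mean()), float(af.mean()),
                              "" if equal else "**", True)
    res = scipy.stats.ttest_ind(af, sr, equal_var=not welch)
    p = float(res.pvalue)
    return ProportionTest(str(cluster), float(res.statistic), p,
                          float(sr.mean()), float(af.mean()), _stars(p), False)


def compare_all(table: CompositionTable, welch: bool = False) -> pd.DataFrame:
    """Proportion tests for every cluster column, as one table."""
    rows = [compare_proportions(table, c, welch=welch) for c in table.fractions.columns]
    return pd.DataFrame([r.__dict__ for r in rows])
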