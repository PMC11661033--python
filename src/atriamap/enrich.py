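"""Projection of external gene sets onto expression patterns.

Given a pattern model over a background gene universe (by default the DEG
universe itself) and an external gene set (e.g. GWAS susceptibility genes or
differentially abundant proteins), the observed statistic per pattern is the
overlap between the set and the pattern's genes.  The null redraws a set of
the same effective size uniformly without replacement from the background and
recomputes the overlap; the empirical p-value uses the add-one correction

    p = (1 + #{null >= observed}) / (n_perm + 1)

so a reported p is never exactly 0 — the smallest attainable value is
1/(n_perm+1).  Under this exchangeable null the overlap is hypergeometric,
so :func:`hypergeometric_tail` provides the closed-form cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from ._utils import ConfigError, rng_for
from .patterns import PatternModel

DEFAULT_N_PERM = 10_000

RESULT_COLUMNS = (
    "pattern", "set_name", "n_background", "n_pattern", "n_set_in_background",
    "observed_overlap", "null_mean", "empirical_p", "n_perm", "seed", "flagged",
)


@dataclass(frozen=True)
class GeneSet:
    """A named gene list; symbols are uppercased and deduplicated."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        cleaned: dict[str, None] = {}
        for g in self.genes:
            g = str(g).strip().upper()
            if g:
                cleaned.setdefault(g)
        if not cleaned:
            raise ConfigError(f"gene set {self.name!r} is empty after deduplication")
        object.__setattr__(self, "genes", tuple(cleaned))

    def __len__(self) -> int:
        return len(self.genes)


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a newline-delimited symbol list (one symbol per line)."""
    p = Path(path)
    symbols = [ln.strip() for ln in p.read_text(encoding="utf-8").splitlines()]
    return GeneSet(name=name or p.stem, genes=tuple(s for s in symbols if s))


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read GMT: one set per line, ``name<TAB>description<TAB>gene...``."""
    sets = []
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need >=3 fields): {ln[:80]!r}")
        sets.append(GeneSet(name=fields[0], genes=tuple(fields[2:])))
    return sets


def overlap_set(gene_set: GeneSet, universe) -> list[str]:
    """Case-insensitive intersection, ordered by the universe, deduplicated."""
    members = {g.upper() for g in gene_set.genes}
    out: dict[str, None] = {}
    for g in universe:
        if str(g).upper() in members:
            out.setdefault(str(g))
    return list(out)


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: background size, K: pattern size, n: draw (set) size, k: overlap.
    """
    if N < 0 or K < 0 or n < 0 or k < 0 or K > N or n > N:
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k > min(K, n):
        return 0.0
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def permutation_enrichment(model: PatternModel, gene_set: GeneSet, background=None,
                           n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> pd.DataFrame:
    """Per-pattern permutation enrichment of a gene set; see module docstring.

    ``background`` defaults to the model's gene universe and must contain all
    pattern genes.  Deterministic given ``seed``.  When the set does not
    intersect the background at all, every pattern reports observed 0 with
    p = 1 and is flagged.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    background = list(model.genes) if background is None else list(dict.fromkeys(background))
    bg_set = set(background)
    missing = [g for g in model.genes if g not in bg_set]
    if missing:
        raise ConfigError(f"background is missing pattern genes: {','.join(missing[:10])}")

    N = len(background)
    pattern_ids = list(range(1, model.K + 1))
    pat_of = model.assignment.reindex(background).fillna(0).astype(int).to_numpy()
    set_in_bg = overlap_set(gene_set, background)
    m = len(set_in_bg)
    member = np.isin(background, set_in_bg)
    observed = {pid: int((member & (pat_of == pid)).sum()) for pid in pattern_ids}

    rows = []
    if m == 0:
        for pid in pattern_ids:
            rows.append((pid, gene_set.name, N, len(model.genes_of(pid)), 0, 0, 0.0, 1.0,
                         n_perm, seed, True))
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    rng = rng_for(seed, f"enrich|{gene_set.name}")
    keys = rng.random((n_perm, N))
    draw_idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    drawn_pat = pat_of[draw_idx]  # n_perm x m pattern ids per drawn gene
    for pid in pattern_ids:
        null = (drawn_pat == pid).sum(axis=1)
        obs = observed[pid]
        p = (1.0 + int((null >= obs).sum())) / (n_perm + 1.0)
        rows.append((pid, gene_set.name, N, len(model.genes_of(pid)), m, obs,
                     float(null.mean()), p, n_perm, seed, False))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
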