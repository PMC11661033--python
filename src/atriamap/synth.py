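"""Synthetic SR/AF single-cell count generator.

Generates hierarchically structured negative-binomial counts: samples within
conditions, subclusters within samples (multinomial composition per
condition), marker genes elevated within their own subcluster / major type,
per-subcluster "program" genes (a slice of the background genes given a
subcluster-specific mean, so that one-vs-rest differential expression yields a
cluster-specific DEG universe), planted condition-dependent genes, and
lognormal per-cell library sizes.  Every cell carries ground-truth metadata
(sample, condition, major type, subcluster).

The count model is gamma-Poisson: for cell *c* and gene *g*,

    count ~ NB(mean = L_c * w_g * bump(g, subcluster_c, condition_c),
               dispersion = alpha)

with Var = mu + alpha * mu^2.  Baseline weights ``w_g`` are fixed at a common
value for panel/extra/program genes and drawn lognormally for the pure
background; ``bump`` multiplies marker genes by ``marker_fold_change`` in
their own subcluster (and major-type markers across the whole compartment),
program genes by ``program_fold_change``, and condition-dependent genes by
``2**log2fc`` in AF cells of the targeted subcluster.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from math import log
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from ._utils import ConfigError, rng_for
from .profiles import DEFAULT_CONDITION_DE, DEFAULT_PANEL, MarkerPanel, default_composition

CONDITIONS = ("SR", "AF")

OBS_COLUMNS = ("sample_id", "condition", "major_type", "subcluster")


@dataclass
class SynthConfig:
    """Full specification of one synthetic dataset.

    composition maps subcluster -> (major_type, fraction_SR, fraction_AF);
    per-condition fractions must each sum to 1.  condition_de is a list of
    (gene, subcluster, log2 fold change AF vs SR).  ``extra_genes`` are
    non-marker genes added to the universe (the default profile uses them for
    the planted condition-DE genes that are not markers).
    """

    composition: dict[str, tuple[str, float, float]]
    marker_panel: MarkerPanel
    n_samples_per_condition: int = 3
    cells_per_sample: int = 1500
    n_background_genes: int = 2000
    program_genes_per_subcluster: int = 25
    program_genes_per_major: int = 40
    marker_fold_change: float = 8.0
    program_fold_change: float = 4.0
    nb_dispersion: float = 0.5
    library_size_lognormal: tuple[float, float] = (log(2000.0), 0.3)
    condition_de: list[tuple[str, str, float]] = field(default_factory=list)
    extra_genes: tuple[str, ...] = ()
    seed: int = 0

    # -- derived structure -------------------------------------------------
    @property
    def subclusters(self) -> list[str]:
        return list(self.composition)

    @property
    def major_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for major, _, _ in self.composition.values():
            seen.setdefault(major)
        return list(seen)

    def program_genes(self, subcluster: str) -> list[str]:
        up = subcluster.upper().replace("_", "")
        return [f"PRG-{up}-{i:02d}" for i in range(self.program_genes_per_subcluster)]

    def major_program_genes(self, major: str) -> list[str]:
        up = major.upper().replace("_", "")
        return [f"LIN-{up}-{i:02d}" for i in range(self.program_genes_per_major)]

    def _n_program_genes(self) -> int:
        return (self.program_genes_per_subcluster * len(self.subclusters)
                + self.program_genes_per_major * len(self.major_types))

    def genes(self) -> list[str]:
        """Ordered gene universe: panel markers, extra, program, background."""
        names: dict[str, None] = {}
        for g in self.marker_panel.all_genes():
            names.setdefault(g)
        for g in self.extra_genes:
            names.setdefault(g)
        for major in self.major_types:
            for g in self.major_program_genes(major):
                names.setdefault(g)
        for sc in self.subclusters:
            for g in self.program_genes(sc):
                names.setdefault(g)
        n_pure = self.n_background_genes - self._n_program_genes()
        for i in range(n_pure):
            names.setdefault(f"BG{i + 1:04d}")
        return list(names)

    def n_fixed_genes(self) -> int:
        """Genes with unit baseline weight (panel + extra + program)."""
        return len(self.genes()) - (self.n_background_genes - self._n_program_genes())

    def to_yaml(self, path: str | Path) -> None:
        """Serialize the full configuration (panel included) as YAML."""
        data = {
            "n_samples_per_condition": self.n_samples_per_condition,
            "cells_per_sample": self.cells_per_sample,
            "composition": {sc: [m, float(a), float(b)] for sc, (m, a, b) in self.composition.items()},
            "marker_panel": {
                "major": {t: list(g) for t, g in self.marker_panel.major.items()},
                "sub": {t: {s: list(g) for s, g in subs.items()}
                        for t, subs in self.marker_panel.sub.items()},
            },
            "n_background_genes": self.n_background_genes,
            "program_genes_per_subcluster": self.program_genes_per_subcluster,
            "program_genes_per_major": self.program_genes_per_major,
            "marker_fold_change": self.marker_fold_change,
            "program_fold_change": self.program_fold_change,
            "nb_dispersion": self.nb_dispersion,
            "library_size_lognormal": [float(x) for x in self.library_size_lognormal],
            "condition_de": [[g, sc, float(l)] for g, sc, l in self.condition_de],
            "extra_genes": list(self.extra_genes),
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        panel = MarkerPanel(
            major={t: tuple(g) for t, g in data["marker_panel"]["major"].items()},
            sub={t: {s: tuple(g) for s, g in subs.items()}
                 for t, subs in data["marker_panel"].get("sub", {}).items()},
        )
        cfg = cls(
            composition={sc: (m, float(a), float(b))
                         for sc, (m, a, b) in data["composition"].items()},
            marker_panel=panel,
            n_samples_per_condition=int(data.get("n_samples_per_condition", 3)),
            cells_per_sample=int(data.get("cells_per_sample", 1500)),
            n_background_genes=int(data.get("n_background_genes", 2000)),
            program_genes_per_subcluster=int(data.get("program_genes_per_subcluster", 25)),
            program_genes_per_major=int(data.get("program_genes_per_major", 40)),
            marker_fold_change=float(data.get("marker_fold_change", 8.0)),
            program_fold_change=float(data.get("program_fold_change", 4.0)),
            nb_dispersion=float(data.get("nb_dispersion", 0.5)),
            library_size_lognormal=tuple(data.get("library_size_lognormal", (log(2000.0), 0.3))),
            condition_de=[(g, sc, float(l)) for g, sc, l in data.get("condition_de", [])],
            extra_genes=tuple(data.get("extra_genes", ())),
            seed=int(data.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        self.marker_panel.validate()
        if self.cells_per_sample <= 0:
            raise ConfigError("cells_per_sample must be positive")
        if self.n_samples_per_condition <= 0:
            raise ConfigError("n_samples_per_condition must be positive")
        if self.marker_fold_change <= 0 or self.program_fold_change <= 0:
            raise ConfigError("fold changes must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        n_programs = self._n_program_genes()
        if self.n_background_genes < n_programs:
            raise ConfigError(
                f"n_background_genes ({self.n_background_genes}) must cover the "
                f"{n_programs} program genes"
            )
        if not self.composition:
            raise ConfigError("composition is empty")
        for cond_idx, cond in enumerate(CONDITIONS):
            total = 0.0
            for sc, (major, f_sr, f_af) in self.composition.items():
                frac = (f_sr, f_af)[cond_idx]
                if frac < 0:
                    raise ConfigError(f"negative fraction for {sc!r} in {cond}")
                if major not in self.marker_panel.major:
                    raise ConfigError(f"subcluster {sc!r} references unknown major type {major!r}")
                total += frac
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{cond} fractions sum to {total!r}, expected 1")
        universe = set(self.genes())
        for gene, sc, _lfc in self.condition_de:
            if sc not in self.composition:
                raise ConfigError(f"condition_de references unknown subcluster {sc!r}")
            if gene not in universe:
                raise ConfigError(f"condition_de references unknown gene {gene!r}")


def default_config(**overrides) -> SynthConfig:
    """The packaged atrial SR/AF profile with optional field overrides."""
    de = list(DEFAULT_CONDITION_DE)
    panel_genes = set(DEFAULT_PANEL.all_genes())
    extra = tuple(g for g, _, _ in de if g not in panel_genes)
    cfg = SynthConfig(
        composition=default_composition(),
        marker_panel=DEFAULT_PANEL,
        condition_de=de,
        extra_genes=extra,
        **overrides,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# moment-level accessors (used by the generator and by exact moment checks)
# ---------------------------------------------------------------------------

def baseline_weights(config: SynthConfig) -> pd.Series:
    """Per-gene baseline weights w_g (sum-normalised), deterministic in seed."""
    genes = config.genes()
    n_fixed = config.n_fixed_genes()
    rng = rng_for(config.seed, "gene-baselines")
    m = np.ones(len(genes))
    m[n_fixed:] = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes) - n_fixed)
    return pd.Series(m / m.sum(), index=genes, name="weight")


def _bump_vector(config: SynthConfig, subcluster: str, condition: str, genes: list[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(genes)}
    bump = np.ones(len(genes))
    major = config.composition[subcluster][0]
    panel = config.marker_panel
    own = set(panel.sub_flat.get(subcluster, ())) | set(panel.major.get(major, ()))
    for g in own:
        if g in index:
            bump[index[g]] *= config.marker_fold_change
    for g in config.program_genes(subcluster):
        bump[index[g]] *= config.program_fold_change
    for g in config.major_program_genes(major):
        bump[index[g]] *= config.program_fold_change
    if condition == "AF":
        for gene, sc, lfc in config.condition_de:
            if sc == subcluster:
                bump[index[gene]] *= 2.0 ** lfc
    return bump


def gene_mean_profile(config: SynthConfig, subcluster: str, condition: str) -> pd.Series:
    """Expected counts per gene for a cell at the nominal library size.

    This is the exact mean parameter of the generator (library factor set to
    ``exp(mu)``), the quantity moment-level tests check without sampling.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    if subcluster not in config.composition:
        raise ConfigError(f"unknown subcluster {subcluster!r}")
    genes = config.genes()
    w = baseline_weights(config).to_numpy()
    lib = np.exp(config.library_size_lognormal[0])
    mu = lib * w * _bump_vector(config, subcluster, condition, genes)
    return pd.Series(mu, index=genes, name=f"{subcluster}|{condition}")


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_composition(config: SynthConfig, sample_id: str, condition: str) -> pd.Series:
    """Multinomial cell counts per subcluster for one sample.

    n = cells_per_sample, probabilities = the condition's fraction vector.
    Reproducible: the draw depends only on (config.seed, sample_id, condition).
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    config.validate()
    cond_idx = CONDITIONS.index(condition)
    subs = config.subclusters
    p = np.array([config.composition[sc][1 + cond_idx] for sc in subs])
    rng = rng_for(config.seed, f"composition|{sample_id}|{condition}")
    counts = rng.multinomial(config.cells_per_sample, p / p.sum())
    return pd.Series(counts, index=subs, name=sample_id)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + alpha*mu^2 (Poisson when alpha=0)."""
    if alpha == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def simulate_counts(config: SynthConfig) -> ad.AnnData:
    """Draw the full dataset; counts in ``.X`` (CSR int32), truth in ``.obs``.

    Deterministic given ``config.seed``: every (sample, subcluster) block has
    its own derived stream, so block order never matters.
    """
    config.validate()
    genes = config.genes()
    w = baseline_weights(config).to_numpy()
    mu_lib, sigma_lib = config.library_size_lognormal
    alpha = config.nb_dispersion

    blocks: list[sp.csr_matrix] = []
    obs_rows: list[tuple[str, str, str, str, str]] = []
    for condition in CONDITIONS:
        for i in range(config.n_samples_per_condition):
            sample_id = f"{condition}{i + 1}"
            comp = sample_composition(config, sample_id, condition)
            cell_no = 0
            for subcluster, n_cells in comp.items():
                if n_cells == 0:
                    continue
                rng = rng_for(config.seed, f"counts|{sample_id}|{subcluster}")
                libs = rng.lognormal(mean=mu_lib, sigma=sigma_lib, size=int(n_cells))
                bump = _bump_vector(config, subcluster, condition, genes)
                mu = libs[:, None] * (w * bump)[None, :]
                block = _nb_draw(rng, mu, alpha).astype(np.int32)
                blocks.append(sp.csr_matrix(block))
                major = config.composition[subcluster][0]
                for _ in range(int(n_cells)):
                    cell_no += 1
                    obs_rows.append(
                        (f"{sample_id}-{cell_no:05d}", sample_id, condition, major, subcluster)
                    )
    if blocks:
        X = sp.vstack(blocks, format="csr")
    else:
        X = sp.csr_matrix((0, len(genes)), dtype=np.int32)
    obs = pd.DataFrame(obs_rows, columns=("cell_id",) + OBS_COLUMNS).set_index("cell_id")
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return adata


# ---------------------------------------------------------------------------
# 10x-style on-disk layout
# ---------------------------------------------------------------------------

def write_tenx(adata: ad.AnnData, directory: str | Path) -> Path:
    """Write genes-by-cells ``matrix.mtx`` + features/barcodes/cell_meta TSVs.

    MatrixMarket coordinate format with integer field and 1-based indices;
    all text files are UTF-8 with LF line endings.  A subsequent
    :func:`read_tenx` reproduces counts and labels exactly.
    """
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        X = sp.coo_matrix(adata.X.T)
        X.data = X.data.astype(np.int64)
        buf = io.BytesIO()
        scipy.io.mmwrite(buf, X, field="integer")
        (d / "matrix.mtx").write_bytes(buf.getvalue())
        with open(d / "features.tsv", "w", encoding="utf-8", newline="\n") as fh:
            for g in adata.var_names:
                fh.write(f"{g}\t{g}\n")
        with open(d / "barcodes.tsv", "w", encoding="utf-8", newline="\n") as fh:
            for b in adata.obs_names:
                fh.write(f"{b}\n")
        meta = adata.obs.reset_index(names="cell_id")
        meta.to_csv(d / "cell_meta.tsv", sep="\t", index=False, lineterminator="\n")
    except OSError as exc:
        raise OSError(f"failed writing 10x layout under {d}: {exc}") from exc
    return d


def read_tenx(directory: str | Path) -> ad.AnnData:
    """Read a directory produced by :func:`write_tenx` back into AnnData."""
    d = Path(directory)
    X = sp.csr_matrix(scipy.io.mmread(d / "matrix.mtx").T).astype(np.int32)
    genes = [ln.split("\t")[0] for ln in _read_lines(d / "features.tsv")]
    barcodes = _read_lines(d / "barcodes.tsv")
    meta_path = d / "cell_meta.tsv"
    if meta_path.exists() and meta_path.stat().st_size > 0:
        obs = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("cell_id")
        obs = obs.reindex(barcodes)
    else:
        obs = pd.DataFrame(index=pd.Index(barcodes, name="cell_id"))
    obs.index.name = "cell_id"
    if X.shape[0] != len(barcodes):  # 0-cell matrices read back as (G, 0)
        X = sp.csr_matrix((len(barcodes), len(genes)), dtype=np.int32)
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))


def _read_lines(path: Path) -> list[str]:
    text = path.read_text(encoding="utf-8")
    return [ln for ln in text.split("\n") if ln != ""]
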