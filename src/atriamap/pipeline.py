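"""Pipeline orchestration: simulate -> QC -> annotate -> DE -> patterns ->
enrichment -> composition, from a single config, with per-stage seeds and a
reproducibility manifest.

Per-stage seeds are derived deterministically from the global seed and the
stage name, so any stage can be rerun in isolation and two runs with the same
config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import ConfigError, StageError, derive_seed
from .annotate import DEFAULT_K_MAJOR, DEFAULT_N_COMPONENTS, annotate_cells
from .composition import compare_all, tabulate_composition
from .differential import condition_deg, deg_universe, rank_markers
from .enrich import permutation_enrichment, read_gene_set, read_gmt
from .patterns import DEFAULT_K, DEFAULT_SIGNATURE_Z, assign_patterns, pattern_matrix
from .preprocess import QCThresholds, filter_cells, normalize_log
from .synth import default_config, read_tenx, simulate_counts, write_tenx

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; unset fields take package defaults."""

    outdir: str
    input: str = "simulate"  # "simulate" or a 10x-layout directory
    seed: int = 0
    synth: dict = field(default_factory=dict)  # overrides for default_config
    qc: QCThresholds = field(default_factory=QCThresholds)
    target_sum: float = 10_000.0
    n_components: int = DEFAULT_N_COMPONENTS
    k_major: int = DEFAULT_K_MAJOR
    k_sub: dict | None = None
    deg_q_max: float = 0.05
    deg_lfc_min: float = 0.25
    condition_deg_subclusters: tuple[str, ...] = ("FB3",)
    k_patterns: int = DEFAULT_K
    signature_threshold: float = DEFAULT_SIGNATURE_Z
    gene_sets: tuple[str, ...] = ()
    n_perm: int = 10_000

    def validation_errors(self, check_files: bool = True) -> list[str]:
        """All invariant violations at once (empty when valid).

        ``check_files=False`` skips gene-set existence checks (run_all defers
        those to the enrich stage so the failure names the stage).
        """
        errors: list[str] = []
        if not isinstance(self.seed, int):
            errors.append("seed must be an integer")
        if self.n_perm < 1:
            errors.append("n_perm must be >= 1")
        if self.k_patterns < 1:
            errors.append("k_patterns must be >= 1")
        if self.k_major < 1:
            errors.append("k_major must be >= 1")
        if self.target_sum <= 0:
            errors.append("target_sum must be positive")
        try:
            self.qc.validate()
        except ConfigError as exc:
            errors.append(str(exc))
        if self.input == "simulate":
            try:
                default_config(seed=0, **self.synth)
            except (ConfigError, TypeError) as exc:
                errors.append(f"synth: {exc}")
        elif not Path(self.input).is_dir():
            errors.append(f"input directory does not exist: {self.input}")
        if check_files:
            for path in self.gene_sets:
                if not Path(path).is_file():
                    errors.append(f"gene set file does not exist: {path}")
        return errors


def validate_config(path: str | Path) -> tuple[RunConfig, list[str]]:
    """Load a YAML run config; returns (config with defaults filled, errors)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in raw.items() if k in known}
    if "qc" in kwargs and isinstance(kwargs["qc"], dict):
        try:
            kwargs["qc"] = QCThresholds(**kwargs["qc"])
        except TypeError as exc:
            errors.append(f"qc: {exc}")
            del kwargs["qc"]
    if "outdir" not in kwargs:
        errors.append("outdir is required")
        kwargs["outdir"] = "."
    for tuple_key in ("gene_sets", "condition_deg_subclusters"):
        if tuple_key in kwargs and isinstance(kwargs[tuple_key], list):
            kwargs[tuple_key] = tuple(kwargs[tuple_key])
    config = RunConfig(**kwargs)
    errors.extend(config.validation_errors())
    return config, errors


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest.

    Any stage error aborts with the stage name; outputs of earlier stages are
    left in place.
    """
    errors = config.validation_errors(check_files=False)
    if errors:
        raise ConfigError("; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: derive_seed(config.seed, stage)
        for stage in ("simulate", "annotate", "patterns", "enrich")
    }
    manifest: dict = {
        "atriamap_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": _config_dict(config),
        "stages": {},
        "inputs": {},
    }

    stage = "simulate"
    try:
        if config.input == "simulate":
            synth_cfg = default_config(seed=seeds["simulate"], **config.synth)
            panel = synth_cfg.marker_panel
            adata = simulate_counts(synth_cfg)
            write_tenx(adata, outdir / "tenx")
        else:
            panel = default_config().marker_panel
            adata = read_tenx(config.input)
            for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
                manifest["inputs"][fname] = _sha256(Path(config.input) / fname)
        manifest["stages"][stage] = {"cells": int(adata.n_obs), "genes": int(adata.n_vars)}

        stage = "preprocess"
        filtered, report = filter_cells(adata, config.qc)
        normed = normalize_log(filtered, target_sum=config.target_sum)
        pd.DataFrame([report]).to_csv(outdir / "qc_report.tsv", sep="\t", index=False,
                                      lineterminator="\n")
        manifest["stages"][stage] = report

        stage = "annotate"
        labels = annotate_cells(
            normed, panel, k_major=config.k_major, k_map=config.k_sub,
            n_components=config.n_components, seed=seeds["annotate"],
        )
        truth_cols = [c for c in ("major_type", "subcluster") if c in normed.obs.columns]
        obs = normed.obs.rename(columns={c: f"truth_{c}" for c in truth_cols})
        meta = obs.join(labels)
        _tsv(meta.reset_index(), outdir / "cell_labels.tsv")
        manifest["stages"][stage] = {
            "clusters": int(labels["cluster_id"].nunique()),
            "major_types": sorted(labels["major_type"].unique().tolist()),
            "subclusters": int(labels["subcluster"].nunique()),
        }

        stage = "differential"
        markers = rank_markers(normed, labels["subcluster"].to_numpy(),
                               q_max=config.deg_q_max, lfc_min=config.deg_lfc_min)
        _tsv(markers, outdir / "markers.tsv")
        universe = deg_universe(markers)
        (outdir / "deg_universe.txt").write_text("\n".join(universe) + "\n", encoding="utf-8")
        cond_rows = []
        for sc in config.condition_deg_subclusters:
            tab = condition_deg(normed, labels["subcluster"].to_numpy(), sc,
                                normed.obs["condition"].to_numpy())
            cond_rows.append(tab)
        if cond_rows:
            _tsv(pd.concat(cond_rows, ignore_index=True), outdir / "condition_deg.tsv")
        manifest["stages"][stage] = {"marker_records": int(len(markers)),
                                     "deg_universe": len(universe)}

        stage = "patterns"
        mat = pattern_matrix(normed, labels["subcluster"].to_numpy(), universe)
        model = assign_patterns(mat, K=min(config.k_patterns, len(universe)),
                                seed=seeds["patterns"],
                                signature_threshold=config.signature_threshold)
        model.to_tsv(outdir / "pattern_assignment.tsv", outdir / "pattern_centroids.tsv")
        manifest["stages"][stage] = {
            "K": model.K,
            "sizes": {str(k): int(v) for k, v in model.sizes().items()},
        }

        stage = "enrich"
        enrichments = []
        for path in config.gene_sets:
            p = Path(path)
            if not p.is_file():
                raise FileNotFoundError(f"gene set file not found: {p}")
            manifest["inputs"][p.name] = _sha256(p)
            sets = read_gmt(p) if p.suffix.lower() == ".gmt" else [read_gene_set(p)]
            for gs in sets:
                enrichments.append(
                    permutation_enrichment(model, gs, n_perm=config.n_perm,
                                           seed=seeds["enrich"])
                )
        if enrichments:
            _tsv(pd.concat(enrichments, ignore_index=True), outdir / "enrichment.tsv")
        manifest["stages"][stage] = {"gene_sets": len(config.gene_sets)}

        stage = "composition"
        for level, col in (("major", "major_type"), ("subcluster", "subcluster")):
            table = tabulate_composition(meta, level=level)
            table.to_tsv(outdir / f"composition_{level}.tsv")
            _tsv(compare_all(table), outdir / f"proportion_tests_{level}.tsv")
        pooled = tabulate_composition(meta, level="major").pooled_fractions()
        manifest["stages"][stage] = {"pooled_major_fractions": pooled.round(6).to_dict()}
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["qc"] = dataclasses.asdict(config.qc)
    d["gene_sets"] = list(config.gene_sets)
    d["condition_deg_subclusters"] = list(config.condition_deg_subclusters)
    return d
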