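"""Shared fixtures: one mid-sized synthetic SR/AF dataset reused across modules.

The fixture runs the packaged profile at 1,500 cells per sample (9,000 cells,
3 samples per condition) — large enough that every one of the 23 subclusters
has tens of cells and the planted effects are detectable, small enough to keep
the suite fast.  All fixtures are session-scoped and deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import atriamap as am

FIXTURE_SEED = 11
ANNOTATE_SEED = 5


@pytest.fixture(scope="session")
def profile_config() -> am.SynthConfig:
    return am.default_config(cells_per_sample=1500, seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def raw_adata(profile_config):
    return am.simulate_counts(profile_config)


@pytest.fixture(scope="session")
def normed_adata(raw_adata):
    filtered, _report = am.filter_cells(raw_adata)
    return am.normalize_log(filtered)


@pytest.fixture(scope="session")
def annotation(normed_adata, profile_config) -> pd.DataFrame:
    return am.annotate_cells(normed_adata, profile_config.marker_panel, seed=ANNOTATE_SEED)


@pytest.fixture(scope="session")
def truth_meta(normed_adata) -> pd.DataFrame:
    return normed_adata.obs.copy()


@pytest.fixture(scope="session")
def markers_df(normed_adata, truth_meta) -> pd.DataFrame:
    return am.rank_markers(normed_adata, truth_meta["subcluster"].to_numpy())


@pytest.fixture(scope="session")
def pattern_model(normed_adata, truth_meta, markers_df) -> am.PatternModel:
    universe = am.deg_universe(markers_df)
    mat = am.pattern_matrix(normed_adata, truth_meta["subcluster"].to_numpy(), universe)
    return am.assign_patterns(mat, K=14, seed=3)


def tiny_config(**overrides) -> am.SynthConfig:
    """A minimal three-type configuration for composition-level tests."""
    panel = am.MarkerPanel(
        major={"A": ("GA1",), "B": ("GB1",), "C": ("GC1",)},
        sub={"A": {"A1": ("GA1",)}, "B": {"B1": ("GB1",)}, "C": {"C1": ("GC1",)}},
    )
    composition = {
        "A1": ("A", 0.5, 0.5),
        "B1": ("B", 0.3, 0.3),
        "C1": ("C", 0.2, 0.2),
    }
    defaults = dict(
        composition=composition,
        marker_panel=panel,
        cells_per_sample=200,
        n_background_genes=300,
        program_genes_per_subcluster=5,
        program_genes_per_major=5,
        seed=0,
    )
    defaults.update(overrides)
    cfg = am.SynthConfig(**defaults)
    cfg.validate()
    return cfg
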