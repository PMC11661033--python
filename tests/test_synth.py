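"""Generator tests: composition draws, count moments, 10x round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import atriamap as am
from atriamap._utils import ConfigError
from atriamap.synth import baseline_weights

from conftest import tiny_config


class TestSampleComposition:
    def test_counts_sum_to_cells_per_sample(self, profile_config):
        counts = am.sample_composition(profile_config, "SR1", "SR")
        assert counts.sum() == profile_config.cells_per_sample
        assert set(counts.index) == set(profile_config.composition)

    def test_multinomial_moments_against_oracle(self):
        """Empirical mean counts over many draws match n*p within 3 SD."""
        cfg = tiny_config(cells_per_sample=10_000)
        n = cfg.cells_per_sample
        expected = {"A1": 5000.0, "B1": 3000.0, "C1": 2000.0}
        draws = pd.DataFrame(
            [am.sample_composition(cfg, f"SR{i}", "SR") for i in range(200)]
        )
        for sc, e in expected.items():
            p = e / n
            tol = 3.0 * np.sqrt(n * p * (1 - p))
            assert abs(draws[sc].mean() - e) < tol

    def test_packaged_profile_fb_expectation(self):
        """FB cells track the configured per-condition fraction; pooled SR+AF
        expectation is the reported 44%."""
        cfg = am.default_config(cells_per_sample=10_000, seed=123)
        fb_subs = [sc for sc, (major, _, _) in cfg.composition.items() if major == "FB"]
        p_sr = sum(cfg.composition[sc][1] for sc in fb_subs)
        p_af = sum(cfg.composition[sc][2] for sc in fb_subs)
        assert abs((p_sr + p_af) / 2 - 0.44 / 0.999) < 1e-12
        n = cfg.cells_per_sample
        for cond, p in (("SR", p_sr), ("AF", p_af)):
            counts = am.sample_composition(cfg, f"{cond}1", cond)
            fb = counts[fb_subs].sum()
            assert abs(fb - n * p) < 3.0 * np.sqrt(n * p * (1 - p))

    def test_degenerate_simplex(self):
        cfg = tiny_config(
            composition={"A1": ("A", 1.0, 1.0), "B1": ("B", 0.0, 0.0), "C1": ("C", 0.0, 0.0)},
            cells_per_sample=50,
        )
        counts = am.sample_composition(cfg, "SR1", "SR")
        assert counts["A1"] == 50
        assert counts.drop("A1").sum() == 0

    def test_unknown_condition_rejected(self, profile_config):
        with pytest.raises(ConfigError):
            am.sample_composition(profile_config, "X1", "af")

    def test_bad_fraction_sum_rejected(self):
        with pytest.raises(ConfigError, match="sum"):
            tiny_config(composition={"A1": ("A", 0.5, 1.0), "B1": ("B", 0.4, 0.0),
                                     "C1": ("C", 0.0, 0.0)})

    def test_fraction_convergence_at_large_n(self):
        """Realized subcluster fractions approach configured fractions (3 SE)."""
        cfg = am.default_config(cells_per_sample=50_000, seed=77)
        counts = am.sample_composition(cfg, "AF1", "AF")
        n = cfg.cells_per_sample
        for sc, (_, _, p_af) in cfg.composition.items():
            se = np.sqrt(p_af * (1 - p_af) / n)
            assert abs(counts[sc] / n - p_af) <= 3 * se


class TestCountMoments:
    def test_marker_mean_dominates_outside_exactly(self, profile_config):
        """Moment-level: each marker's mean is strictly larger inside every
        subcluster that carries it than in any subcluster that does not."""
        cfg = profile_config
        panel = cfg.marker_panel
        profiles = {
            sc: am.gene_mean_profile(cfg, sc, "SR") for sc in cfg.subclusters
        }
        for marker in panel.all_genes():
            own = {
                sc for sc in cfg.subclusters
                if marker in set(panel.sub_flat.get(sc, ()))
                | set(panel.major[cfg.composition[sc][0]])
            }
            inside = min(profiles[sc][marker] for sc in own)
            outside = max(profiles[sc][marker] for sc in cfg.subclusters if sc not in own)
            assert inside > outside

    def test_condition_de_moment_exact(self, profile_config):
        """Planted (COL3A1, FB3, +2) quadruples the AF mean parameter."""
        sr = am.gene_mean_profile(profile_config, "FB3", "SR")
        af = am.gene_mean_profile(profile_config, "FB3", "AF")
        assert af["COL3A1"] / sr["COL3A1"] == pytest.approx(4.0)
        assert af["MT2A"] / sr["MT2A"] == pytest.approx(2.0 ** -1.5)
        # untouched subcluster is condition-invariant
        pd.testing.assert_series_equal(
            am.gene_mean_profile(profile_config, "FB4", "SR"),
            am.gene_mean_profile(profile_config, "FB4", "AF"),
            check_names=False,
        )

    def test_no_condition_de_means_equal(self):
        cfg = tiny_config(condition_de=[])
        for sc in cfg.subclusters:
            pd.testing.assert_series_equal(
                am.gene_mean_profile(cfg, sc, "SR"),
                am.gene_mean_profile(cfg, sc, "AF"),
                check_names=False,
            )

    def test_marker_fold_empirical_dcn(self, raw_adata):
        """Mean DCN counts in FB cells are ~8x the EC mean (NB sampling error)."""
        dcn = np.asarray(raw_adata[:, "DCN"].X.todense()).ravel()
        fb = raw_adata.obs["major_type"].to_numpy() == "FB"
        ec = raw_adata.obs["major_type"].to_numpy() == "EC"
        assert fb.sum() > 500 and ec.sum() > 500
        ratio = dcn[fb].mean() / dcn[ec].mean()
        assert 6.0 < ratio < 10.5

    def test_planted_condition_fold_empirical(self, raw_adata):
        """AF-FB3 COL3A1 mean is ~4x the SR-FB3 mean."""
        col = np.asarray(raw_adata[:, "COL3A1"].X.todense()).ravel()
        obs = raw_adata.obs
        in_fb3 = obs["subcluster"].to_numpy() == "FB3"
        af = in_fb3 & (obs["condition"].to_numpy() == "AF")
        sr = in_fb3 & (obs["condition"].to_numpy() == "SR")
        ratio = col[af].mean() / col[sr].mean()
        assert 2.8 < ratio < 5.5

    def test_condition_de_unknown_gene_rejected(self):
        with pytest.raises(ConfigError, match="unknown gene"):
            tiny_config(condition_de=[("NOTAGENE", "A1", 1.0)])
        with pytest.raises(ConfigError, match="unknown subcluster"):
            tiny_config(condition_de=[("GA1", "Z9", 1.0)])

    def test_dimensions_and_determinism(self):
        cfg = tiny_config(cells_per_sample=100, seed=5)
        a = am.simulate_counts(cfg)
        b = am.simulate_counts(cfg)
        assert (a.X != b.X).nnz == 0
        assert a.obs.equals(b.obs)
        n_expected = cfg.cells_per_sample * cfg.n_samples_per_condition * 2
        assert a.shape == (n_expected, len(cfg.genes()))
        c = am.simulate_counts(tiny_config(cells_per_sample=100, seed=6))
        assert c.shape == a.shape
        assert set(c.obs["subcluster"]) == set(a.obs["subcluster"])
        assert (a.X != c.X).nnz > 0

    def test_baseline_weights_sum_to_one(self, profile_config):
        w = baseline_weights(profile_config)
        assert w.sum() == pytest.approx(1.0)
        assert (w > 0).all()


class TestTenxRoundTrip:
    def test_round_trip_bit_exact(self, tmp_path):
        cfg = tiny_config(cells_per_sample=40, seed=2)
        adata = am.simulate_counts(cfg)
        am.write_tenx(adata, tmp_path / "d")
        back = am.read_tenx(tmp_path / "d")
        assert (back.X != adata.X).nnz == 0
        assert list(back.var_names) == list(adata.var_names)
        assert list(back.obs_names) == list(adata.obs_names)
        for col in ("sample_id", "condition", "major_type", "subcluster"):
            assert back.obs[col].tolist() == adata.obs[col].tolist()

    def test_write_is_deterministic_bytes(self, tmp_path):
        cfg = tiny_config(cells_per_sample=30, seed=9)
        for d in ("x", "y"):
            am.write_tenx(am.simulate_counts(cfg), tmp_path / d)
        for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv", "cell_meta.tsv"):
            assert (tmp_path / "x" / fname).read_bytes() == (tmp_path / "y" / fname).read_bytes()

    def test_empty_matrix_round_trip(self, tmp_path):
        import anndata as ad
        import scipy.sparse as sp

        empty = ad.AnnData(
            X=sp.csr_matrix((0, 3), dtype=np.int32),
            obs=pd.DataFrame(index=pd.Index([], name="cell_id")),
            var=pd.DataFrame(index=pd.Index(["G1", "G2", "G3"], name="gene")),
        )
        am.write_tenx(empty, tmp_path / "e")
        back = am.read_tenx(tmp_path / "e")
        assert back.shape == (0, 3)

    def test_config_yaml_round_trip(self, tmp_path, profile_config):
        profile_config.to_yaml(tmp_path / "cfg.yaml")
        back = am.SynthConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back.composition == profile_config.composition
        assert back.genes() == profile_config.genes()
        assert back.condition_de == list(profile_config.condition_de)
        assert dict(back.marker_panel.major) == dict(profile_config.marker_panel.major)

    def test_panel_yaml_round_trip(self, tmp_path):
        am.DEFAULT_PANEL.to_yaml(tmp_path / "panel.yaml")
        back = am.MarkerPanel.from_yaml(tmp_path / "panel.yaml")
        assert dict(back.major) == {t: tuple(g) for t, g in am.DEFAULT_PANEL.major.items()}
        assert back.sub_flat == am.DEFAULT_PANEL.sub_flat

    def test_sample_ids_enumerate_conditions(self, tmp_path):
        cfg = tiny_config(cells_per_sample=50, n_samples_per_condition=2, seed=4)
        am.write_tenx(am.simulate_counts(cfg), tmp_path / "s")
        back = am.read_tenx(tmp_path / "s")
        assert back.obs["sample_id"].nunique() == cfg.n_samples_per_condition * 2
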