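"""Rank-sum test, BH adjustment, and planted-effect DE recovery."""

from __future__ import annotations

from itertools import combinations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

import atriamap as am
from atriamap.differential import _rank_sum_block


def exact_rank_sum_p(x, y) -> float:
    """Independent oracle: enumerate all rank splits (tie-free inputs only)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    ranks = pd.Series(pooled).rank().to_numpy()
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_textbook_exact_case(self):
        """Fully separated 3-vs-3 gives the exact two-sided p of 0.1."""
        _, p = am.wilcoxon_rank_sum((1, 2, 3), (4, 5, 6))
        assert p == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        _, p = am.wilcoxon_rank_sum((1.0, 2.0, 2.0), (1.0, 2.0, 2.0))
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            am.wilcoxon_rank_sum([], [1.0])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(1, 5), st.integers(1, 5), st.randoms(use_true_random=False))
    def test_agrees_with_rank_split_enumeration(self, n1, n2, rnd):
        """Exact branch matches brute-force enumeration for tie-free samples
        with pooled size <= 10."""
        vals = rnd.sample(range(1000), n1 + n2)
        x, y = vals[:n1], vals[n1:]
        _, p = am.wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_rank_sum_p(x, y))

    def test_type_i_error_rate_under_null(self):
        """Rejection rate at alpha=0.05 over 1000 null simulations, n=20+20."""
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(1000):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            _, p = am.wilcoxon_rank_sum(x, y)
            rejections += p < 0.05
        assert 0.03 < rejections / 1000 < 0.07

    def test_vectorised_matches_scipy_asymptotic(self):
        """The table-level test equals scipy's asymptotic MWU, ties included."""
        import scipy.stats

        rng = np.random.default_rng(7)
        X = rng.poisson(1.0, size=(60, 25)).astype(float)
        mask = np.zeros(60, dtype=bool)
        mask[:22] = True
        (U, p), = _rank_sum_block(X, [mask])
        for j in range(X.shape[1]):
            ref = scipy.stats.mannwhitneyu(X[mask, j], X[~mask, j],
                                           alternative="two-sided", method="asymptotic")
            assert U[j] == pytest.approx(ref.statistic)
            assert p[j] == pytest.approx(ref.pvalue, abs=1e-12)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert am.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stepup_arithmetic(self):
        np.testing.assert_allclose(am.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            am.bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            am.bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_matches_min_over_tail_oracle(self, p):
        """q_i = min_{j>=i} p_(j) * m / j, mapped back to input order."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(am.bh_adjust(p), expected, rtol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(1e-4, 1, 50))
        q = am.bh_adjust(p)
        assert (np.diff(q) >= -1e-15).all()


def _toy_marker_adata(seed=0):
    """200 cells, 30 genes; gene PLANT is 8-fold up in cluster 'b'."""
    rng = np.random.default_rng(seed)
    labels = np.array(["a"] * 120 + ["b"] * 80)
    X = rng.poisson(1.0, size=(200, 30)).astype(float)
    X[labels == "b", 0] = rng.poisson(8.0, size=80)
    genes = ["PLANT"] + [f"N{i:02d}" for i in range(1, 30)]
    adata = ad.AnnData(
        X=sp.csr_matrix(np.log1p(X)),
        obs=pd.DataFrame(index=pd.Index([f"c{i}" for i in range(200)], name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    return adata, labels


class TestRankMarkers:
    def test_planted_marker_recovered(self):
        adata, labels = _toy_marker_adata()
        out = am.rank_markers(adata, labels)
        hit = out[(out.cluster == "b") & (out.gene == "PLANT")]
        assert len(hit) == 1
        assert hit.q.iloc[0] < 0.05
        assert hit.direction.iloc[0] == "up"

    def test_noise_yields_no_markers(self):
        rng = np.random.default_rng(9)
        X = rng.poisson(1.0, size=(300, 100)).astype(float)
        adata = ad.AnnData(
            X=sp.csr_matrix(np.log1p(X)),
            obs=pd.DataFrame(index=pd.Index([f"c{i}" for i in range(300)], name="cell_id")),
            var=pd.DataFrame(index=pd.Index([f"G{i}" for i in range(100)], name="gene")),
        )
        labels = rng.choice(["a", "b", "c"], size=300)
        out = am.rank_markers(adata, labels)
        assert len(out) <= 3

    def test_gene_and_cell_order_invariance(self):
        adata, labels = _toy_marker_adata(seed=4)
        base = am.rank_markers(adata, labels)
        rng = np.random.default_rng(0)
        gperm = rng.permutation(adata.n_vars)
        cperm = rng.permutation(adata.n_obs)
        shuffled = adata[cperm, gperm].copy()
        again = am.rank_markers(shuffled, labels[cperm])
        key = lambda df: set(zip(df.gene, df.cluster, df.q.round(12)))
        assert key(base) == key(again)

    def test_single_cluster_rejected(self):
        adata, _ = _toy_marker_adata()
        with pytest.raises(ValueError):
            am.rank_markers(adata, np.array(["a"] * adata.n_obs))

    def test_dcn_ranks_top10_for_fb(self, normed_adata, truth_meta):
        """DCN is among the 10 strongest FB one-vs-rest markers by log2fc."""
        out = am.rank_markers(normed_adata, truth_meta["major_type"].to_numpy())
        fb = out[out.cluster == "FB"].nlargest(10, "log2fc")
        assert "DCN" in set(fb.gene)

    def test_deg_universe_covers_planted_structure(self, markers_df, profile_config):
        universe = set(am.deg_universe(markers_df))
        assert {"DCN", "GSN", "MYH11", "VWF"} <= universe
        # subcluster program genes are rediscovered as one-vs-rest markers
        assert len(universe & set(profile_config.program_genes("FB3"))) >= 20


class TestConditionDEG:
    def test_planted_fb3_genes_recovered(self, normed_adata, truth_meta):
        out = am.condition_deg(
            normed_adata,
            truth_meta["subcluster"].to_numpy(),
            "FB3",
            truth_meta["condition"].to_numpy(),
        )
        rec = out.set_index("gene")
        assert rec.loc["COL3A1", "q"] < 0.05
        assert rec.loc["COL3A1", "direction"] == "up"
        assert rec.loc["ELN", "direction"] == "up"
        assert rec.loc["MT2A", "q"] < 0.05
        assert rec.loc["MT2A", "direction"] == "down"

    def test_unplanted_subcluster_is_null(self, normed_adata, truth_meta):
        out = am.condition_deg(
            normed_adata,
            truth_meta["subcluster"].to_numpy(),
            "EC2",
            truth_meta["condition"].to_numpy(),
        )
        assert (out.q < 0.05).sum() <= 3

    def test_missing_condition_rejected(self, normed_adata, truth_meta):
        conditions = np.array(["SR"] * normed_adata.n_obs, dtype=object)
        with pytest.raises(ValueError, match="AF"):
            am.condition_deg(normed_adata, truth_meta["subcluster"].to_numpy(),
                             "FB3", conditions)
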