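"""Replicate statistics: Welch t, BH adjustment, rank-sum DE, clustering
order and the caliper volume formula."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lactsig import (
    bh_adjust,
    hierarchical_order,
    per_gene_de,
    top_n_genes,
    tumor_volume,
    welch_t_two_tailed,
)
from lactsig.errors import LactsigError
from lactsig.stats import hierarchical_linkage, welch_de_log2cpm

from conftest import make_adata


def bh_brute_force(p):
    """Step-up definition: min over the tail of p*m/rank, clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_two_tailed([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_complete_separation_tiny_p(self):
        t, p = welch_t_two_tailed([0, 0, 0], [10, 10, 10])
        assert np.isfinite(t) and p < 1e-10

    def test_sign_flips_under_group_swap(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 2, 4)
        t1, p1 = welch_t_two_tailed(a, b)
        t2, p2 = welch_t_two_tailed(b, a)
        assert t1 == -t2 and p1 == p2

    def test_matches_scipy_on_regular_data(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 2, 8)
        t, p = welch_t_two_tailed(a, b)
        ref = ttest_ind(a, b, equal_var=False)
        np.testing.assert_allclose([t, p], [ref.statistic, ref.pvalue], rtol=1e-9)

    def test_undersized_group_rejected(self):
        with pytest.raises(LactsigError):
            welch_t_two_tailed([1.0], [1, 2, 3])

    def test_null_rejection_rate_calibrated(self):
        """n=3 vs n=3 under a true null rejects near the nominal 5%."""
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            _, p = welch_t_two_tailed(rng.normal(size=3), rng.normal(size=3))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.08


class TestBH:
    def test_small_closed_form(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.4]), [0.4])

    def test_out_of_range_rejected(self):
        with pytest.raises(LactsigError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 120))
        np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), rtol=1e-12)

    def test_adjusted_dominates_raw_and_monotone(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 200)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestPerGeneDE:
    def test_constant_gene_null(self):
        counts = np.ones((6, 2), dtype=int)
        counts[:, 1] = [1, 2, 3, 1, 2, 3]
        adata = make_adata(counts)
        t = per_gene_de(adata, ["cell0", "cell1", "cell2"], ["cell3", "cell4", "cell5"])
        row = t.set_index("gene").loc["Gene0"]
        assert row["log2fc"] == 0.0 and row["pvalue"] == 1.0

    def test_one_sided_expression_positive_lfc(self):
        counts = np.zeros((6, 2), dtype=int)
        counts[:3, 0] = 9
        counts[:, 1] = 4  # keeps per-cell totals nonzero
        adata = make_adata(counts)
        t = per_gene_de(adata, ["cell0", "cell1", "cell2"], ["cell3", "cell4", "cell5"])
        assert t.set_index("gene").loc["Gene0", "log2fc"] > 0

    def test_overlapping_groups_rejected(self):
        adata = make_adata(np.ones((4, 2), dtype=int))
        with pytest.raises(LactsigError, match="overlap"):
            per_gene_de(adata, ["cell0", "cell1"], ["cell1", "cell2"])

    def test_planted_fold_changes_recovered(self):
        """30 genes at 4-fold in group A among 1000 nulls: at least 25 of
        the 40 smallest adjusted p-values are planted."""
        rng = np.random.default_rng(7)
        n_cells, n_genes, n_planted = 100, 1030, 30
        base = rng.poisson(2.0, size=(2 * n_cells, n_genes))
        planted_cols = rng.choice(n_genes, n_planted, replace=False)
        base[:n_cells, planted_cols] = rng.poisson(8.0, size=(n_cells, n_planted))
        adata = make_adata(base)
        groups = list(adata.obs_names)
        table = per_gene_de(adata, groups[:n_cells], groups[n_cells:])
        top40 = set(table.sort_values("padj", kind="mergesort").head(40)["gene"])
        planted_names = {f"Gene{j}" for j in planted_cols}
        assert len(top40 & planted_names) >= 25

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(17)
        counts = rng.poisson(2.0, size=(120, 2000))
        adata = make_adata(counts)
        names = list(adata.obs_names)
        table = per_gene_de(adata, names[:60], names[60:])
        assert (table["padj"] < 0.05).mean() <= 0.07


class TestTopN:
    TABLE = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4"],
            "log2fc": [0.5, -3.0, 2.0, 1.0],
            "pvalue": [1e-5, 1e-6, 1e-6, 0.01],
            "padj": [1e-4, 1e-5, 1e-5, 0.05],
        }
    )

    def test_filter_and_order(self):
        # ties on p resolved by |log2fc| descending
        assert top_n_genes(self.TABLE, n=40, p_cutoff=0.0002) == ["g2", "g3", "g1"]

    def test_no_qualifying_genes(self):
        assert top_n_genes(self.TABLE, p_cutoff=1e-12) == []

    def test_truncation_and_determinism(self):
        assert top_n_genes(self.TABLE, n=2, p_cutoff=0.0002) == ["g2", "g3"]
        assert top_n_genes(self.TABLE, n=2, p_cutoff=0.0002) == top_n_genes(
            self.TABLE.sample(frac=1, random_state=0), n=2, p_cutoff=0.0002
        )


def brute_force_upgma(D):
    """Average linkage on a full distance matrix, averaging original pairs."""
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(heights)


class TestHierarchicalOrder:
    def test_identical_rows_merge_first_at_zero(self):
        M = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 1.0, 4.0]],
            index=["r0", "r1", "r2"],
        )
        Z = hierarchical_linkage(M.to_numpy())
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_block_structure_keeps_blocks_contiguous(self):
        rng = np.random.default_rng(21)
        base1, base2 = rng.normal(0, 1, 8), rng.normal(0, 1, 8)
        rows = [base1 + rng.normal(0, 0.05, 8) for _ in range(3)]
        rows += [base2 + rng.normal(0, 0.05, 8) for _ in range(3)]
        M = pd.DataFrame(rows, index=[f"r{i}" for i in range(6)])
        row_order, _ = hierarchical_order(M)
        pos = {r: i for i, r in enumerate(row_order)}
        assert max(pos[f"r{i}"] for i in range(3)) < 3 or min(
            pos[f"r{i}"] for i in range(3)
        ) >= 3

    def test_merge_heights_match_brute_force(self):
        from lactsig.stats import _correlation_distance

        rng = np.random.default_rng(22)
        M = rng.normal(0, 1, size=(20, 6))
        Z = hierarchical_linkage(M)
        np.testing.assert_allclose(
            Z[:, 2], brute_force_upgma(_correlation_distance(M)), rtol=1e-10
        )

    def test_zero_variance_row_handled(self):
        M = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        row_order, col_order = hierarchical_order(M)
        assert sorted(row_order) == [0, 1, 2]


class TestTumorVolume:
    @pytest.mark.parametrize(
        "length,width,expected",
        [(10, 6, 180.0), (5, 0, 0.0), (4, 4, 32.0), (1, 1, 0.5)],
    )
    def test_formula(self, length, width, expected):
        assert tumor_volume(length, width) == expected

    def test_width_over_length_warns(self):
        with pytest.warns(UserWarning, match="width"):
            v = tumor_volume(2, 3)
        assert v == 9.0

    def test_cubic_homogeneity(self):
        assert tumor_volume(3 * 2.0, 3 * 1.5) == pytest.approx(
            27 * tumor_volume(2.0, 1.5)
        )


def test_welch_de_log2cpm_runs_on_bulk_counts():
    rng = np.random.default_rng(30)
    counts = pd.DataFrame(
        rng.poisson(50, size=(40, 6)),
        index=[f"G{i}" for i in range(40)],
        columns=[f"s{i}" for i in range(6)],
    )
    counts.iloc[:5, :3] *= 6
    t = welch_de_log2cpm(counts, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
    assert set(t.columns) == {"gene", "log2fc", "pvalue", "padj"}
    assert (t.set_index("gene").head(5)["log2fc"] > 0).all()
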