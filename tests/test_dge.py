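import itertools
import math

import numpy as np
import pandas as pd
import pytest

from citepipe import dge, stats
from citepipe.matrix_io import CountMatrix


def _gene_matrix(rows):
    rows = np.atleast_2d(np.asarray(rows))
    return CountMatrix(
        np.array([f"c{i}" for i in range(rows.shape[0])], dtype=object),
        np.array([f"g{j}" for j in range(rows.shape[1])], dtype=object),
        rows,
        "gene",
    )


def brute_force_ranksum_p(x, y):
    """Independent oracle: enumerate group assignments and compare the
    Mann-Whitney U statistic (pairwise wins + half-ties) tail counts."""

    def u_stat(a, b):
        return sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)

    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = u_stat(x, y)
    lo = hi = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        in1 = set(comb)
        a = [pooled[i] for i in in1]
        b = [pooled[i] for i in range(len(pooled)) if i not in in1]
        u = u_stat(a, b)
        total += 1
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    return min(1.0, 2 * min(lo, hi) / total)


class TestNormalizeGenes:
    def test_per_cell_hand_computation(self):
        m = _gene_matrix([[10, 990]])
        norm = dge.normalize_genes(m)
        assert norm.values[0, 0] == pytest.approx(math.log2(1 + 10 * 1e6 / 1000))

    def test_zero_count_maps_to_zero(self):
        m = _gene_matrix([[0, 5]])
        assert dge.normalize_genes(m).values[0, 0] == 0.0

    def test_per_cell_scale_invariance(self):
        m1 = _gene_matrix([[3, 7, 1]])
        m2 = _gene_matrix([[6, 14, 2]])
        np.testing.assert_allclose(
            dge.normalize_genes(m1).values, dge.normalize_genes(m2).values
        )

    def test_zero_total_cell_warns(self):
        with pytest.warns(UserWarning, match="zero total"):
            norm = dge.normalize_genes(_gene_matrix([[0, 0], [1, 1]]))
        assert (norm.values[0] == 0).all()

    def test_per_gene_literal_mode(self):
        m = _gene_matrix([[10], [90]])
        norm = dge.normalize_genes(m, mode="per_gene")
        assert norm.values[0, 0] == pytest.approx(math.log2(1 + 10 * 1e6 / 100))


class TestRankSumDE:
    def _norm_frame(self, values):
        values = np.asarray(values, dtype=float)
        return pd.DataFrame(
            values,
            index=[f"c{i}" for i in range(values.shape[0])],
            columns=[f"g{j}" for j in range(values.shape[1])],
        )

    def test_identical_groups_zero_fold_change(self):
        df = self._norm_frame(np.random.default_rng(0).uniform(0, 5, size=(6, 4)))
        out = dge.rank_sum_de(df, df.index[:3], df.index[:3])
        np.testing.assert_allclose(out["avg_log2FC"], 0.0, atol=1e-12)

    def test_pct_definition(self):
        vals = np.zeros((13, 1))
        vals[:3, 0] = 2.0  # 3 of 10 group-1 cells expressing
        df = self._norm_frame(vals)
        out = dge.rank_sum_de(df, df.index[:10], df.index[10:])
        assert out["pct1"].iloc[0] == pytest.approx(0.3)
        assert out["pct2"].iloc[0] == 0.0

    def test_complete_separation_exact_p(self):
        df = self._norm_frame(np.arange(10, dtype=float)[:, None])
        out = dge.rank_sum_de(df, df.index[:5], df.index[5:])
        assert out["p_value"].iloc[0] == pytest.approx(2 / 252)

    def test_constant_gene_p_one_flagged(self):
        df = self._norm_frame(np.ones((8, 1)))
        out = dge.rank_sum_de(df, df.index[:4], df.index[4:])
        assert out["p_value"].iloc[0] == 1.0
        assert bool(out["constant"].iloc[0])

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        df = self._norm_frame(rng.uniform(0, 4, size=(40, 6)))
        g1, g2 = df.index[:20], df.index[20:]
        fwd = dge.rank_sum_de(df, g1, g2)
        rev = dge.rank_sum_de(df, g2, g1)
        np.testing.assert_allclose(fwd["avg_log2FC"], -rev["avg_log2FC"], atol=1e-9)
        np.testing.assert_allclose(fwd["pct1"], rev["pct2"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)

    def test_too_small_groups_rejected(self):
        df = self._norm_frame(np.ones((5, 1)))
        with pytest.raises(ValueError):
            dge.rank_sum_de(df, df.index[:2], df.index[2:])


class TestExactOracle:
    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 6), (5, 5), (2, 8), (8, 8)])
    def test_exact_p_equals_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        x = rng.integers(0, 4, n1).astype(float)  # integer data forces ties
        y = rng.integers(0, 4, n2).astype(float)
        assert stats.exact_ranksum_p(x, y) == pytest.approx(brute_force_ranksum_p(x, y))

    @pytest.mark.parametrize("n1,n2", [(4, 4), (5, 7), (8, 8)])
    def test_matches_scipy_exact_without_ties(self, n1, n2):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(n1 + 100 * n2)
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        expected = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert stats.exact_ranksum_p(x, y) == pytest.approx(expected)

    def test_complete_separation_five_vs_five(self):
        assert stats.exact_ranksum_p([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]) == pytest.approx(2 / 252)


class TestFilters:
    def _rows(self, entries):
        return pd.DataFrame(
            entries, columns=["gene", "adj_p_value", "avg_log2FC", "pct1", "pct2"]
        )

    @pytest.mark.parametrize(
        "row,kept",
        [
            (("a", 0.01, 0.8, 0.5, 0.1), True),  # ratio 5
            (("b", 0.01, 0.8, 0.5, 0.3), False),  # ratio 1.67
            (("c", 0.06, 2.0, 0.9, 0.01), False),  # adj p too large
            (("d", 0.01, -0.5, 0.9, 0.01), False),  # downregulated
            (("e", 0.01, 1.0, 0.4, 0.0), True),  # pct2 = 0 -> infinite ratio
        ],
    )
    def test_marker_filter(self, row, kept):
        out = dge.filter_cluster_markers(self._rows([row]))
        assert (len(out) == 1) is kept

    def _de(self, entries):
        return pd.DataFrame(
            entries, columns=["gene", "adj_p_value", "avg_log2FC", "pct1"]
        )

    def test_overlap_disjoint_sets_empty(self):
        a = self._de([("x", 0.01, 1.0, 0.5)])
        b = self._de([("y", 0.01, 1.0, 0.5)])
        assert dge.condition_overlap(a, b) == []

    def test_overlap_requires_pct_in_both(self):
        a = self._de([("x", 0.01, 1.0, 0.25)])
        b_ok = self._de([("x", 0.01, 0.5, 0.30)])
        b_low = self._de([("x", 0.01, 0.5, 0.15)])
        assert dge.condition_overlap(a, b_ok) == ["x"]
        assert dge.condition_overlap(a, b_low) == []


class TestCalibrationAndRecovery:
    def test_null_type_one_error_close_to_nominal(self, rng):
        """Same-distribution groups: raw p < 0.05 for about 5% of genes."""
        counts = rng.negative_binomial(5, 5 / 9, size=(200, 300))  # NB mean 4
        m = CountMatrix(
            np.array([f"c{i}" for i in range(200)], dtype=object),
            np.array([f"g{j}" for j in range(300)], dtype=object),
            counts, "gene")
        norm = dge.normalize_genes(m)
        df = norm.to_frame()
        out = dge.rank_sum_de(df, df.index[:100], df.index[100:])
        frac = (out["p_value"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_planted_genes_recovered(self, small_study):
        """Planted CAD log2FC = 1 genes reach adjusted significance."""
        meta, gt = small_study["meta"], small_study["truth"]
        norm = dge.normalize_genes(small_study["genes"]).to_frame()
        cells = gt.cells[(~gt.cells["is_doublet"]) & (gt.cells["true_major"] == "CD4T")]
        cad = cells["true_subject"].map(meta["cad_class"])
        g1 = cells.index[(cad == "CAD+").to_numpy()][:200]
        g2 = cells.index[(cad == "CAD-").to_numpy()][:200]
        out = dge.rank_sum_de(norm, g1, g2).set_index("gene")
        for gene in ("TCF7", "GNAI2"):
            assert out.loc[gene, "adj_p_value"] < 0.05
            assert out.loc[gene, "avg_log2FC"] > 0
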