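from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import editome as ed
from editome.diffedit import Comparison


def _matrix_from_levels(levels: pd.DataFrame) -> ed.EditingMatrix:
    cov = pd.DataFrame(1000.0, index=levels.index, columns=levels.columns)
    g = (levels * cov).round()
    sites = [ed.parse_site_id(s) for s in levels.index]
    return ed.EditingMatrix(sites=sites, samples=list(levels.columns),
                            level=g / cov, g_reads=g, cov=cov)


def mwu_exact_oracle(x, y):
    """Two-sided Mann-Whitney p by exhaustive enumeration of assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = stats.rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n * (n + 1) / 2

    u_obs = u_of(range(n))
    dev_obs = abs(u_obs - n * m / 2)
    total = comb(n + m, n)
    extreme = sum(1 for idx in combinations(range(n + m), n)
                  if abs(u_of(idx) - n * m / 2) >= dev_obs - 1e-9)
    return extreme / total


class TestComparison:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            Comparison("F1", ["a", "b"], ["b", "c"])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            Comparison("F1", [], ["a"])


class TestPrefilterSites:
    def test_fully_constant_site_removed(self):
        lv = pd.DataFrame({f"s{i}": [0.3, 0.1 + 0.05 * i] for i in range(8)},
                          index=["chr1:1+", "chr1:2+"])
        mat = _matrix_from_levels(lv)
        comp = Comparison("T", [f"s{i}" for i in range(4)],
                          [f"s{i}" for i in range(4, 8)])
        out, log = ed.prefilter_sites(mat, comp)
        assert "chr1:1+" not in out.site_ids
        assert log["removed_near_constant"] == 1

    def test_median_diff_exactly_3_percent_removed(self):
        case_vals = np.array([0.10, 0.16, 0.23, 0.28, 0.33])
        ref_vals = case_vals - 0.03  # median difference exactly 0.03
        varied = np.array([0.1, 0.5, 0.2, 0.6, 0.3])
        lv = pd.DataFrame(
            np.vstack([np.concatenate([case_vals, ref_vals]),
                       np.concatenate([varied, varied[::-1]]),
                       np.concatenate([varied + 0.3, varied[::-1]])]),
            index=["chr1:1+", "chr1:2+", "chr1:3+"],
            columns=[f"s{i}" for i in range(10)])
        mat = _matrix_from_levels(lv)
        comp = Comparison("T", [f"s{i}" for i in range(5)],
                          [f"s{i}" for i in range(5, 10)])
        out, log = ed.prefilter_sites(mat, comp)
        assert "chr1:1+" not in out.site_ids
        assert log["removed_small_median_diff"] >= 1

    def test_planted_fixture_matches_rule_oracle(self, fixtures):
        fx = fixtures["prefilter"]
        comp = Comparison("T", fx["case"], fx["ref"])
        out, log = ed.prefilter_sites(fx["matrix"], comp)
        assert out.site_ids == fx["truth"]
        assert log["removed_near_constant"] == len(fx["truth_rule1"])
        assert log["removed_small_median_diff"] == len(fx["truth_rule2"])

    def test_sample_order_independent(self, fixtures):
        fx = fixtures["prefilter"]
        comp1 = Comparison("T", fx["case"], fx["ref"])
        comp2 = Comparison("T", fx["case"][::-1], fx["ref"][::-1])
        out1, _ = ed.prefilter_sites(fx["matrix"], comp1)
        out2, _ = ed.prefilter_sites(fx["matrix"], comp2)
        assert out1.site_ids == out2.site_ids


class TestTestDes:
    def test_rank_separated_groups_exact_p(self):
        """case below ref in rank: exact two-sided p = 0.1 = 2/C(6,3)·... by
        enumeration of all 20 assignments."""
        lv = pd.DataFrame([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6]],
                          index=["chr1:1+"], columns=[f"s{i}" for i in range(6)])
        mat = _matrix_from_levels(lv)
        comp = Comparison("T", ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        rec = ed.test_des(mat, comp)
        assert rec["p"].iloc[0] == pytest.approx(0.1, abs=1e-12)
        assert rec["p"].iloc[0] == pytest.approx(
            mwu_exact_oracle([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_identical_groups_not_des(self):
        lv = pd.DataFrame([[0.1, 0.2, 0.3, 0.1, 0.2, 0.3]],
                          index=["chr1:1+"], columns=[f"s{i}" for i in range(6)])
        mat = _matrix_from_levels(lv)
        rec = ed.test_des(mat, Comparison("T", ["s0", "s1", "s2"], ["s3", "s4", "s5"]))
        assert rec["p"].iloc[0] == pytest.approx(1.0)
        assert not rec["is_des"].iloc[0]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_for_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 7), rng.integers(3, 7)
        x = rng.permutation(np.linspace(0.05, 0.9, n + m))
        lv = pd.DataFrame([x], index=["chr1:1+"],
                          columns=[f"s{i}" for i in range(n + m)])
        mat = _matrix_from_levels(lv)
        comp = Comparison("T", [f"s{i}" for i in range(n)],
                          [f"s{i}" for i in range(n, n + m)])
        rec = ed.test_des(mat, comp)
        assert rec["p"].iloc[0] == pytest.approx(
            mwu_exact_oracle(x[:n], x[n:]), abs=1e-9)

    def test_insufficient_group_skipped(self):
        lv = pd.DataFrame([[0.1, np.nan, np.nan, 0.4, 0.5, 0.6]],
                          index=["chr1:1+"], columns=[f"s{i}" for i in range(6)])
        cov = pd.DataFrame([[10.0, np.nan, np.nan, 10, 10, 10]],
                           index=lv.index, columns=lv.columns)
        g = lv * cov
        mat = ed.EditingMatrix(sites=[ed.parse_site_id("chr1:1+")],
                               samples=list(lv.columns), level=lv, g_reads=g, cov=cov)
        rec = ed.test_des(mat, Comparison("T", ["s0", "s1", "s2"], ["s3", "s4", "s5"]))
        assert rec.empty


class TestGeneAggregation:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "comparison", "median_diff",
                                           "u_stat", "p", "padj", "is_des"])

    def _annot(self, pairs):
        return pd.DataFrame(
            {"site_id": [p[0] for p in pairs], "gene": [p[1] for p in pairs],
             "region": "3'UTR"}).set_index("site_id")

    def test_gene_with_one_des_included(self):
        rec = self._records([("chr1:1+", "T", 0.1, 5, 0.001, 0.01, True),
                             ("chr1:2+", "T", 0.0, 5, 0.5, 0.6, False),
                             ("chr1:3+", "T", 0.0, 5, 0.9, 0.9, False)])
        annot = self._annot([("chr1:1+", "A"), ("chr1:2+", "A"), ("chr1:3+", "B")])
        assert ed.genes_with_des(rec, annot) == {"A"}

    def test_empty_records_empty_set(self):
        assert ed.genes_with_des(self._records([]), self._annot([])) == set()

    def test_signed_ranking_scores_and_order(self):
        rec = self._records([("chr1:1+", "T", 0.2, 5, 0.01, 0.02, True),
                             ("chr1:2+", "T", -0.2, 5, 0.001, 0.004, True)])
        annot = self._annot([("chr1:1+", "A"), ("chr1:2+", "B")])
        ranked = ed.rank_genes_signed(rec, annot)
        assert list(ranked["gene"]) == ["A", "B"]
        assert ranked.loc[ranked["gene"] == "A", "score"].iloc[0] == pytest.approx(2.0)
        assert ranked.loc[ranked["gene"] == "B", "score"].iloc[0] == pytest.approx(-3.0)

    def test_most_significant_site_represents_gene(self):
        rec = self._records([("chr1:1+", "T", 0.2, 5, 0.04, 0.08, False),
                             ("chr1:2+", "T", 0.3, 5, 0.01, 0.02, True)])
        annot = self._annot([("chr1:1+", "A"), ("chr1:2+", "A")])
        ranked = ed.rank_genes_signed(rec, annot)
        assert len(ranked) == 1
        assert ranked["site_id"].iloc[0] == "chr1:2+"

    def test_all_positive_diffs_rank_by_significance(self):
        rec = self._records([(f"chr1:{i}+", "T", 0.2, 5, p, p, True)
                             for i, p in enumerate([0.03, 0.001, 0.01], start=1)])
        annot = self._annot([("chr1:1+", "A"), ("chr1:2+", "B"), ("chr1:3+", "C")])
        ranked = ed.rank_genes_signed(rec, annot)
        assert list(ranked["gene"]) == ["B", "C", "A"]


class TestRRHO:
    def test_identical_lists_diagonal_overlap(self):
        genes = [f"g{i}" for i in range(10)]
        grid, counts = ed.rrho_map(genes, genes, step=2)
        for k in (2, 4, 6, 8, 10):
            assert counts.loc[k, k] == k
        assert grid.to_numpy().max() == grid.to_numpy().diagonal().max()

    def test_tiny_universe_matches_enumeration(self):
        """Every cell of an 8-gene step-2 grid equals the brute-force
        hypergeometric tail."""
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(8)]
        l2 = list(rng.permutation(genes))
        grid, counts = ed.rrho_map(genes, l2, step=2)
        for i in grid.index:
            top1 = set(genes[:i])
            for j in grid.columns:
                k = len(top1 & set(l2[:j]))
                assert counts.loc[i, j] == k
                # brute force: sum hypergeometric pmf over >= k overlap
                p = sum(
                    (comb(j, x) * comb(8 - j, i - x)) / comb(8, i)
                    for x in range(k, min(i, j) + 1))
                assert grid.loc[i, j] == pytest.approx(-np.log10(p), abs=1e-9)

    def test_step_too_large_rejected(self):
        genes = [f"g{i}" for i in range(5)]
        with pytest.raises(ValueError, match="step"):
            ed.rrho_map(genes, genes, step=10)

    def test_independent_rankings_stay_below_bonferroni(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(1000)]
        exceed = 0
        n_seeds = 20
        for _ in range(n_seeds):
            l1 = list(rng.permutation(genes))
            l2 = list(rng.permutation(genes))
            grid, _ = ed.rrho_map(l1, l2)
            bound = -np.log10(0.05 / grid.size)
            exceed += grid.to_numpy().max() >= bound
        assert exceed <= 2  # below the bound in >= 90% of seeds
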