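from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

import editome as ed
from editome import regulation as reg


class TestEditingExpressionFit:
    def test_recovers_planted_coefficient(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            editing = rng.beta(2, 8, 100)
            age = rng.normal(55, 10, 100)
            y = 2.0 * editing + 0.01 * age + rng.normal(0, 0.1, 100)
            coef, p = ed.editing_expression_fit(editing, y, age)
            hits += 1.8 <= coef <= 2.2
        assert hits >= 18

    def test_null_p_roughly_uniform(self):
        from scipy.stats import kstest
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            editing = rng.beta(2, 8, 60)
            age = rng.normal(55, 10, 60)
            y = 0.01 * age + rng.normal(0, 0.1, 60)
            pvals.append(ed.editing_expression_fit(rng.permutation(editing), y, age)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_irrelevant_age_covariate_unbiased(self):
        coefs = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            editing = rng.beta(2, 8, 100)
            age = rng.normal(55, 10, 100)
            y = 2.0 * editing + rng.normal(0, 0.1, 100)  # age plays no role
            coefs.append(ed.editing_expression_fit(editing, y, age)[0])
        assert abs(np.mean(coefs) - 2.0) / 2.0 < 0.05

    def test_constant_editing_rejected(self):
        with pytest.raises(ValueError, match="non-informative"):
            ed.editing_expression_fit([0.2] * 20, np.arange(20.0), np.arange(20.0) + 30)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            ed.editing_expression_fit([0.1, 0.2, 0.3], [1, 2, 3], [50, 60, 70])


class TestExpressionCorrelatedSites:
    def _records(self, rows):
        df = pd.DataFrame(rows, columns=["site_id", "gene", "coef", "p"])
        if not df.empty:
            df["fdr"] = ed.bh_adjust(df["p"].to_numpy())
        else:
            df["fdr"] = []
        return df

    def test_all_null_p_empty(self):
        rec = self._records([(f"chr1:{i}+", f"G{i}", 0.1, 1.0) for i in range(5)])
        out = ed.expression_correlated_sites(rec)
        assert not out["significant"].any()

    def test_single_site_bh_identity(self):
        rec = self._records([("chr1:1+", "G1", 1.0, 0.01)])
        out = ed.expression_correlated_sites(rec)
        assert out["fdr"].iloc[0] == pytest.approx(0.01)
        assert out["significant"].iloc[0]

    def test_per_gene_collapse_keeps_smallest_fdr(self):
        rec = self._records([("chr1:1+", "G1", 1.0, 0.04),
                             ("chr1:2+", "G1", 1.0, 0.001),
                             ("chr1:3+", "G2", -1.0, 0.02)])
        out = ed.expression_correlated_sites(rec)
        rep = out[out["gene_representative"]]
        assert set(rep["site_id"]) == {"chr1:2+", "chr1:3+"}


class TestClassifyRegulated:
    def _kd(self, gene="G", log2fc=-1.0, padj=0.001):
        return pd.DataFrame({"gene": [gene], "log2fc": [log2fc],
                             "pvalue": [padj / 2], "padj": [padj]}).set_index("gene")

    def test_truth_table_exhaustive(self):
        """All 12 combinations of coef sign x KD significance x KD sign."""
        for coef, padj, lfc in product((2.0, -2.0), (0.001, 0.2),
                                       (-1.0, 1.0, 0.0)):
            regulated, status = ed.classify_regulated(coef, "G", self._kd("G", lfc, padj))
            expected = (padj < 0.05 and lfc != 0
                        and np.sign(lfc) == -np.sign(coef))
            assert regulated == expected, (coef, padj, lfc)

    def test_untested_distinct_from_failing(self):
        regulated, status = ed.classify_regulated(2.0, "ABSENT", self._kd("G"))
        assert not regulated and status == "untested"

    def test_inverse_relationship_required(self):
        assert ed.classify_regulated(2.0, "G", self._kd("G", -1.0, 0.001))[0]
        assert not ed.classify_regulated(2.0, "G", self._kd("G", 1.0, 0.001))[0]
        assert not ed.classify_regulated(2.0, "G", self._kd("G", -1.0, 0.2))[0]


class TestRegionEnrichment:
    def _annot(self, regions, prefix="chr1"):
        return pd.DataFrame(
            {"site_id": [f"{prefix}:{i}+" for i in range(len(regions))],
             "gene": "G", "region": regions}).set_index("site_id")

    def test_balanced_table_no_enrichment(self):
        bg = self._annot(["3'UTR"] * 10 + ["intronic"] * 10)
        fg = bg.iloc[[0, 1, 2, 3, 4, 10, 11, 12, 13, 14]]
        odds, p = ed.region_enrichment(fg, bg)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        """2x2 table [[8,2],[2,8]] against an exhaustive Fisher oracle."""
        bg = self._annot(["3'UTR"] * 10 + ["intronic"] * 10)
        fg = bg.iloc[list(range(8)) + [10, 11]]
        _, p = ed.region_enrichment(fg, bg)
        # oracle: sum of P(table) over all tables with P <= P(observed)
        def table_p(a):
            return (comb(10, a) * comb(10, 10 - a)) / comb(20, 10)
        p_obs = table_p(8)
        expected = sum(table_p(a) for a in range(0, 11)
                       if table_p(a) <= p_obs + 1e-12)
        assert p == pytest.approx(expected, abs=1e-9)

    def test_foreground_not_subset_rejected(self):
        bg = self._annot(["3'UTR"] * 5 + ["intronic"] * 5)
        fg = self._annot(["3'UTR"] * 3, prefix="chr9")
        with pytest.raises(ValueError, match="subset"):
            ed.region_enrichment(fg, bg)

    def test_intergenic_excluded_from_background(self):
        bg = self._annot(["3'UTR"] * 5 + ["intronic"] * 5 + ["intergenic"] * 30)
        fg = bg.iloc[:5]
        odds, p = ed.region_enrichment(fg, bg)
        bg2 = self._annot(["3'UTR"] * 5 + ["intronic"] * 5)
        odds2, p2 = ed.region_enrichment(bg2.iloc[:5], bg2)
        assert p == pytest.approx(p2)


class TestDirectionBinomial:
    def _classified(self, n_reduced, n_total):
        lfc = [-1.0] * n_reduced + [1.0] * (n_total - n_reduced)
        return pd.DataFrame({
            "gene": [f"G{i}" for i in range(n_total)],
            "coef": 2.0, "regulated": True, "kd_log2fc": lfc})

    def test_all_reduced_closed_form(self):
        frac, p, n = ed.direction_binomial(self._classified(10, 10))
        assert frac == 1.0 and n == 10
        assert p == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_even_split_p_one(self):
        frac, p, _ = ed.direction_binomial(self._classified(5, 10))
        assert p == pytest.approx(1.0)

    def test_no_genes_no_test(self):
        frac, p, n = ed.direction_binomial(self._classified(0, 0))
        assert n == 0 and np.isnan(p)


class TestPrognosticScreen:
    def test_constant_site_skipped_for_that_sex(self, small_cohort):
        mat, meta = small_cohort["mat"], small_cohort["meta"]
        sid = mat.site_ids[0]
        females = [s for s in mat.samples if meta.loc[s, "sex"] == "female"]
        mat = mat.subset_sites(mat.site_ids[:20])
        mat.level.loc[sid, females] = 0.2  # constant in females only
        screen = ed.prognostic_screen(mat, meta, mat.site_ids, min_events=5)
        assert sid not in set(screen.loc[screen["sex"] == "female", "site_id"])

    def test_null_editing_rarely_detected(self):
        rng = np.random.default_rng(3)
        cfg = ed.SimConfig(seed=12, n_samples=120, n_sites=150,
                           n_informative_sites=2, delta_edit=0.0, n_genes=50)
        mat, meta, *_ = ed.generate(cfg)
        screen = ed.prognostic_screen(mat, meta, mat.site_ids[:100], min_events=5)
        assert screen["prognostic"].mean() < 0.1


class TestComposedPipeline:
    def test_recovery_on_small_cohort(self, small_cohort):
        """Regression -> FDR -> KD classification recovers planted regulated
        genes on the session cohort."""
        sc = small_cohort
        mat, truth, annot = sc["mat"], sc["truth"], sc["annot"]
        rng = np.random.default_rng(0)
        anchors = list(truth.anchor_sites.values())
        genic = [s for s in mat.site_ids
                 if annot.loc[s, "gene"] and s not in anchors]
        tested = anchors + list(rng.choice(genic, 100, replace=False))
        fits = reg.fit_des_expression(mat, sc["expr"], sc["meta"], annot, tested)
        out = reg.classify_regulated_table(
            reg.expression_correlated_sites(fits), sc["kd"])
        found = set(out.loc[out["regulated"], "gene"])
        tp = len(found & truth.regulated_genes)
        assert tp / len(truth.regulated_genes) >= 0.8
        assert (len(found) - tp) / max(len(found), 1) <= 0.1
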