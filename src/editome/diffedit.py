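"""Differential-editing detection between risk groups.

Each comparison (e.g. F1: high-risk vs. low-risk females) runs a filter
cascade — near-constant sites (same level in > 70% of samples AND
variance in the bottom 20%) and sites with absolute median difference
<= 3% are removed — followed by a two-sided Mann-Whitney U test per site
with Benjamini-Hochberg correction across the comparison's tested sites.
Sites with adjusted p < 0.05 are differentially edited sites (DESs), and
genes owning at least one DES are differentially edited. Gene-level
signed rankings (direction x -log10 p of the gene's most significant
site) feed rank-rank hypergeometric overlap (RRHO) maps between
comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from editome.io import EditingMatrix
from editome.survival import bh_adjust

logger = logging.getLogger(__name__)

#: cap for -log10(p) when the test returns exactly zero
MAX_NEGLOG10_P = 300.0


@dataclass
class Comparison:
    """A named case-vs-reference contrast within one sex."""

    name: str
    case_samples: list
    ref_samples: list
    sex: str = ""

    def __post_init__(self) -> None:
        case, ref = set(self.case_samples), set(self.ref_samples)
        if not case or not ref:
            raise ValueError(f"comparison {self.name}: empty group")
        if case & ref:
            raise ValueError(f"comparison {self.name}: groups overlap")


def prefilter_sites(
    mat: EditingMatrix, comparison: Comparison, *,
    same_level_frac: float = 0.70, variance_quantile: float = 0.20,
    min_abs_median_diff: float = 0.03, conjunctive: bool = True,
) -> tuple[EditingMatrix, dict]:
    """Remove near-constant and small-difference sites before testing.

    Rule 1 removes sites whose modal editing level occurs in more than
    ``same_level_frac`` of the comparison's samples *and* whose variance
    sits in the bottom ``variance_quantile`` of the per-site variance
    distribution (set ``conjunctive=False`` to remove on either condition
    alone). Rule 2 then removes sites with |case median - ref median|
    <= ``min_abs_median_diff``. Returns the surviving subset (order
    preserved) and a removal log.
    """
    samples = list(comparison.case_samples) + list(comparison.ref_samples)
    lv = mat.level[samples].to_numpy(float)
    n_sites = mat.n_sites

    mode_frac = np.zeros(n_sites)
    variance = np.full(n_sites, np.nan)
    for i in range(n_sites):
        row = lv[i][~np.isnan(lv[i])]
        if row.size == 0:
            mode_frac[i] = 1.0
            continue
        _, counts = np.unique(row, return_counts=True)
        mode_frac[i] = counts.max() / row.size
        variance[i] = np.var(row, ddof=1) if row.size > 1 else 0.0
    var_cut = np.nanquantile(variance, variance_quantile)
    low_var = np.nan_to_num(variance, nan=0.0) <= var_cut
    near_constant = mode_frac > same_level_frac
    rule1 = (near_constant & low_var) if conjunctive else (near_constant | low_var)

    case_lv = mat.level[list(comparison.case_samples)].to_numpy(float)
    ref_lv = mat.level[list(comparison.ref_samples)].to_numpy(float)
    with np.errstate(invalid="ignore"):
        med_diff = np.nanmedian(case_lv, axis=1) - np.nanmedian(ref_lv, axis=1)
    rule2 = ~rule1 & (np.abs(np.nan_to_num(med_diff)) <= min_abs_median_diff)

    keep = ~rule1 & ~rule2
    log = {
        "input_sites": n_sites,
        "removed_near_constant": int(rule1.sum()),
        "removed_small_median_diff": int(rule2.sum()),
        "kept": int(keep.sum()),
    }
    logger.info("prefilter %s: %s", comparison.name, log)
    if not keep.any():
        raise ValueError(f"comparison {comparison.name}: all sites removed by pre-filters")
    out = mat.subset_sites([s for s, k in zip(mat.site_ids, keep) if k])
    return out, log


def test_des(mat: EditingMatrix, comparison: Comparison, *,
             alpha: float = 0.05) -> pd.DataFrame:
    """Mann-Whitney U differential-editing test per pre-filtered site.

    Two-sided, exact for small tieless groups and normal-approximated
    with continuity and tie correction otherwise. BH adjustment spans the
    comparison's tested sites only. Sites with < 2 non-missing values in
    either group are skipped and logged.

    Returns one row per tested site: ``site_id, comparison, median_diff,
    u_stat, p, padj, is_des``.
    """
    case_lv = mat.level[list(comparison.case_samples)].to_numpy(float)
    ref_lv = mat.level[list(comparison.ref_samples)].to_numpy(float)
    rows, skipped = [], []
    for i, sid in enumerate(mat.site_ids):
        x = case_lv[i][~np.isnan(case_lv[i])]
        y = ref_lv[i][~np.isnan(ref_lv[i])]
        if x.size < 2 or y.size < 2:
            skipped.append(sid)
            continue
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            u, p = x.size * y.size / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        rows.append({"site_id": sid, "comparison": comparison.name,
                     "median_diff": float(np.median(x) - np.median(y)),
                     "u_stat": float(u), "p": float(p)})
    if skipped:
        logger.info("test_des %s: %d sites skipped for insufficient data",
                    comparison.name, len(skipped))
    records = pd.DataFrame(rows)
    if records.empty:
        return records.reindex(columns=["site_id", "comparison", "median_diff",
                                        "u_stat", "p", "padj", "is_des"])
    records["padj"] = bh_adjust(records["p"].to_numpy())
    records["is_des"] = records["padj"] < alpha
    return records


def genes_with_des(records: pd.DataFrame, annotation: pd.DataFrame) -> set:
    """Genes owning at least one DES; unannotated DESs land in '<unannotated>'."""
    genes: set = set()
    if records.empty:
        return genes
    for sid in records.loc[records["is_des"], "site_id"]:
        if sid in annotation.index and annotation.loc[sid, "gene"]:
            genes.add(annotation.loc[sid, "gene"])
        else:
            genes.add("<unannotated>")
            logger.warning("DES %s has no gene annotation", sid)
    return genes


def rank_genes_signed(records: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Signed gene ranking: direction x significance of the best site per gene.

    Each gene is represented by its most significant (smallest raw p)
    site; the score is sign(median_diff) * -log10(p), so hyper-edited
    genes in cases rank at the top and hypo-edited at the bottom.
    Descending score order; ties break alphabetically by gene symbol.
    """
    rows = []
    for _, r in records.iterrows():
        sid = r["site_id"]
        gene = annotation.loc[sid, "gene"] if sid in annotation.index else ""
        if not gene:
            continue
        rows.append({"gene": gene, "site_id": sid, "p": r["p"],
                     "median_diff": r["median_diff"]})
    if not rows:
        return pd.DataFrame(columns=["gene", "site_id", "p", "median_diff", "score"])
    df = pd.DataFrame(rows)
    df = (df.sort_values(["p", "site_id"], kind="stable")
            .drop_duplicates("gene", keep="first"))
    neglog = -np.log10(np.maximum(df["p"].to_numpy(), 0.0))
    capped = ~np.isfinite(neglog) | (neglog > MAX_NEGLOG10_P)
    if capped.any():
        logger.warning("%d genes with p = 0; -log10 p capped at %g",
                       int(capped.sum()), MAX_NEGLOG10_P)
    neglog = np.minimum(np.nan_to_num(neglog, posinf=MAX_NEGLOG10_P), MAX_NEGLOG10_P)
    df["score"] = np.sign(df["median_diff"].to_numpy()) * neglog
    return (df.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
              .reset_index(drop=True))


def rrho_map(list1, list2, step: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-rank hypergeometric overlap between two ranked gene lists.

    Restricts both lists to their common universe (logged), then for each
    threshold pair (i*step, j*step) counts the overlap of the two top
    slices and computes the one-sided hypergeometric enrichment p.
    Returns (-log10 p grid, overlap-count grid), rows indexed by list1
    thresholds and columns by list2 thresholds. Default step is
    max(1, N // 100).
    """
    l1, l2 = list(list1), list(list2)
    universe = set(l1) & set(l2)
    if len(universe) < len(l1) or len(universe) < len(l2):
        logger.info("RRHO: restricting to common universe of %d genes", len(universe))
    l1 = [g for g in l1 if g in universe]
    l2 = [g for g in l2 if g in universe]
    n = len(universe)
    if n == 0:
        raise ValueError("empty common gene universe")
    if step is None:
        step = max(1, n // 100)
    if step >= n + 1:
        raise ValueError(f"step {step} too large for universe of {n} genes")
    thresholds = list(range(step, n + 1, step))
    rank2 = {g: i for i, g in enumerate(l2)}
    neglog = np.zeros((len(thresholds), len(thresholds)))
    counts = np.zeros_like(neglog, dtype=int)
    for a, i in enumerate(thresholds):
        top1 = l1[:i]
        in2_rank = np.sort([rank2[g] for g in top1])
        for b, j in enumerate(thresholds):
            k = int(np.searchsorted(in2_rank, j, side="left"))
            counts[a, b] = k
            # P(overlap >= k) drawing i from N with j marked
            p = stats.hypergeom.sf(k - 1, n, j, i)
            neglog[a, b] = min(-np.log10(max(p, 0.0)) if p > 0 else MAX_NEGLOG10_P,
                               MAX_NEGLOG10_P)
    grid = pd.DataFrame(neglog, index=thresholds, columns=thresholds)
    cgrid = pd.DataFrame(counts, index=thresholds, columns=thresholds)
    return grid, cgrid
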