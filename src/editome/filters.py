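"""Editing-evidence testing and discriminative-site selection.

A cell (site x sample) counts as *edited* when three conditions hold:
read coverage A+G >= ``min_cov``, edited-G reads >= ``min_g``, and the
editing level exceeds the null bound ``level_floor`` by a one-sided
binomial test against the sequencing error rate, Benjamini-Hochberg
adjusted across all tested cells at ``fdr``. *Discriminative* sites
additionally show inter-patient variation: the median absolute deviation
of per-site levels from their third quartile must be strictly positive.
Samples with too many low-coverage sites are dropped before subtyping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from editome.io import EditingMatrix
from editome.survival import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds of the editing-evidence filter cascade.

    error_rate : assumed per-base sequencing error probability (0.001,
        i.e. 0.1%); the binomial null for edited-G reads.
    min_cov : minimum A+G read coverage per cell (10).
    min_g : minimum edited-G reads per cell (3).
    level_floor : editing-rate null bound for the binomial test (0.001).
    fdr : BH threshold on adjusted binomial p-values (0.05).
    max_lowcov_frac : tolerated per-sample fraction of low-coverage or
        missing sites (0.20); samples *above* this are removed.
    """

    error_rate: float = 0.001
    min_cov: int = 10
    min_g: int = 3
    level_floor: float = 0.001
    fdr: float = 0.05
    max_lowcov_frac: float = 0.20

    def __post_init__(self) -> None:
        for name in ("error_rate", "level_floor", "fdr", "max_lowcov_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not self.min_cov >= self.min_g >= 0:
            raise ValueError("require min_cov >= min_g >= 0")


def binomial_tail(g: int, n: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= g) for X ~ Binomial(n, p0)."""
    if not 0 <= g <= n:
        raise ValueError(f"require 0 <= g <= n, got g={g}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    return float(stats.binom.sf(g - 1, n, p0))


def call_edited_cells(mat: EditingMatrix, cfg: FilterConfig | None = None) -> pd.DataFrame:
    """Per-cell edited/not-edited mask.

    Cells with missing counts are excluded from testing (mask False). The
    BH family is all non-missing cells of the call, so the adjusted
    p-value of a cell depends on the whole matrix passed in.
    """
    cfg = cfg or FilterConfig()
    if mat.n_sites == 0 or mat.n_samples == 0:
        raise ValueError("empty editing matrix")
    g = mat.g_reads.to_numpy(float)
    c = mat.cov.to_numpy(float)
    tested = ~np.isnan(g) & ~np.isnan(c)
    pvals = np.full(g.shape, np.nan)
    gi, ci = g[tested].astype(int), c[tested].astype(int)
    # sf(g-1, n, p0) vectorised over cells
    pvals[tested] = stats.binom.sf(gi - 1, ci, cfg.level_floor)
    padj = np.full(g.shape, np.nan)
    padj[tested] = bh_adjust(pvals[tested])
    passed = (
        tested
        & (np.nan_to_num(c) >= cfg.min_cov)
        & (np.nan_to_num(g) >= cfg.min_g)
        & (np.nan_to_num(padj, nan=1.0) < cfg.fdr)
    )
    return pd.DataFrame(passed, index=mat.level.index, columns=mat.level.columns)


def mad_from_q3(values) -> float:
    """Median absolute deviation from the third quartile (type-7 Q3).

    The Q3 is the 0.75 quantile under the linear-interpolation convention;
    a strictly positive value certifies inter-patient variation.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("mad_from_q3 requires at least one non-missing value")
    q3 = np.quantile(v, 0.75)  # linear interpolation (type 7)
    return float(np.median(np.abs(v - q3)))


def select_discriminative_sites(
    mat: EditingMatrix, cfg: FilterConfig | None = None
) -> EditingMatrix:
    """Retain sites with editing evidence and inter-patient variation.

    A site survives iff at least one of its cells is called edited and the
    per-site levels have ``mad_from_q3 > 0``. Order is preserved; removal
    counts per criterion are logged and recorded in ``meta``.
    """
    cfg = cfg or FilterConfig()
    mask = call_edited_cells(mat, cfg)
    has_evidence = mask.to_numpy().any(axis=1)
    lv = mat.level.to_numpy(float)
    varied = np.zeros(mat.n_sites, dtype=bool)
    for i in range(mat.n_sites):
        row = lv[i][~np.isnan(lv[i])]
        varied[i] = row.size > 0 and mad_from_q3(row) > 0
    keep = has_evidence & varied
    n_no_evidence = int((~has_evidence).sum())
    n_constant = int((has_evidence & ~varied).sum())
    logger.info(
        "discriminative-site selection: %d/%d kept (%d without editing evidence, "
        "%d without variation among evidenced sites)",
        int(keep.sum()), mat.n_sites, n_no_evidence, n_constant,
    )
    if not keep.any():
        raise ValueError("no discriminative sites survive the filter cascade")
    out = mat.subset_sites([s for s, k in zip(mat.site_ids, keep) if k])
    out.meta["filter_log"] = {
        "input_sites": mat.n_sites,
        "removed_no_evidence": n_no_evidence,
        "removed_no_variation": n_constant,
        "kept": int(keep.sum()),
    }
    return out


def drop_lowcov_samples(mat: EditingMatrix, cfg: FilterConfig | None = None) -> EditingMatrix:
    """Remove samples with more than ``max_lowcov_frac`` low-coverage sites.

    A site counts as low-coverage for a sample when its A+G coverage is
    below ``min_cov`` or missing. A sample at exactly the threshold is
    retained (the rule is "more than").
    """
    cfg = cfg or FilterConfig()
    c = mat.cov.to_numpy(float)
    lowcov = np.isnan(c) | (c < cfg.min_cov)
    frac = lowcov.mean(axis=0)
    keep = frac <= cfg.max_lowcov_frac
    dropped = [s for s, k in zip(mat.samples, keep) if not k]
    if dropped:
        logger.info("dropping %d low-coverage samples: %s", len(dropped), dropped)
    out = mat.subset_samples([s for s, k in zip(mat.samples, keep) if k])
    out.meta["lowcov_dropped"] = dropped
    return out
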