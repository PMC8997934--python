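"""Editing-to-expression regulatory inference and prognostic screening.

Per differentially edited site (DES), host-gene expression is regressed
on editing level with age as a confounder: OLS of log(abundance + 0.5)
on [editing, age]. Sites whose editing coefficient survives BH at
FDR < 0.10 are expression-correlated. A gene counts as editing-regulated
when ADAR1 knockdown significantly changes its expression (adjusted
p < 0.05) in the direction *opposite* to the editing-expression
coefficient — knockdown lowers editing, so a positive coefficient should
show reduced expression. Region enrichment (3'UTR vs. the rest,
intergenic excluded from the background) uses Fisher's exact test, and
the knockdown direction bias uses an exact binomial test against 0.5.
The prognostic screen fits, per site and sex, an age-adjusted Cox model
of survival on editing level, BH-corrected within sex at FDR < 0.15.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from editome.io import EditingMatrix
from editome.survival import bh_adjust, cox_fit

logger = logging.getLogger(__name__)

#: pseudo-count added to abundance before the log transform
EXPR_PSEUDOCOUNT = 0.5


def editing_expression_fit(editing, log_expr, age) -> tuple[float, float]:
    """OLS of log-expression on [editing level, age]; returns (coef, p).

    ``log_expr`` must already be log-transformed (see
    :func:`log_abundance`). Requires >= 10 complete observations and a
    non-constant editing vector.
    """
    e = np.asarray(editing, dtype=float)
    y = np.asarray(log_expr, dtype=float)
    a = np.asarray(age, dtype=float)
    ok = ~(np.isnan(e) | np.isnan(y) | np.isnan(a))
    e, y, a = e[ok], y[ok], a[ok]
    if e.size < 10:
        raise ValueError(f"need >= 10 complete samples, got {e.size}")
    if np.all(e == e[0]):
        raise ValueError("non-informative site: editing level is constant")
    X = sm.add_constant(np.column_stack([e, a]))
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def log_abundance(expr) -> np.ndarray:
    """log(abundance + 0.5) transform for RSEM-like values."""
    return np.log(np.asarray(expr, dtype=float) + EXPR_PSEUDOCOUNT)


def fit_des_expression(
    mat: EditingMatrix, expression: pd.DataFrame, meta: pd.DataFrame,
    annotation: pd.DataFrame, des_site_ids: list,
) -> pd.DataFrame:
    """Editing-expression regression for every DES with an annotated host gene.

    Returns one row per testable (site, gene) pair with ``coef``, ``p``
    and a ``fdr`` column BH-adjusted across all tested pairs of the run.
    """
    samples = [s for s in mat.samples if s in meta.index and s in expression.columns]
    age = meta.loc[samples, "age"].to_numpy(float)
    rows = []
    for sid in des_site_ids:
        if sid not in annotation.index:
            continue
        gene = annotation.loc[sid, "gene"]
        if not gene or gene not in expression.index:
            continue
        editing = mat.level.loc[sid, samples].to_numpy(float)
        y = log_abundance(expression.loc[gene, samples].to_numpy(float))
        try:
            coef, p = editing_expression_fit(editing, y, age)
        except ValueError:
            continue
        rows.append({"site_id": sid, "gene": gene, "coef": coef, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    else:
        out = out.reindex(columns=["site_id", "gene", "coef", "p", "fdr"])
    return out


def expression_correlated_sites(records: pd.DataFrame,
                                fdr_threshold: float = 0.10) -> pd.DataFrame:
    """Flag expression-correlated sites and collapse to one site per gene.

    ``records`` comes from :func:`fit_des_expression` (columns site_id,
    gene, coef, p, fdr). Sites with fdr < threshold are flagged; the
    per-gene representative is the site with the smallest adjusted p
    (ties by site_id).
    """
    if records.empty:
        return records.assign(significant=pd.Series(dtype=bool),
                              gene_representative=pd.Series(dtype=bool))
    out = records.copy()
    out["significant"] = out["fdr"] < fdr_threshold
    best = (out.sort_values(["fdr", "p", "site_id"], kind="stable")
               .drop_duplicates("gene", keep="first")["site_id"])
    out["gene_representative"] = out["site_id"].isin(set(best))
    return out


def classify_regulated(coef: float, gene: str, kd_table: pd.DataFrame,
                       *, alpha: float = 0.05) -> tuple[bool, str]:
    """Editing-regulated call for one expression-correlated gene.

    True iff the ADAR1-knockdown change is significant (padj < alpha) and
    its sign opposes the editing-expression coefficient. Returns
    (regulated, status) where status is one of "regulated",
    "not_significant", "same_direction", "untested" (gene absent from the
    knockdown table — distinct from failing the criteria), or
    "zero_coef".
    """
    if gene not in kd_table.index:
        return False, "untested"
    kd_log2fc = float(kd_table.loc[gene, "log2fc"])
    kd_padj = float(kd_table.loc[gene, "padj"])
    if kd_padj >= alpha:
        return False, "not_significant"
    if coef == 0 or kd_log2fc == 0:
        return False, "zero_coef"
    if np.sign(kd_log2fc) == -np.sign(coef):
        return True, "regulated"
    return False, "same_direction"


def classify_regulated_table(correlated: pd.DataFrame, kd_table: pd.DataFrame,
                             *, alpha: float = 0.05) -> pd.DataFrame:
    """Apply :func:`classify_regulated` to every significant correlated site."""
    out = correlated.copy()
    regulated, status = [], []
    for _, r in out.iterrows():
        if not r.get("significant", False):
            regulated.append(False)
            status.append("not_correlated")
            continue
        reg, st = classify_regulated(r["coef"], r["gene"], kd_table, alpha=alpha)
        regulated.append(reg)
        status.append(st)
    out["regulated"] = regulated
    out["kd_status"] = status
    out["kd_log2fc"] = [
        float(kd_table.loc[g, "log2fc"]) if g in kd_table.index else np.nan
        for g in out["gene"]
    ]
    out["kd_padj"] = [
        float(kd_table.loc[g, "padj"]) if g in kd_table.index else np.nan
        for g in out["gene"]
    ]
    return out


def region_enrichment(foreground: pd.DataFrame, background: pd.DataFrame,
                      region: str = "3'UTR") -> tuple[float, float]:
    """Fisher exact test for region enrichment of foreground sites.

    ``foreground``/``background`` are annotation frames (index site_id,
    column region); foreground must be a subset of background. Intergenic
    sites are excluded from the background before forming the 2x2 table
    (in-region vs. not x foreground vs. background-minus-foreground).
    Returns (odds ratio, two-sided p).
    """
    bg = background[background["region"] != "intergenic"]
    fg = foreground[foreground.index.isin(bg.index)]
    if not set(foreground.index) <= set(background.index):
        raise ValueError("foreground sites must be a subset of the background")
    rest = bg.drop(index=fg.index)
    a = int((fg["region"] == region).sum())
    b = int((fg["region"] != region).sum())
    c = int((rest["region"] == region).sum())
    d = int((rest["region"] != region).sum())
    table = np.array([[a, b], [c, d]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError(f"degenerate 2x2 table {table.tolist()}")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def direction_binomial(classified: pd.DataFrame) -> tuple[float, float, int]:
    """Bias of knockdown direction among positive-coefficient regulated genes.

    Returns (fraction with reduced expression on knockdown, two-sided
    exact binomial p against 0.5, n). With zero regulated
    positive-coefficient genes no test is run and (nan, nan, 0) returned.
    """
    sub = classified[(classified["regulated"]) & (classified["coef"] > 0)]
    sub = sub.drop_duplicates("gene")
    n = len(sub)
    if n == 0:
        logger.info("direction_binomial: no regulated positive-coefficient genes")
        return float("nan"), float("nan"), 0
    k = int((sub["kd_log2fc"] < 0).sum())
    p = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return k / n, float(p), n


def prognostic_screen(
    mat: EditingMatrix, meta: pd.DataFrame, des_site_ids: list,
    *, fdr_threshold: float = 0.15, min_events: int = 10,
) -> pd.DataFrame:
    """Sex-stratified age-adjusted Cox screen of DES editing levels.

    Per site and sex: Cox fit of survival on [editing level, age]; BH
    across the sex's tested sites; prognostic iff fdr < 0.15. Sexes with
    fewer than ``min_events`` events are not screened; non-convergent or
    constant-editing sites are skipped and logged. Returns one row per
    (site, sex) with log-HR, HR, p, fdr and the prognostic flag.
    """
    rows = []
    for sx in ("female", "male"):
        samples = [s for s in mat.samples
                   if s in meta.index and meta.loc[s, "sex"] == sx]
        if not samples:
            continue
        sub = meta.loc[samples]
        if int(sub["event"].sum()) < min_events:
            logger.warning("prognostic screen: %s has < %d events, skipped",
                           sx, min_events)
            continue
        sex_rows = []
        for sid in des_site_ids:
            lv = mat.level.loc[sid, samples].to_numpy(float)
            ok = ~np.isnan(lv)
            if ok.sum() < 10 or np.nanstd(lv) == 0:
                continue
            X = pd.DataFrame({"editing": lv[ok],
                              "age": sub.loc[ok, "age"].to_numpy(float)})
            try:
                fit = cox_fit(sub.loc[ok, "time"], sub.loc[ok, "event"], X)
            except Exception as err:  # noqa: BLE001 - the screen must survive bad sites
                logger.debug("prognostic screen: site %s (%s) skipped: %s", sid, sx, err)
                continue
            sex_rows.append({"site_id": sid, "sex": sx,
                             "hr_age_adj": float(fit.hr["editing"]),
                             "p": float(fit.p["editing"])})
        if not sex_rows:
            continue
        df = pd.DataFrame(sex_rows)
        df["fdr"] = bh_adjust(df["p"].to_numpy())
        df["prognostic"] = df["fdr"] < fdr_threshold
        rows.append(df)
    if not rows:
        return pd.DataFrame(columns=["site_id", "sex", "hr_age_adj", "p", "fdr",
                                     "prognostic"])
    return pd.concat(rows, ignore_index=True)


def prognostic_intersection(screen: pd.DataFrame) -> set:
    """Sites prognostic in both sexes."""
    by_sex = {sx: set(g.loc[g["prognostic"], "site_id"])
              for sx, g in screen.groupby("sex")}
    if len(by_sex) < 2:
        return set()
    out = None
    for s in by_sex.values():
        out = s if out is None else out & s
    return out or set()
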