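"""Survival machinery shared by every pipeline stage.

Kaplan-Meier product-limit estimation, the unweighted log-rank test, Cox
proportional-hazards fits with Efron tie handling, Benjamini-Hochberg
adjustment, and the sex-dependent high/low editing dichotomisation used
for per-site prognostic Kaplan-Meier plots (top 30% of editing labeled
"high" in females, top 70% in males).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from statsmodels.stats.multitest import multipletests


@dataclass
class SurvivalFit:
    """Cox model summary: per-covariate hazard ratios, CIs and Wald p."""

    hr: pd.Series
    ci95: pd.DataFrame  # columns: low, high
    p: pd.Series
    n: int
    events: int
    flags: list

    def __post_init__(self) -> None:
        assert (self.hr > 0).all()
        assert (self.ci95["low"] <= self.hr + 1e-9).all()
        assert (self.hr <= self.ci95["high"] + 1e-9).all()


def _check_times_events(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if not np.isin(e, [0, 1]).all():
        raise ValueError("events must be 0 or 1")
    return t, e.astype(int)


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as a right-continuous step table.

    Returns a frame with columns ``time`` and ``survival`` starting at
    (0, 1.0); the survival column gives S(t) at and after each time.
    """
    t, e = _check_times_events(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    out = pd.DataFrame({"time": sf.index.to_numpy(float),
                        "survival": sf.iloc[:, 0].to_numpy(float)})
    if out.iloc[0]["time"] != 0.0:
        out = pd.concat([pd.DataFrame({"time": [0.0], "survival": [1.0]}), out],
                        ignore_index=True)
    return out


def km_median(times, events) -> float:
    """KM median survival time (inf when the curve never reaches 0.5)."""
    t, e = _check_times_events(times, events)
    kmf = KaplanMeierFitter().fit(t, e)
    return float(kmf.median_survival_time_)


def rmst(times, events, horizon: float | None = None) -> float:
    """Restricted mean survival time up to ``horizon`` (default: last time)."""
    t, e = _check_times_events(times, events)
    horizon = float(np.max(t)) if horizon is None else horizon
    kmf = KaplanMeierFitter().fit(t, e)
    return float(restricted_mean_survival_time(kmf, t=horizon))


def logrank(times, events, groups) -> tuple[float, float]:
    """Unweighted log-rank chi-square test across >= 2 groups.

    Returns ``(statistic, p)``; the statistic has k-1 degrees of freedom
    for k groups.
    """
    t, e = _check_times_events(times, events)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(t, g, e)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(times, events, covariates: pd.DataFrame) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron tie handling, Wald p-values).

    Raises on all-censored data, constant covariates, or non-convergence;
    likely complete separation is reported in ``flags`` rather than
    raised, since the fit may still be usable for screening.
    """
    t, e = _check_times_events(times, events)
    X = pd.DataFrame(covariates).astype(float).reset_index(drop=True)
    if e.sum() == 0:
        raise ValueError("no events observed; Cox model is unidentifiable")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariates: {const}")
    df = X.copy()
    df["_time"], df["_event"] = t, e
    cph = CoxPHFitter()
    flags: list = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as err:
            raise ValueError(f"Cox model failed to converge: {err}") from err
        for w in caught:
            msg = str(w.message)
            if "complete separation" in msg or "convergence" in msg.lower():
                flags.append(msg.splitlines()[0])
    s = cph.summary
    return SurvivalFit(
        hr=s["exp(coef)"].copy(),
        ci95=pd.DataFrame({"low": s["exp(coef) lower 95%"],
                           "high": s["exp(coef) upper 95%"]}),
        p=s["p"].copy(),
        n=len(df),
        events=int(e.sum()),
        flags=flags,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dichotomize_editing(values, sex, *, female_high_frac: float = 0.30,
                        male_high_frac: float = 0.70) -> pd.Series:
    """Sex-dependent high/low split of per-sample editing levels.

    Within each sex the highest ``frac`` of values is labeled ``high``
    (top 30% for females, top 70% for males); ties at the cut are resolved
    by stable sample order. Sexes with fewer than 4 samples, or with
    constant values, are skipped (labels left missing) with a warning.
    """
    v = pd.Series(np.asarray(values, dtype=float))
    s = pd.Series(np.asarray(sex, dtype=object))
    if len(v) != len(s):
        raise ValueError("values and sex must align")
    labels = pd.Series([None] * len(v), dtype=object)
    for sx, frac in (("female", female_high_frac), ("male", male_high_frac)):
        idx = np.flatnonzero((s == sx).to_numpy() & ~v.isna().to_numpy())
        if idx.size < 4:
            if idx.size:
                warnings.warn(f"{sx}: fewer than 4 samples, dichotomisation skipped")
            continue
        if v.iloc[idx].nunique() == 1:
            warnings.warn(f"{sx}: constant editing values, split is non-informative")
            labels.iloc[idx] = "low"
            continue
        k = int(np.floor(frac * idx.size + 0.5))
        order = idx[np.argsort(-v.iloc[idx].to_numpy(), kind="stable")]
        labels.iloc[order[:k]] = "high"
        labels.iloc[order[k:]] = "low"
    return labels
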