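"""Sex-specific cross-cohort subtype classifiers.

Random forests trained on one cohort's editing-based subtype labels and
applied to a second cohort. Feature selection starts from sites that are
strongly differentially edited between the training subtypes (sex-
specific adjusted-p cuts: 5e-4 for females, 1e-5 for males) and shared
with the target cohort, prunes collinear sites greedily in significance
order, then tunes forest hyperparameters and the feature count by
five-fold cross-validation with a survival objective: the log-rank
p-value of training survival split by pooled out-of-fold predicted
labels. The winning model is refit on the full training cohort and its
target predictions evaluated by per-sex Kaplan-Meier/log-rank and an
age-adjusted Cox model (plus MGMT status when supplied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from editome.io import EditingMatrix
from editome.subtype import NOISE, sex_stratified_eval
from editome.survival import cox_fit, logrank

logger = logging.getLogger(__name__)

DEFAULT_PARAM_GRID = [
    {"n_estimators": 200, "max_depth": None},
    {"n_estimators": 200, "max_depth": 4},
]


@dataclass
class ClassifierSpec:
    """Configuration of one sex-specific classifier."""

    sex: str
    init_p_threshold: float | None = None  # default set by sex below
    collinearity_r: float = 0.9
    cv_folds: int = 5
    param_grid: list = field(default_factory=lambda: [dict(g) for g in DEFAULT_PARAM_GRID])
    n_features_grid: list = field(default_factory=lambda: [10, 25, 50])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")
        if self.init_p_threshold is None:
            self.init_p_threshold = 5e-4 if self.sex == "female" else 1e-5


def initial_features(des_records: pd.DataFrame, shared_sites, spec: ClassifierSpec) -> list:
    """Strongly differential sites shared by both cohorts, ordered by padj."""
    shared = set(shared_sites)
    sub = des_records[(des_records["padj"] < spec.init_p_threshold)
                      & des_records["site_id"].isin(shared)]
    if sub.empty:
        raise ValueError(
            f"no initial features at padj < {spec.init_p_threshold}; "
            "relax the threshold or check cohort overlap"
        )
    sub = sub.sort_values(["padj", "site_id"], kind="stable")
    return sub["site_id"].tolist()


def prune_collinear(mat: EditingMatrix, sites: list, r_cut: float = 0.9) -> list:
    """Greedy collinearity pruning in significance order.

    A site is kept iff its absolute Pearson correlation (on per-site
    median-imputed levels) with every already-kept site is < ``r_cut``.
    Deterministic given the input order.
    """
    lv = mat.level.loc[sites].to_numpy(float)
    med = np.nanmedian(lv, axis=1)
    med = np.where(np.isnan(med), 0.0, med)
    lv = np.where(np.isnan(lv), med[:, None], lv)
    kept_idx: list[int] = []
    for i in range(len(sites)):
        x = lv[i]
        if np.std(x) == 0:
            continue
        ok = True
        for j in kept_idx:
            r = np.corrcoef(x, lv[j])[0, 1]
            if abs(r) >= r_cut:
                ok = False
                break
        if ok:
            kept_idx.append(i)
    return [sites[i] for i in kept_idx]


def _feature_frame(mat: EditingMatrix, sites: list) -> pd.DataFrame:
    lv = mat.level.loc[sites]
    med = lv.median(axis=1)
    return lv.T.fillna(med).fillna(0.0)


def tune_by_survival(
    mat: EditingMatrix, labels: pd.Series, meta: pd.DataFrame,
    sites: list, spec: ClassifierSpec,
) -> dict:
    """Grid search with a pooled out-of-fold log-rank objective.

    For every (forest params, feature count) grid point: stratified
    five-fold CV on the training cohort; out-of-fold predicted labels are
    pooled and the log-rank p of training survival across them computed.
    The smallest p wins (ties to the earlier grid point). Feature
    importances are averaged over the five folds and the top-k sites by
    mean importance define the feature-count grid axis. Returns the
    winning parameters, ranked features, and the full audit table.
    """
    samples = [s for s in mat.samples if labels.get(s, NOISE) != NOISE]
    X_all = _feature_frame(mat, sites).loc[samples]
    y = labels.loc[samples].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain fewer than two classes")
    sub = meta.loc[samples]
    n_splits = min(spec.cv_folds, int(pd.Series(y).value_counts().min()))
    if n_splits < 2:
        raise ValueError("a class has too few samples for stratified folding")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(X_all, y))

    audit_rows, best = [], None
    gi = 0
    for params in spec.param_grid:
        # importance ranking is computed per forest-parameter setting
        importances = np.zeros(len(sites))
        oof_full = np.empty(len(samples), dtype=y.dtype)
        for tr, te in folds:
            rf = RandomForestClassifier(random_state=spec.seed, **params)
            rf.fit(X_all.iloc[tr], y[tr])
            importances += rf.feature_importances_
            oof_full[te] = rf.predict(X_all.iloc[te])
        importances /= len(folds)
        rank = np.argsort(-importances, kind="stable")
        for k in spec.n_features_grid:
            k_eff = min(k, len(sites))
            top = [sites[i] for i in rank[:k_eff]]
            oof = np.empty(len(samples), dtype=y.dtype)
            for tr, te in folds:
                rf = RandomForestClassifier(random_state=spec.seed, **params)
                rf.fit(X_all[top].iloc[tr], y[tr])
                oof[te] = rf.predict(X_all[top].iloc[te])
            if len(np.unique(oof)) < 2:
                p = np.nan
            else:
                _, p = logrank(sub["time"], sub["event"], oof)
            audit_rows.append({"grid_index": gi, **params, "n_features": k_eff,
                               "logrank_p": p})
            if not np.isnan(p) and (best is None or p < best["logrank_p"]):
                best = {"grid_index": gi, "params": dict(params), "n_features": k_eff,
                        "features": top,
                        "importances": importances[rank[:k_eff]].tolist(),
                        "logrank_p": p}
            gi += 1
    audit = pd.DataFrame(audit_rows)
    if best is None:
        raise ValueError("no grid point produced a two-class out-of-fold labeling")
    best["audit"] = audit
    return best


def fit_and_transfer(
    train_mat: EditingMatrix, train_labels: pd.Series, train_meta: pd.DataFrame,
    target_mat: EditingMatrix, target_meta: pd.DataFrame | None,
    tuned: dict, spec: ClassifierSpec,
) -> dict:
    """Refit the tuned forest on the full training cohort and label the target.

    Evaluation on the target (when metadata is supplied): per-sex KM and
    log-rank across predicted labels, and a Cox fit of survival on the
    predicted label controlling for age (and ``mgmt`` when the column is
    present).
    """
    features = tuned["features"]
    missing = [s for s in features if s not in set(target_mat.site_ids)]
    if missing:
        raise ValueError(f"selected sites absent from target cohort: {missing[:5]}")
    samples = [s for s in train_mat.samples if train_labels.get(s, NOISE) != NOISE]
    X_train = _feature_frame(train_mat, features).loc[samples]
    y = train_labels.loc[samples].to_numpy()
    rf = RandomForestClassifier(random_state=spec.seed, **tuned["params"])
    rf.fit(X_train, y)
    X_target = _feature_frame(target_mat, features)
    pred = pd.Series(rf.predict(X_target), index=target_mat.samples, name="predicted")

    result = {"model": rf, "predictions": pred, "features": features}
    if target_meta is not None:
        tm = target_meta.loc[pred.index]
        result["per_sex"] = sex_stratified_eval(pred, tm)
        classes = np.unique(pred)
        if len(classes) == 2:
            cov = pd.DataFrame({"subtype": (pred == classes.max()).astype(float),
                                "age": tm["age"].to_numpy(float)})
            if "mgmt" in tm.columns:
                cov["mgmt"] = tm["mgmt"].to_numpy(float)
            try:
                result["cox"] = cox_fit(tm["time"], tm["event"], cov)
            except ValueError as err:
                logger.warning("target Cox evaluation failed: %s", err)
                result["cox"] = None
    return result
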