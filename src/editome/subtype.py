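"""Survival-guided editing-profile subtyping.

Discriminative-site editing profiles are embedded to two dimensions with
UMAP and clustered with HDBSCAN over a grid of density hyperparameters
(min_cluster_size, min_samples, cluster_selection_epsilon). Each grid
point is scored by the log-rank p-value of overall survival across its
cluster labels (noise excluded), and the labeling with the smallest p is
selected. Minimum-p selection is a multiple-looking procedure, so every
run emits the full audit table of evaluated grid points. Sex-stratified
survival is evaluation-only: the winning labels are assessed within each
sex for a direction of effect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import umap
from sklearn.cluster import HDBSCAN

from editome.io import EditingMatrix
from editome.survival import logrank, km_estimate, rmst

#: refuse to embed absurdly wide matrices; pre-filter sites first
MAX_EMBED_FEATURES = 50_000

NOISE = -1


@dataclass
class StratifyConfig:
    """Embedding and clustering settings.

    The clustering grid is the cross product of the three HDBSCAN
    parameter lists; ``min_samples`` entries of None fall back to
    HDBSCAN's default (= min_cluster_size).
    """

    n_neighbors: int = 15
    min_dist: float = 0.1
    n_components: int = 2
    seed: int = 0
    impute: str = "median"  # per-site median; the only supported policy
    min_cluster_size_grid: list = field(default_factory=lambda: [5, 10, 20])
    epsilon_grid: list = field(default_factory=lambda: [0.0, 0.5])
    min_samples_grid: list = field(default_factory=lambda: [5])

    def grid(self) -> list[dict]:
        pts = []
        for mcs, eps, ms in itertools.product(
            self.min_cluster_size_grid, self.epsilon_grid, self.min_samples_grid
        ):
            pts.append({"min_cluster_size": mcs, "cluster_selection_epsilon": eps,
                        "min_samples": ms})
        if not pts:
            raise ValueError("empty clustering grid")
        return pts


@dataclass
class StratifyResult:
    coords: pd.DataFrame          # samples x (umap1, umap2)
    labels: pd.Series             # cluster label per sample, NOISE = -1
    chosen_params: dict
    selection_p: float
    per_sex: dict                 # sex -> evaluation dict (see sex_stratified_eval)
    audit: pd.DataFrame           # one row per evaluated grid point
    seed: int


def _impute_matrix(mat: EditingMatrix) -> np.ndarray:
    """Samples x sites array with per-site median imputation of missing cells."""
    lv = mat.level.to_numpy(float)
    med = np.nanmedian(lv, axis=1)
    med = np.where(np.isnan(med), 0.0, med)
    filled = np.where(np.isnan(lv), med[:, None], lv)
    return filled.T


def embed(mat: EditingMatrix, cfg: StratifyConfig | None = None) -> pd.DataFrame:
    """2-D UMAP embedding of samples; deterministic given cfg.seed."""
    cfg = cfg or StratifyConfig()
    if mat.n_sites > MAX_EMBED_FEATURES:
        raise ValueError(
            f"{mat.n_sites} sites exceeds the embedding cap ({MAX_EMBED_FEATURES}); "
            "apply discriminative-site filtering first"
        )
    X = _impute_matrix(mat)
    n = X.shape[0]
    if n == 1:
        return pd.DataFrame([[0.0, 0.0]], index=mat.samples, columns=["umap1", "umap2"])
    reducer = umap.UMAP(
        n_neighbors=min(cfg.n_neighbors, n - 1),
        min_dist=cfg.min_dist,
        n_components=cfg.n_components,
        random_state=cfg.seed,
    )
    coords = reducer.fit_transform(X)
    return pd.DataFrame(coords, index=mat.samples, columns=["umap1", "umap2"])


def cluster(coords: pd.DataFrame, grid_point: dict) -> pd.Series:
    """HDBSCAN labels for one grid point; -1 marks noise."""
    params = dict(grid_point)
    if params.get("min_samples") is None:
        params.pop("min_samples", None)
    model = HDBSCAN(**params)
    labels = model.fit_predict(coords.to_numpy(float))
    return pd.Series(labels, index=coords.index, name="cluster")


def survival_guided_select(
    mat: EditingMatrix, meta: pd.DataFrame, cfg: StratifyConfig | None = None
) -> StratifyResult:
    """Embed, cluster over the grid, and keep the minimum log-rank p labeling.

    Noise-labeled samples are excluded from each log-rank evaluation but
    retained in the returned labels. Grid points that produce fewer than
    two populated clusters are skipped. Ties in p go to the earlier grid
    point. Every evaluation is recorded in ``audit``.
    """
    cfg = cfg or StratifyConfig()
    missing = [s for s in mat.samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples without survival metadata: {missing[:5]}")
    coords = embed(mat, cfg)
    sub = meta.loc[mat.samples]
    rows, best = [], None
    for gi, gp in enumerate(cfg.grid()):
        labels = cluster(coords, gp)
        use = labels != NOISE
        k = labels[use].nunique()
        if k < 2:
            rows.append({**gp, "grid_index": gi, "n_clusters": k, "p": np.nan,
                         "skipped": True})
            continue
        _, p = logrank(sub.loc[use.values, "time"], sub.loc[use.values, "event"],
                       labels[use])
        rows.append({**gp, "grid_index": gi, "n_clusters": k, "p": p, "skipped": False})
        if best is None or p < best[0]:
            best = (p, gi, gp, labels)
    audit = pd.DataFrame(rows)
    if best is None:
        raise ValueError("no grid point produced >= 2 clusters")
    p, gi, gp, labels = best
    per_sex = sex_stratified_eval(labels, sub)
    return StratifyResult(coords=coords, labels=labels, chosen_params=gp,
                          selection_p=p, per_sex=per_sex, audit=audit, seed=cfg.seed)


def sex_stratified_eval(labels: pd.Series, meta: pd.DataFrame) -> dict:
    """Within-sex survival evaluation of cluster labels.

    For each sex with >= 2 populated non-noise clusters: the log-rank p,
    per-cluster KM curves, and the direction of the highest-label
    cluster's effect ("worse" when its restricted mean survival falls
    below the lowest-label cluster's, "better" otherwise). Sexes that are
    absent or have < 2 populated clusters are reported as not evaluable.
    """
    out = {}
    meta = meta.loc[labels.index]
    for sx in ("female", "male"):
        m = (meta["sex"] == sx).to_numpy() & (labels != NOISE).to_numpy()
        res = {"evaluable": False, "p": None, "direction": None, "km": {}}
        lab = labels[m]
        if m.sum() >= 2 and lab.nunique() >= 2 and all(
            (lab == c).sum() >= 1 for c in lab.unique()
        ):
            t = meta.loc[m, "time"]
            e = meta.loc[m, "event"]
            _, p = logrank(t, e, lab)
            km = {int(c): km_estimate(t[lab == c], e[lab == c]) for c in sorted(lab.unique())}
            lo, hi = min(lab.unique()), max(lab.unique())
            horizon = float(t.max())
            rm_lo = rmst(t[lab == lo], e[lab == lo], horizon)
            rm_hi = rmst(t[lab == hi], e[lab == hi], horizon)
            res = {
                "evaluable": True,
                "p": p,
                "direction": "worse" if rm_hi < rm_lo else "better",
                "km": km,
                "rmst": {int(lo): rm_lo, int(hi): rm_hi},
            }
        out[sx] = res
    return out
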