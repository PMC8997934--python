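"""Synthetic glioma-style cohort generator.

Produces every input the pipeline consumes — an editing matrix with read
counts, survival metadata, host-gene expression, an ADAR1-knockdown
differential-expression table and a site annotation — together with the
ground truth used by recovery tests.

The generative model: each sample belongs to one of two latent editing
clusters; per-site baseline editing rates are Beta-distributed and
shifted upward by ``delta_edit`` in cluster 2 at a planted informative
subset; read coverage is negative-binomial and edited-G reads binomial
given coverage, so observed levels carry realistic sampling noise.
Survival is exponential with a cluster-by-sex interaction of opposite
sign (cluster 2 is harmful in females, protective in males), with
independent exponential censoring. For planted regulated genes,
log abundance is linear in the editing level of one designated anchor
site (plus a weak age trend), and the knockdown table assigns those
genes a fold change of sign opposite to the planted coefficient.
Anchor sites of regulated genes are annotated as 3'UTR, mirroring the
3'UTR concentration of expression-coupled editing in tumor data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from editome.io import EditingMatrix, EditingSite

REGION_PROBS = {
    "3'UTR": 0.45, "intronic": 0.20, "exonic": 0.10, "ncRNA": 0.10,
    "5'UTR": 0.05, "intergenic": 0.10,
}


@dataclass
class SimConfig:
    """Generator settings; the defaults are the reference study conditions.

    delta_edit : mean editing-level increase of cluster 2 at informative
        sites (fraction).
    base_edit_alpha/beta : Beta shape of baseline per-site editing rates
        (2, 8: mean 0.2, right-skewed like bulk editing levels).
    mean_cov, cov_dispersion : negative-binomial A+G coverage (mean 50).
    hr_female, hr_male : cluster-2 hazard ratios by sex (3 and 1/3:
        opposite prognostic directions).
    baseline_hazard : per-day exponential hazard (median ~450 days).
    censor_rate : independent exponential censoring hazard.
    coef_true, expr_sigma : editing-expression coupling and log-scale
        noise for regulated genes.
    kd_effect : magnitude of the planted knockdown log2 fold change.
    """

    n_samples: int = 200
    n_sites: int = 2000
    n_informative_sites: int = 200
    n_genes: int = 300
    delta_edit: float = 0.15
    base_edit_alpha: float = 2.0
    base_edit_beta: float = 8.0
    mean_cov: float = 50.0
    cov_dispersion: float = 5.0
    hr_female: float = 3.0
    hr_male: float = 1.0 / 3.0
    baseline_hazard: float = np.log(2) / 450.0
    censor_rate: float = 5e-4
    n_regulated: int = 30
    coef_true: float = 2.0
    expr_sigma: float = 0.1
    kd_effect: float = 1.0
    seed: int = 0
    structure_seed: int | None = None  # shared site/gene universe; defaults to seed

    def __post_init__(self) -> None:
        if self.n_informative_sites > self.n_sites:
            raise ValueError("more informative sites than sites")
        if not (self.hr_female > 0 and self.hr_male > 0):
            raise ValueError("hazard ratios must be positive")
        if not 0 <= self.delta_edit < 1:
            raise ValueError("delta_edit must be a fraction in [0, 1)")
        for name in ("n_samples", "n_sites", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Planted ground truth of one generated cohort."""

    cluster: pd.Series                 # 1 or 2 per sample
    informative_sites: list
    regulated_genes: set
    anchor_sites: dict                 # gene -> site_id
    prognostic_sign: dict = field(default_factory=dict)  # sex -> +1/-1 per unit editing


def _rngs(seed: int, n: int):
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def generate(config: SimConfig) -> tuple[EditingMatrix, pd.DataFrame, pd.DataFrame,
                                         pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (editing matrix, metadata, expression, KD table, annotation, truth).

    The site/gene universe, baseline editing rates, and planted
    informative/regulated sets are drawn from ``structure_seed`` (default:
    ``seed``); everything sample-level comes from ``seed``. Two configs
    sharing a ``structure_seed`` but differing in ``seed`` yield
    independent cohorts over the same sites — the cross-cohort setting.
    """
    cfg = config
    structure_seed = cfg.seed if cfg.structure_seed is None else cfg.structure_seed
    (r_struct,) = _rngs(structure_seed, 1)
    r_sample, r_counts, r_surv, r_expr, r_kd = _rngs(cfg.seed, 5)

    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    cluster = r_sample.integers(1, 3, size=cfg.n_samples)          # Bernoulli(0.5)
    sex = np.where(r_sample.random(cfg.n_samples) < 0.5, "female", "male")
    age = np.clip(r_sample.normal(55, 10, cfg.n_samples), 18.01, None)

    # --- sites, genes, annotation -------------------------------------------------
    positions = np.sort(r_struct.choice(2_000_000, size=cfg.n_sites, replace=False)) + 1
    strands = r_struct.choice(["+", "-"], size=cfg.n_sites)
    chroms = [f"chr{1 + (i % 22)}" for i in range(cfg.n_sites)]
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    regions = r_struct.choice(list(REGION_PROBS), size=cfg.n_sites,
                              p=list(REGION_PROBS.values()))
    site_gene = np.array([genes[i % cfg.n_genes] for i in range(cfg.n_sites)],
                         dtype=object)
    site_gene[regions == "intergenic"] = ""

    informative = sorted(r_struct.choice(cfg.n_sites, size=cfg.n_informative_sites,
                                         replace=False))

    # regulated genes get a genic anchor site annotated as 3'UTR
    genic_idx = np.flatnonzero(site_gene != "")
    n_anchor = min(cfg.n_regulated, genic_idx.size)
    anchor_idx = r_struct.choice(genic_idx, size=n_anchor, replace=False)
    regions = regions.astype(object)
    anchor_sites: dict[str, str] = {}

    sites = [EditingSite(chrom=chroms[i], pos=int(positions[i]), strand=str(strands[i]),
                         gene=str(site_gene[i]), region=str(regions[i]))
             for i in range(cfg.n_sites)]
    site_ids = [s.site_id for s in sites]
    regulated_genes = set()
    for i in anchor_idx:
        g = str(site_gene[i])
        if g in regulated_genes:      # one anchor per gene
            continue
        regulated_genes.add(g)
        anchor_sites[g] = site_ids[i]
        regions[i] = "3'UTR"
    sites = [EditingSite(chrom=s.chrom, pos=s.pos, strand=s.strand, gene=s.gene,
                         region=str(regions[i])) for i, s in enumerate(sites)]

    # --- editing rates and read counts --------------------------------------------
    base_rate = r_struct.beta(cfg.base_edit_alpha, cfg.base_edit_beta, cfg.n_sites)
    rate = np.tile(base_rate[:, None], (1, cfg.n_samples))
    in_c2 = cluster == 2
    rate[np.ix_(informative, np.flatnonzero(in_c2))] += cfg.delta_edit
    rate = np.clip(rate, 0.0, 1.0)

    p_nb = cfg.cov_dispersion / (cfg.cov_dispersion + cfg.mean_cov)
    cov = r_counts.negative_binomial(cfg.cov_dispersion, p_nb,
                                     size=(cfg.n_sites, cfg.n_samples))
    cov = np.maximum(cov, 1)          # keep every cell quantifiable
    g_reads = r_counts.binomial(cov, rate)
    level = g_reads / cov

    mat = EditingMatrix(
        sites=sites, samples=samples,
        level=pd.DataFrame(level, index=site_ids, columns=samples),
        g_reads=pd.DataFrame(g_reads.astype(float), index=site_ids, columns=samples),
        cov=pd.DataFrame(cov.astype(float), index=site_ids, columns=samples),
    )

    # --- survival -------------------------------------------------------------------
    log_hr = np.where(sex == "female", np.log(cfg.hr_female), np.log(cfg.hr_male))
    hazard = cfg.baseline_hazard * np.exp(np.where(cluster == 2, log_hr, 0.0))
    t_event = r_surv.exponential(1.0 / hazard)
    t_censor = r_surv.exponential(1.0 / cfg.censor_rate, size=cfg.n_samples)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    meta = pd.DataFrame({
        "sample_id": samples, "sex": sex, "age": age,
        "time": np.maximum(time, 1e-3), "event": event, "endpoint": "OS",
    }).set_index("sample_id")

    # --- expression -----------------------------------------------------------------
    intercept = r_expr.normal(5.0, 1.0, cfg.n_genes)
    log_expr = np.empty((cfg.n_genes, cfg.n_samples))
    id_to_row = {sid: i for i, sid in enumerate(site_ids)}
    for gi, g in enumerate(genes):
        z = intercept[gi] + 0.005 * age + r_expr.normal(0, cfg.expr_sigma, cfg.n_samples)
        if g in regulated_genes:
            z = z + cfg.coef_true * level[id_to_row[anchor_sites[g]]]
        log_expr[gi] = z
    expression = pd.DataFrame(np.maximum(np.exp(log_expr) - 0.5, 0.0),
                              index=pd.Index(genes, name="gene"), columns=samples)

    # --- knockdown table --------------------------------------------------------------
    kd_rows = []
    for g in genes:
        if g in regulated_genes:
            lfc = -np.sign(cfg.coef_true) * abs(cfg.kd_effect) + r_kd.normal(0, 0.1)
            padj = 10.0 ** r_kd.uniform(-5, -3)
        else:
            lfc = r_kd.normal(0, 0.2)
            padj = r_kd.uniform(0.2, 1.0)
        kd_rows.append({"gene": g, "log2fc": lfc, "pvalue": padj / 2, "padj": padj})
    kd_table = pd.DataFrame(kd_rows).set_index("gene")

    annotation = pd.DataFrame({
        "site_id": site_ids,
        "gene": [s.gene for s in sites],
        "region": [s.region for s in sites],
    }).set_index("site_id")

    sign = 1.0 if cfg.delta_edit >= 0 else -1.0
    truth = SimTruth(
        cluster=pd.Series(cluster, index=samples, name="cluster"),
        informative_sites=[site_ids[i] for i in informative],
        regulated_genes=regulated_genes,
        anchor_sites=anchor_sites,
        prognostic_sign={
            "female": sign * (1.0 if cfg.hr_female > 1 else -1.0),
            "male": sign * (1.0 if cfg.hr_male > 1 else -1.0),
        },
    )
    return mat, meta, expression, kd_table, annotation, truth


# ---------------------------------------------------------------------------
# hand-constructed fixtures with documented truth
# ---------------------------------------------------------------------------

def make_fixtures() -> dict:
    """Deterministic hand-constructed fixtures used by the filter-cascade tests.

    ``calling``  : 5-site x 4-sample matrix; ``truth`` is the set of cells
        that pass the editing-evidence rules (high-G high-coverage cells).
    ``prefilter``: 12-site x 10-sample matrix and a two-group comparison;
        ``truth`` lists the sites surviving the near-constant and
        median-difference rules.
    ``collinear``: 20 sites in 5 blocks of 4 near-identical profiles in
        significance order; ``truth`` is the expected representative of
        each block (the first site of each block).
    """
    fixtures: dict = {}

    # --- 20-cell calling fixture -------------------------------------------------
    samples = [f"P{j}" for j in range(4)]
    spec_rows = [
        # (chrom, pos, per-sample (g, cov)); strong editing passes, rest fails
        ("chr1", 101, [(10, 50), (12, 40), (0, 30), (1, 50)]),
        ("chr1", 202, [(15, 60), (20, 60), (18, 60), (25, 60)]),
        ("chr2", 303, [(0, 40), (0, 35), (0, 45), (0, 50)]),
        ("chr2", 404, [(2, 100), (1, 80), (2, 90), (1, 70)]),
        ("chr3", 505, [(4, 8), (5, 9), (30, 60), (3, 7)]),
    ]
    truth_cells = {
        ("chr1:101+", "P0"), ("chr1:101+", "P1"),
        ("chr1:202+", "P0"), ("chr1:202+", "P1"), ("chr1:202+", "P2"), ("chr1:202+", "P3"),
        ("chr3:505+", "P2"),
    }
    sites, g_rows, c_rows = [], [], []
    for chrom, pos, cells in spec_rows:
        sites.append(EditingSite(chrom=chrom, pos=pos, strand="+"))
        g_rows.append([g for g, _ in cells])
        c_rows.append([c for _, c in cells])
    ids = [s.site_id for s in sites]
    g = np.array(g_rows, float)
    c = np.array(c_rows, float)
    calling = EditingMatrix(
        sites=sites, samples=samples,
        level=pd.DataFrame(g / c, index=ids, columns=samples),
        g_reads=pd.DataFrame(g, index=ids, columns=samples),
        cov=pd.DataFrame(c, index=ids, columns=samples),
    )
    fixtures["calling"] = {"matrix": calling, "truth": truth_cells}

    # --- 12-site prefilter fixture --------------------------------------------------
    case = [f"C{j}" for j in range(5)]
    ref = [f"R{j}" for j in range(5)]
    rows, truth_kept = {}, []
    base5 = np.array([0.30, 0.33, 0.36, 0.39, 0.42])   # distinct ref values
    for i in range(12):
        sid = f"chr{(i % 4) + 1}:{1000 + i}+"
        if i < 3:                                # constant: removed by rule 1
            rows[sid] = np.full(10, 0.25)
        elif i < 6:                              # median diff 0.02 <= 3%: rule 2
            rows[sid] = np.concatenate([base5 + 0.02, base5])
        else:                                    # median diff 0.20: kept
            rows[sid] = np.concatenate([base5 + 0.20, base5])
            truth_kept.append(sid)
    lv = pd.DataFrame(rows, index=case + ref).T
    n_sites, ids = len(lv), list(lv.index)
    cov = pd.DataFrame(100.0, index=ids, columns=case + ref)
    g = (lv * cov).round()
    prefilter = EditingMatrix(
        sites=[EditingSite(chrom=s.split(":")[0], pos=int(s.split(":")[1][:-1]), strand="+")
               for s in ids],
        samples=case + ref,
        level=g / cov, g_reads=g, cov=cov,
    )
    fixtures["prefilter"] = {
        "matrix": prefilter, "case": case, "ref": ref, "truth": truth_kept,
        "truth_rule1": ids[:3], "truth_rule2": ids[3:6],
    }

    # --- collinearity blocks ---------------------------------------------------------
    rng = np.random.default_rng(20240101)
    n_samp = 30
    block_ids, profiles = [], []
    for b in range(5):
        base_profile = rng.uniform(0.1, 0.6, n_samp)
        for m in range(4):
            block_ids.append(f"chr{b + 1}:{5000 + m}+")
            profiles.append(np.clip(base_profile + rng.normal(0, 0.004, n_samp), 0, 1))
    lvc = pd.DataFrame(profiles, index=block_ids,
                       columns=[f"Q{j}" for j in range(n_samp)])
    covc = pd.DataFrame(200.0, index=block_ids, columns=lvc.columns)
    gc = (lvc * covc).round()
    collinear = EditingMatrix(
        sites=[EditingSite(chrom=s.split(":")[0], pos=int(s.split(":")[1][:-1]),
                           strand="+") for s in block_ids],
        samples=list(lvc.columns),
        level=gc / covc, g_reads=gc, cov=covc,
    )
    fixtures["collinear"] = {
        "matrix": collinear,
        "order": block_ids,                       # significance order
        "truth": [block_ids[b * 4] for b in range(5)],
    }
    return fixtures
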