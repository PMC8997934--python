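# editome

Survival-guided analysis of A-to-I RNA-editing profiles in tumor
cohorts, built for the glioma setting in which the *same* editing-based
subtype carries opposite prognosis in women and men.

A-to-I editing, catalyzed by ADAR enzymes, is read as an A→G change in
RNA-seq; the per-site *editing level* is G/(A+G). Starting from
site-level count matrices (editing level, edited-G reads, A+G coverage),
the package implements the full downstream analysis:

- **Site filtering** — evidence of editing per cell by an exact binomial
  test against a sequencing-error floor (G ≥ 3, A+G ≥ 10, level > 0.1%,
  Benjamini–Hochberg FDR < 0.05), inter-patient variation (median
  absolute deviation from Q3 > 0), and removal of samples with > 20%
  low-coverage sites.
- **Subtyping** — UMAP embedding of editing profiles, HDBSCAN density
  clustering over a hyperparameter grid, and selection of the labeling
  with the smallest log-rank p for overall survival; sex-stratified
  Kaplan–Meier/Cox evaluation of the winning labels.
- **Differential editing** — per-comparison filter cascade (near-constant
  sites, |median difference| ≤ 3%), Mann–Whitney U with BH correction
  (adjusted p < 0.05 ⇒ differentially edited site, DES), signed gene
  rankings (sign(Δmedian) · −log₁₀ p of the gene's most significant
  site), and rank–rank hypergeometric overlap (RRHO) between comparisons.
- **Regulation** — age-adjusted regression of host-gene log abundance on
  editing level; a gene is *editing-regulated* when its expression
  correlates with editing (FDR < 10%) and responds to ADAR1 knockdown
  (adjusted p < 0.05) with the opposite sign; 3′UTR enrichment (Fisher)
  and knockdown-direction bias (exact binomial) tests.
- **Prognostic screen** — per site and sex, age-adjusted Cox of survival
  on editing level, BH within sex at FDR < 0.15, plus the sex-dependent
  high/low dichotomisation (top 30% high for females, top 70% for males).
- **Cross-cohort transfer** — sex-specific random forests on DES features
  (adjusted p < 5×10⁻⁴ females / 10⁻⁵ males, shared across cohorts),
  greedy collinearity pruning, five-fold CV tuned by the log-rank p of
  pooled out-of-fold predictions, and per-sex survival evaluation on the
  target cohort.

A seeded synthetic-cohort generator (`editome.simulate`) produces every
input with planted ground truth — two latent editing clusters, a
cluster × sex survival interaction of opposite sign, editing-coupled
expression for designated genes, and a matching knockdown table — so the
whole pipeline is testable end to end without access-controlled data.

## Worked example

```python
import editome as ed
from editome.subtype import StratifyConfig

cfg = ed.SimConfig(seed=3)                      # 200 samples x 2000 sites
mat, meta, expr, kd, annot, truth = ed.generate(cfg)
mat = ed.select_discriminative_sites(ed.drop_lowcov_samples(mat))
res = ed.survival_guided_select(mat, meta, StratifyConfig(seed=3))
print(res.chosen_params, round(res.selection_p, 3))
for sex, v in res.per_sex.items():
    print(sex, round(v["p"], 6), v["direction"])
```

prints

```
{'min_cluster_size': 5, 'cluster_selection_epsilon': 0.0, 'min_samples': 5} 0.833
female 0.0 better
male 0.001188 worse
```

The pooled selection p is large because the cluster effect has opposite
sign in the two sexes and cancels, while the within-sex log-rank tests
are strongly significant (the female p, 4.5×10⁻⁷, rounds to 0 at six
decimals) with opposite directions — the sexually
dimorphic pattern the subtype is designed to expose. (The per-sex
"direction" describes the higher-numbered cluster; which planted cluster
receives which label is arbitrary.)

The same flow is available from a shell:

```sh
editome simulate --seed 3 sim/
editome filter sim/matrix.tsv sim/filtered.tsv
editome stratify --seed 3 sim/filtered.tsv sim/meta.tsv sim/strat/
```

## Analysis scripts

`analysis/01_simulate.py` … `analysis/07_cross_cohort.py` run the full
study narrative on a paired pair of synthetic cohorts (discovery A,
validation B over the same site universe) and write their tables under
`results/`. Run them in order; each is a thin driver over the library.

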