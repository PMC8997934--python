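"""Editing-to-expression regulation with knockdown integration.

Regresses host-gene log abundance on DES editing level (age-adjusted),
flags expression-correlated sites at FDR < 10%, classifies
editing-regulated genes by the inverse-knockdown criterion, and tests
3'UTR enrichment and the knockdown direction bias.
"""

from pathlib import Path

import click
import pandas as pd

import editome as ed
from editome import regulation as reg
from editome.cli import _write_tsv

RESULTS = Path(__file__).resolve().parent.parent / "results"


@click.command()
def main() -> None:
    cohort = RESULTS / "cohort_A"
    mat = ed.read_editing_matrix(cohort / "matrix.filtered.tsv")
    meta = ed.read_cohort_meta(cohort / "meta.tsv")
    expr = ed.read_expression(cohort / "expression.tsv")
    kd = ed.read_de_table(cohort / "kd_de.tsv")
    annot = ed.read_annotation(cohort / "annotation.tsv")
    des = pd.concat([
        pd.read_csv(RESULTS / "differential_editing" / f"des_{name}.tsv", sep="\t")
        for name in ("F1", "M1")])
    des_ids = sorted(set(des.loc[des["is_des"], "site_id"]))

    fits = reg.fit_des_expression(mat, expr, meta, annot, des_ids)
    correlated = reg.expression_correlated_sites(fits)
    classified = reg.classify_regulated_table(correlated, kd)
    out = RESULTS / "regulation"
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(classified, out / "regulation.tsv", index=False)

    n_sig = int(classified["significant"].sum())
    n_reg = int(classified["regulated"].sum())
    click.echo(f"{len(fits)} DES-gene pairs tested; {n_sig} expression-"
               f"correlated (FDR < 10%); {n_reg} editing-regulated genes")
    frac, p, n = reg.direction_binomial(classified)
    if n:
        click.echo(f"knockdown direction: {100 * frac:.0f}% of positive-"
                   f"coefficient regulated genes reduced (binomial p = {p:.2g})")
    sig_sites = classified.loc[classified["significant"], "site_id"]
    if len(sig_sites) >= 3:
        odds, p_enr = reg.region_enrichment(annot.loc[sig_sites],
                                            annot.loc[des_ids])
        click.echo(f"3'UTR enrichment of expression-correlated DESs: "
                   f"OR = {odds:.2f}, p = {p_enr:.2g}")


if __name__ == "__main__":
    main()
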