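"""Editing-evidence filtering and sample QC of the discovery cohort.

Drops samples with > 20% low-coverage sites, then keeps sites with
binomial editing evidence (BH < 0.05 against a 0.1% error floor,
G >= 3, A+G >= 10) and inter-patient variation (MAD from Q3 > 0).
"""

import json
from pathlib import Path

import click

import editome as ed

RESULTS = Path(__file__).resolve().parent.parent / "results"


@click.command()
def main() -> None:
    for tag in ("A", "B"):
        cohort = RESULTS / f"cohort_{tag}"
        mat = ed.read_editing_matrix(cohort / "matrix.tsv")
        mat = ed.drop_lowcov_samples(mat)
        mat = ed.select_discriminative_sites(mat)
        ed.write_editing_matrix(mat, cohort / "matrix.filtered.tsv")
        log = {"lowcov_dropped": mat.meta.get("lowcov_dropped", []),
               "filter_log": mat.meta.get("filter_log", {})}
        (cohort / "filter.log.json").write_text(json.dumps(log, indent=1))
        click.echo(f"cohort {tag}: {log['filter_log']}")


if __name__ == "__main__":
    main()
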