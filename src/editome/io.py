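"""Data model and TSV I/O for editing matrices, metadata and tables.

Coordinates are 1-based, fully closed and strand-explicit; the canonical
string form of a site is ``chrom:pos`` immediately followed by the strand
character, e.g. ``chr8:56069413-``. Editing levels are stored as fractions
in [0, 1]; percent-formatted inputs are rejected rather than converted.
Missing cells are encoded as ``NA``; zero coverage is distinct from missing
(a covered cell with ``cov == 0`` necessarily has a missing level).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("3'UTR", "5'UTR", "exonic", "intronic", "ncRNA", "intergenic", "other")

_SITE_RE = re.compile(r"^(?P<chrom>[A-Za-z0-9_.]+):(?P<pos>\d+)(?P<strand>[+\-−])$")

#: numeric tolerance for level == g_reads / cov on load
_LEVEL_TOL = 1e-9


class ParseError(ValueError):
    """Raised for malformed tokens or files."""


@dataclass(frozen=True, order=False)
class EditingSite:
    """One A-to-I editing position with optional gene/region annotation."""

    chrom: str
    pos: int
    strand: str
    gene: str = ""
    region: str = "unknown"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}{self.strand}"

    def __str__(self) -> str:
        return self.site_id

    def sort_key(self) -> tuple:
        """Natural chromosome order, then position, then strand."""
        name = self.chrom[3:] if self.chrom.lower().startswith("chr") else self.chrom
        try:
            chrom_key = (0, int(name), "")
        except ValueError:
            chrom_key = (1, 0, name)
        return (*chrom_key, self.pos, self.strand)


def parse_site_id(token: str) -> EditingSite:
    """Parse a canonical site token like ``chr1:45509673+``.

    Accepts the Unicode minus sign as a strand character and normalises it
    to ASCII ``-`` so that formatting round-trips.
    """
    m = _SITE_RE.match(token.strip())
    if m is None:
        raise ParseError(f"malformed site token: {token!r}")
    strand = m.group("strand").replace("−", "-")
    return EditingSite(chrom=m.group("chrom"), pos=int(m.group("pos")), strand=strand)


@dataclass
class EditingMatrix:
    """Sites x samples triplet of editing level, edited-G reads and A+G coverage.

    The three frames share an index of canonical site IDs and columns of
    sample IDs; missing cells are NaN in all three frames. Invariants
    (``g_reads <= cov``; ``level == g_reads / cov`` where ``cov > 0``;
    jointly-consistent missingness) are enforced by :meth:`validate`.
    """

    sites: list[EditingSite]
    samples: list[str]
    level: pd.DataFrame
    g_reads: pd.DataFrame
    cov: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate(self) -> None:
        ids = self.site_ids
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ParseError(f"duplicate site IDs: {list(dup[dup > 1].index)}")
        for frame, name in ((self.level, "level"), (self.g_reads, "g_reads"), (self.cov, "cov")):
            if list(frame.index) != ids or list(frame.columns) != self.samples:
                raise ParseError(f"{name} frame index/columns out of sync with sites/samples")
        g, c, lv = (f.to_numpy(float) for f in (self.g_reads, self.cov, self.level))
        bad = _first_bad_cell(g, c, lv)
        if bad is not None:
            i, j, msg = bad
            raise ParseError(f"invalid cell at site {ids[i]}, sample {self.samples[j]}: {msg}")
        if np.nanmin(lv, initial=0.0) < 0 or np.nanmax(lv, initial=0.0) > 1:
            raise ParseError("editing levels must be fractions in [0, 1]")

    def subset_sites(self, keep_ids: list[str]) -> "EditingMatrix":
        """Return the site subset in the given order."""
        idx = {s: i for i, s in enumerate(self.site_ids)}
        sites = [self.sites[idx[s]] for s in keep_ids]
        return EditingMatrix(
            sites=sites, samples=list(self.samples),
            level=self.level.loc[keep_ids].copy(),
            g_reads=self.g_reads.loc[keep_ids].copy(),
            cov=self.cov.loc[keep_ids].copy(),
            meta=dict(self.meta),
        )

    def subset_samples(self, keep: list[str]) -> "EditingMatrix":
        return EditingMatrix(
            sites=list(self.sites), samples=list(keep),
            level=self.level[keep].copy(),
            g_reads=self.g_reads[keep].copy(),
            cov=self.cov[keep].copy(),
            meta=dict(self.meta),
        )

    def annotate(self, annotation: pd.DataFrame) -> "EditingMatrix":
        """Attach gene/region annotation (index: site_id) to the sites."""
        sites = []
        for s in self.sites:
            if s.site_id in annotation.index:
                row = annotation.loc[s.site_id]
                sites.append(replace(s, gene=str(row["gene"]), region=str(row["region"])))
            else:
                sites.append(s)
        return EditingMatrix(
            sites=sites, samples=list(self.samples),
            level=self.level, g_reads=self.g_reads, cov=self.cov, meta=dict(self.meta),
        )


def _first_bad_cell(g: np.ndarray, c: np.ndarray, lv: np.ndarray):
    """Locate the first invariant-violating cell, or None."""
    gm, cm, lm = np.isnan(g), np.isnan(c), np.isnan(lv)
    # counts must be missing together
    cnt_bad = gm != cm
    # level present iff cov > 0 (undefined at cov == 0)
    lvl_bad = np.where(cm, ~lm, lm == (np.nan_to_num(c) > 0))
    both = ~(gm | cm)
    with np.errstate(invalid="ignore", divide="ignore"):
        gt = both & (g > c)
        ratio_bad = both & (np.nan_to_num(c) > 0) & ~lm & (np.abs(lv - g / np.where(c > 0, c, 1)) > _LEVEL_TOL)
        neg = both & ((g < 0) | (c < 0))
    for mask, msg in (
        (cnt_bad, "g_reads and cov must be jointly missing"),
        (lvl_bad, "level must be present exactly when cov > 0"),
        (neg, "negative read count"),
        (gt, "g_reads > cov"),
        (ratio_bad, "level != g_reads / cov"),
    ):
        if mask.any():
            i, j = np.argwhere(mask)[0]
            return int(i), int(j), msg
    return None


# ---------------------------------------------------------------------------
# readers / writers (long-format TSV: site_id  sample_id  g_reads  cov  level)
# ---------------------------------------------------------------------------

def read_editing_matrix(path) -> EditingMatrix:
    """Load a long-format editing matrix TSV and validate its invariants.

    Columns: ``site_id``, ``sample_id``, ``g_reads``, ``cov``, ``level``;
    ``NA`` marks missing values. Site and sample order follows first
    appearance in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "sample_id": str},
                     na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    required = ["site_id", "sample_id", "g_reads", "cov", "level"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {missing}")
    if df["level"].dtype == object and df["level"].astype(str).str.contains("%").any():
        raise ParseError(f"{path}: percent-formatted editing levels are not accepted")
    dup = df.duplicated(subset=["site_id", "sample_id"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ParseError(f"{path}: duplicate cell for site {r['site_id']}, sample {r['sample_id']}")
    site_order = df["site_id"].drop_duplicates().tolist()
    sample_order = df["sample_id"].drop_duplicates().tolist()
    frames = {}
    for col in ("level", "g_reads", "cov"):
        frames[col] = (
            df.pivot(index="site_id", columns="sample_id", values=col)
            .reindex(index=site_order, columns=sample_order)
            .astype(float)
        )
    sites = [parse_site_id(t) for t in site_order]
    mat = EditingMatrix(sites=sites, samples=sample_order,
                        level=frames["level"], g_reads=frames["g_reads"], cov=frames["cov"])
    mat.validate()
    return mat


def write_editing_matrix(mat: EditingMatrix, path) -> None:
    """Write a matrix to long-format TSV, preserving order and missing cells."""
    rows = []
    ids = mat.site_ids
    g, c, lv = mat.g_reads.to_numpy(float), mat.cov.to_numpy(float), mat.level.to_numpy(float)
    for i, sid in enumerate(ids):
        for j, samp in enumerate(mat.samples):
            rows.append((sid, samp, _fmt_count(g[i, j]), _fmt_count(c[i, j]), _fmt_level(lv[i, j])))
    out = pd.DataFrame(rows, columns=["site_id", "sample_id", "g_reads", "cov", "level"])
    out.to_csv(path, sep="\t", index=False)


def _fmt_count(x: float) -> str:
    return "NA" if np.isnan(x) else str(int(round(x)))


def _fmt_level(x: float) -> str:
    return "NA" if np.isnan(x) else repr(float(x))


def read_cohort_meta(path) -> pd.DataFrame:
    """Load per-sample metadata; index sample_id.

    Required columns: ``sample_id``, ``sex``, ``age``, ``time``, ``event``.
    Extra columns (endpoint, MGMT status, ...) are carried through untouched.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "sex", "age", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample IDs")
    df = df.set_index("sample_id")
    return validate_cohort_meta(df, name=str(path))


def validate_cohort_meta(df: pd.DataFrame, name: str = "metadata") -> pd.DataFrame:
    bad_event = ~df["event"].isin([0, 1])
    if bad_event.any():
        raise ParseError(f"{name}: event must be 0 or 1 (samples {list(df.index[bad_event])})")
    if (df["time"] <= 0).any():
        raise ParseError(f"{name}: survival time must be positive")
    if (df["age"] <= 0).any():
        raise ParseError(f"{name}: age must be positive")
    known = df["sex"].isin(["female", "male"]) | df["sex"].isna()
    if not known.all():
        raise ParseError(f"{name}: sex must be 'female' or 'male' (samples {list(df.index[~known])})")
    return df


def read_expression(path) -> pd.DataFrame:
    """Load a genes x samples abundance table (first column ``gene``)."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ParseError(f"{path}: missing required column 'gene'")
    if df["gene"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene symbols")
    df = df.set_index("gene")
    if (df.to_numpy(float) < 0).any():
        raise ParseError(f"{path}: negative abundance values")
    return df


def read_de_table(path) -> pd.DataFrame:
    """Load a differential-expression table (gene, log2fc, pvalue, padj)."""
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "log2fc", "pvalue", "padj"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {missing}")
    if df["gene"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene rows")
    for col in ("pvalue", "padj"):
        v = df[col].to_numpy(float)
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ParseError(f"{path}: {col} outside [0, 1]")
    if (df["padj"].to_numpy(float) < df["pvalue"].to_numpy(float) - 1e-12).any():
        raise ParseError(f"{path}: adjusted p smaller than raw p")
    return df.set_index("gene")


def read_annotation(path) -> pd.DataFrame:
    """Load a site -> (gene, region) map; unknown region labels become 'other'."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["site_id", "gene", "region"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {missing}")
    if df["site_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate site annotations")
    unknown = ~df["region"].isin(REGIONS)
    if unknown.any():
        labels = sorted(df.loc[unknown, "region"].unique())
        logger.warning("annotation %s: unknown region labels mapped to 'other': %s", path, labels)
        df.loc[unknown, "region"] = "other"
    df["gene"] = df["gene"].fillna("")
    return df.set_index("site_id")


def sort_sites(sites: list[EditingSite]) -> list[EditingSite]:
    """Deterministic canonical ordering of sites."""
    return sorted(sites, key=EditingSite.sort_key)
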