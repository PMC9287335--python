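"""Readers, writers and validators for the external table formats.

Counts travel as TSV (one feature-id column, one column per sample),
prediction tables as TSV with a fixed column order
(``mirna_id  mrna_id  source  score  site_type``), genomic annotation as
GTF v2.2 (1-based, closed intervals) and gene lists as plain text, one
symbol per line.  All readers transparently accept gzip-compressed files.
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MirnaLocusAnnotation",
    "PREDICTION_SOURCES",
    "SITE_TYPES",
    "read_counts",
    "write_counts",
    "read_predictions",
    "filter_predictions",
    "write_predictions",
    "read_gene_list",
    "classify_mirna_loci",
]

PREDICTION_SOURCES = ("targetscan", "mirdb", "mirtarbase")
#: TargetScan canonical seed-match classes, strongest first, plus "none"
#: for sources that carry no site-type notion (miRDB, miRTarBase).
SITE_TYPES = ("8mer", "7mer-m8", "7mer-1a", "none")

PREDICTION_COLUMNS = ["mirna_id", "mrna_id", "source", "score", "site_type"]


@dataclass
class ExpressionMatrix:
    """A validated features x samples matrix of non-negative counts.

    ``feature_class`` tags the matrix as ``"miRNA"`` or ``"mRNA"`` so
    downstream stages can assert they were handed the right side of the
    paired cohort.
    """

    counts: pd.DataFrame
    feature_class: str = "mRNA"

    def __post_init__(self) -> None:
        validate_counts(self.counts)
        if self.feature_class not in ("miRNA", "mRNA"):
            raise ValueError(f"unknown feature_class {self.feature_class!r}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count matrix contains non-numeric cells")
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"non-finite count at feature {counts.index[r]!r}, sample {counts.columns[c]!r}"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count {values[r, c]} at feature {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}"
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_counts(path: str | Path, feature_class: str = "mRNA") -> ExpressionMatrix:
    """Read a count TSV (feature id column + one column per sample)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    # pandas silently coerces unreadable cells to object columns; surface them
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any() and not df[col].isna().any():
            bad = df.index[converted.isna() & ~df[col].isna()][0]
            raise ValueError(
                f"non-numeric cell {df.loc[bad, col]!r} at feature {bad!r}, sample {col!r}"
            )
        df[col] = converted
    return ExpressionMatrix(counts=df, feature_class=feature_class)


def write_counts(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    counts = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_gene_list(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# prediction tables
# ---------------------------------------------------------------------------

def _read_prediction_tsv(path: str | Path, source: str) -> pd.DataFrame:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: prediction table missing columns {sorted(missing)}")
    df = df[PREDICTION_COLUMNS].copy()
    df["source"] = source
    bad_site = ~df["site_type"].isin(SITE_TYPES)
    if bad_site.any():
        raise ValueError(
            f"{path}: unknown site_type token {df.loc[bad_site, 'site_type'].iloc[0]!r}"
        )
    if source == "mirdb":
        scores = df["score"].to_numpy(dtype=float)
        if ((scores < 0) | (scores > 100)).any():
            bad = scores[(scores < 0) | (scores > 100)][0]
            raise ValueError(f"{path}: miRDB score {bad} outside [0, 100]")
    return df


def collapse_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple records per (miRNA, mRNA, source) to the best score.

    Prediction exports list one record per binding site; "best" is the most
    negative context score for TargetScan and the highest score for miRDB.
    miRTarBase carries no score, so duplicates simply collapse.
    """
    parts = []
    for source, sub in table.groupby("source", sort=True):
        ascending = source == "targetscan"  # most negative context first
        sub = sub.sort_values(
            ["mirna_id", "mrna_id", "score"],
            ascending=[True, True, ascending],
            na_position="last",
        )
        parts.append(sub.drop_duplicates(["mirna_id", "mrna_id"], keep="first"))
    return (
        pd.concat(parts, ignore_index=True)
        .sort_values(["source", "mirna_id", "mrna_id"])
        .reset_index(drop=True)
    )


def filter_predictions(
    table: pd.DataFrame,
    mirdb_min_score: float | None = None,
    targetscan_max_context: float | None = None,
    mirdb_top_fraction: float | None = None,
) -> pd.DataFrame:
    """Apply per-source score filters to a merged prediction table.

    TargetScan records are kept when ``score < targetscan_max_context``
    (context scores are negative; more negative means stronger predicted
    repression).  miRDB records are kept either above an absolute score
    cut-off or within the top ``mirdb_top_fraction`` of scores — the caller
    chooses one mode, not both.  Functionally validated miRTarBase records
    pass unfiltered.
    """
    if mirdb_min_score is not None and mirdb_top_fraction is not None:
        raise ValueError("choose either mirdb_min_score or mirdb_top_fraction, not both")
    keep = np.ones(len(table), dtype=bool)
    is_ts = (table["source"] == "targetscan").to_numpy()
    is_db = (table["source"] == "mirdb").to_numpy()
    if targetscan_max_context is not None:
        keep[is_ts] = (table["score"].to_numpy()[is_ts] < targetscan_max_context)
    if mirdb_min_score is not None:
        keep[is_db] = (table["score"].to_numpy()[is_db] > mirdb_min_score)
    elif mirdb_top_fraction is not None:
        sub = table[is_db]
        n_keep = int(math.ceil(mirdb_top_fraction * len(sub)))
        # ties at the boundary broken by (mirna_id, mrna_id) order
        order = sub.sort_values(
            ["score", "mirna_id", "mrna_id"], ascending=[False, True, True]
        )
        chosen = set(order.index[:n_keep])
        keep[is_db] = np.array([i in chosen for i in table.index[is_db]], dtype=bool)
    return table[keep].reset_index(drop=True)


def read_predictions(
    paths: Mapping[str, str | Path],
    mirdb_min_score: float | None = None,
    targetscan_max_context: float | None = None,
    mirdb_top_fraction: float | None = None,
) -> pd.DataFrame:
    """Read one TSV per prediction source, collapse duplicates and filter.

    ``paths`` maps source name (``targetscan`` / ``mirdb`` / ``mirtarbase``)
    to a file path; at least one source is required.
    """
    if not paths:
        raise ValueError("at least one prediction source path is required")
    unknown = set(paths) - set(PREDICTION_SOURCES)
    if unknown:
        raise ValueError(f"unknown prediction sources {sorted(unknown)}")
    tables = [_read_prediction_tsv(p, source) for source, p in sorted(paths.items())]
    merged = collapse_duplicates(pd.concat(tables, ignore_index=True))
    return filter_predictions(
        merged,
        mirdb_min_score=mirdb_min_score,
        targetscan_max_context=targetscan_max_context,
        mirdb_top_fraction=mirdb_top_fraction,
    )


def write_predictions(table: pd.DataFrame, path: str | Path) -> None:
    table[PREDICTION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF-based miRNA locus classification
# ---------------------------------------------------------------------------

@dataclass
class MirnaLocusAnnotation:
    """Genomic classification of one miRNA as intragenic or intergenic."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str
    host_gene_id: str | None = None

    @property
    def locus_class(self) -> str:
        return "intragenic" if self.host_gene_id is not None else "intergenic"


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_genes(path: str | Path) -> list[dict]:
    """Parse gene-level records out of a GTF v2.2 file.

    Only the fields this package consumes are extracted (gene_id and
    gene_biotype attributes); malformed lines raise with their line number.
    """
    genes = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 fields, got {len(fields)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from None
            if start_i > end_i:
                raise ValueError(f"malformed GTF line {lineno}: start > end")
            attr = dict(_ATTR_RE.findall(attrs))
            if "gene_id" not in attr:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id attribute")
            genes.append(
                {
                    "gene_id": attr["gene_id"],
                    "chrom": chrom,
                    "start": start_i,
                    "end": end_i,
                    "strand": strand,
                    "biotype": attr.get("gene_biotype", attr.get("gene_type", "")),
                }
            )
    return genes


def classify_mirna_loci(gtf_path: str | Path) -> list[MirnaLocusAnnotation]:
    """Classify every miRNA gene in a GTF as intragenic or intergenic.

    A miRNA is intragenic iff its interval is fully contained (1-based,
    closed coordinates) within a protein-coding gene on the same
    chromosome, strand-agnostically; the host is the containing gene with
    the smallest span.  Otherwise it is intergenic.
    """
    genes = _parse_gtf_genes(gtf_path)
    mirnas = [g for g in genes if g["biotype"] == "miRNA"]
    coding = sorted(
        (g for g in genes if g["biotype"] == "protein_coding"),
        key=lambda g: (g["chrom"], g["start"], g["end"], g["gene_id"]),
    )
    by_chrom: dict[str, list[dict]] = {}
    for g in coding:
        by_chrom.setdefault(g["chrom"], []).append(g)

    annotations = []
    for mir in sorted(mirnas, key=lambda g: g["gene_id"]):
        host = None
        host_span = None
        for g in by_chrom.get(mir["chrom"], ()):
            if g["start"] <= mir["start"] and mir["end"] <= g["end"]:
                span = g["end"] - g["start"]
                if host is None or span < host_span:
                    host, host_span = g["gene_id"], span
        annotations.append(
            MirnaLocusAnnotation(
                mirna_id=mir["gene_id"],
                chrom=mir["chrom"],
                start=mir["start"],
                end=mir["end"],
                strand=mir["strand"],
                host_gene_id=host,
            )
        )
    return annotations


def annotation_frame(annotations: Iterable[MirnaLocusAnnotation]) -> pd.DataFrame:
    """Tabular view of a set of locus annotations."""
    rows = [
        {
            "mirna_id": a.mirna_id,
            "chrom": a.chrom,
            "start": a.start,
            "end": a.end,
            "strand": a.strand,
            "host_gene_id": a.host_gene_id if a.host_gene_id is not None else "",
            "locus_class": a.locus_class,
        }
        for a in annotations
    ]
    return pd.DataFrame(rows)
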