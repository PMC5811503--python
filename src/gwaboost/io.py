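"""Readers and writers for every external format the pipeline touches.

All genomic intervals are 0-based half-open internally; conversions happen
only at the parse/serialize boundary (GFF3 is 1-based inclusive on disk,
BED already matches the internal convention). SNP positions stay 1-based,
as in summary-statistics tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "GeneRecord",
    "ReferenceGeneSet",
    "read_summary_stats",
    "read_gene_models",
    "read_gene_list",
    "write_ranked_table",
    "read_ranked_table",
    "write_scan_summary",
]

#: Number of significant digits used when serializing scores.
FLOAT_PRECISION = 6

DEFAULT_DIALECT = {"chrom": "chrom", "pos": "pos", "pvalue": "pvalue"}


@dataclass(frozen=True)
class SnpRecord:
    """One tested locus: chromosome, 1-based position, association P-value."""

    chrom: str
    pos: int
    pvalue: float


@dataclass(frozen=True)
class GeneRecord:
    """A gene span in internal 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."


@dataclass(frozen=True)
class ReferenceGeneSet:
    """The curated positive gene set for a phenotype."""

    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("reference gene set must be non-empty")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


def read_summary_stats(
    path: str | Path,
    dialect: Mapping[str, str | int] | None = None,
    sep: str | None = None,
    pvalue_floor: float | None = None,
) -> list[SnpRecord]:
    """Read GWAS summary statistics (per-SNP P-values) from a delimited table.

    Parameters
    ----------
    path
        TSV/CSV file with one row per SNP.
    dialect
        Maps the keys ``chrom``, ``pos``, ``pvalue`` to column names (header
        present) or 0-based column indices (headerless file). Default column
        names are ``chrom``, ``pos``, ``pvalue``.
    sep
        Field separator; autodetected between tab and comma when omitted.
    pvalue_floor
        If set, P-values of exactly 0 are replaced by this floor instead of
        being skipped. Zero P-values break the log-odds arithmetic downstream,
        so by default they are treated as record-level errors.

    Returns
    -------
    list of :class:`SnpRecord`, input order preserved. Malformed records
    (unparseable fields, P outside (0, 1], non-positive positions) are
    skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    by_index = all(isinstance(v, int) for v in dialect.values())
    if sep is None:
        with open(path) as fh:
            first = fh.readline()
        sep = "," if ("," in first and "\t" not in first) else "\t"
    df = pd.read_csv(
        path,
        sep=sep,
        header=None if by_index else 0,
        dtype=str,
        comment="#",
        skip_blank_lines=True,
    )
    if df.empty:
        logger.warning("%s: no SNP records found", path)
        return []
    try:
        chrom_col = df[dialect["chrom"]]
        pos_col = df[dialect["pos"]]
        p_col = df[dialect["pvalue"]]
    except KeyError as exc:
        raise ValueError(
            f"{path}: required column {exc} not found; available: {list(df.columns)}"
        ) from exc

    pos = pd.to_numeric(pos_col, errors="coerce")
    # Python float() round-trips "%.17g" exactly; pd.to_numeric can be 1 ulp off
    pval = p_col.map(_parse_float).astype("float64")
    if pvalue_floor is not None:
        pval = pval.mask(pval == 0.0, float(pvalue_floor))
    ok = (
        pos.notna()
        & pval.notna()
        & (pos >= 1)
        & (pos == pos.round())
        & (pval > 0.0)
        & (pval <= 1.0)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        for line in df.index[~ok][:10]:
            logger.warning("%s: skipping malformed SNP record at data row %d", path, line)
        if n_bad > 10:
            logger.warning("%s: ... and %d more skipped records", path, n_bad - 10)
    records = [
        SnpRecord(chrom=str(c).strip(), pos=int(p), pvalue=float(v))
        for c, p, v in zip(chrom_col[ok], pos[ok], pval[ok])
    ]
    if not records:
        logger.warning("%s: no valid SNP records after filtering", path)
    return records


def _parse_float(x) -> float:
    try:
        return float(x)
    except (TypeError, ValueError):
        return float("nan")


def _strip_suffix(gene_id: str) -> str:
    return re.sub(r"\.\d+$", "", gene_id)


def read_gene_models(
    path: str | Path,
    format: str = "bed",
    strip_suffix: bool = False,
) -> list[GeneRecord]:
    """Read gene spans from BED4+ or GFF3.

    BED intervals are kept as-is (already 0-based half-open); GFF3
    ``gene``-type features are converted from 1-based inclusive to 0-based
    half-open (start-1, end). Gene IDs come from BED column 4 or the GFF3
    ``ID`` attribute and must be unique.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed":
        genes = _read_bed(path)
    elif format == "gff3":
        genes = _read_gff3(path)
    else:
        raise ValueError(f"unknown gene-model format: {format!r} (expected bed or gff3)")
    if strip_suffix:
        genes = [
            GeneRecord(_strip_suffix(g.gene_id), g.chrom, g.start, g.end, g.strand)
            for g in genes
        ]
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
        if g.start < 0 or g.start >= g.end:
            raise ValueError(
                f"{path}: invalid span for {g.gene_id}: [{g.start}, {g.end})"
            )
    return genes


def _read_bed(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED file needs >= 4 columns (chrom start end name)")
    genes = []
    for row in df.itertuples(index=False):
        strand = str(row[5]).strip() if df.shape[1] >= 6 else "."
        if strand not in {"+", "-", "."}:
            strand = "."
        genes.append(
            GeneRecord(
                gene_id=str(row[3]).strip(),
                chrom=str(row[0]).strip(),
                start=int(row[1]),
                end=int(row[2]),
                strand=strand,
            )
        )
    return genes


def _read_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        from_string=False,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneRecord(
                gene_id=str(gene_id).strip(),
                chrom=feat.seqid,
                start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                end=feat.end,
                strand=feat.strand if feat.strand in {"+", "-"} else ".",
            )
        )
    if not genes:
        logger.warning("%s: GFF3 contains no 'gene' features", path)
    return genes


def read_gene_list(path: str | Path, strip_suffix: bool = False) -> ReferenceGeneSet:
    """Read a one-ID-per-line gene list ('#' comments allowed) as a reference set.

    IDs are matched case-sensitively after stripping whitespace; duplicates
    are collapsed with a warning.
    """
    path = Path(path)
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                ids.append(_strip_suffix(line) if strip_suffix else line)
    unique = frozenset(ids)
    if len(unique) < len(ids):
        logger.warning("%s: %d duplicate gene IDs collapsed", path, len(ids) - len(unique))
    if not unique:
        raise ValueError(f"{path}: empty gene list")
    return ReferenceGeneSet(gene_ids=unique)


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.{FLOAT_PRECISION}g}"


def write_ranked_table(
    results: Sequence,
    path: str | Path,
    reference: ReferenceGeneSet | None = None,
    assigned_pvalues: Mapping[str, float | None] | None = None,
) -> None:
    """Write the final ranked gene table as TSV.

    Columns: gene_id, assigned_pvalue, gwas_log_odds, gba_score, final_score,
    rank, is_reference. ``results`` is an ordered sequence of
    :class:`~gwaboost.boosting.BoostResult` (already sorted by final score).
    """
    assigned_pvalues = assigned_pvalues or {}
    ref = reference.gene_ids if reference is not None else frozenset()
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tassigned_pvalue\tgwas_log_odds\tgba_score\tfinal_score\trank\tis_reference\n"
        )
        for rank, r in enumerate(results, start=1):
            fh.write(
                "\t".join(
                    [
                        r.gene_id,
                        _fmt(assigned_pvalues.get(r.gene_id)),
                        _fmt(r.log_odds_gwas),
                        _fmt(r.gba_score),
                        _fmt(r.final_score),
                        str(rank),
                        str(int(r.gene_id in ref)),
                    ]
                )
                + "\n"
            )


def read_ranked_table(path: str | Path) -> pd.DataFrame:
    """Read a ranked gene table written by :func:`write_ranked_table`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_scan_summary(scan, path: str | Path) -> None:
    """Write the per-threshold scan summary as TSV.

    One row per grid threshold with the quantities behind the performance
    curve: pAUC on the real network, null mean/SD over the randomized
    networks, and the 2-SD significance call (NA when no null was built).
    """
    with open(path, "w") as fh:
        fh.write("log10p_threshold\tauc_real\tauc_random_mean\tauc_random_sd\tsignificant\n")
        for i, t in enumerate(scan.grid):
            sig = scan.significant[i]
            fh.write(
                "\t".join(
                    [
                        f"{t:.10g}",
                        _fmt(scan.auc_real[i]),
                        _fmt(scan.auc_random_mean[i]),
                        _fmt(scan.auc_random_sd[i]),
                        "NA" if sig is None else str(int(sig)),
                    ]
                )
                + "\n"
            )


def write_scan_curves(scan, path: str | Path) -> None:
    """Plot-ready export of the performance curves as data.

    One row per grid threshold with everything needed to redraw the scan
    figure: the real-network curve, the flat GWAS-only baseline, and the
    lower/upper edges of the 2-SD null band.
    """
    with open(path, "w") as fh:
        fh.write(
            "log10p_threshold\tauc_real\tauc_gwas_only\tauc_random_mean\t"
            "null_band_lo\tnull_band_hi\n"
        )
        for i, t in enumerate(scan.grid):
            m, s = scan.auc_random_mean[i], scan.auc_random_sd[i]
            fh.write(
                "\t".join(
                    [
                        f"{t:.10g}",
                        _fmt(scan.auc_real[i]),
                        _fmt(scan.auc_gwas_only),
                        _fmt(m),
                        _fmt(m - 2 * s),
                        _fmt(m + 2 * s),
                    ]
                )
                + "\n"
            )


def write_gene_list(gene_ids: Iterable[str], path: str | Path) -> None:
    """Write a one-ID-per-line gene list."""
    with open(path, "w") as fh:
        for g in gene_ids:
            fh.write(f"{g}\n")
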