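"""SNP-to-gene assignment: best P-value within a window around each gene span.

Each gene receives the minimum SNP P-value among SNPs within a fixed
chromosomal distance of either gene boundary (default 10 kb). A SNP at
1-based position p falls in the window of a gene with internal 0-based
half-open span [start, end) iff start - window < p <= end + window; a SNP
may land in several overlapping gene windows and is assigned to all of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GeneRecord, SnpRecord

logger = logging.getLogger(__name__)

__all__ = ["GeneAssignment", "assign_snps_to_genes"]


@dataclass(frozen=True)
class GeneAssignment:
    """Best window P-value for one gene.

    ``assigned_pvalue`` and ``best_snp`` are None iff no SNP fell in the
    window. Ties among equally significant SNPs resolve to the smallest
    position, so output is deterministic.
    """

    gene_id: str
    assigned_pvalue: float | None
    best_snp: tuple[str, int] | None
    n_snps_in_window: int


def assign_snps_to_genes(
    snps: list[SnpRecord],
    genes: list[GeneRecord],
    window: int = 10_000,
) -> list[GeneAssignment]:
    """Assign to each gene the most significant SNP P-value within ``window``.

    Uses a per-chromosome sorted sweep: SNP positions are sorted once and
    each gene's window is resolved by binary search, O((n+m) log n) overall.
    Gene order of the input is preserved in the output; SNP input order is
    irrelevant.
    """
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {s.chrom for s in snps}:
        recs = [(s.pos, s.pvalue) for s in snps if s.chrom == chrom]
        recs.sort()
        pos = np.array([r[0] for r in recs], dtype=np.int64)
        pv = np.array([r[1] for r in recs], dtype=np.float64)
        by_chrom[chrom] = (pos, pv)

    gene_chroms = {g.chrom for g in genes}
    orphans = sorted(gene_chroms - set(by_chrom)) + sorted(set(by_chrom) - gene_chroms)
    if orphans and snps and genes:
        logger.warning(
            "chromosome naming mismatch between SNPs and genes; orphan chromosomes: %s",
            ", ".join(orphans),
        )

    out: list[GeneAssignment] = []
    for g in genes:
        if g.chrom not in by_chrom:
            out.append(GeneAssignment(g.gene_id, None, None, 0))
            continue
        pos, pv = by_chrom[g.chrom]
        lo = int(np.searchsorted(pos, g.start - window, side="right"))  # pos > start - window
        hi = int(np.searchsorted(pos, g.end + window, side="right"))  # pos <= end + window
        if hi <= lo:
            out.append(GeneAssignment(g.gene_id, None, None, 0))
            continue
        block = pv[lo:hi]
        k = int(np.argmin(block))  # first minimum = smallest position (pos sorted)
        out.append(
            GeneAssignment(
                gene_id=g.gene_id,
                assigned_pvalue=float(block[k]),
                best_snp=(g.chrom, int(pos[lo + k])),
                n_snps_in_window=hi - lo,
            )
        )
    return out
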