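"""Gene-level GWAS evidence scores.

Two quantities are derived from each gene's assigned P-value:

* ``prob`` — the probability p_j that the gene is involved in the phenotype,
  which enters the soft guilt-by-association sum through the weight
  2 p_j - 1. The default calibration is the complement rule p_j = 1 - P,
  under which only very strong associations donate near-full weight
  (2p - 1 -> 1 as P -> 0) and P = 0.5 is exactly neutral.
* ``log_odds_gwas`` — the log odds of phenotype association given the GWAS
  data, the additive GWAS term of the naive-Bayes posterior. It is
  calibrated empirically against the reference gene set: genes are ranked
  by ascending P, partitioned into consecutive rank bins, each bin scored
  by a pseudocounted log-likelihood ratio of reference vs non-reference
  membership, and the bin scores made non-increasing in P by isotonic
  regression (pool-adjacent-violators, bin-size weights).

Genes with no SNP in their window carry neutral scores (prob 0.5, log odds
0) rather than being dropped, so the network can still nominate them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .io import ReferenceGeneSet
from .mapping import GeneAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "GeneGwasScore",
    "prob_from_pvalue",
    "calibrate_gene_log_odds",
    "score_genes",
]

#: Jeffreys-style pseudocount used in the per-bin log-likelihood ratio.
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class GeneGwasScore:
    """Per-gene GWAS evidence: assigned P, calibrated log odds, and p_j."""

    gene_id: str
    assigned_pvalue: float | None
    log_odds_gwas: float
    prob: float


def prob_from_pvalue(
    assignments: Sequence[GeneAssignment],
    mode: str = "complement",
    reference: ReferenceGeneSet | None = None,
    bin_size: int = 100,
) -> dict[str, float]:
    """Phenotype-involvement probability p_j per gene.

    mode="complement" (default): p_j = 1 - P. Needs no reference set and
    makes the GBA weight 2p_j - 1 equal 1 - 2P, so P >= 0.5 contributes
    nothing.

    mode="calibrated": p_j = sigmoid(log_odds_gwas + log prior odds), with
    prior odds = |positives| / |negatives| over the scored universe; the
    log odds come from :func:`calibrate_gene_log_odds` (requires
    ``reference``).

    Genes with a missing assigned P-value get the neutral p_j = 0.5.
    """
    if mode == "complement":
        return {
            a.gene_id: (1.0 - a.assigned_pvalue) if a.assigned_pvalue is not None else 0.5
            for a in assignments
        }
    if mode == "calibrated":
        if reference is None:
            raise ValueError("mode='calibrated' requires a reference gene set")
        log_odds = calibrate_gene_log_odds(assignments, reference, bin_size=bin_size)
        universe = {a.gene_id for a in assignments}
        n_pos = len(universe & reference.gene_ids)
        n_neg = len(universe) - n_pos
        if n_pos == 0 or n_neg == 0:
            raise ValueError("calibrated mode needs both positives and negatives in the universe")
        log_prior = math.log(n_pos / n_neg)
        out = {}
        for a in assignments:
            if a.assigned_pvalue is None:
                out[a.gene_id] = 0.5
            else:
                z = log_odds[a.gene_id] + log_prior
                out[a.gene_id] = 1.0 / (1.0 + math.exp(-z))
        return out
    raise ValueError(f"unknown prob mode: {mode!r} (expected complement or calibrated)")


def calibrate_gene_log_odds(
    assignments: Sequence[GeneAssignment],
    reference: ReferenceGeneSet,
    bin_size: int = 100,
) -> dict[str, float]:
    """Empirical GWAS log odds per gene via rank-binned isotonic LLR.

    Genes with a non-missing P are sorted by ascending P (ties broken by
    gene ID for determinism) and partitioned into consecutive bins of
    ``bin_size`` (the last bin may be smaller). Each bin b gets

        LLR_b = ln[ ((TP_b + 0.5) / (P_tot + 1)) / ((FP_b + 0.5) / (N_tot + 1)) ]

    where TP_b / FP_b count reference / non-reference genes in the bin and
    P_tot / N_tot are the totals over the scored genes. The bin scores are
    then made non-increasing in P by weighted isotonic regression
    (pool-adjacent-violators, weights = bin sizes) and every gene inherits
    its bin's isotonic value. Missing-P genes get log odds 0.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    scored = sorted(
        (a for a in assignments if a.assigned_pvalue is not None),
        key=lambda a: (a.assigned_pvalue, a.gene_id),
    )
    out = {a.gene_id: 0.0 for a in assignments}
    if not scored:
        logger.warning("no genes with assigned P-values; all log odds neutral")
        return out
    is_ref = np.array([a.gene_id in reference.gene_ids for a in scored], dtype=bool)
    p_tot = int(is_ref.sum())
    n_tot = len(scored) - p_tot
    if p_tot == 0:
        raise ValueError(
            "reference gene set has no overlap with genes carrying GWAS scores; "
            "check that gene IDs use the same naming scheme in both inputs"
        )

    edges = list(range(0, len(scored), bin_size)) + [len(scored)]
    tp = np.array([is_ref[a:b].sum() for a, b in zip(edges[:-1], edges[1:])], dtype=float)
    sizes = np.diff(edges).astype(float)
    fp = sizes - tp
    llr = np.log((tp + PSEUDOCOUNT) / (p_tot + 1)) - np.log((fp + PSEUDOCOUNT) / (n_tot + 1))

    if len(llr) > 1:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        llr = iso.fit_transform(np.arange(len(llr)), llr, sample_weight=sizes)
    # the calibration contract: retrieval odds never increase with P
    assert np.all(np.diff(llr) <= 1e-9), "isotonic step failed to enforce monotonicity"

    for b, (a, z) in enumerate(zip(edges[:-1], edges[1:])):
        for gene in scored[a:z]:
            out[gene.gene_id] = float(llr[b])
    return out


def score_genes(
    assignments: Sequence[GeneAssignment],
    reference: ReferenceGeneSet,
    prob_mode: str = "complement",
    bin_size: int = 100,
) -> list[GeneGwasScore]:
    """Bundle p_j and calibrated log odds into per-gene GWAS scores."""
    probs = prob_from_pvalue(assignments, mode=prob_mode, reference=reference, bin_size=bin_size)
    log_odds = calibrate_gene_log_odds(assignments, reference, bin_size=bin_size)
    return [
        GeneGwasScore(
            gene_id=a.gene_id,
            assigned_pvalue=a.assigned_pvalue,
            log_odds_gwas=log_odds[a.gene_id],
            prob=probs[a.gene_id],
        )
        for a in assignments
    ]
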