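"""Soft guilt-by-association boosting and naive-Bayes integration.

The GBA score of gene i is the one-hop sum over its network neighbors j

    S_i = sum_j (2 p_j - 1) * l_ij,

restricted to neighbors that (a) pass the contributor P-value threshold on
their assigned GWAS P-value and (b) have 2 p_j - 1 > 0, so weak or missing
evidence never donates weight. Assuming the network and the GWAS are
conditionally independent, the final posterior log odds is the plain sum

    final_score_i = S_i + log O(i | D_GWAS).

Any gene can *receive* a boost (including genes with no GWAS signal at
all, which is how purely network-nominated candidates arise); only genes
past the threshold can *give* one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import CoFunctionalNetwork
from .scoring import GeneGwasScore

__all__ = ["BoostResult", "select_contributors", "soft_gba", "combine", "boost"]


@dataclass(frozen=True)
class BoostResult:
    """Final score decomposition for one gene."""

    gene_id: str
    gba_score: float
    log_odds_gwas: float
    final_score: float
    was_contributor: bool


def select_contributors(
    scores: Sequence[GeneGwasScore], log10p_threshold: float
) -> set[str]:
    """Genes allowed to donate GBA weight at a given log10(P) threshold.

    A gene contributes iff it has a non-missing assigned P-value with
    log10(P) <= threshold (boundary inclusive). Everything else can still
    receive boosts.
    """
    return {
        s.gene_id
        for s in scores
        if s.assigned_pvalue is not None
        and math.log10(s.assigned_pvalue) <= log10p_threshold
    }


def soft_gba(
    net: CoFunctionalNetwork,
    probs: Mapping[str, float],
    contributors: set[str] | frozenset[str],
) -> dict[str, float]:
    """Soft GBA score S_i for every network gene.

    ``probs`` maps gene IDs to p_j; genes absent from the map are treated
    as neutral (p = 0.5, zero weight). Genes absent from the network get
    S_i = 0 implicitly (they simply do not appear in the result).
    """
    p = np.full(net.n_nodes, 0.5)
    contrib = np.zeros(net.n_nodes, dtype=bool)
    for i, g in enumerate(net.nodes):
        p[i] = probs.get(g, 0.5)
        contrib[i] = g in contributors
    s = _gba_node_scores(net.edge_u, net.edge_v, net.weights, p, contrib, net.n_nodes)
    return {g: float(s[i]) for i, g in enumerate(net.nodes)}


def _gba_node_scores(
    edge_u: np.ndarray,
    edge_v: np.ndarray,
    weights: np.ndarray,
    p: np.ndarray,
    contrib: np.ndarray,
    n: int,
) -> np.ndarray:
    """Vectorized S_i over node slots: scatter-add (2p_j - 1) l_ij from
    eligible donors j to each edge's opposite endpoint."""
    donation = np.where(contrib & (2.0 * p - 1.0 > 0.0), 2.0 * p - 1.0, 0.0)
    s = np.zeros(n)
    np.add.at(s, edge_u, weights * donation[edge_v])
    np.add.at(s, edge_v, weights * donation[edge_u])
    return s


def combine(
    gba: Mapping[str, float],
    gwas: Mapping[str, float],
    contributors: set[str] | frozenset[str] = frozenset(),
) -> list[BoostResult]:
    """Integrate GBA and GWAS log odds over the union gene universe.

    Missing entries default to the neutral 0. Output is sorted by final
    score descending, ties broken by gene ID ascending.
    """
    universe = set(gba) | set(gwas)
    results = [
        BoostResult(
            gene_id=g,
            gba_score=gba.get(g, 0.0),
            log_odds_gwas=gwas.get(g, 0.0),
            final_score=gba.get(g, 0.0) + gwas.get(g, 0.0),
            was_contributor=g in contributors,
        )
        for g in universe
    ]
    results.sort(key=lambda r: (-r.final_score, r.gene_id))
    return results


def boost(
    net: CoFunctionalNetwork,
    scores: Sequence[GeneGwasScore],
    log10p_threshold: float,
) -> list[BoostResult]:
    """Run one boosting pass at a single contributor threshold.

    Returns ranked :class:`BoostResult` for the union of network genes and
    scored genes.
    """
    contributors = select_contributors(scores, log10p_threshold)
    probs = {s.gene_id: s.prob for s in scores}
    gba = soft_gba(net, probs, contributors)
    gwas = {s.gene_id: s.log_odds_gwas for s in scores}
    return combine(gba, gwas, contributors)
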