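"""Ranking evaluation and the contributor-threshold scan.

Prediction quality is the area under the ROC curve restricted to false-
positive rates below ``fpr_max`` (default 5%), an early-retrieval metric:
only the top of the ranking matters because only high-ranked candidates
get follow-up. The partial area is normalized by ``fpr_max`` so a perfect
ranking scores 1 and the chance line scores ``fpr_max / 2 / fpr_max`` =
0.025 at the default.

The scan repeats boosting over a grid of contributor log10(P) thresholds,
builds a null band from label-permuted networks (the same permuted
networks reused at every grid point, so variation across thresholds
reflects the thresholds and not permutation noise), and selects the
threshold maximizing the real-network pAUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boosting import BoostResult, combine, select_contributors
from .io import ReferenceGeneSet
from .network import CoFunctionalNetwork, randomize_network
from .scoring import GeneGwasScore

__all__ = ["ScanResult", "partial_auc", "build_grid", "run_scan"]


def _pauc(scores: np.ndarray, y: np.ndarray, fpr_max: float) -> float:
    """Normalized partial AUC below ``fpr_max`` from raw score and label arrays.

    Builds the ROC step function with tied scores collapsed into single
    blocks (each block contributes one diagonal segment, equivalent to
    averaging over all orderings of the tied genes), truncates at
    ``fpr_max`` by linear interpolation and integrates by trapezoid.
    """
    if not 0.0 < fpr_max <= 1.0:
        raise ValueError(f"fpr_max must be in (0, 1], got {fpr_max}")
    y = np.asarray(y, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0:
        raise ValueError(
            "no positives in the evaluation universe; check that reference gene "
            "IDs match the annotation/network naming scheme"
        )
    if n_neg == 0:
        raise ValueError("no negatives in the evaluation universe")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    yy = y[order]
    ends = np.append(np.nonzero(np.diff(s))[0], len(s) - 1)  # last index of each tie block
    tp = np.cumsum(yy)[ends]
    fp = (ends + 1) - tp
    tpr = np.concatenate(([0.0], tp / n_pos))
    fpr = np.concatenate(([0.0], fp / n_neg))

    over = fpr > fpr_max
    if over.any():
        k = int(np.argmax(over))  # first vertex beyond fpr_max; fpr[k-1] <= fpr_max < fpr[k]
        frac = (fpr_max - fpr[k - 1]) / (fpr[k] - fpr[k - 1])
        t_cut = tpr[k - 1] + frac * (tpr[k] - tpr[k - 1])
        fpr = np.concatenate((fpr[:k], [fpr_max]))
        tpr = np.concatenate((tpr[:k], [t_cut]))
    area = float(np.trapezoid(tpr, fpr))
    return area / fpr_max


def partial_auc(
    ranking: Sequence,
    positives: ReferenceGeneSet | set[str] | frozenset[str],
    fpr_max: float = 0.05,
) -> float:
    """Normalized AUC below ``fpr_max`` FPR of a scored gene ranking.

    ``ranking`` is a sequence of :class:`~gwaboost.boosting.BoostResult`
    or ``(gene_id, score)`` pairs; the evaluation universe is exactly the
    ranked genes, positives are the reference genes among them and
    negatives all others. Ties in score are handled as diagonal ROC blocks,
    so the value does not depend on the ordering of tied genes.
    """
    pos = positives.gene_ids if isinstance(positives, ReferenceGeneSet) else positives
    if ranking and hasattr(ranking[0], "gene_id"):
        genes = [r.gene_id for r in ranking]
        scores = np.array([r.final_score for r in ranking], dtype=np.float64)
    else:
        genes = [g for g, _ in ranking]
        scores = np.array([v for _, v in ranking], dtype=np.float64)
    y = np.array([g in pos for g in genes], dtype=bool)
    return _pauc(scores, y, fpr_max)


def build_grid(lo: float = -6.0, hi: float = -2.0, step: float = 0.3) -> list[float]:
    """Arithmetic grid of contributor log10(P) thresholds over [lo, hi).

    The grid starts at ``lo`` and advances by ``step``, keeping values
    strictly below ``hi`` (the scan range is an open interval at the weak
    end). Defaults give the 14 thresholds -6.0, -5.7, ..., -2.1.
    """
    if not lo < hi:
        raise ValueError(f"grid requires lo < hi, got lo={lo}, hi={hi}")
    if step <= 0:
        raise ValueError(f"grid step must be positive, got {step}")
    n = max(1, math.ceil((hi - lo) / step - 1e-9))
    grid = [round(lo + k * step, 10) for k in range(n)]
    if not grid:
        raise ValueError("empty threshold grid")
    return grid


@dataclass
class ScanResult:
    """Outcome of a full contributor-threshold scan."""

    grid: list[float]
    auc_real: list[float]
    auc_random_mean: list[float]
    auc_random_sd: list[float]
    auc_gwas_only: float
    optimal_threshold: float
    significant: list[bool | None]
    final_ranking: list[BoostResult] = field(repr=False)
    n_random: int = 0

    @property
    def optimal_index(self) -> int:
        return self.grid.index(self.optimal_threshold)


def run_scan(
    net: CoFunctionalNetwork,
    scores: Sequence[GeneGwasScore],
    reference: ReferenceGeneSet,
    grid: Sequence[float] | None = None,
    n_random: int = 100,
    seed: int | None = None,
    fpr_max: float = 0.05,
    null_model: str = "permute",
) -> ScanResult:
    """Scan contributor thresholds and build the randomized-network null band.

    For each grid threshold the boosting pass runs once on the real network
    and once on each of ``n_random`` randomized networks (built once from
    seeds derived deterministically from ``seed`` and reused at every
    threshold); prediction quality is the normalized pAUC against
    ``reference``. The optimal threshold is the grid value maximizing the
    real-network pAUC (earliest grid point on ties); a threshold is called
    significant when the real pAUC exceeds the null mean by more than two
    null standard deviations (sample SD, n-1 denominator).

    The evaluation universe is the union of scored genes, network genes and
    reference genes; genes unseen by the GWAS carry neutral scores so the
    network can still rank them.
    """
    if grid is None:
        grid = build_grid()
    grid = list(grid)
    if n_random > 0 and seed is None:
        raise ValueError("seed is required when n_random > 0 (the null must be reproducible)")
    if n_random < 0:
        raise ValueError("n_random must be >= 0")

    universe = sorted({s.gene_id for s in scores} | set(net.nodes) | set(
        reference.gene_ids))
    uidx = {g: i for i, g in enumerate(universe)}
    n_uni = len(universe)

    p = np.full(n_uni, 0.5)
    lo_arr = np.zeros(n_uni)
    log10p = np.full(n_uni, np.nan)
    for s in scores:
        i = uidx[s.gene_id]
        p[i] = s.prob
        lo_arr[i] = s.log_odds_gwas
        if s.assigned_pvalue is not None:
            log10p[i] = math.log10(s.assigned_pvalue)
    y = np.array([g in reference.gene_ids for g in universe], dtype=bool)

    w = net.weights
    nets = [net] + [
        randomize_network(net, _child_seed(seed, r), method=null_model)
        for r in range(n_random)
    ]
    # per-network edge endpoints expressed as universe indices
    edge_maps = []
    for nw in nets:
        m = np.array([uidx[g] for g in nw.nodes], dtype=np.int64)
        edge_maps.append((m[nw.edge_u], m[nw.edge_v]))

    auc_real: list[float] = []
    auc_rand_mean: list[float] = []
    auc_rand_sd: list[float] = []
    significant: list[bool | None] = []
    with np.errstate(invalid="ignore"):
        weight_pos = np.where(2.0 * p - 1.0 > 0.0, 2.0 * p - 1.0, 0.0)
        for t in grid:
            contrib = log10p <= t  # NaN compares False: missing-P genes never contribute
            donation = np.where(contrib, weight_pos, 0.0)
            aucs = np.empty(len(nets))
            for k, (mu, mv) in enumerate(edge_maps):
                s_uni = np.zeros(n_uni)
                np.add.at(s_uni, mu, w * donation[mv])
                np.add.at(s_uni, mv, w * donation[mu])
                aucs[k] = _pauc(s_uni + lo_arr, y, fpr_max)
            auc_real.append(float(aucs[0]))
            if n_random >= 1:
                auc_rand_mean.append(float(aucs[1:].mean()))
                sd = float(aucs[1:].std(ddof=1)) if n_random >= 2 else float("nan")
                auc_rand_sd.append(sd)
                significant.append(
                    bool(auc_real[-1] > auc_rand_mean[-1] + 2.0 * sd)
                    if n_random >= 2
                    else None
                )
            else:
                auc_rand_mean.append(float("nan"))
                auc_rand_sd.append(float("nan"))
                significant.append(None)

    auc_gwas_only = _pauc(lo_arr, y, fpr_max)
    opt_i = int(np.argmax(auc_real))  # argmax returns the earliest maximum
    t_opt = grid[opt_i]

    contributors = select_contributors(scores, t_opt)
    with np.errstate(invalid="ignore"):
        donation = np.where(log10p <= t_opt, weight_pos, 0.0)
    mu, mv = edge_maps[0]
    s_uni = np.zeros(n_uni)
    np.add.at(s_uni, mu, w * donation[mv])
    np.add.at(s_uni, mv, w * donation[mu])
    final_ranking = combine(
        {g: float(s_uni[i]) for g, i in uidx.items()},
        {g: float(lo_arr[i]) for g, i in uidx.items()},
        contributors,
    )

    return ScanResult(
        grid=grid,
        auc_real=auc_real,
        auc_random_mean=auc_rand_mean,
        auc_random_sd=auc_rand_sd,
        auc_gwas_only=auc_gwas_only,
        optimal_threshold=t_opt,
        significant=significant,
        final_ranking=final_ranking,
        n_random=n_random,
    )


def _child_seed(master: int | None, replicate: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence([int(master), int(replicate)])
    return int(ss.generate_state(1)[0] % (2**31))
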