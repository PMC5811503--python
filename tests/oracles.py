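"""Independent brute-force oracles used to check the optimized implementations.

Each oracle is written in the most literal form possible (plain Python
loops, threshold enumeration, adjacency matrices) and deliberately shares
no code path with the package internals it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_assign(snps, genes, window):
    """All-pairs SNP-gene scan: for each gene, filter SNPs by the window rule
    and take the minimum P (smallest position on ties)."""
    out = {}
    for g in genes:
        hits = [
            s
            for s in snps
            if s.chrom == g.chrom and g.start - window < s.pos <= g.end + window
        ]
        if not hits:
            out[g.gene_id] = (None, None, 0)
        else:
            best = min(hits, key=lambda s: (s.pvalue, s.pos))
            out[g.gene_id] = (best.pvalue, (best.chrom, best.pos), len(hits))
    return out


def brute_force_gba(net, probs, contributors):
    """O(|V|^2) double loop over a dense adjacency matrix."""
    n = net.n_nodes
    A = np.zeros((n, n))
    for a, b, w in zip(net.edge_u, net.edge_v, net.weights):
        A[a, b] = A[b, a] = w
    out = {}
    for i in range(n):
        s = 0.0
        for j in range(n):
            gj = net.nodes[j]
            p = probs.get(gj, 0.5)
            if A[i, j] > 0 and gj in contributors and 2 * p - 1 > 0:
                s += (2 * p - 1) * A[i, j]
        out[net.nodes[i]] = s
    return out


def brute_force_pauc(genes, scores, positives, fpr_max=0.05):
    """Partial AUC by explicit ROC-vertex enumeration over score thresholds."""
    n_pos = sum(1 for g in genes if g in positives)
    n_neg = len(genes) - n_pos
    assert n_pos > 0 and n_neg > 0
    vertices = [(0.0, 0.0)]
    for t in sorted(set(scores), reverse=True):
        tp = sum(1 for g, s in zip(genes, scores) if s >= t and g in positives)
        fp = sum(1 for g, s in zip(genes, scores) if s >= t and g not in positives)
        vertices.append((fp / n_neg, tp / n_pos))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(vertices[:-1], vertices[1:]):
        if x1 <= fpr_max:
            area += (x1 - x0) * (y0 + y1) / 2.0
        elif x0 < fpr_max:
            frac = (fpr_max - x0) / (x1 - x0)
            y_cut = y0 + frac * (y1 - y0)
            area += (fpr_max - x0) * (y0 + y_cut) / 2.0
            break
        else:
            break
    return area / fpr_max


def random_weighted_network(rng, n_max=300):
    """A random simple weighted graph as a CoFunctionalNetwork."""
    from gwaboost.network import CoFunctionalNetwork

    n = int(rng.integers(4, n_max + 1))
    nodes = [f"g{i}" for i in range(n)]
    m = int(rng.integers(1, 2 * n))
    pairs = set()
    while len(pairs) < m:
        a, b = (int(x) for x in rng.integers(0, n, 2))
        if a != b:
            pairs.add((min(a, b), max(a, b)))
    pairs = sorted(pairs)
    eu = np.array([p[0] for p in pairs], dtype=np.int64)
    ev = np.array([p[1] for p in pairs], dtype=np.int64)
    w = rng.random(len(pairs)) * 3.0 + 0.01
    return CoFunctionalNetwork(nodes, eu, ev, w)
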