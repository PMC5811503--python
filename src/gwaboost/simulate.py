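"""Synthetic input bundles with controlled signal structure.

Emulates the statistical shape of a plant GWAS boosting problem: a genome
of non-overlapping genes on one (or more) synthetic chromosomes, a scale-
free weighted co-functional network, uniform null SNP P-values, and a
planted phenotype module — a set of genes wired densely in the network, of
which only a fraction carries genuine association signal. That fraction
models genetic heterogeneity: phenotype-associated variants occur in only
a subset of the pathway's genes, so GWAS alone misses the rest and one-hop
guilt-by-association should rescue them. The reference gene list is the
full module, including the signal-free members.

Signal SNPs get P = 10^(-X) with X exponential (mean ``signal_neglog10p``)
truncated to X >= 2, so every signal gene is at least nominally associated
(P <= 1e-2) with a heavy tail of genome-wide-significant hits.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io import GeneRecord, ReferenceGeneSet, SnpRecord, write_gene_list
from .network import CoFunctionalNetwork, serialize_network

__all__ = ["SimulationConfig", "generate", "generate_bundle"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic bundle.

    Defaults are sized like a desk-scale Arabidopsis problem: 2,000 genes
    at ~1 gene / 5 kb, a scale-free network (preferential attachment,
    m = 3), a 40-gene planted module of which 40% carry signal with mean
    -log10 P of 5 for the signal SNPs.
    """

    n_genes: int = 2000
    n_snps: int = 20_000
    genome_length: int = 10_000_000
    network_model: str = "barabasi_albert"
    attach_m: int = 3
    edge_prob: float = 0.003
    weight_mu: float = 0.0
    weight_sigma: float = 0.6
    module_size: int = 40
    module_extra_edges: int = 120
    signal_frac: float = 0.4
    signal_neglog10p: float = 5.0
    window_placement: bool = True
    n_chromosomes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.signal_frac <= 1:
            raise ValueError("signal_frac must be in [0, 1]")
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")


def generate(cfg: SimulationConfig):
    """Generate one bundle in memory.

    Returns ``(network, genes, snps, reference, truth)`` where ``truth`` is
    a dict with the planted module, the signal genes and the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _place_genes(cfg, rng)
    net, module_genes = _build_network(cfg, rng, [g.gene_id for g in genes])
    n_signal = int(round(cfg.signal_frac * len(module_genes)))
    signal_genes = sorted(rng.choice(module_genes, size=n_signal, replace=False).tolist())
    snps = _draw_snps(cfg, rng, genes, signal_genes)
    reference = ReferenceGeneSet(gene_ids=frozenset(module_genes))
    truth = {
        "module_genes": sorted(module_genes),
        "signal_genes": signal_genes,
        "seed": cfg.seed,
        "config": asdict(cfg),
    }
    return net, genes, snps, reference, truth


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneRecord]:
    """Non-overlapping gene spans: one slot per gene, jittered within it."""
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)  # ceil
    chrom_len = cfg.genome_length // cfg.n_chromosomes
    slot = chrom_len // per_chrom
    if slot < 700:
        raise ValueError(
            f"genome_length {cfg.genome_length} too short for {cfg.n_genes} genes "
            f"(slot {slot} < 700 bases)"
        )
    max_len = min(3000, slot - 100)
    genes = []
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        chrom = f"chr{i // per_chrom + 1}"
        k = i % per_chrom
        length = int(rng.integers(500, max_len + 1))
        start = k * slot + int(rng.integers(0, slot - length + 1))
        genes.append(
            GeneRecord(
                gene_id=f"G{i:0{width}d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    return genes


def _build_network(
    cfg: SimulationConfig, rng: np.random.Generator, gene_ids: list[str]
) -> tuple[CoFunctionalNetwork, list[str]]:
    import networkx as nx

    n = cfg.n_genes
    if cfg.network_model == "barabasi_albert":
        g = nx.barabasi_albert_graph(n, cfg.attach_m, seed=int(rng.integers(2**31)))
    elif cfg.network_model == "erdos_renyi":
        g = nx.fast_gnp_random_graph(n, cfg.edge_prob, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown network model: {cfg.network_model!r}")

    # detach gene identity from attachment order (early BA nodes are hubs)
    node_to_gene = rng.permutation(n)
    edges = {(min(a, b), max(a, b)) for a, b in g.edges()}
    module_idx = sorted(rng.choice(n, size=cfg.module_size, replace=False).tolist())

    # densify the planted module so GBA can relay signal between its members
    candidates = [
        (a, b)
        for i, a in enumerate(module_idx)
        for b in module_idx[i + 1 :]
        if (a, b) not in edges
    ]
    n_extra = min(cfg.module_extra_edges, len(candidates))
    extra_pos = rng.choice(len(candidates), size=n_extra, replace=False)
    extra = {candidates[i] for i in extra_pos}

    base = sorted(edges)
    w_base = rng.lognormal(cfg.weight_mu, cfg.weight_sigma, size=len(base))
    # module wiring gets upper-quartile weights: lognormal conditioned on q75+
    from scipy.stats import norm

    u = rng.random(len(extra))
    w_extra = np.exp(cfg.weight_mu + cfg.weight_sigma * norm.ppf(0.75 + 0.25 * u))

    all_edges = base + sorted(extra)
    all_w = np.concatenate([w_base, w_extra])
    gene_of = [gene_ids[node_to_gene[i]] for i in range(n)]
    nodes = sorted(gene_of)
    index = {g_: i for i, g_ in enumerate(nodes)}
    eu = np.array([index[gene_of[a]] for a, _ in all_edges], dtype=np.int64)
    ev = np.array([index[gene_of[b]] for _, b in all_edges], dtype=np.int64)
    net = CoFunctionalNetwork(nodes, eu, ev, all_w)
    module_genes = [gene_of[i] for i in module_idx]
    return net, module_genes


def _draw_snps(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genes: list[GeneRecord],
    signal_genes: list[str],
) -> list[SnpRecord]:
    per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    chrom_len = cfg.genome_length // cfg.n_chromosomes
    snps = []
    chrom_ids = rng.integers(0, cfg.n_chromosomes, size=cfg.n_snps)
    positions = rng.integers(1, chrom_len + 1, size=cfg.n_snps)
    pvals = 1.0 - rng.random(cfg.n_snps)  # Uniform(0, 1]
    for c, pos, pv in zip(chrom_ids, positions, pvals):
        snps.append(SnpRecord(chrom=f"chr{c + 1}", pos=int(pos), pvalue=float(pv)))

    by_id = {g.gene_id: g for g in genes}
    for gid in signal_genes:
        g = by_id[gid]
        x = 2.0 + rng.exponential(cfg.signal_neglog10p)  # Exp truncated to >= 2
        if cfg.window_placement:
            pos = int(rng.integers(g.start + 1, g.end + 1))  # inside the span (1-based)
        else:
            offset = int(rng.integers(1, 5001))
            pos = g.end + offset
        snps.append(SnpRecord(chrom=g.chrom, pos=pos, pvalue=float(10.0 ** (-x))))
    return snps


def generate_bundle(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a bundle and write it as the four pipeline input files.

    Writes ``network.tsv`` (edge list), ``genes.bed`` (BED4+),
    ``snps.tsv`` (summary statistics) and ``reference.txt`` (gene list),
    plus ``truth.json`` with the planted ground truth for assertions.
    Bit-reproducible for a fixed config (seed included).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, genes, snps, reference, truth = generate(cfg)

    paths = {
        "network": outdir / "network.tsv",
        "genes": outdir / "genes.bed",
        "snps": outdir / "snps.tsv",
        "reference": outdir / "reference.txt",
        "truth": outdir / "truth.json",
    }
    serialize_network(net, paths["network"])
    with open(paths["genes"], "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    with open(paths["snps"], "w") as fh:
        fh.write("chrom\tpos\tpvalue\n")
        for s in snps:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pvalue:.17g}\n")
    write_gene_list(sorted(reference.gene_ids), paths["reference"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
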