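# Methods

## Model

`gwaboost` ranks genes for a phenotype by the posterior log odds

    final_i = S_i + log O(i ∈ D | D_GWAS),

a naive-Bayes combination of two evidence sources assumed conditionally
independent: a one-hop soft guilt-by-association (GBA) score over a
weighted co-functional gene network,

    S_i = Σ_j (2 p_j − 1) l_ij ,

and a gene-level GWAS log odds. The GBA sum runs over direct network
neighbors *j* of gene *i* only (no diffusion, no iteration), restricted to
neighbors that (a) pass the contributor threshold on their assigned GWAS
P-value and (b) satisfy 2 p_j − 1 > 0. Link weights l_ij are the network's
own confidence scores (AraNet-style log-likelihood scores, strictly
positive); p_j is the probability that gene *j* is involved in the
phenotype. Any gene may receive a boost — including genes without any
assigned SNP, which enter with neutral scores — but only genes past the
threshold donate weight. The contributor threshold is the method's defense
against hub inflation: without it, a hub accumulates many small
(2 p_j − 1) l_ij terms from noise-level neighbors.

## From SNP P-values to gene scores

**Assignment.** A SNP at 1-based position p lies in the window of a gene
with 0-based half-open span [start, end) iff start − w < p ≤ end + w, with
w = 10 kb by default. Each gene receives the minimum P-value among its
window SNPs (ties resolve to the smallest position); a SNP may be counted
by several overlapping gene windows. Assignment is strand-agnostic: the
window extends from both gene boundaries. Genes with no window SNP keep a
missing P and neutral downstream scores (p = 0.5, log odds 0) rather than
being dropped, so the network can still nominate them.

**Involvement probability p_j.** The default is the complement rule
p_j = 1 − P: it needs no reference set, gives P ≥ 0.5 zero GBA weight, and
approaches full weight only for very strong associations. An alternative
`calibrated` mode maps the calibrated log odds through a logistic with the
reference-set prior odds; the scan machinery is agnostic to the choice.

**GWAS log odds.** Genes with assigned P-values are sorted by ascending P
and cut into consecutive rank bins of 100 (configurable). Bin b with TP_b
reference and FP_b non-reference genes gets the pseudocounted
log-likelihood ratio

    LLR_b = ln[ (TP_b + 0.5)/(P_tot + 1) ] − ln[ (FP_b + 0.5)/(N_tot + 1) ],

with P_tot/N_tot the reference/non-reference totals among scored genes.
Jeffreys-style 0.5 pseudocounts keep empty bins finite. Because retrieval
odds must not increase with P, the bin values are made non-increasing by
weighted isotonic regression (pool-adjacent-violators, weights = bin
sizes); each gene inherits its bin's isotonic value. The same reference
set later scores retrieval; this mild circularity is intrinsic to the
design (the calibration is identical for the real and the permuted
networks, so it cannot manufacture a significant band exceedance).

## Evaluation and the threshold scan

**Partial AUC.** Ranking quality is the area under the ROC curve from
FPR 0 to 0.05, normalized by 0.05 so that 1.0 is perfect and 0.025 is the
chance line. The evaluation universe is the union of annotated, network
and reference genes; positives are the reference genes, negatives all
others. Tied scores form single ROC blocks integrated as diagonal
segments — equivalent to averaging over all orderings of the tied genes,
and therefore deterministic.

**Null model.** Significance is judged against networks with gene labels
permuted uniformly at random. Label permutation preserves every
topological property — degree sequence, weight distribution, hubness —
and destroys only the association between gene identity and network
position, which is precisely the quantity the method exploits. A
degree-preserving edge-rewiring null (double-edge swaps, 10×|E| swaps,
weights travelling with edges) is available for sensitivity analysis. The
same permuted replicates are reused at every grid threshold, so variation
across thresholds reflects the thresholds rather than permutation noise;
replicate seeds derive deterministically from the master seed.

**Scan.** The contributor threshold runs over an arithmetic log10(P) grid,
[lo, hi) by step, default −6.0 to −2.0 step 0.3 → 14 points (the weak end
is exclusive: the scan range is an open interval at −2). Per threshold the
real network's pAUC is compared with the null mean ± 2 SD (sample SD over
100 replicates); the optimal threshold maximizes the real pAUC, earliest
grid point on ties. A threshold low enough to empty the contributor set
collapses the ranking onto the GWAS-only baseline exactly.

## Synthetic data

The generator emulates the statistical structure of a plant GWAS boosting
problem rather than any particular dataset. Defaults: 2,000 genes of
0.5–3 kb placed without overlap on a 10 Mb chromosome (~1 gene / 5 kb,
roughly Arabidopsis gene density); 20,000 null SNPs with P ~ Uniform(0, 1];
a Barabási–Albert network (m = 3) with lognormal(0, 0.6) weights, node
identity detached from attachment order; a 40-gene planted module wired
with 120 extra within-module edges drawn from the upper weight quartile;
40% of module genes carry signal — one SNP inside the gene span with
P = 10^(−X), X exponential with mean 5 truncated to X ≥ 2 (implemented as
2 + Exp(5), identical by memorylessness). The reference list is the full
module including its silent members — exactly the genes GWAS alone misses
and boosting should rescue. Heterogeneity is modeled at the gene level
(which genes carry signal), not at the variant level: there is no LD, no
allele-frequency structure, and no mixed-model P-value generation, so
passing tests demonstrate the boosting and evaluation machinery, not
robustness to LD-driven or population-structure artifacts in real summary
statistics.

The full negative control sets signal_frac = 0 **and** module_extra_edges
= 0. Removing only the signal is not a clean null: a still-wired module
keeps the reference genes network-clustered, and any gene that crosses the
contributor threshold by chance inside the module boosts several reference
neighbors at once, legitimately lifting the real network above the
permutation band (the same clustering artifact the contributor threshold
exists to control). With the wiring removed the real network is exactly
exchangeable with its label permutations, which is the property a
calibration check needs.

## Numerical choices

- Internal coordinates are 0-based half-open everywhere; GFF3 converts at
  the parse boundary, BED is native. SNP positions stay 1-based.
- P-values of exactly 0 are rejected at parse time (they break the
  log-odds arithmetic); an explicit `--pvalue-floor` opts into clamping.
- Weights/P-values are serialized with 17 significant digits and parsed
  with exact `float()`, so written bundles round-trip bit-identically;
  ranked tables print 6 significant digits.
- Ranking ties break by gene ID ascending; grid values are rounded to 10
  decimals to keep thresholds exact; the SD of the null uses the n − 1
  denominator; with fewer than 2 replicates significance is reported as
  missing rather than guessed.
- The scan evaluates ~1,400 GBA passes per run (14 thresholds × 101
  networks), so the network lives in flat edge arrays and the permutation
  null permutes the label list in O(n); scatter-add accumulation makes a
  pass linear in edges. Against a brute-force double loop this
  accumulation order agrees to ≤ 1e-12 (floating-point summation-order
  rounding, not a tolerance in the modeling sense).
- Problem sizes in the test suite (300–2,000 genes, 20–100 null
  replicates, 20 seeds for the planted-module controls) are chosen so the
  full suite exercises every stage end to end at desk scale.

## Limitations

- One-hop GBA only; no random-walk or diffusion variants.
- The contributor threshold is the only hub control; no explicit degree
  normalization.
- p_j and the GWAS log odds are calibration choices layered on summary
  statistics; with very sparse reference sets the rank-binned LLR gets
  noisy and the isotonic step flattens most of the signal.
- The 2-SD significance band is a normal approximation over 100
  replicates; the null pAUC distribution is right-skewed when few genes
  pass the threshold, so band exceedances near the weak-threshold end of
  the grid should be read with that skew in mind.
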