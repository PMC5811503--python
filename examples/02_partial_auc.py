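"""Early-retrieval evaluation with the normalized partial AUC.

The quality of a candidate ranking is the area under the ROC curve
restricted to false-positive rates below 5%, normalized so a perfect
ranking scores 1.0 and a random one 0.025. Ties are handled as diagonal
blocks, so the value is independent of how tied genes are ordered.
"""

from gwaboost import partial_auc

positives = {"G1", "G2", "G3"}
negatives = [f"N{i}" for i in range(60)]

perfect = [("G1", 9.0), ("G2", 8.0), ("G3", 7.0)] + [
    (n, float(-i)) for i, n in enumerate(negatives)
]
print("perfect ranking:", partial_auc(perfect, positives))

interleaved = [("G1", 9.0), (negatives[0], 8.5), ("G2", 8.0)] + [
    (n, float(-i)) for i, n in enumerate(negatives[1:])
] + [("G3", -100.0)]
print("one positive buried:", round(partial_auc(interleaved, positives), 4))

all_tied = [(g, 1.0) for g in list(positives) + negatives]
print("all tied (chance):", partial_auc(all_tied, positives))

# 1.0 means every reference gene precedes every non-reference gene;
# 0.025 is the chance line: with no information, early retrieval is the
# diagonal ROC segment integrated to FPR = 0.05 and normalized by 0.05.
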