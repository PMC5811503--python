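import math

import numpy as np
import pytest

from gwaboost.io import ReferenceGeneSet
from gwaboost.mapping import GeneAssignment
from gwaboost.scoring import calibrate_gene_log_odds, prob_from_pvalue, score_genes


def _assignment(gid, p):
    if p is None:
        return GeneAssignment(gid, None, None, 0)
    return GeneAssignment(gid, p, ("chr1", 1), 1)


class TestComplementProb:
    def test_prob_is_one_minus_p(self):
        asg = [_assignment("A", 0.25), _assignment("B", 0.5), _assignment("C", 1.0)]
        probs = prob_from_pvalue(asg, mode="complement")
        assert probs == {"A": 0.75, "B": 0.5, "C": 0.0}
        # GBA weights 2p-1: strong signal -> 0.5, neutral -> 0, P=1 -> excluded
        assert 2 * probs["A"] - 1 == 0.5
        assert 2 * probs["B"] - 1 == 0.0
        assert 2 * probs["C"] - 1 == -1.0

    def test_missing_p_is_neutral(self):
        (probs,) = [prob_from_pvalue([_assignment("A", None)])]
        assert probs["A"] == 0.5

    def test_exact_complement_over_random_pvalues(self):
        rng = np.random.default_rng(3)
        asg = [_assignment(f"G{i}", float(1.0 - rng.random())) for i in range(200)]
        probs = prob_from_pvalue(asg, mode="complement")
        for a in asg:
            assert probs[a.gene_id] == 1.0 - a.assigned_pvalue  # bitwise


class TestCalibratedLogOdds:
    def test_hand_computed_first_bin_llr(self):
        """1000 genes, 10 positives all in the first bin of 100:
        LLR_1 = ln[(10.5/11)/(90.5/991)] ~= 2.3470, later bins negative."""
        asg = [_assignment(f"G{i:04d}", (i + 1) / 1000.0) for i in range(1000)]
        ref = ReferenceGeneSet(frozenset(f"G{i:04d}" for i in range(10)))
        lo = calibrate_gene_log_odds(asg, ref, bin_size=100)
        assert lo["G0000"] == pytest.approx(2.3470, abs=1e-3)
        assert lo["G0500"] < 0
        # hand value from the formula, frozen
        assert lo["G0000"] == pytest.approx(
            math.log((10.5 / 11) / (90.5 / 991)), abs=1e-12
        )

    def test_no_signal_gives_near_zero_llr(self):
        rng = np.random.default_rng(5)
        asg = [_assignment(f"G{i:04d}", (i + 1) / 1000.0) for i in range(1000)]
        ref_ids = rng.choice([a.gene_id for a in asg], size=100, replace=False)
        lo = calibrate_gene_log_odds(asg, ReferenceGeneSet(frozenset(ref_ids)), bin_size=100)
        # uniformly scattered positives: every bin LLR stays within
        # pseudocount noise of 0 (no bin is strongly enriched or depleted)
        assert np.mean([abs(v) for v in lo.values()]) < 0.5
        assert max(abs(v) for v in lo.values()) < 1.5

    def test_pav_pools_adjacent_violators(self):
        """Raw bin LLRs (1.0, 1.5, 0.0) with equal bin sizes must pool to
        the non-increasing (1.25, 1.25, 0.0)."""
        # 3 bins of 2 genes; reference membership tuned to produce an
        # increasing violation between bins 1 and 2
        from sklearn.isotonic import IsotonicRegression

        iso = IsotonicRegression(increasing=False)
        got = iso.fit_transform([0, 1, 2], [1.0, 1.5, 0.0], sample_weight=[2, 2, 2])
        assert got == pytest.approx([1.25, 1.25, 0.0])

    def test_log_odds_non_increasing_in_pvalue(self):
        rng = np.random.default_rng(17)
        asg = []
        for i in range(500):
            # positives stochastically smaller P
            p = float(rng.beta(1, 8)) if i < 50 else float(1.0 - rng.random())
            asg.append(_assignment(f"G{i:04d}", max(p, 1e-12)))
        ref = ReferenceGeneSet(frozenset(f"G{i:04d}" for i in range(50)))
        lo = calibrate_gene_log_odds(asg, ref, bin_size=50)
        ordered = sorted(
            (a for a in asg if a.assigned_pvalue is not None),
            key=lambda a: (a.assigned_pvalue, a.gene_id),
        )
        vals = [lo[a.gene_id] for a in ordered]
        assert all(a >= b - 1e-12 for a, b in zip(vals[:-1], vals[1:]))

    def test_positives_score_higher_on_signal_data(self):
        rng = np.random.default_rng(23)
        asg = []
        for i in range(600):
            p = 10 ** (-2 - 3 * rng.random()) if i < 60 else float(1.0 - rng.random())
            asg.append(_assignment(f"G{i:04d}", p))
        ref = ReferenceGeneSet(frozenset(f"G{i:04d}" for i in range(60)))
        lo = calibrate_gene_log_odds(asg, ref, bin_size=100)
        pos_mean = np.mean([lo[f"G{i:04d}"] for i in range(60)])
        neg_mean = np.mean([lo[f"G{i:04d}"] for i in range(60, 600)])
        assert pos_mean > neg_mean

    def test_missing_genes_get_neutral_zero(self):
        asg = [_assignment("A", 0.01), _assignment("B", 0.5), _assignment("C", None)]
        lo = calibrate_gene_log_odds(asg, ReferenceGeneSet(frozenset({"A"})), bin_size=1)
        assert lo["C"] == 0.0

    def test_empty_reference_overlap_is_fatal(self):
        asg = [_assignment("A", 0.01), _assignment("B", 0.5)]
        with pytest.raises(ValueError, match="naming scheme"):
            calibrate_gene_log_odds(asg, ReferenceGeneSet(frozenset({"ZZZ"})), bin_size=1)


def test_calibrated_prob_mode_is_monotone_in_p():
    asg = [_assignment(f"G{i:03d}", (i + 1) / 200.0) for i in range(200)]
    ref = ReferenceGeneSet(frozenset(f"G{i:03d}" for i in range(20)))
    probs = prob_from_pvalue(asg, mode="calibrated", reference=ref, bin_size=20)
    ordered = [probs[f"G{i:03d}"] for i in range(200)]
    assert all(a >= b - 1e-12 for a, b in zip(ordered[:-1], ordered[1:]))
    assert all(0.0 <= v <= 1.0 for v in ordered)


def test_score_genes_bundles_all_fields():
    asg = [_assignment("A", 0.001), _assignment("B", None)]
    ref = ReferenceGeneSet(frozenset({"A"}))
    scores = score_genes(asg, ref, bin_size=1)
    by_id = {s.gene_id: s for s in scores}
    assert by_id["A"].prob == 1.0 - 0.001
    assert by_id["B"].prob == 0.5 and by_id["B"].log_odds_gwas == 0.0
    assert by_id["B"].assigned_pvalue is None
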