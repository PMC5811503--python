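import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gwaboost.evaluation import build_grid, partial_auc, run_scan
from gwaboost.io import ReferenceGeneSet
from gwaboost.scoring import GeneGwasScore

from oracles import brute_force_pauc, random_weighted_network


def _ranking(scores):
    return [(f"G{i}", s) for i, s in enumerate(scores)]


class TestPartialAuc:
    def test_perfect_ranking_scores_one(self):
        pairs = _ranking([10, 9, 8] + [float(x) for x in range(5, 0, -1)])
        positives = {"G0", "G1", "G2"}
        assert partial_auc(pairs, positives) == pytest.approx(1.0)

    def test_worst_ranking_scores_zero(self):
        # 3 positives below 40 negatives: >5% of negatives above every positive
        pairs = _ranking([float(43 - i) for i in range(43)])
        positives = {"G40", "G41", "G42"}
        assert partial_auc(pairs, positives) == 0.0

    def test_all_tied_gives_chance_value(self):
        """A single diagonal block: area 0.05^2/2 over [0, 0.05], normalized
        by 0.05 -> exactly 0.025."""
        pairs = _ranking([1.0] * 200)
        positives = {f"G{i}" for i in range(0, 200, 10)}
        assert partial_auc(pairs, positives) == pytest.approx(0.025, abs=1e-15)

    def test_fixed_small_instance_against_enumeration(self):
        # 10 genes, positives at ranks 1, 4, 9 (descending scores)
        scores = [10.0 - i for i in range(10)]
        positives = {"G0", "G3", "G8"}
        pairs = _ranking(scores)
        expected = brute_force_pauc([g for g, _ in pairs], scores, positives)
        assert partial_auc(pairs, positives) == pytest.approx(expected, abs=1e-15)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(10, 200),
        n_pos=st.integers(1, 8),
        n_levels=st.integers(1, 12),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_with_ties(self, n, n_pos, n_levels, seed):
        rng = np.random.default_rng(seed)
        scores = [float(x) for x in rng.integers(0, n_levels, size=n)]  # ties injected
        genes = [f"G{i}" for i in range(n)]
        positives = set(rng.choice(genes, size=min(n_pos, n - 1), replace=False))
        got = partial_auc(list(zip(genes, scores)), positives)
        assert got == pytest.approx(brute_force_pauc(genes, scores, positives), abs=1e-12)
        assert 0.0 <= got <= 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(31)
        scores = rng.standard_normal(150)
        genes = [f"G{i}" for i in range(150)]
        positives = set(rng.choice(genes, 12, replace=False))
        base = partial_auc(list(zip(genes, scores)), positives)
        warped = np.exp(3.0 * scores) + 7.0  # strictly increasing map
        assert partial_auc(list(zip(genes, warped)), positives) == pytest.approx(base, abs=1e-12)

    def test_accepts_reference_gene_set_and_boost_results(self):
        from gwaboost.boosting import BoostResult

        results = [
            BoostResult("A", 0.0, 2.0, 2.0, False),
            BoostResult("B", 0.0, 1.0, 1.0, False),
            *[BoostResult(f"N{i}", 0.0, -float(i), -float(i), False) for i in range(40)],
        ]
        ref = ReferenceGeneSet(frozenset({"A", "B"}))
        assert partial_auc(results, ref) == pytest.approx(1.0)

    def test_no_positives_is_fatal_with_diagnostic(self):
        with pytest.raises(ValueError, match="naming scheme"):
            partial_auc(_ranking([1.0, 2.0]), {"ZZZ"})

    def test_cross_check_against_sklearn_roc(self):
        """Independent route: sklearn's ROC vertices + trapezoid truncation."""
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(41)
        scores = rng.standard_normal(300)
        y = rng.random(300) < 0.1
        if not y.any():
            y[0] = True
        fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
        cut = 0.05
        area = float(np.trapezoid(np.interp(np.linspace(0, cut, 20001), fpr, tpr),
                                  np.linspace(0, cut, 20001)))
        genes = [f"G{i}" for i in range(300)]
        positives = {g for g, yy in zip(genes, y) if yy}
        got = partial_auc(list(zip(genes, scores)), positives, fpr_max=cut)
        assert got == pytest.approx(area / cut, abs=1e-4)


class TestBuildGrid:
    def test_default_grid_is_the_14_point_progression(self):
        grid = build_grid()
        assert len(grid) == 14
        assert grid[0] == -6.0 and grid[-1] == -2.1
        assert np.allclose(np.diff(grid), 0.3)

    def test_lo_equals_hi_minus_step_gives_single_point(self):
        assert build_grid(-3.3, -3.0, 0.3) == [-3.3]

    def test_step_larger_than_range_gives_single_point(self):
        assert build_grid(-5.0, -4.0, 2.0) == [-5.0]

    def test_invalid_bounds_are_fatal(self):
        with pytest.raises(ValueError):
            build_grid(-2.0, -6.0, 0.3)
        with pytest.raises(ValueError):
            build_grid(-6.0, -2.0, 0.0)


def _neutral_scores(net, rng, reference):
    """Scores with p_j = 0.5 everywhere and flat log odds."""
    return [
        GeneGwasScore(g, 0.5, 0.0, 0.5)
        for g in net.nodes
    ]


class TestRunScan:
    def test_no_signal_case_not_significant(self):
        rng = np.random.default_rng(51)
        net = random_weighted_network(rng, n_max=150)
        scores = _neutral_scores(net, rng, None)
        ref = ReferenceGeneSet(frozenset(rng.choice(net.nodes, 10, replace=False)))
        scan = run_scan(net, scores, ref, n_random=30, seed=5)
        # p_j = 0.5 everywhere: GBA sums vanish, real == null at every threshold
        assert all(a == pytest.approx(m, abs=1e-12) for a, m in
                   zip(scan.auc_real, scan.auc_random_mean))
        assert not any(scan.significant)

    def test_n_random_zero_skips_null(self):
        rng = np.random.default_rng(53)
        net = random_weighted_network(rng, n_max=100)
        scores = _neutral_scores(net, rng, None)
        ref = ReferenceGeneSet(frozenset(rng.choice(net.nodes, 8, replace=False)))
        scan = run_scan(net, scores, ref, n_random=0, seed=None)
        assert all(s is None for s in scan.significant)
        assert all(np.isnan(m) for m in scan.auc_random_mean)
        assert scan.optimal_threshold in scan.grid

    def test_seed_required_with_nonzero_n_random(self):
        rng = np.random.default_rng(55)
        net = random_weighted_network(rng, n_max=50)
        scores = _neutral_scores(net, rng, None)
        ref = ReferenceGeneSet(frozenset(net.nodes[:5]))
        with pytest.raises(ValueError, match="seed"):
            run_scan(net, scores, ref, n_random=10, seed=None)

    def test_bit_reproducible_for_fixed_master_seed(self, small_instance):
        from gwaboost.mapping import assign_snps_to_genes
        from gwaboost.scoring import score_genes

        net, genes, snps, ref, _ = small_instance
        asg = assign_snps_to_genes(snps, genes, 10_000)
        scores = score_genes(asg, ref)
        a = run_scan(net, scores, ref, n_random=20, seed=77)
        b = run_scan(net, scores, ref, n_random=20, seed=77)
        assert a.auc_real == b.auc_real
        assert a.auc_random_mean == b.auc_random_mean
        assert a.auc_random_sd == b.auc_random_sd
        assert a.optimal_threshold == b.optimal_threshold
        assert a.final_ranking == b.final_ranking

    def test_optimal_threshold_is_grid_argmax(self, small_instance):
        from gwaboost.mapping import assign_snps_to_genes
        from gwaboost.scoring import score_genes

        net, genes, snps, ref, _ = small_instance
        asg = assign_snps_to_genes(snps, genes, 10_000)
        scores = score_genes(asg, ref)
        scan = run_scan(net, scores, ref, n_random=5, seed=3)
        i = scan.optimal_index
        assert scan.auc_real[i] == max(scan.auc_real)
        assert all(scan.auc_real[j] < scan.auc_real[i] for j in range(i))  # earliest on ties
        assert all(0.0 <= a <= 1.0 for a in scan.auc_real)

    def test_final_ranking_matches_single_boost_at_optimum(self, small_instance):
        from gwaboost.boosting import boost
        from gwaboost.mapping import assign_snps_to_genes
        from gwaboost.scoring import score_genes

        net, genes, snps, ref, _ = small_instance
        asg = assign_snps_to_genes(snps, genes, 10_000)
        scores = score_genes(asg, ref)
        scan = run_scan(net, scores, ref, n_random=0)
        direct = {r.gene_id: r.final_score for r in boost(net, scores, scan.optimal_threshold)}
        for r in scan.final_ranking:
            if r.gene_id in direct:
                assert r.final_score == pytest.approx(direct[r.gene_id], abs=1e-12)
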