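import itertools
import math

import numpy as np
import pytest

from crepipe.causal import (AMBIGUOUS, CREFilterConfig, Hypothesis,
                            apply_cre_filters, compute_predictions,
                            correctness_pvalue, enrichment_pvalue,
                            rank_hypotheses, run_cre, score_hypothesis)
from crepipe.io import CausalGraph

from conftest import make_signature


class TestComputePredictions:
    def test_sign_product_positive(self, toy_graph):
        pred = compute_predictions(toy_graph, "R", +1)
        assert pred.predicted["G1"] == +1
        assert pred.predicted["G3"] == -1

    def test_double_negative_is_positive(self):
        g = CausalGraph()
        g.add_edge("R", "g", -1)
        pred = compute_predictions(g, "R", -1)
        assert pred.predicted["G"] == +1

    def test_conflicting_paths_are_ambiguous(self):
        g = CausalGraph()
        g.add_edge("R", "g", +1)
        g.add_edge("R", "m", +1)
        g.add_edge("m", "g", -1)
        pred = compute_predictions(g, "R", +1, max_depth=2)
        assert pred.predicted["G"] == AMBIGUOUS
        assert pred.predicted["M"] == +1

    def test_depth_one_ignores_indirect_paths(self):
        g = CausalGraph()
        g.add_edge("R", "m", +1)
        g.add_edge("m", "g", -1)
        pred = compute_predictions(g, "R", +1, max_depth=1)
        assert "G" not in pred.predicted

    def test_hypothesis_node_excluded(self):
        g = CausalGraph()
        g.add_edge("R", "g", +1)
        g.add_edge("g", "R", +1)
        pred = compute_predictions(g, "R", +1, max_depth=2)
        assert "R" not in pred.predicted

    def test_absent_node_errors(self, toy_graph):
        with pytest.raises(KeyError):
            compute_predictions(toy_graph, "nope", +1)


class TestScoreHypothesis:
    def test_direct_count(self, toy_graph):
        pred = compute_predictions(toy_graph, "R", +1)
        sig = make_signature({"G1": 1, "G2": -1, "G3": -1, "OTHER": 1})
        h = score_hypothesis(pred, sig)
        assert (h.n_correct, h.n_incorrect) == (2, 1)
        assert h.score == 1
        assert h.percent_correct == pytest.approx(2 / 3)

    def test_no_overlap(self, toy_graph):
        pred = compute_predictions(toy_graph, "R", +1)
        h = score_hypothesis(pred, make_signature({"ZZ": 1}))
        assert h.score == 0 and h.percent_correct is None

    def test_ambiguous_excluded_from_score(self):
        g = CausalGraph()
        g.add_edge("R", "g", +1)
        g.add_edge("R", "g", -1)
        pred = compute_predictions(g, "R", +1)
        h = score_hypothesis(pred, make_signature({"G": 1}))
        assert (h.n_correct, h.n_incorrect, h.n_ambiguous) == (0, 0, 1)

    def test_brute_force_recount(self, rng):
        genes = [f"G{i}" for i in range(30)]
        for _ in range(200):
            pred_signs = {g: int(s) for g, s in
                          zip(genes, rng.choice([-1, 0, 1], size=30))}
            sig_genes = rng.choice(genes, size=int(rng.integers(0, 20)),
                                   replace=False)
            sig = make_signature({g: int(rng.choice([-1, 1]))
                                  for g in sig_genes}) if len(sig_genes) else \
                make_signature({"DUMMY": 1})
            from crepipe.causal import HypothesisPrediction
            h = score_hypothesis(
                HypothesisPrediction("R", +1, dict(pred_signs), 1), sig)
            nc = sum(1 for g, s in pred_signs.items()
                     if s != 0 and sig.direction.get(g) == s)
            ni = sum(1 for g, s in pred_signs.items()
                     if s != 0 and sig.direction.get(g) == -s)
            assert (h.n_correct, h.n_incorrect) == (nc, ni)
            assert h.score == nc - ni

    def test_opposite_direction_swaps_counts(self, rng):
        g = CausalGraph()
        genes = [f"G{i}" for i in range(15)]
        for gene in genes:
            g.add_edge("R", gene, int(rng.choice([-1, 1])))
        sig = make_signature({gene: int(rng.choice([-1, 1]))
                              for gene in genes})
        h_plus = score_hypothesis(compute_predictions(g, "R", +1), sig)
        h_minus = score_hypothesis(compute_predictions(g, "R", -1), sig)
        assert h_plus.n_correct == h_minus.n_incorrect
        assert h_plus.n_incorrect == h_minus.n_correct
        assert h_plus.score == -h_minus.score
        assert h_plus.n_ambiguous == h_minus.n_ambiguous


class TestEnrichmentPvalue:
    def universe(self, n=20):
        return {f"G{i}" for i in range(n)}

    def test_zero_overlap(self):
        g = CausalGraph()
        g.add_edge("R", "G0", +1)
        pred = compute_predictions(g, "R", +1)
        sig = make_signature({"G5": 1})
        assert enrichment_pvalue(pred, sig, self.universe()) == pytest.approx(1.0)

    def test_perfect_overlap_small_universe(self):
        g = CausalGraph()
        for i in range(5):
            g.add_edge("R", f"G{i}", +1)
        pred = compute_predictions(g, "R", +1)
        sig = make_signature({f"G{i}": 1 for i in range(5)})
        p = enrichment_pvalue(pred, sig, self.universe())
        assert p == pytest.approx(1 / 15504, rel=1e-12)

    def test_predictions_equal_universe(self):
        g = CausalGraph()
        for i in range(5):
            g.add_edge("R", f"G{i}", +1)
        pred = compute_predictions(g, "R", +1)
        sig = make_signature({"G0": 1, "G1": -1})
        assert enrichment_pvalue(pred, sig, {f"G{i}" for i in range(5)}) \
            == pytest.approx(1.0)


def enumerate_correctness_p(pred_signs: list[int], n_correct: int,
                            q_up: float) -> float:
    """Exhaust all 2^n observed sign assignments of the scored overlap."""
    n = len(pred_signs)
    total = 0.0
    for obs in itertools.product([+1, -1], repeat=n):
        prob = 1.0
        for o in obs:
            prob *= q_up if o > 0 else (1 - q_up)
        correct = sum(1 for s, o in zip(pred_signs, obs) if s == o)
        if correct >= n_correct:
            total += prob
    return total


class TestCorrectnessPvalue:
    def make_case(self, pred_signs, obs_signs):
        from crepipe.causal import HypothesisPrediction
        genes = [f"G{i}" for i in range(len(pred_signs))]
        pred = HypothesisPrediction(
            "R", +1, {g: s for g, s in zip(genes, pred_signs)}, 1)
        sig = make_signature({g: o for g, o in zip(genes, obs_signs)})
        h = score_hypothesis(pred, sig)
        return h, pred, sig

    def test_all_correct_balanced_null(self):
        # 5 predicted-up transcripts all observed up; half the signature is
        # up overall, so the null chance of 5/5 is 2^-5
        from crepipe.causal import HypothesisPrediction
        pred = HypothesisPrediction(
            "R", +1, {f"G{i}": +1 for i in range(5)}, 1)
        obs = {f"G{i}": +1 for i in range(5)}
        obs.update({f"H{i}": -1 for i in range(5)})
        sig = make_signature(obs)
        h = score_hypothesis(pred, sig)
        p = correctness_pvalue(h, pred, sig, method="exact")
        assert p == pytest.approx(0.03125, abs=1e-12)

    def test_no_evidence_gives_p_one(self):
        h, pred, sig = self.make_case([], [])
        sig = make_signature({"ZZ": 1})
        assert correctness_pvalue(h, pred, sig) == 1.0

    def test_exact_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 11))
            pred_signs = [int(s) for s in rng.choice([-1, 1], size=n)]
            obs_signs = [int(s) for s in rng.choice([-1, 1], size=n)]
            h, pred, sig = self.make_case(pred_signs, obs_signs)
            q_up = sum(1 for d in sig.direction.values() if d > 0) / len(sig)
            p = correctness_pvalue(h, pred, sig, method="exact")
            expected = enumerate_correctness_p(pred_signs, h.n_correct, q_up)
            assert p == pytest.approx(expected, abs=1e-10)

    def test_permutation_agrees_with_exact(self, rng):
        n_perm = 100_000
        for trial in range(5):
            n = int(rng.integers(3, 12))
            pred_signs = [int(s) for s in rng.choice([-1, 1], size=n)]
            obs_signs = [int(s) for s in rng.choice([-1, 1], size=n)]
            h, pred, sig = self.make_case(pred_signs, obs_signs)
            p_exact = correctness_pvalue(h, pred, sig, method="exact")
            p_perm = correctness_pvalue(h, pred, sig, method="permutation",
                                        n_perm=n_perm, seed=trial)
            tol = 3 * math.sqrt(max(p_exact * (1 - p_exact), 1e-6) / n_perm) \
                + 2 / n_perm
            assert abs(p_perm - p_exact) <= tol

    def test_null_super_uniform(self, rng):
        # random observed directions: P(p <= a) should not exceed a (+3 SE)
        trials = 500
        pvals = []
        for _ in range(trials):
            n = 10
            pred_signs = [int(s) for s in rng.choice([-1, 1], size=n)]
            obs_signs = [int(s) for s in rng.choice([-1, 1], size=n)]
            h, pred, sig = self.make_case(pred_signs, obs_signs)
            pvals.append(correctness_pvalue(h, pred, sig, method="exact"))
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.1):
            se = math.sqrt(alpha * (1 - alpha) / trials)
            assert (pvals <= alpha).mean() <= alpha + 3 * se


class TestRankAndFilter:
    def hyp(self, node, score_pair, p_enrich=0.01, p_correct=0.01):
        nc, ni = score_pair
        return Hypothesis(node, +1, nc, ni, 0, p_enrich, p_correct)

    def test_tie_break_by_enrichment_p(self):
        hs = [self.hyp("a", (5, 0)), self.hyp("b", (3, 0), p_enrich=0.02),
              self.hyp("c", (3, 0), p_enrich=0.01)]
        ranked = rank_hypotheses(hs)
        assert [h.node for h in ranked] == ["a", "c", "b"]
        assert [h.rank for h in ranked] == [1, 2, 3]

    def test_single_hypothesis_rank_one(self):
        assert rank_hypotheses([self.hyp("a", (1, 0))])[0].rank == 1

    def test_input_order_irrelevant(self, rng):
        hs = [self.hyp(f"n{i}", (int(rng.integers(0, 6)), 0),
                       float(rng.uniform()), float(rng.uniform()))
              for i in range(10)]
        ranked1 = [(h.node, h.rank) for h in rank_hypotheses(list(hs))]
        rng.shuffle(hs)
        ranked2 = [(h.node, h.rank) for h in rank_hypotheses(list(hs))]
        assert sorted(ranked1) == sorted(ranked2)

    def test_min_correct_boundary(self):
        h = self.hyp("a", (2, 0))
        h.rank = 1
        assert apply_cre_filters([h]) == []
        h2 = self.hyp("b", (3, 0))
        h2.rank = 1
        assert apply_cre_filters([h2]) == [h2]

    def test_percent_correct_boundary(self):
        h = self.hyp("a", (59, 41))  # 59%
        h.rank = 1
        assert apply_cre_filters([h]) == []
        h2 = self.hyp("b", (60, 40))  # exactly 60%
        h2.rank = 1
        assert apply_cre_filters([h2]) == [h2]

    def test_rank_cutoff_strict(self):
        h = self.hyp("a", (10, 0))
        h.rank = 100
        assert apply_cre_filters([h]) == []


class TestRunCre:
    def test_planted_direction_recovered(self):
        g = CausalGraph()
        for i in range(5):
            g.add_edge("R", f"G{i}", +1)
        # all 5 targets observed down, in a balanced signature (q-hat = 1/2,
        # so the null chance of 5/5 correct is 2^-5 < 0.05)
        obs = {f"G{i}": -1 for i in range(5)}
        obs.update({f"H{i}": 1 for i in range(5)})
        sig = make_signature(obs)
        universe = set(obs) | {f"U{i}" for i in range(40)}
        ranked, kept = run_cre(g, sig, universe)
        labels = [h.label for h in kept]
        assert "R (-)" in labels and "R (+)" not in labels

    def test_empty_signature_empty_output(self, toy_graph):
        ranked, kept = run_cre(toy_graph, make_signature({}), {"G1"})
        assert ranked == [] and kept == []

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            run_cre(CausalGraph(), make_signature({"G1": 1}), {"G1"})

    def test_rerun_deterministic(self, toy_graph):
        sig = make_signature({"G1": 1, "G2": -1, "G3": -1, "G4": 1})
        uni = {f"G{i}" for i in range(1, 10)}
        out1 = run_cre(toy_graph, sig, uni, seed=3)
        out2 = run_cre(toy_graph, sig, uni, seed=3)
        assert [(h.label, h.rank, h.p_correct) for h in out1[0]] == \
            [(h.label, h.rank, h.p_correct) for h in out2[0]]
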