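"""Causal reasoning engine: upstream-hypothesis inference over a signed graph.

A hypothesis is a (node, direction) pair proposed as the upstream cause of
an observed differential-expression signature.  The hypothesis predicts the
sign of every transcript reachable along signed edges (the product of edge
signs times the hypothesis direction); transcripts reachable with
conflicting sign products are marked ambiguous and carry no direction
evidence.  Against a signature the engine counts correctly and incorrectly
explained transcripts, scores the hypothesis as their difference, and
attaches two p-values:

* an enrichment p-value — the hypergeometric upper tail for the overlap of
  the hypothesis's possible transcripts with the signature (signs ignored);
* a correctness p-value — the probability, under a null in which each
  overlapping transcript is independently up with the signature's empirical
  up-fraction q, of a score at least as large as observed.

Hypotheses are ranked (score desc, then enrichment p, correctness p, name)
and filtered with the standard cutoffs: correctness p < 0.05, enrichment
p < 0.05, n_correct >= 3, percent correct >= 60%, rank < 100.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import DESignature
from .io import CausalGraph, canon

__all__ = [
    "HypothesisPrediction",
    "Hypothesis",
    "CREFilterConfig",
    "compute_predictions",
    "score_hypothesis",
    "enrichment_pvalue",
    "correctness_pvalue",
    "rank_hypotheses",
    "apply_cre_filters",
    "run_cre",
    "hypotheses_frame",
]

log = logging.getLogger(__name__)

AMBIGUOUS = 0  # sentinel sign for conflicting path products


@dataclass
class HypothesisPrediction:
    """Predicted transcript signs for one (node, direction) hypothesis."""

    node: str
    direction: int
    predicted: dict[str, int]  # canonical transcript -> +1 / -1 / AMBIGUOUS
    max_depth: int

    def unambiguous(self) -> dict[str, int]:
        return {t: s for t, s in self.predicted.items() if s != AMBIGUOUS}


@dataclass
class Hypothesis:
    """A scored upstream explanation of a signature."""

    node: str
    direction: int
    n_correct: int
    n_incorrect: int
    n_ambiguous: int
    p_enrich: float = float("nan")
    p_correct: float = float("nan")
    rank: int = 0

    @property
    def score(self) -> int:
        return self.n_correct - self.n_incorrect

    @property
    def percent_correct(self) -> float | None:
        n = self.n_correct + self.n_incorrect
        return self.n_correct / n if n else None

    @property
    def label(self) -> str:
        return f"{self.node} ({'+' if self.direction > 0 else '-'})"


@dataclass(frozen=True)
class CREFilterConfig:
    """Hypothesis-acceptance cutoffs (defaults are the standard ones)."""

    max_p_correct: float = 0.05
    max_p_enrich: float = 0.05
    min_correct: int = 3
    min_percent_correct: float = 0.60
    max_rank: int = 100

    def __post_init__(self) -> None:
        if min(self.max_p_correct, self.max_p_enrich,
               self.min_percent_correct) <= 0 or self.min_correct < 0 \
                or self.max_rank < 1:
            raise ValueError("filter thresholds must be positive")


# ---------------------------------------------------------------------------
# prediction and scoring
# ---------------------------------------------------------------------------

def compute_predictions(graph: CausalGraph, node: str, direction: int,
                        max_depth: int = 1) -> HypothesisPrediction:
    """Propagate the hypothesis sign along edges up to ``max_depth``.

    A transcript's predicted sign is direction x (product of edge signs)
    along each path of length <= max_depth; conflicting products across
    paths yield the ambiguous mark.  The hypothesis node itself is excluded.
    """
    if node not in graph:
        raise KeyError(f"node {node!r} not in causal graph")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    # BFS over (node, accumulated sign); track every sign a node is reached with
    reached: dict[str, set[int]] = {}
    frontier: list[tuple[str, int]] = [(node, direction)]
    for _ in range(max_depth):
        nxt: list[tuple[str, int]] = []
        for src, acc in frontier:
            for tgt, sign in graph.out_edges(src):
                prod = acc * sign
                signs = reached.setdefault(tgt, set())
                if prod not in signs:
                    signs.add(prod)
                    nxt.append((tgt, prod))
        frontier = nxt
        if not frontier:
            break
    reached.pop(node, None)
    predicted = {canon(t): (next(iter(s)) if len(s) == 1 else AMBIGUOUS)
                 for t, s in reached.items()}
    return HypothesisPrediction(node, direction, predicted, max_depth)


def score_hypothesis(prediction: HypothesisPrediction,
                     signature: DESignature) -> Hypothesis:
    """Count correctly/incorrectly explained signature genes.

    Only transcripts both unambiguously predicted and present in the
    signature contribute; ambiguous predictions overlapping the signature
    are tallied in n_ambiguous.
    """
    n_correct = n_incorrect = n_ambiguous = 0
    for transcript, pred in prediction.predicted.items():
        obs = signature.direction.get(transcript)
        if obs is None:
            continue
        if pred == AMBIGUOUS:
            n_ambiguous += 1
        elif pred == obs:
            n_correct += 1
        else:
            n_incorrect += 1
    return Hypothesis(prediction.node, prediction.direction,
                      n_correct, n_incorrect, n_ambiguous)


def enrichment_pvalue(prediction: HypothesisPrediction,
                      signature: DESignature, universe: set[str]) -> float:
    """Hypergeometric upper-tail p for the prediction/signature overlap.

    All possible transcripts (including ambiguous) count toward the
    hypothesis's draw size; the overlap numerator uses only unambiguously
    predicted transcripts, which carry the direction evidence.
    """
    uni = {canon(g) for g in universe}
    preds_all = {t for t in prediction.predicted} & uni
    sig = {g for g in signature.direction} & uni
    if len(signature.direction) and not set(signature.direction) <= uni:
        raise ValueError("signature genes must lie inside the universe")
    N = len(uni)
    if N == 0 or N < max(len(preds_all), len(sig)):
        raise ValueError("universe smaller than predictions or signature")
    K = len(preds_all)
    n = len(sig)
    k = len({t for t, s in prediction.predicted.items() if s != AMBIGUOUS}
            & sig)
    if K == 0 or n == 0:
        return 1.0
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


def correctness_pvalue(hypothesis: Hypothesis, prediction: HypothesisPrediction,
                       signature: DESignature, method: str = "exact",
                       n_perm: int = 10_000,
                       seed: int | None = None) -> float:
    """P(null score >= observed score) for direction concordance.

    Null model: each of the n = n_correct + n_incorrect overlapping
    transcripts is independently observed up with probability q (the
    signature's empirical up-fraction), else down.  A transcript predicted
    up is then correct with probability q, one predicted down with 1 - q,
    so the null number of correct calls is the sum of two binomials.
    ``exact`` convolves them; ``permutation`` simulates with the given seed.
    """
    if method not in ("exact", "permutation"):
        raise ValueError("method must be 'exact' or 'permutation'")
    n = hypothesis.n_correct + hypothesis.n_incorrect
    if n == 0:
        log.info("correctness_pvalue: no direction evidence for %s, p = 1",
                 hypothesis.label)
        return 1.0
    n_sig = len(signature.direction)
    q_up = (sum(1 for d in signature.direction.values() if d > 0) / n_sig
            if n_sig else 0.5)
    # split the scored overlap by predicted direction
    preds = prediction.unambiguous()
    n_up_pred = sum(1 for t, s in preds.items()
                    if t in signature.direction and s > 0)
    n_down_pred = n - n_up_pred
    if method == "exact":
        pmf_up = stats.binom.pmf(np.arange(n_up_pred + 1), n_up_pred, q_up)
        pmf_down = stats.binom.pmf(np.arange(n_down_pred + 1), n_down_pred,
                                   1.0 - q_up)
        pmf = np.convolve(pmf_up, pmf_down)  # null #correct in 0..n
        p = float(pmf[hypothesis.n_correct:].sum())
        return min(max(p, 0.0), 1.0)
    rng = np.random.default_rng(seed)
    null_correct = (rng.binomial(n_up_pred, q_up, size=n_perm)
                    + rng.binomial(n_down_pred, 1.0 - q_up, size=n_perm))
    exceed = int((null_correct >= hypothesis.n_correct).sum())
    return (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# ranking, filtering, driver
# ---------------------------------------------------------------------------

def rank_hypotheses(hypotheses: list[Hypothesis]) -> list[Hypothesis]:
    """Assign deterministic 1-based ranks.

    Sort by score descending, then enrichment p, correctness p, node name
    and direction; input order never matters.
    """
    ordered = sorted(hypotheses,
                     key=lambda h: (-h.score, h.p_enrich, h.p_correct,
                                    h.node, -h.direction))
    for i, h in enumerate(ordered, 1):
        h.rank = i
    return ordered


def apply_cre_filters(hypotheses: list[Hypothesis],
                      config: CREFilterConfig | None = None) -> list[Hypothesis]:
    """Keep hypotheses passing every cutoff (bounds exactly as stated)."""
    cfg = config or CREFilterConfig()
    kept = []
    for h in hypotheses:
        pc = h.percent_correct
        if (h.p_correct < cfg.max_p_correct
                and h.p_enrich < cfg.max_p_enrich
                and h.n_correct >= cfg.min_correct
                and pc is not None and pc >= cfg.min_percent_correct
                and h.rank < cfg.max_rank):
            kept.append(h)
    return kept


def run_cre(graph: CausalGraph, signature: DESignature, universe: set[str],
            config: CREFilterConfig | None = None, max_depth: int = 1,
            seed: int | None = None, method: str = "exact",
            n_perm: int = 10_000) -> tuple[list[Hypothesis], list[Hypothesis]]:
    """Evaluate both directions of every regulator against a signature.

    Returns (all ranked hypotheses, the filtered survivors).  Deterministic
    given the seed (the seed only matters for the permutation method).
    """
    if not graph.nodes:
        raise ValueError("causal graph is empty")
    if not signature.direction:
        return [], []
    hypotheses: list[Hypothesis] = []
    for i, node in enumerate(graph.regulators()):
        for direction in (+1, -1):
            pred = compute_predictions(graph, node, direction, max_depth)
            h = score_hypothesis(pred, signature)
            h.p_enrich = enrichment_pvalue(pred, signature, universe)
            n = h.n_correct + h.n_incorrect
            use = method if (method == "permutation" or n <= 1000) else "permutation"
            h.p_correct = correctness_pvalue(
                h, pred, signature, method=use, n_perm=n_perm,
                seed=None if seed is None else seed + 7919 * i + (direction > 0))
            hypotheses.append(h)
    ranked = rank_hypotheses(hypotheses)
    return ranked, apply_cre_filters(ranked, config)


def hypotheses_frame(hypotheses: list[Hypothesis],
                     config: CREFilterConfig | None = None) -> pd.DataFrame:
    """Tabulate hypotheses with per-filter pass flags for export."""
    cfg = config or CREFilterConfig()
    rows = []
    for h in hypotheses:
        pc = h.percent_correct
        rows.append({
            "node": h.node,
            "direction": "+" if h.direction > 0 else "-",
            "n_correct": h.n_correct, "n_incorrect": h.n_incorrect,
            "n_ambiguous": h.n_ambiguous, "score": h.score,
            "percent_correct": math.nan if pc is None else pc,
            "p_enrich": h.p_enrich, "p_correct": h.p_correct, "rank": h.rank,
            "pass_p_correct": h.p_correct < cfg.max_p_correct,
            "pass_p_enrich": h.p_enrich < cfg.max_p_enrich,
            "pass_min_correct": h.n_correct >= cfg.min_correct,
            "pass_percent": pc is not None and pc >= cfg.min_percent_correct,
            "pass_rank": h.rank < cfg.max_rank,
        })
    return pd.DataFrame(rows, columns=[
        "node", "direction", "n_correct", "n_incorrect", "n_ambiguous",
        "score", "percent_correct", "p_enrich", "p_correct", "rank",
        "pass_p_correct", "pass_p_enrich", "pass_min_correct",
        "pass_percent", "pass_rank"])
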