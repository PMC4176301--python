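"""Gene-set over-representation, q-values, control subtraction and ranking.

Over-representation is the one-sided hypergeometric (Fisher) tail for the
overlap between a differential-expression gene list and each gene set,
computed over the universe of genes actually measured on the filtered
array.  Multiplicity is handled with Storey q-values (pi0 estimated by a
cubic smoother over a lambda grid; with pi0 = 1 the q-value reduces exactly
to Benjamini-Hochberg).  Sets significantly enriched in the control
comparison (shRNA control vs untransduced) are treated as transduction
artifacts and subtracted from every treatment's results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ContrastResult, DESignature, bh_adjust
from .io import GeneSetCollection, ProbeAnnotation, canon

__all__ = [
    "EnrichmentResult",
    "EnrichmentTable",
    "fisher_gene_set",
    "storey_qvalue",
    "enrich_collection",
    "gene_fold_map",
    "directional_member_counts",
    "subtract_control_sets",
    "interactome_overlap",
    "rank_pathways_across_conditions",
]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One gene set's over-representation against one DE list."""

    set_name: str
    k: int          # in set and DE
    set_only: int   # in set, not DE
    de_only: int    # DE, not in set
    neither: int
    odds_ratio: float
    odds_continuity: bool
    p: float
    q: float = float("nan")
    up_count: int = 0
    down_count: int = 0
    rank: int = 0

    @property
    def universe_size(self) -> int:
        return self.k + self.set_only + self.de_only + self.neither


@dataclass
class EnrichmentTable:
    """All sets' enrichment for one condition, with q-values and ranks."""

    condition: str
    results: dict[str, EnrichmentResult] = field(default_factory=dict)

    def significant(self, q_threshold: float = 0.05) -> list[str]:
        return [n for n, r in self.results.items() if r.q <= q_threshold]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "set_name": r.set_name, "overlap": r.k, "set_size": r.k + r.set_only,
            "de_size": r.k + r.de_only, "universe": r.universe_size,
            "odds_ratio": r.odds_ratio, "p": r.p, "q": r.q,
            "up_count": r.up_count, "down_count": r.down_count, "rank": r.rank,
        } for r in self.results.values()]
        return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)


def fisher_gene_set(de_genes: set[str], gene_set: set[str],
                    universe: set[str]) -> EnrichmentResult:
    """One-sided hypergeometric over-representation test.

    ``gene_set`` is intersected with the universe before testing;
    ``de_genes`` must already be a subset of the universe.  The odds ratio
    gets a 0.5 continuity addition only when a table margin is zero, and is
    flagged when it does.
    """
    if not universe:
        raise ValueError("universe is empty")
    extra = de_genes - universe
    if extra:
        raise ValueError(f"DE genes outside universe: {sorted(extra)[:5]}")
    s = gene_set & universe
    N = len(universe)
    K = len(s)
    n = len(de_genes)
    k = len(s & de_genes)
    if K == 0 or n == 0:
        p = 1.0
    else:
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b_, c, d = k, K - k, n - k, N - K - n + k
    continuity = 0 in (a, b_, c, d)
    if continuity:
        odds = (a + 0.5) * (d + 0.5) / ((b_ + 0.5) * (c + 0.5))
    else:
        odds = a * d / (b_ * c)
    return EnrichmentResult("", a, b_, c, d, float(odds), continuity,
                            min(p, 1.0))


def storey_qvalue(p_values: np.ndarray,
                  lambda_grid: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with smoothed pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is fit with a cubic
    polynomial over the lambda grid and evaluated at its upper end, clipped
    to (0, 1].  With fewer than 10 p-values pi0 falls back to 1 (the
    Benjamini-Hochberg limit, logged).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    m = p.size
    if m < 10:
        log.info("storey_qvalue: %d p-values < 10, using pi0 = 1 (BH fallback)", m)
        pi0 = 1.0
    else:
        pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam))
                               for lam in lambda_grid])
        coef = np.polyfit(lambda_grid, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coef, lambda_grid[-1]))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * ranked * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def gene_fold_map(contrast: ContrastResult,
                  annotation: ProbeAnnotation) -> dict[str, float]:
    """Representative signed linear fold per measured, annotated gene.

    Per gene the probe with the largest |log2fc| is representative.
    """
    probes = [str(p) for p in contrast.table.index]
    mags = contrast.table["log2fc"].abs().to_numpy()
    folds = contrast.table["fold_linear"].to_numpy()
    best: dict[str, tuple[float, float]] = {}
    for probe, mag, fold in zip(probes, mags, folds):
        symbol = annotation.gene(probe)
        if symbol is None:
            continue
        key = canon(symbol)
        if key not in best or mag > best[key][0]:
            best[key] = (float(mag), float(fold))
    return {g: fold for g, (_, fold) in best.items()}


def directional_member_counts(gene_set: set[str],
                              contrast: ContrastResult | dict[str, float],
                              annotation: ProbeAnnotation | None = None,
                              min_fold: float = 1.5) -> tuple[int, int]:
    """Count set members altered at least ``min_fold`` up and down.

    ``contrast`` may be a ContrastResult (with its annotation) or a
    precomputed :func:`gene_fold_map`.  A member counts up when its
    representative fold >= +min_fold and down when <= -min_fold.
    """
    if isinstance(contrast, ContrastResult):
        if annotation is None:
            raise ValueError("annotation required with a ContrastResult")
        folds = gene_fold_map(contrast, annotation)
    else:
        folds = contrast
    members = {canon(g) for g in gene_set}
    up = sum(1 for g in members if g in folds and folds[g] >= min_fold)
    down = sum(1 for g in members if g in folds and folds[g] <= -min_fold)
    return up, down


def enrich_collection(signature: DESignature, collection: GeneSetCollection,
                      universe: set[str],
                      contrast: ContrastResult | None = None,
                      annotation: ProbeAnnotation | None = None,
                      min_fold: float = 1.5,
                      rank_by: str = "q") -> EnrichmentTable:
    """Test every set in a collection against one signature.

    Adds Storey q-values across the collection, directional member counts
    when the contrast and annotation are supplied, and within-condition
    ranks (1 = most significant by q, ties broken by p then name; or by
    descending odds ratio with ``rank_by='odds'``).
    """
    if rank_by not in ("q", "odds"):
        raise ValueError("rank_by must be 'q' or 'odds'")
    de = signature.genes & universe
    table = EnrichmentTable(signature.condition)
    names = collection.names()
    folds = (gene_fold_map(contrast, annotation)
             if contrast is not None and annotation is not None else None)
    for name in names:
        r = fisher_gene_set(de, set(collection.sets[name]), universe)
        r.set_name = name
        if folds is not None:
            r.up_count, r.down_count = directional_member_counts(
                collection.sets[name], folds, min_fold=min_fold)
        table.results[name] = r
    ps = np.array([table.results[n].p for n in names])
    qs = storey_qvalue(ps)
    for name, q in zip(names, qs):
        table.results[name].q = float(q)
    if rank_by == "q":
        key = sorted(names, key=lambda n: (table.results[n].q,
                                           table.results[n].p, n))
    else:
        key = sorted(names, key=lambda n: (-table.results[n].odds_ratio,
                                           table.results[n].p, n))
    for i, name in enumerate(key, 1):
        table.results[name].rank = i
    return table


def subtract_control_sets(treatment_enrichments: dict[str, EnrichmentTable],
                          control_enrichment: EnrichmentTable,
                          q_threshold: float = 0.05
                          ) -> tuple[dict[str, EnrichmentTable], list[str]]:
    """Remove sets significant in the control comparison from every treatment.

    Returns the filtered per-condition tables plus the list of removed set
    names (logged with their control q).  All tables must cover the same
    collection.
    """
    control_names = set(control_enrichment.results)
    for cond, table in treatment_enrichments.items():
        if set(table.results) != control_names:
            raise ValueError(
                f"condition {cond!r} tested a different collection than control")
    removed = sorted(control_enrichment.significant(q_threshold))
    for name in removed:
        log.info("subtract_control_sets: removing %r (control q = %.3g)",
                 name, control_enrichment.results[name].q)
    filtered = {}
    for cond, table in treatment_enrichments.items():
        kept = EnrichmentTable(table.condition)
        kept.results = {n: r for n, r in table.results.items()
                        if n not in removed}
        filtered[cond] = kept
    return filtered, removed


def interactome_overlap(signatures: dict[str, DESignature],
                        interactome_genes: list[str], universe: set[str],
                        min_conditions: int = 3
                        ) -> tuple[dict[str, EnrichmentResult], pd.DataFrame]:
    """Interactome enrichment per condition plus a gene x condition fold matrix.

    The matrix lists interactome genes significant in at least
    ``min_conditions`` conditions; cells carry the signed linear fold and
    are empty (NaN) where the gene was not significant.
    """
    if not interactome_genes:
        raise ValueError("interactome gene list is empty")
    inter = {canon(g): g for g in interactome_genes}
    per_condition: dict[str, EnrichmentResult] = {}
    for cond, sig in signatures.items():
        r = fisher_gene_set(sig.genes & universe, set(inter), universe)
        r.set_name = "interactome"
        per_condition[cond] = r
    conds = list(signatures)
    rows = []
    for key, shown in inter.items():
        hits = {c: signatures[c].fold[key] for c in conds
                if key in signatures[c].direction}
        if len(hits) >= min_conditions:
            row: dict[str, object] = {"gene": shown, "n_conditions": len(hits)}
            for c in conds:
                row[c] = hits.get(c, np.nan)
            rows.append(row)
    matrix = pd.DataFrame(rows, columns=["gene", "n_conditions", *conds])
    if len(matrix):
        matrix = matrix.sort_values(
            ["n_conditions", "gene"], ascending=[False, True]).reset_index(drop=True)
    return per_condition, matrix


def rank_pathways_across_conditions(enrichments: dict[str, EnrichmentTable],
                                    q_threshold: float = 0.05) -> pd.DataFrame:
    """Aggregate within-condition pathway ranks across conditions.

    A pathway is present in a condition when q <= q_threshold there; rows
    are sorted by the number of conditions present (descending), then by
    the average within-condition rank over those conditions (ascending),
    then by name.  Per-condition columns carry the rank where present.
    """
    conds = list(enrichments)
    all_sets: dict[str, None] = {}
    for table in enrichments.values():
        for name in table.results:
            all_sets.setdefault(name, None)
    rows = []
    for name in all_sets:
        present = {c: enrichments[c].results[name].rank for c in conds
                   if name in enrichments[c].results
                   and enrichments[c].results[name].q <= q_threshold}
        if not present:
            continue
        rows.append({
            "set_name": name,
            "condition_count": len(present),
            "average_rank": sum(present.values()) / len(present),
            **{c: present.get(c, np.nan) for c in conds},
        })
    df = pd.DataFrame(rows, columns=["set_name", "condition_count",
                                     "average_rank", *conds])
    if len(df):
        df = df.sort_values(["condition_count", "average_rank", "set_name"],
                            ascending=[False, True, True]).reset_index(drop=True)
    return df
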