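"""Probe filtering, empirical-Bayes moderated-t contrasts and significance calls.

The moderated t shrinks each probe's pooled two-group variance s^2 toward a
prior variance s0^2 with prior weight d0 (degrees of freedom), estimated
across probes by matching the first two moments of log s^2 under the
scaled-F model (closed-form moment estimation).  The moderated statistic

    t~ = log2FC / sqrt( s~^2 * (1/n_a + 1/n_b) ),
    s~^2 = (d0*s0^2 + df*s^2) / (d0 + df)

is referred to a t distribution with d0 + df degrees of freedom (standard
normal when d0 is infinite).  Multiplicity is controlled by Benjamini-
Hochberg, and the significance call is FDR-adjusted p <= alpha together with
a signed linear fold change of at least min_fold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ProbeAnnotation, canon

__all__ = [
    "EBPriors",
    "ContrastResult",
    "DESignature",
    "filter_probe_sets",
    "estimate_eb_priors",
    "pooled_residual_variances",
    "moderated_t_contrast",
    "bh_adjust",
    "call_significant",
    "collapse_to_genes",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EBPriors:
    """Empirical-Bayes variance prior: d0 (may be ``inf``) and s0^2."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be >= 0 or inf, got {self.d0}")
        if not (self.s0_sq > 0) and not (self.d0 == 0):
            raise ValueError(f"s0_sq must be positive, got {self.s0_sq}")


@dataclass
class ContrastResult:
    """Per-probe statistics for one condition-vs-control comparison."""

    condition_a: str
    condition_b: str
    table: pd.DataFrame  # indexed by probe id
    priors: EBPriors

    _COLUMNS = ["mean_a", "mean_b", "log2fc", "fold_linear", "s_sq",
                "s_tilde_sq", "t_mod", "df_total", "p", "p_adj", "significant"]


@dataclass
class DESignature:
    """Gene-level significant changes with direction, for one contrast.

    ``direction`` maps canonical gene symbol to +1/-1; ``fold`` carries the
    representative signed linear fold; ``display`` preserves input casing.
    """

    condition: str
    direction: dict[str, int]
    fold: dict[str, float]
    display: dict[str, str]

    def __post_init__(self) -> None:
        for g, d in self.direction.items():
            if d not in (+1, -1):
                raise ValueError(f"direction for {g} must be +/-1, got {d}")
            if np.sign(self.fold[g]) != d:
                raise ValueError(f"fold/direction sign mismatch for {g}")

    @property
    def genes(self) -> set[str]:
        return set(self.direction)

    def __len__(self) -> int:
        return len(self.direction)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_probe_sets(matrix: ExpressionMatrix,
                      exclude_suffixes: tuple[str, ...] = ("_x_at",),
                      min_linear: float = 50.0) -> ExpressionMatrix:
    """Drop cross-hybridising and absent probe sets before any statistics.

    Probes whose id ends with any of ``exclude_suffixes`` are removed, as are
    probes whose linear-scale expression (2**log2 value) is below
    ``min_linear`` in *every* sample.  Probe order is preserved.
    """
    keep = []
    vals = matrix.values
    linear_floor = np.log2(min_linear) if min_linear > 0 else -np.inf
    present = (vals.to_numpy() >= linear_floor).any(axis=1)
    for i, probe in enumerate(vals.index):
        if any(probe.endswith(suf) for suf in exclude_suffixes):
            continue
        if not present[i]:
            continue
        keep.append(probe)
    if not keep:
        raise ValueError("probe filtering removed every probe set")
    return ExpressionMatrix(vals.loc[keep], dict(matrix.condition_of))


# ---------------------------------------------------------------------------
# empirical-Bayes prior estimation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return math.inf
    # trigamma(y) ~ 1/y + 1/(2y^2); start from the 1/y approximation
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def pooled_residual_variances(matrix: ExpressionMatrix) -> tuple[np.ndarray, int]:
    """Per-probe one-way residual variance across all conditions.

    Returns (variances, residual df = N - k); used to fit one global prior.
    """
    groups = [matrix.samples_for(c) for c in matrix.conditions]
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        raise ValueError("no condition has >= 2 replicates")
    n_total = sum(len(g) for g in groups)
    df = n_total - len(groups)
    ss = np.zeros(len(matrix.values.index))
    for g in groups:
        sub = matrix.values[g].to_numpy()
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return ss / df, df


def estimate_eb_priors(per_probe_variances: np.ndarray,
                       residual_df: int) -> EBPriors:
    """Moment-match (d0, s0^2) on log sample variances.

    Under the scaled-F model, e = log s^2 - digamma(df/2) + log(df/2) has
    mean log s0^2 - digamma(d0/2) + log(d0/2) and excess variance
    trigamma(d0/2) beyond trigamma(df/2); d0 is reported infinite when the
    observed spread of log variances does not exceed the trigamma floor.
    """
    if residual_df < 1:
        raise ValueError("residual_df must be >= 1")
    v = np.asarray(per_probe_variances, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size < 2:
        raise ValueError("need >= 2 positive variances to estimate priors")
    z = np.log(v)
    df = float(residual_df)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return EBPriors(d0=math.inf, s0_sq=float(np.exp(z.mean())))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return EBPriors(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def moderated_t_contrast(matrix: ExpressionMatrix, cond_a: str, cond_b: str,
                         priors: EBPriors) -> ContrastResult:
    """Moderated-t contrast of ``cond_a`` minus ``cond_b``.

    With d0 = 0 this is exactly the classical pooled two-sample t; with
    d0 infinite the variance is fixed at s0^2 and p-values are normal.
    """
    samples_a = matrix.samples_for(cond_a)
    samples_b = matrix.samples_for(cond_b)
    for cond, s in ((cond_a, samples_a), (cond_b, samples_b)):
        if len(s) < 2:
            raise ValueError(f"condition {cond!r} has {len(s)} samples; need >= 2")
    a = matrix.values[samples_a].to_numpy()
    b = matrix.values[samples_b].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]
    df = n_a + n_b - 2
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    log2fc = mean_a - mean_b
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s_sq = ss / df
    d0, s0 = priors.d0, priors.s0_sq
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s_sq, s0)
        df_total = math.inf
    else:
        s_tilde_sq = (d0 * s0 + df * s_sq) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
        t_mod = np.where((se == 0) & (log2fc != 0),
                         np.sign(log2fc) * np.inf, t_mod)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    p_adj = bh_adjust(p)
    fold_linear = np.where(log2fc >= 0, 2.0 ** log2fc, -(2.0 ** (-log2fc)))
    table = pd.DataFrame({
        "mean_a": mean_a, "mean_b": mean_b, "log2fc": log2fc,
        "fold_linear": fold_linear, "s_sq": s_sq, "s_tilde_sq": s_tilde_sq,
        "t_mod": t_mod, "df_total": df_total, "p": p, "p_adj": p_adj,
        "significant": False,
    }, index=matrix.values.index)
    return ContrastResult(cond_a, cond_b, table, priors)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_significant(contrast: ContrastResult, alpha: float = 0.05,
                     min_fold: float = 1.5,
                     strict_bounds: bool = False) -> tuple[pd.Series, int, int]:
    """Flag probes with adjusted p <= alpha and |linear fold| >= min_fold.

    Boundaries are inclusive by default (``strict_bounds`` switches both to
    strict).  Returns (boolean series, n_up, n_down) and records the call in
    the contrast table.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    t = contrast.table
    if strict_bounds:
        sig = (t["p_adj"] < alpha) & (t["fold_linear"].abs() > min_fold)
    else:
        sig = (t["p_adj"] <= alpha) & (t["fold_linear"].abs() >= min_fold)
    contrast.table["significant"] = sig
    n_up = int((sig & (t["log2fc"] > 0)).sum())
    n_down = int((sig & (t["log2fc"] < 0)).sum())
    return sig, n_up, n_down


def collapse_to_genes(contrast: ContrastResult, annotation: ProbeAnnotation,
                      alpha: float = 0.05, min_fold: float = 1.5,
                      strict_bounds: bool = False) -> DESignature:
    """Collapse significant probes to a gene-level directional signature.

    Per gene the significant probe with maximal |log2fc| is representative;
    genes whose significant probes disagree in sign are dropped (logged).
    """
    sig, _, _ = call_significant(contrast, alpha, min_fold, strict_bounds)
    t = contrast.table[sig.to_numpy()]
    by_gene: dict[str, list[tuple[float, float, str]]] = {}
    display: dict[str, str] = {}
    for probe, row in t.iterrows():
        symbol = annotation.gene(str(probe))
        if symbol is None:
            continue
        key = canon(symbol)
        by_gene.setdefault(key, []).append(
            (abs(row["log2fc"]), row["fold_linear"], str(probe)))
        display.setdefault(key, symbol.strip())
    direction: dict[str, int] = {}
    fold: dict[str, float] = {}
    dropped = []
    for gene, probes in by_gene.items():
        signs = {1 if f > 0 else -1 for _, f, _ in probes}
        if len(signs) > 1:
            dropped.append(gene)
            continue
        best = max(probes)
        direction[gene] = 1 if best[1] > 0 else -1
        fold[gene] = float(best[1])
    if dropped:
        log.info("collapse_to_genes: dropped %d genes with conflicting probe "
                 "signs: %s", len(dropped), sorted(dropped)[:10])
    if not direction:
        log.warning("collapse_to_genes: no annotated significant probes for %s",
                    contrast.condition_a)
    return DESignature(contrast.condition_a, direction, fold,
                       {g: display[g] for g in direction})
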