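"""Synthetic shRNA knockdown studies with known ground truth.

The generator emulates a quadruplicate knockdown experiment in primary
neuronal culture: eight gene-knockdown conditions, a control shRNA
(targeting luciferase) that carries the same viral-transduction artifact as
every other transduced condition, and an untransduced blank.  Each
knockdown reduces its target by log2(1 - efficiency) and propagates planted
signed effects to the target's downstream genes in a known causal network;
a shared block of targets regulated by all knocked-down genes plants
pathways that should be conserved across conditions.  All randomness flows
through a single seeded generator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (CausalGraph, ExpressionMatrix, GeneSetCollection,
                 ProbeAnnotation, canon)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimStudy",
    "DEFAULT_EFFICIENCIES",
    "generate_network",
    "simulate_study",
    "evaluate_recovery",
]

LUCIFERASE = "Luciferase"
BLANK = "Blank"

# Published per-gene knockdown efficiencies used as the default conditions.
DEFAULT_EFFICIENCIES: dict[str, float] = {
    "Mecp2": 0.86, "Mef2a": 0.94, "Mef2d": 0.89, "Fmr1": 0.86,
    "Nlgn1": 0.89, "Nlgn3": 0.89, "Pten": 0.95, "Shank3": 0.90,
}

SHARED_PATHWAY = "SHARED_DOWNSTREAM_PROGRAM"
ARTIFACT_PATHWAY = "VIRAL_TRANSDUCTION_RESPONSE"


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic knockdown experiment.

    Defaults mirror the emulated design: 8 knockdowns with efficiencies in
    0.86-0.95, quadruplicates with 10% QC dropout, a viral artifact of
    -0.8 log2 on 120 genes shared by all transduced conditions, downstream
    effects of 1.0 log2 and residual noise of 0.25 log2.
    """

    n_probes: int = 2000
    n_regulators: int = 8
    targets_per_regulator: int = 20
    shared_targets: int = 15
    p_negative_edge: float = 0.3
    knockdown_efficiency: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFICIENCIES))
    effect_size: float = 1.0
    artifact_gene_count: int = 120
    artifact_effect: float = -0.8
    noise_sd: float = 0.25
    n_reps: int = 4
    qc_dropout_prob: float = 0.1
    decoy_fraction: float = 0.10
    noise_df: float | None = None  # heavier-tailed t noise when set
    seed: int = 0

    def __post_init__(self) -> None:
        for g, e in self.knockdown_efficiency.items():
            if not (0.75 < e <= 1.0):
                raise ValueError(
                    f"knockdown efficiency for {g} must be in (0.75, 1], got {e}")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        for name in ("p_negative_edge", "qc_dropout_prob", "decoy_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_regulators < 1 or self.targets_per_regulator < 1:
            raise ValueError("need >= 1 regulator with >= 1 target")

    @property
    def regulator_names(self) -> list[str]:
        names = list(self.knockdown_efficiency)
        if len(names) >= self.n_regulators:
            return names[: self.n_regulators]
        extra = [f"REG{i:02d}" for i in range(len(names), self.n_regulators)]
        return names + extra

    def efficiency(self, gene: str) -> float:
        return self.knockdown_efficiency.get(gene, 0.90)


@dataclass
class SimTruth:
    """Everything needed to score recovery of the planted structure."""

    condition_of_target: dict[str, str]  # condition label -> perturbed node
    artifact_genes: list[str]
    shared_target_genes: list[str]
    true_effects: dict[str, dict[str, float]]  # condition -> gene -> log2 shift
    planted_pathways: list[str]
    artifact_pathways: list[str]
    seed: int

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimStudy:
    """A complete simulated study: data, metadata and ground truth."""

    matrix: ExpressionMatrix
    annotation: ProbeAnnotation
    network: CausalGraph
    gene_sets: GeneSetCollection
    truth: SimTruth


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def generate_network(config: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[CausalGraph, list[str], list[str]]:
    """Build the planted signed network.

    Each regulator gets ``targets_per_regulator`` private targets plus the
    shared block regulated by every regulator; edge signs are -1 with
    probability ``p_negative_edge``.  Returns (graph, private target genes,
    shared target genes).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    regs = config.regulator_names
    n_private = config.n_regulators * config.targets_per_regulator
    n_target_genes = n_private + config.shared_targets
    approx_genes = max(int(config.n_probes / 1.3), 1)
    if n_target_genes + config.artifact_gene_count + len(regs) > approx_genes:
        raise ValueError("more network targets than available genes/probes")
    private = [f"TGT{i:04d}" for i in range(n_private)]
    shared = [f"SHT{i:04d}" for i in range(config.shared_targets)]
    graph = CausalGraph()
    for r, reg in enumerate(regs):
        block = private[r * config.targets_per_regulator:
                        (r + 1) * config.targets_per_regulator]
        for tgt in block + shared:
            sign = -1 if rng.random() < config.p_negative_edge else +1
            graph.add_edge(reg, tgt, sign, provenance="planted")
    return graph, private, shared


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _gene_universe(config: SimConfig, private: list[str], shared: list[str]
                   ) -> tuple[list[str], list[str]]:
    """All gene symbols in the study plus the artifact subset."""
    regs = config.regulator_names
    artifact = [f"ART{i:04d}" for i in range(config.artifact_gene_count)]
    n_named = len(regs) + len(private) + len(shared) + len(artifact)
    # leave room for ~1.3 probes/gene plus the decoy fraction
    n_regular = int(config.n_probes * (1.0 - config.decoy_fraction))
    approx_genes = max(int(n_regular / 1.3), n_named)
    background = [f"BGD{i:04d}" for i in range(approx_genes - n_named)]
    return regs + private + shared + artifact + background, artifact


def simulate_study(config: SimConfig) -> SimStudy:
    """Generate the full study: matrix, annotation, network, sets, truth."""
    rng = np.random.default_rng(config.seed)
    graph, private, shared = generate_network(config, rng)
    genes, artifact = _gene_universe(config, private, shared)
    regs = config.regulator_names

    # probe map: 1-2 probes per gene plus _x_at decoys
    probes: list[str] = []
    symbol_of: dict[str, str] = {}
    pid = 10000
    n_regular_max = int(config.n_probes * (1.0 - config.decoy_fraction))
    for g in genes:
        n_p = 2 if rng.random() < 0.3 else 1
        for _ in range(n_p):
            probe = f"{pid}_at"
            probes.append(probe)
            symbol_of[probe] = g
            pid += 1
    while len(probes) > n_regular_max and symbol_of[probes[-1]].startswith("BGD"):
        symbol_of.pop(probes.pop())
    n_decoys = min(int(round(config.decoy_fraction * config.n_probes)),
                   config.n_probes - len(probes))
    for _ in range(max(n_decoys, 0)):
        probe = f"{pid}_x_at"
        probes.append(probe)
        symbol_of[probe] = genes[int(rng.integers(len(genes)))]
        pid += 1
    annotation = ProbeAnnotation(dict(symbol_of))

    # baseline log2 means; planted and artifact genes kept well-expressed
    base_by_gene = {g: float(rng.uniform(4.0, 12.0)) for g in genes}
    floor_genes = set(regs) | set(private) | set(shared) | set(artifact)
    for g in floor_genes:
        base_by_gene[g] = max(base_by_gene[g], 7.0)

    # true per-condition gene-level shifts
    conditions = list(regs)
    true_effects: dict[str, dict[str, float]] = {}
    artifact_shift = {g: config.artifact_effect for g in artifact}
    for reg in regs:
        eff: dict[str, float] = {}
        eff[reg] = math.log2(1.0 - config.efficiency(reg))
        for tgt, sign in graph.out_edges(reg):
            # the knocked-down regulator loses its influence: an activated
            # target falls, a repressed target rises
            eff[tgt] = eff.get(tgt, 0.0) + (-sign) * config.effect_size
        true_effects[reg] = eff
    true_effects[LUCIFERASE] = {}
    true_effects[BLANK] = {g: -config.artifact_effect for g in artifact}
    # (blank relative to luciferase lacks the artifact; stored relative to
    # the luciferase condition for direct comparison with pipeline contrasts)

    # sample layout with QC dropout (>= 3 replicates always kept)
    all_conditions = conditions + [LUCIFERASE, BLANK]
    sample_ids: list[str] = []
    condition_of: dict[str, str] = {}
    kept_by_condition: dict[str, int] = {}
    for cond in all_conditions:
        drops = rng.random(config.n_reps) < config.qc_dropout_prob
        n_keep = max(config.n_reps - int(drops.sum()), min(3, config.n_reps))
        kept_by_condition[cond] = n_keep
        for i in range(n_keep):
            s = f"{cond}_rep{i + 1}"
            sample_ids.append(s)
            condition_of[s] = cond

    probe_genes = [symbol_of[p] for p in probes]
    base = np.array([base_by_gene[g] for g in probe_genes])
    art_set = set(artifact)
    art_vec = np.array([artifact_shift.get(g, 0.0) if g in art_set else 0.0
                        for g in probe_genes])

    mean_by_condition: dict[str, np.ndarray] = {}
    mean_by_condition[BLANK] = base
    mean_by_condition[LUCIFERASE] = base + art_vec
    for reg in regs:
        eff = true_effects[reg]
        shift = np.array([eff.get(g, 0.0) for g in probe_genes])
        mean_by_condition[reg] = base + art_vec + shift

    n_samples = len(sample_ids)
    if config.noise_df is not None:
        scale = math.sqrt((config.noise_df - 2) / config.noise_df)
        noise = rng.standard_t(config.noise_df, size=(len(probes), n_samples))
        noise *= config.noise_sd * scale
    else:
        noise = rng.normal(0.0, config.noise_sd, size=(len(probes), n_samples))
    data = np.empty((len(probes), n_samples))
    for j, s in enumerate(sample_ids):
        data[:, j] = mean_by_condition[condition_of[s]] + noise[:, j]
    matrix = ExpressionMatrix(
        pd.DataFrame(data, index=probes, columns=sample_ids),
        condition_of)

    gene_sets = _build_gene_sets(config, rng, regs, private, shared,
                                 artifact, genes)
    truth = SimTruth(
        condition_of_target={reg: reg for reg in regs},
        artifact_genes=list(artifact),
        shared_target_genes=list(shared),
        true_effects=true_effects,
        planted_pathways=[SHARED_PATHWAY],
        artifact_pathways=[ARTIFACT_PATHWAY],
        seed=config.seed)
    return SimStudy(matrix, annotation, graph, gene_sets, truth)


def _build_gene_sets(config: SimConfig, rng: np.random.Generator,
                     regs: list[str], private: list[str], shared: list[str],
                     artifact: list[str], genes: list[str]) -> GeneSetCollection:
    """Planted, artifact and random background gene sets (GMT-shaped)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    sets[SHARED_PATHWAY] = frozenset(canon(g) for g in shared)
    descriptions[SHARED_PATHWAY] = "targets shared by all planted regulators"
    sets[ARTIFACT_PATHWAY] = frozenset(
        canon(g) for g in artifact[: max(len(artifact) // 2, 5)])
    descriptions[ARTIFACT_PATHWAY] = "genes responding to transduction itself"
    for r, reg in enumerate(regs):
        block = private[r * config.targets_per_regulator:
                        (r + 1) * config.targets_per_regulator]
        name = f"{reg.upper()}_PROGRAM"
        sets[name] = frozenset(canon(g) for g in block)
        descriptions[name] = f"private targets of {reg}"
    for i in range(20):
        members = rng.choice(genes, size=30, replace=False)
        name = f"RANDOM_SET_{i:02d}"
        sets[name] = frozenset(canon(g) for g in members)
        descriptions[name] = "random background set"
    return GeneSetCollection(sets, descriptions)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def evaluate_recovery(pipeline_result, truth: SimTruth,
                      min_conditions: int = 6) -> pd.DataFrame:
    """Score a pipeline run against the planted ground truth.

    Per knockdown condition: the rank of the planted hypothesis
    (perturbed node, -1) in the filtered hypothesis list (NaN when absent),
    the count of other surviving hypotheses, whether every planted shared
    pathway passed conservation at ``min_conditions``, and whether every
    artifact pathway was removed by control subtraction.
    """
    conds = list(truth.condition_of_target)
    missing = [c for c in conds if c not in pipeline_result.cre_filtered]
    if missing:
        raise ValueError(f"pipeline output lacks conditions: {missing}")
    pathway_tbl = pipeline_result.pathway_conservation(min_conditions)
    conserved = set(pathway_tbl.frame["item"]) if len(pathway_tbl.frame) else set()
    pathways_ok = all(p in conserved for p in truth.planted_pathways)
    removed = set(pipeline_result.removed_sets)
    artifact_ok = all(p in removed for p in truth.artifact_pathways)
    rows = []
    for cond in conds:
        target = truth.condition_of_target[cond]
        kept = pipeline_result.cre_filtered[cond]
        planted_rank = math.nan
        false_count = 0
        for pos, h in enumerate(kept, 1):
            if h.node == target and h.direction == -1:
                planted_rank = pos
            else:
                false_count += 1
        rows.append({
            "condition": cond, "planted_node": target,
            "planted_rank": planted_rank,
            "planted_is_top": planted_rank == 1,
            "false_hypotheses": false_count,
            "planted_pathways_conserved": pathways_ok,
            "artifact_sets_removed": artifact_ok,
        })
    return pd.DataFrame(rows)
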