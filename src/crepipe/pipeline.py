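"""End-to-end orchestration: filter -> contrasts -> signatures -> enrichment
-> causal engine -> conservation, with a run manifest.

Every knockdown condition is contrasted against the shRNA-control
(luciferase) condition; the luciferase-vs-blank contrast estimates the
transduction artifact, whose enriched gene sets and inferred hypotheses are
subtracted from every treatment before conservation analysis.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .causal import CREFilterConfig, Hypothesis, hypotheses_frame, run_cre
from .conservation import (ConservationTable, conserve, direction_summary,
                           linkage_to_newick, ward_cluster)
from .diffexp import (ContrastResult, DESignature, call_significant,
                      collapse_to_genes, estimate_eb_priors, filter_probe_sets,
                      moderated_t_contrast, pooled_residual_variances)
from .enrichment import (EnrichmentTable, enrich_collection,
                         interactome_overlap, rank_pathways_across_conditions,
                         subtract_control_sets)
from .io import (CausalGraph, ExpressionMatrix, GeneSetCollection,
                 ProbeAnnotation, canon, read_annotation, read_causal_edges,
                 read_expression_table, read_gene_list, read_gmt,
                 write_results)
from .simulate import BLANK, LUCIFERASE, SimConfig, SimStudy, simulate_study

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline thresholds and inputs; defaults are the standard cutoffs."""

    alpha: float = 0.05
    min_fold: float = 1.5
    strict_bounds: bool = False
    exclude_suffixes: tuple[str, ...] = ("_x_at",)
    min_linear: float = 50.0
    q_threshold: float = 0.05
    min_conditions: int = 3
    max_depth: int = 1
    cre: CREFilterConfig = field(default_factory=CREFilterConfig)
    control_condition: str = LUCIFERASE
    blank_condition: str = BLANK
    seed: int = 0
    simulate: SimConfig | None = None
    expression_path: str | None = None
    condition_map_path: str | None = None
    annotation_path: str | None = None
    gmt_path: str | None = None
    network_path: str | None = None
    interactome_path: str | None = None
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclude_suffixes"] = list(self.exclude_suffixes)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML/JSON file (flat keys + simulate block)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cre = raw.pop("cre", None)
    if "exclude_suffixes" in raw:
        raw["exclude_suffixes"] = tuple(raw["exclude_suffixes"])
    cfg = RunConfig(**raw)
    if sim is not None:
        cfg.simulate = SimConfig(**sim)
    if cre is not None:
        cfg.cre = CREFilterConfig(**cre)
    return cfg


@dataclass
class PipelineResult:
    """Everything a run produces, kept in memory for inspection."""

    config: RunConfig
    matrix: ExpressionMatrix
    filtered: ExpressionMatrix
    annotation: ProbeAnnotation
    universe: set[str]
    contrasts: dict[str, ContrastResult]
    control_contrast: ContrastResult
    signatures: dict[str, DESignature]
    control_signature: DESignature
    enrichments: dict[str, EnrichmentTable]
    control_enrichment: EnrichmentTable | None
    removed_sets: list[str]
    cre_ranked: dict[str, list[Hypothesis]]
    cre_filtered: dict[str, list[Hypothesis]]
    blank_hypotheses: list[Hypothesis]
    hypothesis_conservation: ConservationTable
    direction_table: pd.DataFrame
    linkage: object
    interactome_per_condition: dict | None = None
    interactome_matrix: pd.DataFrame | None = None
    study: SimStudy | None = None

    def pathway_conservation(self, min_conditions: int | None = None
                             ) -> ConservationTable:
        """Pathways significant in >= min_conditions knockdowns, not in blank."""
        mc = min_conditions or self.config.min_conditions
        qt = self.config.q_threshold
        items = {c: set(t.significant(qt)) for c, t in self.enrichments.items()}
        blank = (set(self.control_enrichment.significant(qt))
                 if self.control_enrichment is not None else set())
        return conserve(items, blank, mc)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage in order and (optionally) write all output tables."""
    stage = "inputs"
    try:
        if config.simulate is not None:
            config.simulate.seed = config.seed
            study = simulate_study(config.simulate)
            matrix, annotation = study.matrix, study.annotation
            collection, graph = study.gene_sets, study.network
            interactome = None
        else:
            study = None
            for name in ("expression_path", "condition_map_path",
                         "annotation_path", "gmt_path", "network_path"):
                if getattr(config, name) is None:
                    raise ValueError(f"config missing required field {name!r}")
            matrix = read_expression_table(config.expression_path,
                                           config.condition_map_path)
            annotation = read_annotation(config.annotation_path)
            collection = read_gmt(config.gmt_path)
            graph = read_causal_edges(config.network_path)
            interactome = (read_gene_list(config.interactome_path)
                           if config.interactome_path else None)
        control, blank = config.control_condition, config.blank_condition
        for cond in (control, blank):
            if cond not in matrix.conditions:
                raise ValueError(f"condition {cond!r} absent from matrix")

        stage = "probe_filter"
        filtered = filter_probe_sets(matrix, config.exclude_suffixes,
                                     config.min_linear)
        log.info("probe filter: %d of %d probe sets retained",
                 len(filtered.probe_ids), len(matrix.probe_ids))
        universe = {canon(annotation.symbol_of[p])
                    for p in filtered.probe_ids if p in annotation.symbol_of}

        stage = "eb_priors"
        variances, df = pooled_residual_variances(filtered)
        priors = estimate_eb_priors(variances, df)

        stage = "contrasts"
        knockdowns = [c for c in matrix.conditions if c not in (control, blank)]
        contrasts: dict[str, ContrastResult] = {}
        signatures: dict[str, DESignature] = {}
        for cond in knockdowns:
            c = moderated_t_contrast(filtered, cond, control, priors)
            contrasts[cond] = c
            signatures[cond] = collapse_to_genes(
                c, annotation, config.alpha, config.min_fold,
                config.strict_bounds)
        control_contrast = moderated_t_contrast(filtered, control, blank, priors)
        control_signature = collapse_to_genes(
            control_contrast, annotation, config.alpha, config.min_fold,
            config.strict_bounds)

        stage = "enrichment"
        enrichments = {
            cond: enrich_collection(signatures[cond], collection, universe,
                                    contrasts[cond], annotation,
                                    config.min_fold)
            for cond in knockdowns}
        control_enrichment = enrich_collection(
            control_signature, collection, universe, control_contrast,
            annotation, config.min_fold)
        enrichments, removed = subtract_control_sets(
            enrichments, control_enrichment, config.q_threshold)

        stage = "interactome"
        inter_per_cond = inter_matrix = None
        if interactome:
            inter_per_cond, inter_matrix = interactome_overlap(
                signatures, interactome, universe, config.min_conditions)

        stage = "cre"
        cre_ranked: dict[str, list[Hypothesis]] = {}
        cre_filtered: dict[str, list[Hypothesis]] = {}
        for cond in knockdowns:
            ranked, kept = run_cre(graph, signatures[cond], universe,
                                   config.cre, config.max_depth,
                                   seed=config.seed)
            cre_ranked[cond] = ranked
            cre_filtered[cond] = kept
        _, blank_kept = run_cre(graph, control_signature, universe,
                                config.cre, config.max_depth,
                                seed=config.seed)

        stage = "conservation"
        items = {c: {h.label for h in cre_filtered[c]} for c in knockdowns}
        blank_items = {h.label for h in blank_kept}
        hyp_conservation = conserve(items, blank_items, config.min_conditions)
        direction_table = direction_summary(
            {c: [h.direction for h in cre_filtered[c]] for c in knockdowns})

        stage = "clustering"
        linkage = ward_cluster(filtered)

        result = PipelineResult(
            config=config, matrix=matrix, filtered=filtered,
            annotation=annotation, universe=universe, contrasts=contrasts,
            control_contrast=control_contrast, signatures=signatures,
            control_signature=control_signature, enrichments=enrichments,
            control_enrichment=control_enrichment, removed_sets=removed,
            cre_ranked=cre_ranked, cre_filtered=cre_filtered,
            blank_hypotheses=blank_kept,
            hypothesis_conservation=hyp_conservation,
            direction_table=direction_table, linkage=linkage,
            interactome_per_condition=inter_per_cond,
            interactome_matrix=inter_matrix, study=study)

        stage = "write"
        if config.out_dir is not None:
            _write_outputs(result)
        return result
    except Exception as exc:
        if config.out_dir is not None and stage not in ("inputs", "write"):
            shutil.rmtree(config.out_dir, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _contrast_frame(contrast: ContrastResult,
                    annotation: ProbeAnnotation) -> pd.DataFrame:
    t = contrast.table
    return pd.DataFrame({
        "probe": t.index,
        "gene": [annotation.gene(str(p)) or "" for p in t.index],
        "log2fc": t["log2fc"].to_numpy(),
        "fold_linear": t["fold_linear"].to_numpy(),
        "t_mod": t["t_mod"].to_numpy(),
        "p": t["p"].to_numpy(),
        "p_adj": t["p_adj"].to_numpy(),
        "significant": t["significant"].to_numpy(),
    })


def _write_outputs(result: PipelineResult) -> dict[str, str]:
    cfg = result.config
    tables: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}
    for cond, contrast in result.contrasts.items():
        tables[f"contrast_{cond}"] = _contrast_frame(contrast, result.annotation)
        counts[f"contrast_{cond}_significant"] = int(
            contrast.table["significant"].sum())
    tables["contrast_control_vs_blank"] = _contrast_frame(
        result.control_contrast, result.annotation)
    for cond, table in result.enrichments.items():
        tables[f"enrichment_{cond}"] = table.to_frame()
    for cond, ranked in result.cre_ranked.items():
        tables[f"cre_{cond}"] = hypotheses_frame(ranked, cfg.cre)
    tables["hypothesis_conservation"] = result.hypothesis_conservation.frame
    tables["pathway_conservation"] = rank_pathways_across_conditions(
        result.enrichments, cfg.q_threshold)
    tables["direction_summary"] = result.direction_table
    if result.interactome_matrix is not None:
        tables["interactome_matrix"] = result.interactome_matrix
    link = result.linkage
    tables["ward_linkage"] = pd.DataFrame(
        link, columns=["left", "right", "height", "size"])
    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "versions": {"crepipe": __version__,
                     "python": sys.version.split()[0]},
        "stage_rows": {name: len(df) for name, df in tables.items()},
        "significant_counts": counts,
        "removed_sets": result.removed_sets,
    }
    paths = write_results(tables, cfg.out_dir, manifest)
    newick = linkage_to_newick(link, result.filtered.sample_ids)
    with open(Path(cfg.out_dir) / "ward_dendrogram.nwk", "w") as fh:
        fh.write(newick + "\n")
    return paths
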