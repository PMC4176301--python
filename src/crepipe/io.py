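"""Readers, writers and validated in-memory containers.

All external formats the pipeline touches are plain text: tab-delimited
expression matrices (probes x samples, log2 scale), a sample-to-condition
map, a probe-to-gene annotation table, standard GMT gene-set collections,
SIF-like signed causal edge lists, and interactome gene lists (one symbol
per line).  Parsers validate and refuse to silently repair malformed input.

Gene symbols are case-preserved for display but matched case-insensitively
throughout the pipeline (mouse/human symbol casing is mixed in the wild);
:func:`canon` is the single canonicalisation used everywhere.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "canon",
    "ExpressionMatrix",
    "ProbeAnnotation",
    "GeneSetCollection",
    "CausalGraph",
    "read_expression_table",
    "write_expression_table",
    "read_condition_map",
    "read_annotation",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_causal_edges",
    "write_causal_edges",
    "write_results",
]


def canon(symbol: str) -> str:
    """Canonical (case-insensitive) form of a gene symbol."""
    return symbol.strip().upper()


class FormatError(ValueError):
    """Raised when an input file violates a structural invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2 expression values, probes x samples, with condition labels.

    ``values`` is a DataFrame indexed by probe id with sample-id columns;
    ``condition_of`` maps every sample id to its condition label.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise FormatError(f"samples missing from condition map: {missing}")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            raise FormatError("expression matrix contains non-finite values")
        counts: dict[str, int] = {}
        for s in self.values.columns:
            counts[self.condition_of[s]] = counts.get(self.condition_of[s], 0) + 1
        if counts and max(counts.values()) < 2:
            raise FormatError("no condition has >= 2 samples")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.condition_of[s], None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def subset_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [p for p in self.values.index if p in set(probe_ids)]
        return ExpressionMatrix(self.values.loc[keep], dict(self.condition_of))


@dataclass
class ProbeAnnotation:
    """Probe id -> gene symbol (many probes may map to one gene)."""

    symbol_of: dict[str, str]

    def __post_init__(self) -> None:
        for p, g in self.symbol_of.items():
            if not str(g).strip():
                raise FormatError(f"empty gene symbol for probe {p!r}")

    def gene(self, probe_id: str) -> str | None:
        return self.symbol_of.get(probe_id)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions.

    Member symbols are stored canonicalised (see :func:`canon`).
    """

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


class CausalGraph:
    """Signed causal network: edges (source, target, sign, provenance).

    Backed by a :class:`networkx.MultiDiGraph`; parallel edges with opposite
    signs are allowed, duplicate (source, target, sign) triples are not.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()

    def add_edge(self, source: str, target: str, sign: int,
                 provenance: str = "") -> None:
        if sign not in (+1, -1):
            raise FormatError(f"edge sign must be +1 or -1, got {sign!r}")
        if self._g.has_edge(source, target):
            for key in self._g[source][target]:
                if self._g[source][target][key]["sign"] == sign:
                    raise FormatError(
                        f"duplicate edge ({source!r}, {target!r}, {sign:+d})")
        self._g.add_edge(source, target, sign=sign, provenance=provenance)

    @property
    def nodes(self) -> list[str]:
        return list(self._g.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def edges(self) -> list[tuple[str, str, int, str]]:
        return [(u, v, d["sign"], d.get("provenance", ""))
                for u, v, d in self._g.edges(data=True)]

    def out_edges(self, node: str) -> list[tuple[str, int]]:
        return [(v, d["sign"]) for _, v, d in self._g.out_edges(node, data=True)]

    def regulators(self) -> list[str]:
        """Nodes with at least one outgoing edge, in insertion order."""
        return [n for n in self._g.nodes if self._g.out_degree(n) > 0]

    def n_edges(self) -> int:
        return self._g.number_of_edges()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_condition_map(path: str | Path) -> dict[str, str]:
    """Read a two-column sample<TAB>condition map."""
    cond: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            sample, condition = parts
            if sample in cond:
                raise FormatError(f"{path}:{lineno}: duplicate sample {sample!r}")
            cond[sample] = condition
    return cond


def read_expression_table(path: str | Path, condition_map_path: str | Path,
                          linear: bool = False) -> ExpressionMatrix:
    """Read a probes-x-samples expression TSV plus its condition map.

    Values are log2 intensities unless ``linear`` is set, in which case they
    are log2-transformed on read (non-positive values are rejected).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe id {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(f"{path}: non-numeric value at probe {row!r}, sample {col!r}")
    if linear:
        if (df.to_numpy() <= 0).any():
            raise FormatError(f"{path}: non-positive value cannot be log2-transformed")
        df = np.log2(df)
    cond = read_condition_map(condition_map_path)
    missing = [s for s in df.columns if s not in cond]
    if missing:
        raise FormatError(f"{path}: samples missing from condition map: {missing}")
    return ExpressionMatrix(df, {s: cond[s] for s in df.columns})


def write_expression_table(matrix: ExpressionMatrix, path: str | Path,
                           condition_map_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id")
    if condition_map_path is not None:
        with open(condition_map_path, "w") as fh:
            for s in matrix.sample_ids:
                fh.write(f"{s}\t{matrix.condition_of[s]}\n")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a two-column probe<TAB>gene-symbol table (header optional)."""
    symbol_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            probe, gene = parts[0], parts[1]
            if lineno == 1 and probe.lower() in {"probe", "probe_id"}:
                continue
            if probe in symbol_of:
                raise FormatError(f"{path}:{lineno}: duplicate probe {probe!r}")
            symbol_of[probe] = gene
    return ProbeAnnotation(symbol_of)


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_symbol\n")
        for p, g in annotation.symbol_of.items():
            fh.write(f"{p}\t{g}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, then member genes."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = parts[0], parts[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = frozenset(canon(g) for g in parts[2:] if g.strip())
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one symbol per line."""
    genes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if not g or g.startswith("#"):
                continue
            if canon(g) not in seen:
                seen.add(canon(g))
                genes.append(g)
    return genes


_RELATION_SIGN = {"increases": +1, "+": +1, "decreases": -1, "-": -1}


def read_causal_edges(path: str | Path, default_sign: int | None = None) -> CausalGraph:
    """Read a SIF-like signed edge list.

    Three-or-four column form: ``source<TAB>relation<TAB>target[<TAB>provenance]``
    with relation in {increases, decreases, +, -}.  A two-column
    ``source<TAB>target`` dialect is accepted when ``default_sign`` is given.
    """
    graph = CausalGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                if default_sign is None:
                    raise FormatError(
                        f"{path}:{lineno}: 2-column edge needs a default sign")
                src, tgt, sign, prov = parts[0], parts[1], default_sign, ""
            elif len(parts) in (3, 4):
                src, rel, tgt = parts[0], parts[1], parts[2]
                prov = parts[3] if len(parts) == 4 else ""
                if rel not in _RELATION_SIGN:
                    raise FormatError(
                        f"{path}:{lineno}: unknown relation token {rel!r}")
                sign = _RELATION_SIGN[rel]
            else:
                raise FormatError(f"{path}:{lineno}: expected 2-4 fields")
            graph.add_edge(src, tgt, sign, prov)
    return graph


def write_causal_edges(graph: CausalGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, tgt, sign, prov in graph.edges():
            rel = "increases" if sign > 0 else "decreases"
            fh.write(f"{src}\t{rel}\t{tgt}\t{prov}\n")


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  manifest: Mapping | None = None) -> dict[str, str]:
    """Write result tables as TSVs plus a JSON run manifest.

    Column order of each table is preserved as given.  Returns the mapping
    of table name to written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")
    paths: dict[str, str] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths[name] = str(path)
    if manifest is not None:
        mpath = out_dir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(dict(manifest), fh, indent=2, sort_keys=True, default=str)
        paths["manifest"] = str(mpath)
    return paths
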