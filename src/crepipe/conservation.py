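"""Cross-condition integration: conserved items, direction summaries, clustering.

An item (a signed hypothesis or a pathway name) is conserved when it appears
in at least ``min_count`` knockdown conditions and not in the control
comparison.  Sample clustering uses Ward minimum-variance agglomeration on
the correlation distance 1 - r between samples, the standard replicate-QC
dendrogram for expression studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix

__all__ = [
    "ConservationTable",
    "conserve",
    "direction_summary",
    "ward_cluster",
    "linkage_to_newick",
]


@dataclass
class ConservationTable:
    """Item x condition presence with per-item condition counts."""

    frame: pd.DataFrame  # columns: item, condition_count, one bool per condition
    min_count: int

    @property
    def items(self) -> list[str]:
        return list(self.frame["item"])


def conserve(items_by_condition: dict[str, set[str] | list[str]],
             blank_items: set[str] | list[str] | None = None,
             min_count: int = 3) -> ConservationTable:
    """Items present in >= min_count conditions and absent from the blank.

    Rows are sorted by condition count descending, then item name.
    """
    conds = list(items_by_condition)
    if len(set(conds)) != len(conds):
        raise ValueError("condition labels must be unique")
    blank = set(blank_items or ())
    membership = {c: set(v) for c, v in items_by_condition.items()}
    all_items: dict[str, None] = {}
    for c in conds:
        for item in sorted(membership[c]):
            all_items.setdefault(item, None)
    rows = []
    for item in all_items:
        if item in blank:
            continue
        present = {c: item in membership[c] for c in conds}
        count = sum(present.values())
        if count >= min_count:
            rows.append({"item": item, "condition_count": count, **present})
    frame = pd.DataFrame(rows, columns=["item", "condition_count", *conds])
    if len(frame):
        frame = frame.sort_values(["condition_count", "item"],
                                  ascending=[False, True]).reset_index(drop=True)
    return ConservationTable(frame, min_count)


def direction_summary(directions_by_condition: dict[str, list[int]]
                      ) -> pd.DataFrame:
    """Fraction of down-regulated hypotheses per condition and pooled.

    Each condition maps to a list of hypothesis directions (+1/-1).  The
    returned table carries counts, the exact fraction (as a string rational
    alongside the float) and the rounded percentage as conventionally
    printed.  Conditions with no hypotheses are flagged with NaN.
    """
    rows = []
    total_down = total = 0
    for cond, dirs in directions_by_condition.items():
        n_down = sum(1 for d in dirs if d < 0)
        n = len(dirs)
        total_down += n_down
        total += n
        rows.append(_summary_row(cond, n_down, n))
    rows.append(_summary_row("all", total_down, total))
    return pd.DataFrame(rows, columns=["condition", "n_down", "n_total",
                                       "fraction_down", "exact", "percent"])


def _summary_row(label: str, n_down: int, n: int) -> dict:
    if n == 0:
        return {"condition": label, "n_down": 0, "n_total": 0,
                "fraction_down": float("nan"), "exact": "undefined",
                "percent": ""}
    frac = Fraction(n_down, n)
    return {"condition": label, "n_down": n_down, "n_total": n,
            "fraction_down": n_down / n, "exact": f"{frac.numerator}/{frac.denominator}",
            "percent": f"{round(100 * n_down / n):d}%"}


def ward_cluster(matrix: ExpressionMatrix) -> np.ndarray:
    """Ward linkage over samples with correlation distance 1 - r.

    r is the Pearson correlation over probes; anti-correlated samples sit at
    distance 2.  Returns the standard 4-column linkage matrix (merge ids,
    height, cluster size); heights are non-decreasing.
    """
    vals = matrix.values.to_numpy()
    n = vals.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples to cluster")
    sd = vals.std(axis=0)
    for i, s in enumerate(matrix.sample_ids):
        if sd[i] == 0:
            raise ValueError(f"sample {s!r} has zero variance")
    r = np.corrcoef(vals.T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return hierarchy.linkage(squareform(d, checks=False), method="ward")


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    inner = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)})"
    return inner + ";"
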