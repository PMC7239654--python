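"""Cross-screen comparison of hit genes by orientation-bias score.

Enrichment q-values depend on library depth and sorting stringency, which
differ between screens, so hits are compared across screens on the
orientation-bias score instead: genes significant (q < alpha, strict) in at
least one screen are collected and hierarchically clustered on their
per-screen scores to produce the heat-map row ordering.

Clustering is agglomerative with Euclidean distance and average linkage;
rows are pre-sorted by gene_id so ties break deterministically and the leaf
order is invariant to input row permutation. Missing scores (genes with no
intronic insertion in a screen) are imputed as 0 and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage


@dataclass
class ScreenComparison:
    """Heat-map-ready comparison of hit genes across screens."""

    screen_ids: list[str]
    genes: list[str]  # leaf order after clustering
    igtiob_matrix: pd.DataFrame  # genes x screens, NaN = undefined
    q_matrix: pd.DataFrame  # genes x screens

    def to_frame(self) -> pd.DataFrame:
        """Flat table: gene_id, then igtiob_<screen> and q_<screen> columns."""
        out = pd.DataFrame({"gene_id": self.genes})
        for sid in self.screen_ids:
            out[f"igtiob_{sid}"] = self.igtiob_matrix.loc[self.genes, sid].to_numpy()
        for sid in self.screen_ids:
            out[f"q_{sid}"] = self.q_matrix.loc[self.genes, sid].to_numpy()
        return out


def union_significant(
    results_per_screen: Sequence[pd.DataFrame], alpha: float = 0.01
) -> list[str]:
    """Genes with q < alpha (strict) in at least one screen.

    Ordered by (minimum q across screens, gene_id) — a stable pre-clustering
    order. Warns when the union is empty.
    """
    if not results_per_screen:
        raise ValueError("need at least one screen result table")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    min_q: dict[str, float] = {}
    for results in results_per_screen:
        for gid, q in zip(results["gene_id"], results["q_value"]):
            if np.isnan(q):
                continue
            if gid not in min_q or q < min_q[gid]:
                min_q[gid] = q
    selected = [(q, gid) for gid, q in min_q.items() if q < alpha]
    if not selected:
        warnings.warn(f"no gene reaches q < {alpha} in any screen", stacklevel=2)
    return [gid for _, gid in sorted(selected)]


def cluster_rows(matrix: pd.DataFrame) -> list[str]:
    """Leaf order of genes after hierarchical clustering of score rows.

    ``matrix`` is genes x screens, indexed by gene_id; NaN entries are
    imputed as 0 for the distance computation. Deterministic: rows are
    sorted by gene_id before linkage, so the result does not depend on the
    input row order.
    """
    if matrix.empty:
        return []
    ordered = matrix.sort_index(kind="mergesort")
    if len(ordered) == 1:
        return list(ordered.index)
    values = np.nan_to_num(ordered.to_numpy(dtype=float), nan=0.0)
    link = linkage(values, method="average", metric="euclidean")
    return [ordered.index[i] for i in leaves_list(link)]


def compare_screens(
    results_per_screen: Sequence[pd.DataFrame],
    screen_ids: Sequence[str],
    alpha: float = 0.01,
) -> ScreenComparison:
    """Build the cross-screen comparison for genes significant anywhere.

    Collects genes with q < alpha in >= 1 screen, assembles their
    orientation-bias and q matrices (NaN where a gene has no intronic
    insertions in a screen), and clusters rows into the heat-map order.
    """
    if len(results_per_screen) != len(screen_ids):
        raise ValueError("one screen_id per result table required")
    genes = union_significant(results_per_screen, alpha)
    igtiob_m = pd.DataFrame(index=genes, columns=list(screen_ids), dtype=float)
    q_m = pd.DataFrame(index=genes, columns=list(screen_ids), dtype=float)
    for sid, results in zip(screen_ids, results_per_screen):
        indexed = results.set_index("gene_id")
        present = [g for g in genes if g in indexed.index]
        igtiob_m.loc[present, sid] = indexed.loc[present, "igtiob"].to_numpy()
        q_m.loc[present, sid] = indexed.loc[present, "q_value"].to_numpy()
    leaf_order = cluster_rows(igtiob_m)
    return ScreenComparison(
        screen_ids=list(screen_ids),
        genes=leaf_order,
        igtiob_matrix=igtiob_m,
        q_matrix=q_m,
    )
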