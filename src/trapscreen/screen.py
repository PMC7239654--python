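"""Per-gene enrichment statistics for one gene-trap screen.

The analysis compares, for each gene, the number of unique *inactivating*
insertions recovered from the phenotype-sorted population against the
number of insertions (any class) recovered from the unsorted control
population, relative to the total unique insertions in each population.
Significance is a one-sided Fisher exact (hypergeometric upper-tail) test,
corrected across genes by Benjamini-Hochberg.

The intronic orientation bias score summarizes selection for gene
inactivation independently of the control library: among intronic
insertions in the sorted population, only the sense orientation
inactivates, so genes under selection accumulate an excess of sense over
antisense intronic insertions. The score is the signed bias fraction
``(S - A) / (S + A)`` in [-1, 1], undefined when a gene has no intronic
insertions.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation import GenomeAnnotation
from .insertions import (
    CLASS_INACTIVATING,
    FEATURE_INTRON,
    ORIENT_ANTISENSE,
    ORIENT_SENSE,
    InsertionDataset,
    classify_dataset,
)

#: q-values are floored here before -log10 so perfect separation does not
#: produce infinities in plot tables.
Q_FLOOR = 1e-300

#: Circle diameter per unique inactivating insertion (arbitrary plot units).
DIAMETER_PER_INSERTION = 2.0

COUNT_COLUMNS = [
    "gene_id",
    "inactivating_sorted",
    "sense_intronic_sorted",
    "antisense_intronic_sorted",
    "control_insertions",
    "total_sorted",
    "total_control",
]


def tabulate(
    sorted_ds: InsertionDataset,
    control_ds: InsertionDataset,
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Per-gene unique-insertion counts for a sorted/control screen pair.

    Returns one row per annotated gene (zero-count genes included) with the
    count columns plus the population totals ``total_sorted`` /
    ``total_control`` (all unique insertions, intergenic included).
    """
    if sorted_ds.population != "sorted":
        raise ValueError(
            f"first dataset must have population 'sorted', got {sorted_ds.population!r}"
        )
    if control_ds.population != "control":
        raise ValueError(
            f"second dataset must have population 'control', got {control_ds.population!r}"
        )

    inact = defaultdict(int)
    sense_intr = defaultdict(int)
    anti_intr = defaultdict(int)
    ctrl = defaultdict(int)

    for call in classify_dataset(sorted_ds, annotation):
        if call.gene_id is None:
            continue
        if call.classification == CLASS_INACTIVATING:
            inact[call.gene_id] += 1
        if call.feature == FEATURE_INTRON:
            if call.orientation == ORIENT_SENSE:
                sense_intr[call.gene_id] += 1
            elif call.orientation == ORIENT_ANTISENSE:
                anti_intr[call.gene_id] += 1
    for call in classify_dataset(control_ds, annotation):
        if call.gene_id is not None:
            ctrl[call.gene_id] += 1

    rows = [
        {
            "gene_id": gid,
            "inactivating_sorted": inact[gid],
            "sense_intronic_sorted": sense_intr[gid],
            "antisense_intronic_sorted": anti_intr[gid],
            "control_insertions": ctrl[gid],
            "total_sorted": len(sorted_ds),
            "total_control": len(control_ds),
        }
        for gid in sorted(annotation.gene_ids)
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def enrichment_test(
    inactivating_sorted: int,
    total_sorted: int,
    control_insertions: int,
    total_control: int,
) -> float:
    """One-sided exact enrichment p-value for a single gene.

    Tests enrichment of inactivating insertions in the sorted population
    (``a`` of ``T_s``) over the gene's insertions in the control population
    (``g`` of ``T_c``) as the hypergeometric upper-tail probability of
    drawing >= a marked insertions in the 2x2 table
    ``[[a, T_s - a], [g, T_c - g]]``.
    """
    a, ts, g, tc = inactivating_sorted, total_sorted, control_insertions, total_control
    if ts <= 0 or tc <= 0:
        raise ValueError("population totals must be positive")
    if not (0 <= a <= ts):
        raise ValueError(f"inactivating count {a} outside [0, {ts}]")
    if not (0 <= g <= tc):
        raise ValueError(f"control count {g} outside [0, {tc}]")
    # Population of T_s + T_c insertions of which a + g fall in the gene;
    # draw T_s as "sorted" and count gene insertions among them.
    return float(hypergeom.sf(a - 1, ts + tc, a + g, ts))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def igtiob(sense_intronic: int, antisense_intronic: int) -> float:
    """Intronic insertion orientation-bias score in [-1, 1].

    ``(S - A) / (S + A)`` over sense/antisense intronic insertions in the
    sorted population; NaN (undefined) when the gene has none.
    """
    s, a = sense_intronic, antisense_intronic
    if s < 0 or a < 0:
        raise ValueError("counts must be non-negative")
    if s + a == 0:
        return float("nan")
    return (s - a) / (s + a)


def screen_results(
    sorted_ds: InsertionDataset,
    control_ds: InsertionDataset,
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Full per-gene result table for one screen.

    Adds to the count table: one-sided enrichment ``p_value``, BH-FDR
    ``q_value`` computed jointly across all annotated genes, ``igtiob``
    (NaN when no intronic insertions), and the two hit flags used for
    labeling (q < 0.01) and top-hit annotation (q < 1e-4). Rows are sorted
    by (q, p, gene_id).

    When either population is empty every gene gets p = q = 1.
    """
    counts = tabulate(sorted_ds, control_ds, annotation)
    if counts.empty:
        result = counts.copy()
        for col in ("p_value", "q_value", "igtiob"):
            result[col] = pd.Series(dtype=float)
        for col in ("hit_q_lt_0_01", "hit_q_lt_1e_4"):
            result[col] = pd.Series(dtype=bool)
        return result

    if len(sorted_ds) == 0 or len(control_ds) == 0:
        p = np.ones(len(counts))
    else:
        p = np.array(
            [
                enrichment_test(
                    row.inactivating_sorted,
                    row.total_sorted,
                    row.control_insertions,
                    row.total_control,
                )
                for row in counts.itertuples()
            ]
        )
    q = bh_fdr(p)
    result = counts.copy()
    result["p_value"] = p
    result["q_value"] = q
    result["igtiob"] = [
        igtiob(s, a)
        for s, a in zip(
            counts["sense_intronic_sorted"], counts["antisense_intronic_sorted"]
        )
    ]
    result["hit_q_lt_0_01"] = q < 0.01
    result["hit_q_lt_1e_4"] = q < 1e-4
    return result.sort_values(
        ["q_value", "p_value", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)


def circle_plot_table(
    results: pd.DataFrame,
    seed: int,
    diameter_per_insertion: float = DIAMETER_PER_INSERTION,
    q_floor: float = Q_FLOOR,
) -> pd.DataFrame:
    """Data table behind the screen circle plot.

    One row per gene with ``x_rank`` (a seeded random permutation — genes
    are displayed in random order along x), ``y = -log10(q)`` with q floored
    at ``q_floor``, and ``diameter`` proportional to the number of unique
    inactivating insertions in the sorted population.
    """
    if results.empty:
        raise ValueError("results table is empty")
    table = results.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    x_rank = rng.permutation(len(table))
    q = np.clip(table["q_value"].to_numpy(float), q_floor, 1.0)
    return pd.DataFrame(
        {
            "gene_id": table["gene_id"],
            "x_rank": x_rank,
            "y_neg_log10_q": -np.log10(q),
            "diameter": diameter_per_insertion
            * table["inactivating_sorted"].to_numpy(float),
        }
    )
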