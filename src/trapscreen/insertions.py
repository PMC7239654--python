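"""Gene-trap insertion tables and strand-aware classification.

An insertion is a single mapped retroviral gene-trap integration site:
chromosome, 0-based position (the BED start) and the strand into which the
cassette integrated. Classification against a gene model follows the
standard haploid gene-trap interpretation:

* inside a union exon -> ``inactivating`` in either orientation (the
  cassette truncates the transcript regardless of splice-acceptor use);
* inside an intron -> ``inactivating`` only in the *sense* orientation
  (splice-acceptor capture requires the cassette to run with the gene);
  antisense intronic insertions are ``non_inactivating``;
* outside every gene's exon extent -> ``intergenic``.

"Inside a gene" means inside the union-exon extent ``[first exon start,
last exon end)``; promoter/flank windows are not counted. An insertion
overlapping several genes yields one call per gene.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, GenomeAnnotation, normalize_strand

POPULATIONS = ("sorted", "control")

FEATURE_EXON = "exon"
FEATURE_INTRON = "intron"
FEATURE_INTERGENIC = "intergenic"

ORIENT_SENSE = "sense"
ORIENT_ANTISENSE = "antisense"
ORIENT_NA = "not_applicable"

CLASS_INACTIVATING = "inactivating"
CLASS_NON_INACTIVATING = "non_inactivating"
CLASS_INTERGENIC = "intergenic"


class Insertion(NamedTuple):
    """A unique mapped gene-trap integration site."""

    chrom: str
    pos: int
    strand: str


@dataclass(frozen=True)
class InsertionCall:
    """Classification of one insertion relative to one gene (or none)."""

    insertion: Insertion
    gene_id: str | None
    feature: str
    orientation: str
    classification: str


@dataclass
class InsertionDataset:
    """Deduplicated insertions for one cell population of one screen."""

    screen_id: str
    population: str
    insertions: tuple[Insertion, ...]
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(
                f"population must be one of {POPULATIONS}, got {self.population!r}"
            )
        if len(set(self.insertions)) != len(self.insertions):
            raise ValueError("insertions contain duplicates after deduplication")

    def __len__(self) -> int:
        return len(self.insertions)

    @classmethod
    def from_insertions(
        cls, screen_id: str, population: str, insertions: Iterable[Insertion]
    ) -> "InsertionDataset":
        """Deduplicate and sort raw insertions into a dataset."""
        raw = list(insertions)
        unique = sorted(set(raw))
        return cls(
            screen_id=screen_id,
            population=population,
            insertions=tuple(unique),
            n_duplicates_dropped=len(raw) - len(unique),
        )


def read_insertions(
    path: str | Path, screen_id: str, population: str
) -> InsertionDataset:
    """Read a BED6-like insertion table into a deduplicated dataset.

    The insertion position is the BED start (0-based). Exact duplicate rows
    (same chrom, pos, strand) are collapsed and counted. Rows whose
    ``end != start + 1`` trigger a warning; the start is used.
    """
    path = Path(path)
    insertions: list[Insertion] = []
    odd_width = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path.name}:{lineno}: expected 6 BED fields (missing "
                    f"strand?), got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path.name}:{lineno}: non-integer coordinates"
                ) from None
            if end != start + 1:
                odd_width += 1
            insertions.append(
                Insertion(fields[0], start, normalize_strand(fields[5]))
            )
    if odd_width:
        warnings.warn(
            f"{path.name}: {odd_width} rows with end != start+1; start used "
            "as the insertion site",
            stacklevel=2,
        )
    return InsertionDataset.from_insertions(screen_id, population, insertions)


def write_bed6(dataset: InsertionDataset, path: str | Path) -> None:
    """Write a dataset as deterministic BED6 (sorted by chrom, pos, strand)."""
    with open(path, "w") as fh:
        for i, ins in enumerate(sorted(dataset.insertions)):
            fh.write(
                f"{ins.chrom}\t{ins.pos}\t{ins.pos + 1}\tins{i:06d}\t0\t{ins.strand}\n"
            )


class GeneIndex:
    """Interval index over gene exon extents for fast classification."""

    def __init__(self, annotation: GenomeAnnotation):
        self.annotation = annotation
        self._trees: dict[str, IntervalTree] = {}
        self._exon_bounds: dict[str, list[int]] = {}
        for gene in annotation.genes:
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            tree.addi(gene.start, gene.end, gene)
            # Flattened sorted exon boundaries: pos is exonic iff an odd
            # number of boundaries lie at or before it.
            bounds: list[int] = []
            for s, e in gene.exons:
                bounds.extend((s, e))
            self._exon_bounds[gene.gene_id] = bounds

    def overlapping_genes(self, chrom: str, pos: int) -> list[GeneModel]:
        if chrom not in self.annotation.chromosomes:
            raise KeyError(f"chromosome {chrom!r} absent from annotation")
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        hits.sort(key=lambda g: g.gene_id)
        return hits

    def in_exon(self, gene: GeneModel, pos: int) -> bool:
        return bisect_right(self._exon_bounds[gene.gene_id], pos) % 2 == 1


def _index_for(annotation: GenomeAnnotation) -> GeneIndex:
    index = getattr(annotation, "_gene_index", None)
    if index is None or index.annotation is not annotation:
        index = GeneIndex(annotation)
        annotation._gene_index = index  # cached; annotation treated as immutable
    return index


def classify(
    insertion: Insertion, annotation: GenomeAnnotation
) -> list[InsertionCall]:
    """Classify one insertion against every overlapping gene.

    Returns one call per overlapping gene, ordered by gene_id, or a single
    intergenic call when no gene overlaps. Raises ``KeyError`` when the
    insertion's chromosome is absent from the annotation.
    """
    index = _index_for(annotation)
    genes = index.overlapping_genes(insertion.chrom, insertion.pos)
    if not genes:
        return [
            InsertionCall(insertion, None, FEATURE_INTERGENIC, ORIENT_NA, CLASS_INTERGENIC)
        ]
    calls = []
    for gene in genes:
        orientation = ORIENT_SENSE if insertion.strand == gene.strand else ORIENT_ANTISENSE
        if index.in_exon(gene, insertion.pos):
            feature, classification = FEATURE_EXON, CLASS_INACTIVATING
        else:
            feature = FEATURE_INTRON
            classification = (
                CLASS_INACTIVATING if orientation == ORIENT_SENSE else CLASS_NON_INACTIVATING
            )
        calls.append(InsertionCall(insertion, gene.gene_id, feature, orientation, classification))
    return calls


def classify_dataset(
    dataset: InsertionDataset, annotation: GenomeAnnotation
) -> list[InsertionCall]:
    """Classify every insertion of a dataset (order-independent result)."""
    calls: list[InsertionCall] = []
    for insertion in sorted(dataset.insertions):
        calls.extend(classify(insertion, annotation))
    return calls


def calls_to_frame(calls: Iterable[InsertionCall]) -> pd.DataFrame:
    """Tabulate calls as a DataFrame (the TSV output schema)."""
    rows = [
        {
            "chrom": c.insertion.chrom,
            "pos": c.insertion.pos,
            "strand": c.insertion.strand,
            "gene_id": c.gene_id if c.gene_id is not None else ".",
            "feature": c.feature,
            "orientation": c.orientation,
            "classification": c.classification,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "gene_id", "feature", "orientation",
            "classification",
        ],
    )
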