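"""Gene annotation input/output and strand-aware interval structures.

All coordinates are normalized to a single internal convention: 0-based,
half-open ``[start, end)`` intervals, matching BED. GTF/GFF3 records
(1-based, inclusive) are converted on read. A gene is represented at gene
level only: the exons of all of its transcripts are merged into a single
union-exon set, and the gene span is clipped to the extent of that union
(first exon start to last exon end), so that exons and introns exactly tile
the span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils

Interval = tuple[int, int]

#: Strand symbols accepted on input; the unicode minus shows up in
#: hand-edited annotation tables.
_STRAND_ALIASES = {"+": "+", "-": "-", "−": "-"}


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


def normalize_strand(symbol: str) -> str:
    """Map a strand symbol to '+' or '-', rejecting anything else."""
    try:
        return _STRAND_ALIASES[symbol]
    except KeyError:
        raise AnnotationError(f"invalid strand {symbol!r}: must be '+' or '-'") from None


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, returned sorted and non-overlapping.

    Abutting intervals ([0,10), [10,20)) are merged into one.
    """
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for start, end in ivs:
        if start >= end:
            raise AnnotationError(f"empty or inverted interval [{start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand-aware set of union exons on one chromosome.

    ``exons`` are sorted, pairwise non-overlapping ``[start, end)`` intervals;
    ``span`` is the exon extent (first exon start, last exon end).
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    span: Interval
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise AnnotationError(
                    f"gene {self.gene_id}: empty exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons unsorted or overlapping at {start}"
                )
            prev_end = end
        if self.span != (self.exons[0][0], self.exons[-1][1]):
            raise AnnotationError(
                f"gene {self.gene_id}: span {self.span} does not match exon extent"
            )

    @property
    def start(self) -> int:
        return self.span[0]

    @property
    def end(self) -> int:
        return self.span[1]

    @classmethod
    def from_exons(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Iterable[Interval],
        gene_name: str | None = None,
    ) -> "GeneModel":
        """Build a gene from raw (possibly overlapping) exon intervals.

        Exons of all transcripts are unioned; the span is clipped to the
        union-exon extent.
        """
        merged = merge_intervals(exons)
        if not merged:
            raise AnnotationError(f"gene {gene_id} has no exons")
        return cls(
            gene_id=gene_id,
            gene_name=gene_name or gene_id,
            chrom=chrom,
            strand=normalize_strand(strand),
            span=(merged[0][0], merged[-1][1]),
            exons=tuple(merged),
        )


def introns(gene: GeneModel) -> list[Interval]:
    """Gaps between consecutive union exons of ``gene``.

    Exons and introns tile the gene span exactly; abutting exons yield no
    intron. Single-exon genes have none.
    """
    gaps = []
    for (_, left_end), (right_start, _) in zip(gene.exons, gene.exons[1:]):
        if left_end < right_start:
            gaps.append((left_end, right_start))
    return gaps


@dataclass
class GenomeAnnotation:
    """A set of gene models plus chromosome lengths.

    ``chromosomes`` maps chromosome name to length in bp. Gene ids are
    unique and every gene lies within its chromosome.
    """

    chromosomes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene in self.genes:
            if gene.gene_id in seen:
                raise AnnotationError(f"duplicate gene_id {gene.gene_id}")
            seen.add(gene.gene_id)
            length = self.chromosomes.get(gene.chrom)
            if length is None:
                raise AnnotationError(
                    f"gene {gene.gene_id}: unknown chromosome {gene.chrom}"
                )
            if not (0 <= gene.start < gene.end <= length):
                raise AnnotationError(
                    f"gene {gene.gene_id}: span {gene.span} outside "
                    f"{gene.chrom} [0, {length})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_FORMAT_BY_SUFFIX = {
    ".gtf": "GTF",
    ".gff": "GFF3",
    ".gff3": "GFF3",
    ".bed": "BED12",
    ".bed12": "BED12",
}


def _detect_format(path: Path) -> str:
    fmt = _FORMAT_BY_SUFFIX.get(path.suffix.lower())
    if fmt is None:
        raise AnnotationError(
            f"cannot infer annotation format from {path.name}; pass fmt= explicitly"
        )
    return fmt


def read_annotation(
    path: str | Path,
    fmt: str | None = None,
    chrom_sizes: dict[str, int] | None = None,
) -> GenomeAnnotation:
    """Read a GTF, GFF3 or BED12 annotation into a :class:`GenomeAnnotation`.

    GTF/GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open on read; exons of all transcripts of a gene are merged into a
    union-exon set. Chromosome lengths are taken from ``chrom_sizes`` when
    given, otherwise inferred as the maximum gene end per chromosome.

    Raises :class:`AnnotationError` on malformed lines (with the line
    number) and on genes that have no exon features.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or _detect_format(path)).upper()
    if fmt == "BED12":
        genes = _read_bed12(path)
    elif fmt in ("GTF", "GFF3"):
        genes = _read_gxf(path, fmt)
    else:
        raise AnnotationError(f"unsupported annotation format {fmt!r}")

    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    if chrom_sizes is not None:
        chromosomes = dict(chrom_sizes)
    else:
        chromosomes = {}
        for g in genes:
            chromosomes[g.chrom] = max(chromosomes.get(g.chrom, 0), g.end)
    return GenomeAnnotation(chromosomes=chromosomes, genes=genes)


def _validate_gxf_lines(path: Path) -> None:
    """Pre-flight line check so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path.name}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path.name}:{lineno}: non-integer coordinates "
                    f"{fields[3]!r}..{fields[4]!r}"
                ) from None
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path.name}:{lineno}: invalid 1-based interval {start}..{end}"
                )


def _read_gxf(path: Path, fmt: str) -> list[GeneModel]:
    _validate_gxf_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def gene_id_of(feature) -> str:
        if fmt == "GTF":
            return feature.attributes["gene_id"][0]
        return feature.id

    # Gene features declared in the file (may be absent in exon-only GTFs).
    declared: dict[str, gffutils.Feature] = {}
    for gene in db.features_of_type("gene"):
        declared[gene_id_of(gene)] = gene

    exons_by_gene: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # gid -> (name, chrom, strand)
    for exon in db.features_of_type("exon"):
        if fmt == "GTF":
            gid = exon.attributes["gene_id"][0]
            name = exon.attributes.get("gene_name", [gid])[0]
        else:
            parents = [p for p in db.parents(exon) if p.featuretype == "gene"]
            if parents:
                gid = parents[0].id
                name = parents[0].attributes.get("Name", [gid])[0]
            else:
                gid = exon.attributes.get("gene_id", [exon.id])[0]
                name = gid
        strand = normalize_strand(exon.strand)
        prior = meta.get(gid)
        if prior is not None and (prior[1] != exon.seqid or prior[2] != strand):
            raise AnnotationError(
                f"gene {gid}: exons on inconsistent chromosome/strand"
            )
        meta[gid] = (name, exon.seqid, strand)
        # 1-based inclusive -> 0-based half-open
        exons_by_gene.setdefault(gid, []).append((exon.start - 1, exon.end))

    for gid in declared:
        if gid not in exons_by_gene:
            raise AnnotationError(f"gene {gid} has no exon features")

    return [
        GeneModel.from_exons(gid, chrom, strand, exons, gene_name=name)
        for gid, exons in exons_by_gene.items()
        for name, chrom, strand in [meta[gid]]
    ]


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path.name}:{lineno}: expected 12 BED fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                strand = normalize_strand(fields[5])
                block_count = int(fields[9])
                block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except (ValueError, AnnotationError) as exc:
                raise AnnotationError(f"{path.name}:{lineno}: {exc}") from None
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise AnnotationError(
                    f"{path.name}:{lineno}: block count {block_count} does not "
                    f"match sizes/starts"
                )
            gene_id, _, gene_name = name.partition("|")
            exons = [
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(block_starts, block_sizes)
            ]
            genes.append(
                GeneModel.from_exons(
                    gene_id, chrom, strand, exons, gene_name=gene_name or gene_id
                )
            )
    return genes


def write_bed12(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write the normalized annotation as BED12, one record per gene.

    Blocks are the union exons; the name field is ``gene_id`` or
    ``gene_id|gene_name`` when the two differ. Output is deterministic
    (genes sorted by chromosome, start, gene_id).
    """
    genes = sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        for g in genes:
            name = g.gene_id if g.gene_name == g.gene_id else f"{g.gene_id}|{g.gene_name}"
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.start) for s, _ in g.exons)
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(g.start),
                        str(g.end),
                        name,
                        "0",
                        g.strand,
                        str(g.start),
                        str(g.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
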