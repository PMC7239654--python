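"""Shared fixtures: tiny hand-built annotations and insertion sets."""

import pytest

from trapscreen import GeneModel, GenomeAnnotation


@pytest.fixture
def two_exon_gene():
    """Plus-strand gene with exons [100,200) and [300,400) (intron [200,300))."""
    return GeneModel.from_exons("gA", "chr1", "+", [(100, 200), (300, 400)])


@pytest.fixture
def toy_annotation(two_exon_gene):
    """Two genes on chr1: gA (+, two exons) and gB (-, single exon)."""
    gene_b = GeneModel.from_exons("gB", "chr1", "-", [(600, 800)])
    return GenomeAnnotation(
        chromosomes={"chr1": 1000}, genes=[two_exon_gene, gene_b]
    )


def brute_force_classify(insertion, annotation):
    """Independent oracle: test pos against every interval of every gene.

    Returns a sorted list of (gene_id, feature, orientation, classification)
    tuples, or the single intergenic tuple.
    """
    hits = []
    for gene in annotation.genes:
        if gene.chrom != insertion.chrom:
            continue
        if not (gene.exons[0][0] <= insertion.pos < gene.exons[-1][1]):
            continue
        exonic = any(s <= insertion.pos < e for s, e in gene.exons)
        orientation = "sense" if insertion.strand == gene.strand else "antisense"
        if exonic:
            classification = "inactivating"
            feature = "exon"
        else:
            feature = "intron"
            classification = (
                "inactivating" if orientation == "sense" else "non_inactivating"
            )
        hits.append((gene.gene_id, feature, orientation, classification))
    if not hits:
        return [(None, "intergenic", "not_applicable", "intergenic")]
    return sorted(hits)
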