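"""Synthetic annotations, gene-trap screens and dose-response tables.

The screen simulator emulates the *mapped* insertion tables of a
reporter-based haploid gene-trap screen:

* each mutagenized cell carries exactly one insertion (haploid, single
  retroviral integration), uniformly positioned on the chromosome with a
  random cassette strand;
* FACS sorting is a Bernoulli gate per cell: a cell passes with
  probability ``gate_fraction`` (phi, the reporter-low gate, default 0.1),
  raised to ``phi + (1 - phi) * penetrance`` when the cell's insertion is
  *inactivating in a planted hit gene* (exonic in either orientation, or
  intronic sense);
* the sorted library is the set of unique insertions among gated cells and
  the control library the set of unique insertions among all mutagenized
  cells, each subsampled to the requested sequencing depth.

The expected per-gene enrichment for inactivating insertions in a planted
hit is ``(phi + (1 - phi) * eps) / phi`` — the closed form used by the
recovery tests. ``orientation_bias`` sets the pre-sort probability that an
intronic insertion in a hit gene lands in the sense orientation (0.5 =
unbiased library); the sense excess observed among *sorted* insertions
then arises from selection, because only sense intronic insertions
inactivate.

All generators are deterministic under ``SimulationConfig.seed`` and emit
byte-identical files on repeated runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, GenomeAnnotation, write_bed12
from .doseresponse import four_pl
from .insertions import Insertion, InsertionDataset, write_bed6

# Distinct rng streams per generator so simulate_screen(annotation, config)
# does not depend on whether the annotation came from simulate_annotation.
_STREAM_ANNOTATION = 1
_STREAM_SCREEN = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic screen."""

    seed: int = 0
    n_genes: int = 100
    chrom: str = "chr1"
    chrom_length: int | None = None  # None: sized to fit the gene layout
    n_exons_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (500, 3000)
    intergenic_gap_range: tuple[int, int] = (1000, 5000)
    n_cells: int = 50_000
    gate_fraction: float = 0.1  # phi: reporter-low FACS gate
    penetrance: float = 0.9  # eps: extra gate probability for hit inactivation
    orientation_bias: float = 0.5  # pre-sort P(sense) for intronic hit insertions
    hit_gene_ids: tuple[str, ...] = ()
    depth_sorted: int = 10_000
    depth_control: int = 20_000
    strict_depth: bool = False  # True: error if depth exceeds unique insertions

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not (0.0 < self.gate_fraction < 1.0):
            raise ValueError("gate_fraction must lie in (0, 1)")
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValueError("penetrance must lie in [0, 1]")
        if not (0.0 <= self.orientation_bias <= 1.0):
            raise ValueError("orientation_bias must lie in [0, 1]")
        if self.depth_sorted <= 0 or self.depth_control <= 0:
            raise ValueError("depths must be positive")
        for name in ("n_exons_range", "exon_length_range", "intron_length_range",
                     "intergenic_gap_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a (lo, hi) range with 1 <= lo <= hi")

    def expected_enrichment(self) -> float:
        """Closed-form sorted/control enrichment for hit-gene inactivation."""
        phi, eps = self.gate_fraction, self.penetrance
        return (phi + (1 - phi) * eps) / phi


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Generate a single-chromosome annotation of non-overlapping genes.

    Genes are laid out left to right with random intergenic gaps; strands
    are drawn uniformly, so roughly half the genes sit on each strand.
    Raises when ``chrom_length`` is given but the layout does not fit.
    """
    rng = np.random.default_rng([_STREAM_ANNOTATION, config.seed])
    genes: list[GeneModel] = []
    cursor = 0
    for i in range(config.n_genes):
        cursor += int(rng.integers(*config.intergenic_gap_range, endpoint=True))
        n_exons = int(rng.integers(*config.n_exons_range, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = cursor
        for j in range(n_exons):
            if j > 0:
                pos += int(rng.integers(*config.intron_length_range, endpoint=True))
            size = int(rng.integers(*config.exon_length_range, endpoint=True))
            exons.append((pos, pos + size))
            pos += size
        genes.append(
            GeneModel.from_exons(f"g{i + 1:04d}", config.chrom, strand, exons)
        )
        cursor = pos
    cursor += int(rng.integers(*config.intergenic_gap_range, endpoint=True))
    length = config.chrom_length if config.chrom_length is not None else cursor
    if cursor > length:
        raise ValueError(
            f"{config.n_genes} genes need {cursor} bp but chrom_length is {length}"
        )
    return GenomeAnnotation(chromosomes={config.chrom: length}, genes=genes)


def _gene_arrays(annotation: GenomeAnnotation, chrom: str):
    """Sorted extent arrays for vectorized lookup (non-overlapping genes)."""
    genes = sorted(
        (g for g in annotation.genes if g.chrom == chrom), key=lambda g: g.start
    )
    starts = np.array([g.start for g in genes], dtype=np.int64)
    ends = np.array([g.end for g in genes], dtype=np.int64)
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("simulate_screen requires non-overlapping genes")
    return genes, starts, ends


def simulate_screen(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[InsertionDataset, InsertionDataset, pd.DataFrame]:
    """Simulate one screen: (sorted dataset, control dataset, truth table).

    The truth table has one row per gene with ``is_planted_hit`` and the
    closed-form ``expected_enrichment``. Depths act as sequencing-depth
    caps: when a population holds fewer unique insertions than the
    requested depth, all of them are kept (``strict_depth=True`` turns this
    into an error instead).
    """
    unknown = set(config.hit_gene_ids) - set(annotation.gene_ids)
    if unknown:
        raise ValueError(f"hit_gene_ids not in annotation: {sorted(unknown)}")
    chrom = config.chrom
    if chrom not in annotation.chromosomes:
        raise ValueError(f"chromosome {chrom!r} absent from annotation")
    length = annotation.chromosomes[chrom]
    genes, starts, ends = _gene_arrays(annotation, chrom)
    hit_mask_by_gene = np.array(
        [g.gene_id in config.hit_gene_ids for g in genes], dtype=bool
    )
    gene_strand_neg = np.array([g.strand == "-" for g in genes], dtype=bool)
    exon_bounds = [np.fromiter((b for iv in g.exons for b in iv), dtype=np.int64)
                   for g in genes]

    rng = np.random.default_rng([_STREAM_SCREEN, config.seed])
    pos = rng.integers(0, length, size=config.n_cells)
    u_strand = rng.random(config.n_cells)
    u_gate = rng.random(config.n_cells)

    # Gene membership by exon extent (genes are non-overlapping).
    idx = np.searchsorted(starts, pos, side="right") - 1
    in_gene = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
    idx = np.where(in_gene, idx, -1)

    # Exonic membership: odd number of exon boundaries at or before pos.
    exonic = np.zeros(config.n_cells, dtype=bool)
    for gi, bounds in enumerate(exon_bounds):
        cells = np.nonzero(idx == gi)[0]
        if cells.size:
            exonic[cells] = np.searchsorted(bounds, pos[cells], side="right") % 2 == 1

    in_hit = in_gene & hit_mask_by_gene[np.maximum(idx, 0)]
    intronic = in_gene & ~exonic

    # Strand: uniform, except intronic insertions in hit genes which land in
    # the sense orientation with probability orientation_bias.
    p_sense = np.full(config.n_cells, 0.5)
    p_sense[in_hit & intronic] = config.orientation_bias
    sense = u_strand < p_sense  # for intergenic cells: '+' with p=0.5
    neg_gene = in_gene & gene_strand_neg[np.maximum(idx, 0)]
    strand_neg = np.where(in_gene, sense == neg_gene, ~sense)

    inactivating_hit = in_hit & (exonic | (intronic & sense))
    phi, eps = config.gate_fraction, config.penetrance
    gate_p = np.where(inactivating_hit, phi + (1 - phi) * eps, phi)
    gated = u_gate < gate_p

    def build_dataset(mask: np.ndarray, population: str, depth: int) -> InsertionDataset:
        keys = pos[mask] * 2 + strand_neg[mask]
        unique_keys = np.unique(keys)
        n_dropped = int(mask.sum() - unique_keys.size)
        if unique_keys.size > depth:
            pick = rng.choice(unique_keys.size, size=depth, replace=False)
            unique_keys = np.sort(unique_keys[pick])
        elif config.strict_depth and unique_keys.size < depth:
            raise ValueError(
                f"{population}: depth {depth} exceeds {unique_keys.size} "
                "available unique insertions"
            )
        insertions = tuple(
            Insertion(chrom, int(k >> 1), "-" if k & 1 else "+") for k in unique_keys
        )
        return InsertionDataset(
            screen_id=f"sim{config.seed}",
            population=population,
            insertions=insertions,
            n_duplicates_dropped=n_dropped,
        )

    sorted_ds = build_dataset(gated, "sorted", config.depth_sorted)
    control_ds = build_dataset(
        np.ones(config.n_cells, dtype=bool), "control", config.depth_control
    )

    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "is_planted_hit": hit_mask_by_gene,
            "expected_enrichment": np.where(
                hit_mask_by_gene, config.expected_enrichment(), 1.0
            ),
        }
    ).sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    return sorted_ds, control_ds, truth


def simulate_dose_response(
    bottom: float,
    top: float,
    ec50_nm: float,
    hill: float,
    doses: np.ndarray,
    noise_sd: float,
    n_replicates: int,
    seed: int,
    sample_id: str = "sim",
) -> pd.DataFrame:
    """Noisy per-well median responses on a 4PL curve.

    Returns a tidy table (sample, dose_nM, replicate, response) with
    additive Gaussian noise of standard deviation ``noise_sd`` on each
    well, deterministic under ``seed``.
    """
    doses = np.asarray(doses, dtype=float)
    if ec50_nm <= 0:
        raise ValueError("ec50_nm must be positive")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        clean = four_pl(doses, bottom, top, np.log10(ec50_nm), hill)
        noisy = clean + rng.normal(0.0, noise_sd, size=len(doses)) if noise_sd else clean
        for d, r in zip(doses, np.atleast_1d(noisy)):
            rows.append({"sample": sample_id, "dose_nM": d, "replicate": rep,
                         "response": float(r)})
    return pd.DataFrame(rows, columns=["sample", "dose_nM", "replicate", "response"])


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("n_exons_range", "exon_length_range", "intron_length_range",
                "intergenic_gap_range", "hit_gene_ids"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return SimulationConfig(**raw)


def write_screen_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write annotation BED12, sorted/control BED6, truth TSV
    and a config echo YAML into ``out_dir``. Byte-reproducible under seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    sorted_ds, control_ds, truth = simulate_screen(annotation, config)
    paths = {
        "annotation": out_dir / "annotation.bed",
        "sorted": out_dir / "sorted.bed",
        "control": out_dir / "control.bed",
        "truth": out_dir / "truth.tsv",
        "config": out_dir / "config.yaml",
    }
    write_bed12(annotation, paths["annotation"])
    write_bed6(sorted_ds, paths["sorted"])
    write_bed6(control_ds, paths["control"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    echo = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()}
    paths["config"].write_text(yaml.safe_dump(echo, sort_keys=True))
    return paths
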