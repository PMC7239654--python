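# Methods

This note documents the statistical model behind each component, the
defaults and why they were chosen, what the simulator does and does not
emulate, and the numerical choices that affect results.

## Coordinate and annotation model

All intervals are 0-based half-open `[start, end)`, the BED convention;
GTF/GFF3 input (1-based inclusive) is converted on read by subtracting 1
from starts. The analysis is gene-level: exons of all transcripts of a
gene are merged into a union-exon set, "exonic" means inside that union,
and the gene span is clipped to the union-exon extent so that exons and
introns exactly tile it. Transcript-isoform effects, UTR/CDS distinctions
and promoter/flank windows are deliberately out of scope. Chromosome
lengths are taken from an optional `chrom_sizes` mapping or inferred as the
maximum gene end per chromosome; they are metadata for simulation and
validation, not part of any statistic.

## Insertion classification

A gene-trap cassette inactivates its host gene when integrated in a
transcriptionally productive position. The rules implemented are the
standard haploid gene-trap interpretation:

* exonic insertion → inactivating in either orientation;
* intronic insertion → inactivating iff sense (cassette strand equals gene
  strand), because splice-acceptor capture requires the sense orientation;
* outside every gene's exon extent → intergenic.

An insertion overlapping several genes yields one call per gene and counts
toward each independently; overlap is rare in both simulated and typical
annotations, and this choice avoids an arbitrary tie-break.

## Per-gene enrichment

For each gene: `a` = unique inactivating insertions in the sorted
population, `g` = unique insertions (any class) in the control population,
with population totals `T_s`, `T_c` (all unique insertions, intergenic
included). The statistic is deliberately asymmetric — inactivating-only in
the sorted library versus all insertions in the control — because the
control library measures insertional accessibility, not phenotype.

The p-value is the one-sided Fisher exact test on
`[[a, T_s−a], [g, T_c−g]]`, computed as the hypergeometric upper tail
`P(X ≥ a)` with population `T_s+T_c`, `a+g` marked, `T_s` drawn
(`scipy.stats.hypergeom.sf`). The test suite verifies it against an
exact-fraction enumeration of the full support for every table with
margins ≤ 12 (max deviation at machine epsilon).

FDR correction is Benjamini–Hochberg step-up across **all** annotated
genes jointly (zero-count genes get p = 1), keeping the gene universe
fixed so q-values are comparable across screens with different hit counts.
Hit thresholds are strict: q < 0.01 for the comparative hit list,
q < 10⁻⁴ for top-hit labeling.

## Orientation-bias score

`(S − A)/(S + A)` over sense (`S`) and antisense (`A`) intronic insertions
in the sorted population only; undefined (NaN) when `S + A = 0`. It is the
simplest bounded, antisymmetric statistic of those two counts: +1 when
every intronic insertion is sense (strong selection for inactivation), 0
for an unselected gene, independent of the control library and of
sequencing depth, which is what makes it suitable for cross-screen
comparison. In comparison matrices NaN is imputed as 0 for clustering and
left NaN in the output table, so a missing score is distinguishable from a
measured zero.

## Cross-screen comparison

Genes with q < alpha (strict; default 0.01 — the relaxed threshold used so
hits unique to one screen are not missed) in at least one screen are
collected, ordered by (min q, gene_id), and clustered on their per-screen
orientation-bias scores: agglomerative, Euclidean distance, average
linkage. Rows are sorted by gene_id before linkage so ties break
deterministically and the leaf order is invariant to input row
permutation. Metric and linkage are package defaults, exposed as the
single place to change if a different clustering is preferred.

## Dose-response model

The variable-slope (four-parameter) agonist equation,

    r(d) = Bottom + (Top − Bottom) / (1 + 10^(h·(logEC50 − log10 d)))

is fitted by Levenberg–Marquardt least squares in the parameter vector
(Bottom, Top, logEC50, h) with an analytic Jacobian. Parameterizing in
log10-EC50 makes the EC50 positivity constraint implicit and the error
surface close to quadratic. Initial values: Bottom = min response,
Top = max response, logEC50 at the dose whose mean response is nearest
half-maximal, h = 1. The equation is invariant under
(Bottom, Top, h) → (Top, Bottom, −h); fits are canonicalized to
Top > Bottom so the Hill slope's sign carries the direction of the curve.

Standard errors are Gauss–Newton: `cov = (JᵀJ)⁻¹·RSS/(n−4)`; EC50 is
reported on the nM scale with the delta-method SE
`ln(10)·EC50·se(logEC50)`. A fit is **converged** only when the optimizer
succeeds, Top > Bottom, all SEs are finite, and the fitted EC50 lies
within 10× of the dosed range — a titration that never turns over cannot
support an EC50 claim, so none is reported. Zero-dose (untreated) wells
are excluded from the fit (log-dose undefined).

Potency comparisons: fold-change is the plain EC50 ratio; the two-tailed
unpaired t-test uses the two fit SEs with Welch–Satterthwaite degrees of
freedom computed from each fit's residual df (n − 4). This operates at the
level of curve-fit uncertainty, not replicate-level EC50s; with equal
variances and equal residual dfs it reduces to the pooled df. "Efficacy"
is operationalized as the fitted dynamic range Top − Bottom relative to a
reference fit.

## Synthetic data

The simulator generates the statistical structure the analysis assumes,
not the sequencing process:

* **Annotation**: `n_genes` non-overlapping genes laid left-to-right on
  one chromosome with uniform random strands; exon count 2–8, exon length
  100–300 bp, intron length 500–3000 bp, intergenic gaps 1000–5000 bp —
  compact gene models that give each gene enough insertional target while
  keeping simulated chromosomes around 1 Mb for 100 genes.
* **Screen**: each of `n_cells` cells carries one insertion (haploid,
  single integration), uniform in position, random strand. Sorting is a
  Bernoulli gate: pass probability φ (`gate_fraction`, default 0.1 — the
  reporter-low decile gate), raised to φ + (1−φ)·ε for cells whose
  insertion is inactivating in a planted hit gene. ε (`penetrance`,
  default 0.9) absorbs reporter effect size and gate position; the
  expected sorted/control enrichment for hit-gene inactivation has the
  closed form (φ + (1−φ)·ε)/φ (= 9.1 at defaults), which the recovery
  tests check. `orientation_bias` (default 0.5, unbiased) is the pre-sort
  sense probability of intronic hit-gene insertions; the sense excess
  among *sorted* insertions emerges from selection, since only sense
  intronic insertions inactivate. Libraries are the unique insertions of
  the gated cells (sorted) and of all cells (control). Sequencing depths
  (defaults 10 000 / 20 000) act as caps: when a population holds fewer
  unique insertions than the requested depth — routine for the sorted
  gate, which passes ~φ·n_cells cells — all of them are kept;
  `strict_depth=True` makes a shortfall an error instead.
* **Default scale**: 100 genes and 50 000 cells keep a 10-seed recovery
  experiment and a 20-seed null calibration in seconds while leaving
  per-gene control counts (~100–200) deep enough for the exact test to
  resolve hits at q < 10⁻⁴.
* **Titrations**: per-well responses are the 4PL curve plus i.i.d.
  Gaussian noise (`noise_sd`), emulating noise on per-well median reporter
  fluorescence. The noisy-recovery benchmark uses 8 three-fold dilutions
  from 10 nM with the true EC50 (0.2 nM) at the grid's geometric center —
  the design a titration experiment aims for — with 2 replicates and
  noise sd = 5% of Top.

Not emulated: insertion hotspots and mappability bias, multi-insertion
cells, PCR/duplication artifacts, read-level errors, continuous reporter
fluorescence (the gate is a Bernoulli reduction of FACS), and
between-replicate systematic shifts in titrations. Tests passing on this
generator therefore demonstrate correctness of the statistics under the
stated model, not robustness to those real-data artifacts.

All generators draw from `numpy.random.default_rng` seeded with
(stream, seed) pairs — separate streams for annotation and screen, so
screen output does not depend on whether the annotation was generated or
loaded — and emit byte-identical files under a fixed seed.

## Numerical choices

* Exact-test tail via `hypergeom.sf(a−1, …)`: exact in double precision
  for the table sizes screens produce.
* q-values floored at 1e-300 before −log10 in plot tables.
* Optimizer tolerances 1e-15 (xtol/ftol/gtol) so noiseless titrations are
  recovered to ~1e-9 relative, far inside the 1e-6 contract.
* Circle-plot x positions are a seeded random permutation
  (`default_rng(seed).permutation`), reproducible by construction.
* Degenerate inputs: constant-response titrations short-circuit to a
  non-converged fit; empty insertion files are valid (all-zero counts,
  p = 1 everywhere); an empty significant-gene union warns and yields an
  empty comparison.

## Known limitations

* The enrichment test and orientation-bias score are the package's own
  minimal faithful formulations of the screen statistics; laboratories
  with an established in-house formula can swap the single functions
  `enrichment_test` and `igtiob`.
* The EC50 t-test assumes approximate normality of the EC50 estimate on
  the nM scale; for poorly constrained fits the log-scale interval would
  be more faithful.
* BED12 output stores no chromosome lengths; round-trips preserve all
  intervals but recover lengths only from `chrom_sizes` or gene extents.
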