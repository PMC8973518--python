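# Methods

This note records the models, conventions and design choices behind
`marseq`, in the order the pipeline applies them.

## Coordinates and interval algebra

All intervals are 0-based half-open (`[start, end)`), the BED convention;
GFF3 input (1-based inclusive) is converted on read. Merging collapses every
maximal run of intervals in which each overlaps **or directly abuts**
(`end == next start`) the next — the behaviour of `bedtools merge` with
distance 0, which is the de-facto standard for MAR peak post-processing.
Merging is idempotent and preserves covered bases; both properties are
enforced by tests against a per-base occupancy oracle.

The seven-region partition of three peak sets first merges each input, then
merges their union and assigns every union interval to exactly one region
(`onlyA` … `ABC`) by presence/absence: an interval belongs to a set when
their total overlap is at least `min_overlap` bp (default 1 bp, matching the
`bedtools intersect` default; the threshold is exposed because different
intersect variants behave differently). A union interval covering two peaks
of the same set counts that set once — region counts are reported, not pair
counts. If a large `min_overlap` leaves an interval below threshold for
every input, it is assigned to the input covering it most, so the seven
counts always sum to the union size.

## Chromosome statistics and loop length

Densities are `count / size_Mb`, reported raw and rounded to two decimals
with half-away-from-zero rounding (the convention that reproduces published
two-decimal density tables exactly; banker's rounding does not). Chromosomes
present in the peaks but absent from the size table abort in strict mode; in
lenient mode they are pooled into a residual `unplaced` row carrying counts
only, so genome-wide totals are conserved even when per-chromosome tables
exclude unplaced scaffolds.

Chromatin loop length is the distance between consecutive MARs on a
chromosome. The anchor is the peak **midpoint** by default (an `end → next
start` gap mode is provided); the overall average is the mean of
per-chromosome means by default, with a pooled global mean as the
alternative. Both choices are flags because neither anchor nor aggregation
is standardized in the literature, and published averages generally cannot
be recomputed from per-chromosome count tables alone. Chromosomes with
fewer than two MARs contribute nothing. On peaks planted at exactly uniform
spacing every mode returns the planted spacing exactly, which is the
property the acceptance checks use.

Correlation between chromosome-level quantities (e.g. MAR count vs gene
density) is the Pearson product-moment coefficient with Spearman's rho as a
robustness companion; zero variance in either variable yields a missing
value rather than an arbitrary number.

## Annotation

Context classification uses the precedence exon > intron > non-genic: a MAR
overlapping any exon by ≥ 1 bp is exonic, otherwise any gene-body overlap
makes it intronic, otherwise it is non-genic. Totals always equal the number
of classified MARs.

TSS distances are signed and strand-aware: the distance from the MAR
midpoint to the nearest TSS, positive downstream of the TSS in the gene's
orientation (on the − strand the TSS is `gene_end − 1` and the sign flips).
The midpoint anchor is a deliberate choice — peak summits are not available
after merging. Ties between equidistant TSSs resolve to the smaller gene id
for determinism. Distances within ±window (default 100 kb) are binned
(default 10 kb); a distance of exactly +window falls into the last bin. The
profile is invariant under coordinate translation of all inputs.

Gene-flank reports restrict each dataset's merged peaks to
`[gene_start − flank, gene_end + flank)` (clipped at zero) and, for three
datasets, re-partition the restricted sets to count window-local unique and
common MARs. Pathway joins count distinct MAR-associated genes per pathway
and return genes missing from the mapping explicitly rather than dropping
them.

## Motif catalog and scanning

Patterns are written as literal IUPAC segments separated by fixed spacers:
`n_k_` denotes k unconstrained bases; a bare `n` inside a segment is IUPAC
N. Parsing is case-insensitive and whitespace-tolerant because published
catalog tables are typeset inconsistently (e.g. a lower-case `Ta` or spaced
`CA n_3_`). The shipped catalog is m_1–m_18: three ORI motifs, three
TG-rich, three curved-DNA, six kinked-DNA permutations, two
topoisomerase-II consensus sites and the AT-rich `WWWWWW`. For the
mitochondrial-type topo-II signal two printed variants circulate (18
positions vs 15); the 18-position form is shipped as `m_16` and the short
variant is available as the optional alias `m_16a`.

Scanning is exact gapped matching: a hit requires every segment to match at
its offset under IUPAC semantics. An `N` in the *sequence* fails every
pattern position except pattern-`N`, so masked regions cannot inflate
AT-rich counts. All overlapping hits are reported. The default is
forward-strand scanning for reproducibility of counts; `strands="both"`
scans the reverse complement and maps hits back to forward coordinates. The
implementation compiles patterns to lookahead regular expressions; tests
compare it hit-for-hit against a naive per-position matcher on thousands of
random sequences.

The MRS detector finds all 8-mer (`AATAAYAA`) and 16-mer
(`AWWRTAANNWWGNNNC`) element matches — on both strands by default, the
behaviour of the classical implementation, with a strict forward-only mode —
and reports every deduplicated (8-mer, 16-mer) pair whose inter-element gap
is at most 200 bp (overlapping elements count as gap 0, either element may
come first).

Abundance reporting distinguishes **total hits** (distinct
(motif, start, strand) triples summed over sequences) from **presence
percentage** (share of sequences with ≥ 1 hit); category-level presence
counts a sequence once if any motif of the category hits it.

## SSR detection

Following the MISA conventions used for MAR repeat analysis: perfect tandem
arrays of units of 2–6 bp with at least 5 copies (`min_reps` uniform across
unit sizes, as configured in the motivating analysis; MISA's shipped
per-size defaults differ and can be restored via the parameter), detected as
maximal k-periodic regions with the repeat count truncated to whole copies.
A run whose unit is itself a tandem of a smaller allowed unit is reported
only at the smaller size; mononucleotide runs are excluded by default and do
not resurface as fake dinucleotide records. When two maximal periodic
regions of the same unit size abut so closely that their tandem spans would
overlap (possible when a chance base restarts the periodicity one position
later), the later record is trimmed to start at the earlier one's end, so
same-size spans never overlap. Units are reported exactly as found — no
rotation or reverse-complement canonicalization, since e.g. the silkworm
telomeric repeats TTAGG and CCTAA are conventionally listed separately.

Simple SSRs separated by at most 100 bp (`max_interruption`) are
additionally grouped into compound records; the simple members remain in
the output, so unit summaries count compound members individually.

## TE hit filtering

Alignment itself is external; the module consumes 12-column blast tabular
hits. Hits below 90 % identity or 100 bp aligned length are removed, with
boundary values retained (≥, not >). Per-TE occupancy merges overlapping
alignment spans per target sequence before summing, so stacked hits are not
double-counted. Filtering is monotone in both thresholds.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated: three chromosomes of 1.6 Mb (a ~4.8 Mb genome — large enough for
hundreds of well-separated peaks and dozens of genes, small enough that the
whole suite runs in seconds), GC fraction 0.38 matching the AT-rich
silkworm genome, 50 three-exon genes per chromosome, peaks 200–400 bp long
(the enriched size range of matrix-attached fragments), and a default
seven-region overlap design (union 146) that scales the motivating
datasets' peak counts and common/unique proportions down to this genome
size. Motif planting rates mirror the observed presence percentages of the
motif categories (AT-rich 0.92, ORI 0.77, curved 0.15, kinked 0.12,
TG-rich 0.02, topo-II 0.01, MRS 0.09).

Peaks are placed without replacement on a coarse slot grid (slot = max peak
length + 2 bp), which guarantees ≥ 2 bp separation cheaply so that merging
can never fuse two distinct truth regions; a region shared between datasets
is the identical interval in each. Planted motifs sample one concrete
expansion per degenerate position; planted SSRs are perfect tandems flanked
by guard bases chosen to break the periodicity, so the detector reports
exactly the planted unit rather than a rotated frame extended by a chance
flanking base; planted MRS pairs use separations ≤ 200 bp. All randomness
flows from one seeded PCG64 generator with fixed consumption order, making
bundles byte-identical across runs and platforms.

What the generator does **not** emulate: read-level noise and mapping
artefacts (the pipeline starts from peaks), irregular exon structure,
overlapping genes, nested or imperfect repeats, TE sequence evolution
(TE hits are synthesized directly at the tabular-hit level), and chromosome
size heterogeneity. Passing the suite therefore demonstrates algorithmic
correctness on idealized inputs, not robustness to peak-calling noise.

## Numerical and degenerate-input conventions

- Empty interval sets produce empty histograms/series, never errors.
- Chromosomes with < 2 MARs have missing (NaN) loop length, not 0.
- Zero-variance correlation inputs give NaN coefficients.
- Density rounding is half-away-from-zero at 2 decimals; raw values are
  retained alongside.
- BED parse errors name the 1-based line number; pattern compile errors name
  the offending character.
- The pipeline aborts on the first stage error (named), but cleanly skips
  stages whose optional inputs are absent.

## Validation problem sizes

The test suite and acceptance script use: per-base oracle comparisons on
≤ 100 kb of sequence; 1,000 random sequences (80–320 bp, AT-rich) for
scanner-vs-oracle equivalence with a rotating 4-pattern subset of the
catalog per sequence plus periodic MRS and SSR cross-checks; a full
synthetic bundle (146 regions, ~320 planted features) for recovery and the
end-to-end pipeline; and 100 kb of uniform-random sequence for the SSR
background false-positive bound (≤ 5 simple records at the default
threshold). These sizes were chosen so the complete validation runs in
well under a minute while every check remains exact rather than sampled.

## Known limitations

- `venn_partition` is specified for exactly three sets (the seven-region
  decomposition); two-set or k-set comparisons are not provided.
- Motif scanning is exact-match over IUPAC classes; there is no
  position-weight-matrix scoring, background model, or de novo discovery.
- SSR detection is perfect-tandem only (no mismatched/approximate repeats).
- Pathway reporting is a counting join; no enrichment statistics are
  computed.
- Published aggregate quantities that depend on the original peak
  coordinates (e.g. dataset-level loop-length averages or motif hit
  totals) cannot be recomputed from summary tables alone; the package
  validates the corresponding operations by exact recovery of planted
  ground truth instead.
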