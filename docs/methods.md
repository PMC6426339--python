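# Methods

## The problem

DamID tethers *E. coli* Dam methylase to Lamin B1 so that DNA contacting
the nuclear lamina acquires adenine methylation (m6A) at GATC motifs.
After DpnI digestion (cuts methylated GATC only), adaptor ligation, DpnII
counter-selection (destroys templates with an unmethylated GATC) and PCR,
sequencing reads report which *DpnI fragments* — the intervals between
adjacent GATC sites — were near the lamina.  A soluble Dam-only control
normalizes for accessibility and amplification bias.  Lamina-associated
domains (LADs) appear as broad blocks of positive
log2(LaminB1-Dam / Dam-only) signal covering up to roughly half the genome,
from tens of kilobases to several megabases long.

`damidkit` implements the computational half of this assay: in-silico
digestion, alignment QC with mitochondrial-contamination accounting,
normalized ratio profiles, circular binary segmentation (CBS), rule-based
LAD calling, and a generative simulator so every stage is testable against
known truth without external data.

## Coordinate system

All intervals are 0-based, half-open (BED convention).  DpnI cleaves GA^TC
leaving blunt ends, so the cut coordinate is `motif_start + 2`; fragments
are the intervals between consecutive cuts plus the two terminal
intervals.  Runs of N produce no motifs and fragments may span them;
assembly gaps are handled downstream by gap subtraction.  Soft-masked
(lower-case) bases are treated as ordinary bases.  Fixed-size bins
(2–5 kb is a good starting range) are a drop-in alternative coordinate
system via `build_bin_map`.

## Alignment QC

"Ambiguous" alignments are operationalized as mapping quality below
`mapq_min` (default 10) plus secondary/supplementary records; the
mitochondrial contigs `chrM`/`MT`/`chrMT` are recognized by default.  The
report mirrors standard DamID accounting: total, mapped (`n_mapped_chrs`,
after the ambiguity filter, mitochondria included), `% chrM` of mapped,
and post-filter counts, with the unmapped/ambiguous breakdown kept
explicit.  Warnings fire below 30 M clean reads (the recommended minimum
for a mammalian genome), above 26% chrM (the top of the range we treat as
unexceptional for primary cells), and above 50% unmapped (possible foreign
DNA such as mycoplasma, which is otherwise a wet-lab PCR check upstream of
this tool).  Excluded contigs are also dropped from the fragment map
before quantitation: after QC they have zero counts in both samples, and a
pseudocount-only ratio is pure normalization offset.

## Profiles

Counts per fragment use overlap semantics by default (a read increments
every fragment it overlaps by at least 1 bp); midpoint assignment is
available.  Normalized counts are proportions of the sample's filtered
read total, so overlap-mode proportions can sum to slightly more than 1 by
design.  The signal is

    value[f] = log2( ((c_L[f] + p) / T_L) / ((c_D[f] + p) / T_D) )

with pseudocount `p = 1` read guaranteeing finite values on zero-count
fragments.  Quantile normalization (applied across whatever set of
profiles is supplied; a single profile is a no-op) maps each rank to the
across-profile mean of that rank, ties receiving the mean of the reference
values they span — verified against limma's `normalizeQuantiles` in the
test suite.  Smoothing replaces each value by the mean of itself and `n/2`
fragments on each side (21 values at the default `n = 20`); windows
truncate at chromosome ends and never cross chromosomes; odd `n` rounds
down with a warning.  Smoothing runs after normalization by default, with
a switch for the reverse order.  Strand is ignored throughout (Dam
methylation is strand-symmetric at GATC).

## Circular binary segmentation

Each chromosome's value vector is split recursively at the circular arc
`(i, j]` maximizing a two-sample t statistic (pooled variance with a
1e-12 floor) between the arc and its complement.  The statistic is
symmetric under complementation, so contiguous arcs cover the wrapped
ones; on exact |T| ties the elevated arc wins, then the smallest `i`, then
the smallest `j`.  A split is accepted when the permutation p-value
`(1 + #{perm >= obs}) / (1 + n_perm)` is below `alpha`; defaults
`alpha = 0.01`, `n_perm = 1000`, `min_width = 2`.  Recursion stops on
pieces shorter than `2 * min_width` or with zero variance.  All
randomness flows from one seeded generator traversed in deterministic
order, so output is reproducible bit-for-bit.

Numerical strategy: |T| at fixed arc width is monotone in the centered arc
sum, so each width contributes only its extreme arcs.  Segments up to
2000 fragments are scanned at every width; longer segments use a
geometric width grid (ratio 1.02) with local refinement for boundary
placement.  The permutation decision always evaluates the observed and
permuted maxima on the same width set (every width ≤ n/2 for segments up
to 64 fragments, a coarser 1.2-ratio grid above), keeping the test a
like-for-like exchangeability comparison at any size, and permutation
batches stop early once significance is impossible.  The DNAcopy-style
"undo splits" pruning is deliberately omitted: the downstream
threshold/merge/size rules subsume its role, at the cost of transient
over-segmentation of smoothed (autocorrelated) noise that never reaches
the final calls.

## LAD calling

Four steps in fixed order: subtract assembly gaps (UCSC gap-table BED),
keep segments with mean strictly above `tau` (default 0; up to ~0.1 for
noisy data), merge intervals separated by at most `max_gap` bp (default
5000, from the 5–8 kb range that avoids fragmenting large LADs), and drop
intervals shorter than `min_size` bp inclusive (default 10000, inside the
5–30 kb range used depending on noise).  Boundary semantics (strict `>`,
inclusive `>=`, gap `<= max_gap`) are pinned by tests, including
cross-checks against `bedtools subtract`/`bedtools merge`.  LAD-set
comparison is binary presence/absence: base-pair Jaccard plus
nearest-boundary distances.

## The simulator

The generator follows the assay's mechanism rather than drawing
log-ratios directly:

1. **Genome** — i.i.d. uniform ACGT chromosomes plus a 16 kb `chrM`
   contig.  GATC density is ~1/256 per position, giving a median DpnI
   fragment of ~177 bp (geometric inter-motif law); the real mouse map's
   ~260 bp median reflects sequence composition the i.i.d. model does not
   emulate.
2. **LAD truth** — disjoint blocks with log-uniform lengths over
   [30 kb, 2 Mb], placed with ≥ 20 kb separation until the coverage target
   (default 0.4) is met.
3. **Methylation and amplicons** — every internal GATC site is methylated
   independently: with the lamina-contact probability (0.9 inside LADs,
   0.1 outside) in the LaminB1 sample, with the accessibility constant
   0.95 in the Dam-only sample (optionally dipped inside LADs, peripheral
   DNA being less accessible to free Dam).  A fragment is an amplifiable
   template iff *both* flanking sites are methylated — the DpnI/DpnII
   selection — so terminal fragments never amplify.  The accessibility
   default is deliberately high: the Dam-only control works because free
   Dam labels accessible chromatin broadly, and a sparse Dam channel
   would turn low-coverage noise into depth-independent structural
   artifacts.
4. **Reads** — per-fragment Poisson counts with mean proportional to
   amplifiable-indicator × fragment length, times `2^enrichment`
   (default 2.0) for LaminB1 fragments inside LADs; read starts are
   uniform within the fragment (length 90 bp), and a `chrm_fraction`
   (default 0.15, inside the 7–26% range seen in primary hepatocytes) of
   each sample's reads lands uniformly on chrM.

`enrichment` is a *rate* contrast in log2 units on top of the
methylation-level selection.  It is not the realized mean in-LAD log
ratio: per-sample proportions sum to ~1, which caps the genome-wide mean
in-LAD proportion ratio at about −log2(coverage-weighted LaminB1 share),
so a literal mean-level target is not a free parameter.  The realized
in-LAD mean is measured, not assumed, by the recovery tests.

What passing tests show — and what they do not: the simulator produces
realistic zero-count fragments, LAD-scale block structure, mitochondrial
contamination and depth-dependent interLAD noise, so parameter-recovery
results demonstrate the pipeline's logic end to end.  It does not emulate
mappability or GC bias, PCR duplicates, sequence-composition-driven
fragment-size structure, adaptor artifacts, or biological replicate
variation; performance on real libraries depends on those factors and on
read depth.

## Numerical and degenerate-input choices

Pseudocount 1 read in both samples; variance floor 1e-12 in the CBS
statistic; constant vectors and chromosomes with fewer than 4 fragments
yield a single segment; empty alignment inputs produce zeroed reports
with warnings rather than errors; reads on contigs absent from the
fragment map are tallied and skipped; a zero-read track refuses
normalization.  Permutation p-values use the add-one estimator, which is
valid (never anti-conservative) at any `n_perm`.

## Problem sizes used in the checks

The end-to-end recovery runs a 40 Mb genome over 4 chromosomes with 2 M
reads per sample (≈ 156 k fragments, matching real per-fragment depth at
~30 M reads on a mammalian genome); smoothing-behavior checks use 6 Mb /
0.05–0.4 M reads with means over several seeds; CBS calibration uses 500
pure-noise vectors of 50 fragments at `alpha = 0.05` and oracle
equivalence 500 planted-changepoint vectors of length 12–50.  These sizes
make every behavior measurable at desk scale while preserving the
per-fragment statistics of a full experiment.

## Known limitations

- CBS split decisions on heavily smoothed profiles are anti-conservative
  (the permutation null assumes exchangeability, smoothing induces
  autocorrelation); the calling rules absorb the resulting
  over-segmentation, but segment counts themselves should not be
  interpreted before post-processing.
- Exact numeric agreement with DNAcopy is not claimed; behavioral
  agreement is enforced via the exhaustive-scan oracle and calibration
  tests.
- BigWig output is delegated to the external `wigToBigWig` tool
  (`wigToBigWig profile.bedGraph chrom.sizes profile.bw`); the package
  writes bedGraph.
- Differential LAD analysis between conditions is limited to binary
  presence/absence comparison; windowed signal-intensity differences are
  out of scope.
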