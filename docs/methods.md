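# Methods

## Scope and data model

`cnvpop` analyses per-individual *windowed read-depth tracks*: one integer
read count and one zero-mapping-quality (q0) read fraction per fixed window
(default 100 bp) per chromosome. Upstream steps of a resequencing study —
trimming, alignment, duplicate removal, liftover between assemblies — are out
of scope; the pipeline consumes depth tracks (bedGraph-like text) and emits
BED-like TSVs. Coordinates are 0-based half-open everywhere inside the
package; 1-based inclusive conversion happens only when reading files
declared with the `one-based` dialect and when rendering report spans.

## Synthetic cohort generator

The generator (`cnvpop.synthetic`) emulates the statistical structure the
caller assumes, not sequencing itself:

* **Copy-number truth.** CNV loci are placed disjointly genome-wide (one
  window of clearance), snapped to window boundaries (the caller's native
  resolution, making recovery tests exact), with lengths drawn uniformly
  from `cnv_length_range` and rounded to whole windows. Each locus is a
  deletion (true CN drawn from `{0, 1}`) or duplication (`{3, 4}`) with
  probability `duplication_fraction` (default 0.3, reflecting the strong
  excess of deletions over duplications in read-depth CNV surveys).
  *Shared* loci receive carriers in every group (carrier probability
  `shared_frequency`, default 0.6); *differentiated* loci carry at
  `diff_freq_high` (0.9) in one group and `diff_freq_low` (0.1) in the rest.
* **Depth noise.** Window counts are negative-binomial with mean
  `mean_depth × CN/2` and variance `μ + α·μ²`; α (`overdispersion`, default
  0.02) interpolates to Poisson at 0. Default `mean_depth` is 30 reads per
  window, matching the ~30× coverage typical of resequencing CNV studies.
* **q0 track.** Beta-distributed around `q0_baseline` (default 0.05) with
  concentration 50; designated regions can be inflated to exercise the q0
  filter.
* **Defaults as study conditions.** `cnv_length_range = (1200, 8000)` bp
  (mean ≈ 4.6 kb) emulates the detectable, filter-surviving CNV class
  (> 1 kb) whose reported mean length in sheep resequencing is ≈ 4.3 kb.

What the generator does **not** model: GC-content waves (flat by default; a
sinusoidal `gc_bias` knob exists solely to exercise the GC-bin median
normalization), mapping artefacts correlated across individuals, repetitive
regions with structured q0, breakpoint microhomology, mosaic states, and sex
chromosomes with non-diploid baselines. Passing recovery tests therefore
demonstrates correctness of the *method* under its own noise assumptions,
not performance on real genomes, where segmentation behaviour depends on
artefacts the generator omits.

## Read-depth caller

1. **Normalization.** `rd = 2 × count / mean(count)` over autosomal windows.
   The default mean is 10 %-trimmed (each tail) so that large planted or real
   events do not bias the diploid baseline; the plain mean is available by
   configuration and makes the genome-mean-of-rd = 2 identity exact. An
   optional GC correction divides counts by their GC-bin median (50 bins)
   before rescaling. Sex chromosomes (X/Y names) are excluded from the
   baseline and calls on them are flagged, since their ploidy differs.
2. **Segmentation.** The partition into constant-CN segments is this
   package's explicit, deterministic stand-in for mean-shift read-depth
   partitioners: for each bandwidth h ∈ {2, 4, 8, 16} windows the rd track is
   Gaussian-smoothed (σ = h) and boundaries are declared where the absolute
   adjacent difference of the smoothed track exceeds t·σ̂ₕ, with σ̂ₕ the
   robust (1.4826 × MAD) SD of that scale's smoothed differences. Estimating
   σ̂ per scale is what makes one threshold constant t workable across the
   whole schedule: after smoothing at bandwidth h the noise in adjacent
   differences shrinks like h^(−3/2) while a true step's signature shrinks
   only like h^(−1), so small scales localise boundaries precisely and large
   scales catch shallow events. Within an above-threshold run only the peak
   difference becomes a breakpoint; scales are processed small-to-large and a
   coarser breakpoint is discarded when a finer one lies within h windows.
   Finally adjacent segments with |Δmean| < ε = 0.3 are merged iteratively
   (smallest gap first), which also absorbs spurious breakpoints. The default
   t = 3.5 keeps the spurious call rate on pure diploid simulations below one
   filtered call per 10 Mb while retaining > 99 % sensitivity for |ΔCN| ≥ 1
   events ≥ 1.2 kb at 30×.
3. **Calling and genotyping.** Segments with |mean rd − 2| > 0.5 become
   candidates; CN is the segment mean rd (so diploid = 2, matching the copy
   -number scale on which the 0.4/1.6 class bounds are defined); significance
   is a two-sided one-sample t-test of the segment's windows against the
   genome mean rd. This approximates, but does not reproduce, the
   multiple-testing-adjusted e-values of mean-shift callers. One-window
   segments cannot carry a t-test: they are emitted with e-val = 1 (never
   passing the filter) and flagged. q0 over an interval is read-weighted;
   an interval with zero reads (homozygous deletion) gets q0 = 0 so that
   absence of reads never disqualifies a deletion.
4. **Filtering.** Keep iff e-val < 0.01 AND size > 1000 bp AND q0 < 0.5.
   The size bound is strict: a call of exactly 1 kb is removed.

## CNVR construction and summaries

CNVRs are connected components of the ≥ 1 bp-overlap graph over filtered
calls from all individuals. Abutting half-open intervals do not merge —
"overlapping" is taken literally, and the half-open convention makes the
criterion crisp. When an individual contributes several calls to one region,
its region-level CN is their length-weighted mean. Classification uses the
diploid-scale bounds deleted < 0.4 ≤ conserved ≤ 1.6 < duplicated; region
type is *deletion*/*duplication*/*both* by which non-conserved states occur.
A region whose member CNs are all conserved (e.g. heterozygous deletions near
CN 1) keeps the label implied by its member call types, so a deletion-only
region never silently becomes typeless. By default a single supporting
individual suffices to found a CNVR (the aggregation rule as usually quoted);
a stricter recurrence rule can be imposed downstream by filtering on the
number of supporting individuals.

Summaries report counts by type, total length (Mb), mean length (kb), and
genome fraction (%), all rounded to two decimals with ties away from zero —
the convention of printed cohort tables (Python's default banker's rounding
would, e.g., print 1,747,604 / 32 as 54612.62 instead of 54612.63). The
count-versus-chromosome-length relationship is the R² of an ordinary
least-squares fit of per-chromosome CNVR count on chromosome length; it is
undefined (NaN) for fewer than two chromosomes or degenerate spreads. The
genome-fraction denominator is the summed length of the chromosomes actually
analysed.

## Interval comparisons

External catalogues, QTL tables and gene annotations are loaded as labelled
interval sets with a declared coordinate dialect (`bed` or `one-based`).
Cross-study overlap counts a *reference* record as overlapped when it shares
at least one base with any query CNVR, and reports the percentage over the
reference catalogue's size — the denominator convention that reproduces
published comparison tables. QTL association reports the number of query
CNVRs hitting at least one QTL, the number of distinct trait labels hit, and
per-label overlap-pair counts. Gene capture keeps genes covered completely or
at least 50 % (inclusive) *of the gene's length*, summed across the disjoint
query regions; the gene-anchored reading is the natural one for
"completely and partially overlapped genes", though a CNVR-anchored variant
is conceivable — the threshold is a parameter (`min_fraction`).

## VST

VST = (V_T − V_S)/V_T per window, with V_T the pooled sample variance of the
two groups' signals and V_S the group-size-weighted mean of the within-group
sample variances. Choices a user should know:

* **Signal.** Normalized read depth on the diploid scale substitutes for the
  SNP-array log-R ratio of the original formulation: resequencing has no
  LRR, and normalized RD is the copy-number-proportional signal available per
  window.
* **Sample variances** use the n − 1 denominator (small groups; this makes
  the hand-checkable arithmetic unambiguous: A = {1.8, 2.2, 2.0} vs
  B = {0.9, 1.1, 1.0} gives V_T = 0.32, V_S = 0.025, VST = 0.921875).
* **Monomorphic windows** (V_T = 0) contribute VST = 0 — an invariant region
  is by definition undifferentiated.
* **Region value** is the unweighted mean over the CNVR's windows.
* **Candidate selection** supports both a top-fraction rule (default 5 %,
  ceil of fraction × n) and a top-k rule (default 5); both conventions
  circulate and the package reports the threshold actually applied; ties at
  the cut are all kept.

No permutation significance is attached to VST; the statistic ranks regions.

## qPCR validation

CN = 2 × 2^(−ΔΔCt) with ΔΔCt differenced against a user-designated calibrator
sample (the diploid anchor; which sample served as calibrator must be chosen
by the analyst). Triplicates are averaged on the Ct scale before
differencing, standard ΔΔCt practice; a replicate SD above a configurable
bound flags (not rejects) the estimate. Amplification-efficiency correction
and standard curves are out of scope. Concordance maps qPCR CN through the
same 0.4/1.6 state bounds; a target is *confirmed* when states agree in a
strict majority of its matched samples (default), in all samples (`strict`),
or with any CN below 1.6 accepted for a deletion prediction (`lenient`,
tolerant of heterozygous deletions) — agreement had to be given an operational
definition, and all three are reported explicitly in the output.

## Determinism and numerical notes

* Every stochastic component flows from one mandatory integer seed; truth
  sets and depth tracks are bit-identical across reruns, and the pipeline's
  stage outputs are byte-identical for a fixed config.
* Per-individual streams derive from `(seed, individual index)` seed
  sequences, so adding an individual does not reshuffle others' data.
* Segment means are merged by weighted average; the merge loop always takes
  the currently smallest adjacent gap, making tie behaviour deterministic.
* Degenerate inputs: empty call lists produce empty CNVR lists and all-zero
  summaries (mean length and R² reported as NaN); zero-read intervals get
  q0 = 0; a zero-variance segment against a differing genome mean gets
  e-val 0, against an equal mean e-val 1.

## Problem sizes used in the shipped checks

The test suite and acceptance script run on deliberately small instances
chosen to exercise every code path at desk scale: caller recovery uses 20
seeds × one 3 Mb chromosome × 15 planted loci per seed (≈ 300 scoreable
events), VST recovery 10 seeds × 16 individuals × 0.8 Mb, oracle
cross-checks 120 random instances on ≤ 100 kb toys, and the demo pipeline an
8-individual, 1.5 Mb cohort. These sizes were chosen as the smallest that
give stable statistics for the stated thresholds (sensitivity ≥ 0.90, median
CN error ≤ 0.3, median boundary error ≤ 2 windows, differentiated-deletion
VST ≥ 0.8).

## Known limitations

* The segmentation is a transparent approximation of mean-shift partitioning,
  not a reimplementation; exact segment boundaries and e-values will differ
  from CNVnator-class callers on the same data.
* CN is estimated from mean depth only; no genotype likelihoods, no mosaic
  or fractional states beyond what the depth implies.
* VST on normalized depth inherits depth noise; with few individuals per
  group the statistic is coarse, and no significance is attached.
* The generator's independence of windows (no autocorrelated artefacts)
  makes the false-positive analysis optimistic relative to real data.
* Liftover, enrichment analysis (GO/KEGG), primer design and BAM parsing are
  intentionally out of scope.
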