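# Methods

This note documents the statistical models, conventions and design
choices behind each stage of `nmiscape`, and what the synthetic-data
generator does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open `[start, end)`. GTF
(1-based inclusive) is converted at the I/O boundary and nowhere else;
BED and bedGraph pass through unchanged. The TSS of a minus-strand gene
is `end − 1` (the last base of the half-open span), symmetric with the
plus-strand definition. Chromosome names are used verbatim — there is no
`chr` normalisation — and a validation pass raises on cross-file
mismatches rather than silently dropping chromosomes. Promoter windows
"±w" around a TSS base t denote the half-open span `[t − w, t + w + 1)`,
so the window is symmetric and contains the TSS itself; with `w = 0` it
degenerates to the TSS base. Coverage tracks default to 1-bp bins
(exactness first); coarser binning is available for profile speed.

## Nucleotide statistics and CGI prediction

GC content is `(N_C + N_G) / L` and CpG O/E is `N_CpG · L / (N_C · N_G)`,
with ambiguous (N) bases excluded from the counted length and from all
counts alike — counting Ns in the denominator would deflate GC in
assembly gaps. A CpG split across an interval edge is not counted, and
counting is strand-agnostic (CpG is its own reverse complement). The
ratio is defined as 0 when `N_C · N_G = 0`. Each interval is paired with
a control region of the same length starting 10 kb upstream of its start;
controls that would underrun position 0 are flagged absent, not shifted,
since shifting would bias control composition near contig edges.

CGI prediction uses the classic thresholds as configurable defaults:
window 200 bp (step 1 bp), GC ≥ 0.50, CpG O/E ≥ 0.60, minimum island
length 200 bp. The island definition is: take the union of the footprints
of all qualifying windows, extract maximal runs, and keep runs of at
least `min_length` bp whose whole-run GC and O/E also pass both
thresholds. This "merged qualifying window" criterion is the package's
own operational definition (window-based CGI algorithms differ in their
extension rules); an all-substring brute-force oracle in the test suite
pins its semantics exactly. One consequence is that island edges can
extend up to one window length into flanking sequence whose windows still
qualify. Prediction is monotone in both thresholds.

## NMI calling

Bio-CAP enrichment has no strand-shift structure, so no fragment-model
building is performed; the caller is a windowed Poisson test, which is
all the downstream analysis requires (intervals plus a q-value filter).
Sliding windows of `bandwidth` (default 300 bp, step bandwidth/2) are
scored by the Poisson upper tail `P(X ≥ k | λ)` where `k` is the window's
read count (coverage area / read length, rounded) and

    λ = max(local input reads × input_scale, genome-wide sample rate × bandwidth)

with `input_scale` the sample/input total-read ratio. The max with the
genome-wide rate guards against spuriously low local input. p-values are
Benjamini–Hochberg corrected across all windows genome-wide (one global
q threshold, default 0.01); windows also passing the fold filter
(default ≥ 2) are merged when within `merge_gap` (default = bandwidth)
and the statistics are recomputed on each merged island, with the island
q-value adjusted against the full window-test family. A zero-read input
falls back to the uniform genome-wide expectation with a warning. Output
is deterministic, ordered by (chrom, start). Duplicate libraries are
assumed pooled upstream by summing tracks. The caller's false-call rate
under a null (no-enrichment) simulation respects the q-level bound; note
the Poisson test is anti-conservative under overdispersed coverage, which
the fold filter absorbs in practice.

## Annotation

Gene-relative annotation is a strict, category-level hierarchy across all
protein-coding genes: TSS (≥ 1 bp overlap with the ±1 kb promoter
window) ≻ gene body ≻ upstream/downstream (strand-oriented 5-kb flank
measured from the gene-span boundaries) ≻ intergenic. Every NMI receives
exactly one category; when several genes tie at the winning level the
gene with the nearest TSS to the NMI midpoint is assigned (gene id as
final tie-break, so annotation is deterministic). Intergenic NMIs are
sub-classified by first match in a fixed priority order — lncRNA TSSs,
other ncRNA TSSs, other TSSs (pseudogene/processed transcript), H3K4me1
enhancer peaks, novel RNA-seq TSSs — using ±1 kb windows for all TSS
tiers and raw ≥ 1 bp overlap for peaks; no match means `unexplained`.
All overlap thresholds are a single base pair; no fractional-overlap
options are offered.

The overlap-significance utility re-places query intervals uniformly at
random on their own chromosomes (lengths preserved, mutual overlap not
forbidden) and reports `(1 + #{null ≥ observed}) / (n_perm + 1)`. Uniform
placement ignores isochore structure, so for GC-correlated features the
test is anti-conservative relative to composition-matched sampling; it is
a significance utility, not a headline statistic.

## Conservation

For 1:1 orthologue pairs with boolean NMI-at-TSS status on each side, the
conservation score is `n / min(x, y)` — shared NMI-positive pairs over
the smaller species-wise NMI-positive count — defined as 0 when
`min(x, y) = 0`. Significance is the hypergeometric upper tail
`P(X ≥ n)` conditioning on x and y as fixed margins (one-sided,
Fisher-style). Status maps are produced by the same ±1 kb TSS-overlap
machinery as annotation, so the promoter definition lives in one place.
Pairs missing from a status map are dropped and counted. The three-way
partition tallies the 8 presence/absence cells of a 1:1:1 table.

## Tissue comparison and differential expression

An NMI is `unique` to its tissue when it overlaps no NMI of the other
tissue by even one base pair, else `shared`; the relation is per-tissue
and need not be 1:1 (one NMI may overlap several in the other tissue).
Strata summaries report length and CpG-per-bp quantiles for the
tissue × status groups.

Differential expression is deliberately a dispersion-free simplification:
median-of-ratios size factors (per sample, median ratio to the per-gene
geometric mean over genes observed in all samples), then per gene an
exact binomial rate test on the rounded pooled normalized counts of the
two tissues (success probability = replicate-count share; two-sided by
tail doubling, capped at 1), BH correction, and a call rule of q < 0.05
together with a pseudocount-1 normalized-mean ratio beyond 2-fold either
way. The raw threshold is interpreted on BH-adjusted values. Under
negative-binomial overdispersion the rate test is anti-conservative; the
fold filter absorbs nearly all of that in the flag decision (the null
false-flag rate is ~0.1 %), and callers needing DESeq-class inference can
inject an external results table through `de_results_from_table`, which
applies the same thresholds. MA coordinates use pseudocount 1; an
all-zero gene has M = 0, p = 1 and is never flagged.

The tissue association test restricts the gene universe to genes with a
TSS-associated NMI in at least one tissue and, per tissue t, tabulates
{has unique-in-t promoter NMI} × {flagged overexpressed in t}, reporting
the sample odds ratio (Haldane 0.5 correction when a cell is zero) and a
one-sided Fisher exact p for enrichment.

## Signal profiles

Point profiles average a coverage track in fixed windows (default 6 kb,
120 bins) centred on points, reversing minus-strand rows so bin 0 is
always 5′; points off their chromosome are dropped with a count, and
window parts beyond chromosome edges are NaN, excluded from column
means. Heatmap matrices centre on interval midpoints and order rows by
class, then descending length, then (chrom, start) — deterministic and
independent of input order. Metagene profiles rescale each gene body to
`n_body_bins` and each flank of `flank_gene_lengths × gene length` to
`n_flank_bins` using area-preserving fractional-bin means of the
cumulative signal (unbiased for genes shorter than the bin count, unlike
nearest-position sampling). Bin counts (50 bp bins; 100 body bins) are
package defaults, not literature values. Profiles report raw mean density
by default; per-library scaling is the caller's choice of input track.

## Broad-NMI and polycomb analysis

Gene NMI coverage is the exact per-base intersection of the merged NMI
footprint with the gene's genomic span (introns included; gene length is
genomic length). Classes use strict inequalities: broad > 0.9, short in
(0, 0.1), none = 0, intermediate otherwise — the four classes partition
the universe, and genes between 10 % and 90 % are kept explicit rather
than silently dropped. GO enrichment is a hypergeometric upper tail per
term with at least one query hit, the mapping taken as given (no
true-path ancestry propagation), sorted by p with a BH column; any
p-cutoff is an output filter only. Chromatin-mark association compares
broad-class genes against "canonical" genes (an NMI within ±1 kb of the
TSS but not broad): a gene is mark-associated when ≥ 1 bp of the mark
peak set overlaps its NMI footprint (the NMI intervals touching its span
or promoter window); a gene-span overlap mode is available. The 2×2
table is tested one-sided (Fisher) with a Haldane-corrected sample odds
ratio.

## The synthetic-data generator

The generator emulates exactly the statistical structure the analysis
assumes, no more:

* **Sequence.** Each segment class (background, promoter/broad island,
  plastic island) is drawn from a first-order Markov chain whose
  transition matrix is solved in closed form so the stationary base
  distribution hits the target GC and the expected CpG rate equals
  `O/E × π_C × π_G`: the C row fixes `P(G|C) = O/E · π_G` and the common
  A/G/T row follows from stationarity. Defaults: background GC 0.41,
  O/E 0.20; islands GC 0.60, O/E 0.90; plastic islands O/E 0.65.
  Realized statistics land within ±0.05 of targets at these scales.
  A `zebrafish_mode` preset sets island GC equal to background (the
  regime where composition-based prediction fails) and `chicken_mode`
  maximises the contrast.
* **Layout.** One chromosome (default 1 Mb) divided into evenly spaced
  slots with ±2 kb jitter, randomly assigned to genes (default 40, spans
  2–6 kb, random strand) and plastic islands (default 10), which
  guarantees plastic islands sit ≥ 5 kb from any gene. Infeasible
  packings raise before any sequence is generated. Canonical islands
  (0.8–2 kb) centre on the TSS; broad islands cover the whole gene span
  plus 200 bp (> 90 % coverage by construction); plastic islands are
  short (0.3–0.6 kb). A configurable fraction (default 0.15) of
  canonical promoter islands is made tissue-specific — non-methylated in
  one tissue only — to emulate methylation-plastic promoters; plastic
  islands are always non-methylated in exactly one tissue.
* **Bio-CAP tracks.** Sample reads arise from a uniform background at
  `input_depth` (default 1× coverage) plus `capture_efficiency` (default
  10) expected reads per CpG that is non-methylated in the profiled
  tissue, each read (51 bp, the typical single-end read length of the
  assay era) placed within a 300-bp fragment window around its CpG; the
  input track carries the background only. All counts are
  negative-binomial (variance μ + φμ², default φ = 0.05; Poisson at
  φ = 0). The capture efficiency is a free parameter chosen to make
  calling comfortably feasible, not a claim about assay chemistry.
* **Expression and chromatin.** Counts are negative-binomial (lognormal
  base means around 200, default 4 replicates per tissue, sample size
  factors in [0.7, 1.3]); genes with tissue-specific promoter islands
  are preferentially made truly differentially expressed (|log2FC| = 2)
  in the direction of their non-methylated tissue, topped up with random
  genes to `de_fraction` (default 0.2). H3K4me3 coverage sits over
  islands only in tissues where they are non-methylated; H3K27me3
  intervals cover broad islands with probability 0.9 and canonical ones
  with 0.05; H3K4me1 covers plastic islands with probability 0.7. The GO
  mapping carries 20 random terms plus one term planted among broad-NMI
  genes at 5× the base annotation probability.
* **Orthologues.** Species are generated independently; island presence
  at orthologous promoters in species > 1 copies species 1 with
  probability `conservation_rate` (default 0.9) and is otherwise redrawn
  from `island_presence_rate`. The expected pairwise conservation score
  is therefore `r + (1 − r)·p`, which the recovered score matches within
  ±0.02 at 5,000 pairs. A lightweight orthologue-status simulator
  provides this at scales a desk-sized genome cannot.

Determinism: one global seed; every stage derives a sub-seed from
(seed, stage labels) via SHA-256, so any stochastic stage can be replayed
alone and identical configs are byte-identical.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: mappability, repeats and assembly gaps;
fragment-size and GC biases of library preparation; isochore-scale
composition structure; partial methylation and cell-type mixtures;
transcript-level annotation complexity (one TSS per gene); sequence
homology between species (orthologue sharing is imposed, not evolved).
Recovery rates on this generator are upper bounds on real-data
performance, while the *contrasts* (composition-blind calling vs
composition-based prediction; shared-vs-unique strata; broad/polycomb
coupling) are the properties the suite actually certifies.

## Problem sizes

The test suite and acceptance script run on 0.25–1 Mb genomes with
40–50 planted islands, 2,000-gene count matrices, 5,000 orthologue
pairs and a few hundred Monte-Carlo repetitions — sizes at which every
checked statistic has comfortable margin over its Monte-Carlo error while
a full run stays in the seconds-to-minutes range on one CPU.

## Known limitations

The Poisson window test ignores replicate structure and overdispersion
(pool replicates upstream; interpret q-values with the fold filter). The
DE test is anti-conservative without the fold filter. The randomization
overlap test is anti-conservative for GC-correlated features. GO
enrichment does not propagate term ancestry. The CGI definition is one of
several in circulation; its brute-force oracle, not any external
implementation, defines this package's semantics.
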