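# Methods

## The detection problem

A DART fusion protein (APOBEC1–YTH for C-to-U, ADARcd–YTH for A-to-I)
converts m6A occupancy into point mutations. Sequencing then yields, at
every transcribed position, a count of reads supporting each nucleotide.
Detection reduces to finding positions where the mutant fraction in the
DART sample is high enough, and sufficiently enriched over a negative
control, to be attributed to YTH-directed deamination rather than to
sequencing noise, SNPs/RNA variants, or deaminase-intrinsic off-targets.
Each confound has a dedicated mechanism:

- sequencing noise and one-off artifacts — replicate concordance;
- positions edited regardless of methylation (variants, control-condition
  editing) — the fold-enrichment test against the control;
- deaminase-intrinsic off-targets — blacklist subtraction of positions
  edited when the deaminase is expressed alone;
- C-to-U calls outside the m6A consensus — the RAC motif filter
  (C-to-U mode only; A-to-I editing is near, not adjacent to, m6A and has
  no positional consensus, so that mode never applies a motif filter).

## Pileup counting

`build_pileup` counts, per reference position, reads whose aligned base is
A, C, G or T, in reference-plus-strand space. Coverage is defined as the
sum of the four counts: bases below the quality threshold, Ns, deletions
and reference skips contribute to neither the counts nor the coverage, so
the invariant `coverage == A+C+G+T` holds by construction. CIGAR handling
follows SAM semantics (M/=/X consume query and reference, I query only,
D/N reference only). Inputs must be coordinate-sorted and de-duplicated;
sortedness is verified and violations name the offending read.

Defaults `min_base_quality = 25`, `min_mapping_quality = 10` are
conventional for editing-site detection, where a miscalled base directly
mimics the signal; both are exposed as flags. Strand is *not* resolved at
counting time — a C-to-U event on a minus-strand gene appears as G>A in
plus-strand counts — because strand is an annotation property, resolved by
the caller through the gene index.

## Site calling

For a position assigned to a gene of known strand, the (ref, alt) pair is
fixed by the edit type and strand (C2U: C>T on plus, G>A on minus; A2I:
A>G / T>C). With `n_ref`, `n_alt` the counts of those two bases:

- edit ratio `r = n_alt / (n_ref + n_alt)`. The denominator is the ref+alt
  pair rather than total coverage, so unrelated mismatches at the position
  do not dilute the ratio; a flag-controlled alternative using total
  coverage is deliberately not provided because the pair denominator is
  also what the coverage threshold is applied to, keeping the two tests
  consistent.
- called iff `n_ref + n_alt >= 10`, `n_alt >= 2`, `0.05 <= r <= 0.95`
  (bounds inclusive), the control has `>= 10` ref+alt reads, and
  `r >= 1.2 × r_control`.

Decisions where the procedure is underdetermined:

- **Zero control editing passes the fold test.** `r_control = 0` is maximal
  enrichment; requiring a finite fold would discard exactly the cleanest
  sites.
- **Thin control coverage fails the position.** With fewer than
  `min_control_coverage` control reads the enrichment is unmeasurable, and
  an unmeasurable enrichment is not evidence of methylation.
- **Control replicates are pooled** (counts summed) before the ratio is
  computed, maximizing control coverage for the fold test;
  per-replicate-control calling is available by invoking the caller once
  per control.
- **Unannotated positions are not callable**: without a strand the ref/alt
  pair is ambiguous.
- **The genome check is optional.** When a FASTA is supplied, positions
  whose reference base does not match the edit type's source base are
  skipped outright. Without one, the threshold arithmetic excludes nearly
  all such positions anyway (a non-C position has ratio ~0 or ~1).
- The YTH-blocking control is the same computation with a different
  control matrix; `control_kind` is recorded as metadata only.

Replicate merging keeps sites called in at least `min_replicates` (default
2) replicates; the merged record carries summed counts, the arithmetic
mean of per-replicate edit and control ratios, and the support count.

## Filters

The RAC filter tests the transcript-strand trinucleotide ending at the
edited C: plus-strand genes read the genome at `[pos-2, pos]`, minus-strand
genes the reverse complement of `[pos, pos+2]`. Ambiguous bases (N) and
windows off the contig edge fail conservatively. Both filters return exact
subsets of their input — sites pass through unmodified — so filter order
cannot change the final set, and replicate → motif → blacklist is fixed
merely for the auditability of the per-stage counts.

Blacklist matching is by exact key (contig, position, strand, edit type):
the blacklist records editing *events*, not genes, and a site seen in any
single deaminase-alone replicate is removed. When deaminase-alone count
matrices (rather than ready site lists) are given, the pipeline derives the
blacklist by scanning them with the same coverage/alt-read/ratio-low bar
but no upper ratio bound, no control and no fold test — any reproducible
editing by the deaminase alone disqualifies the position regardless of
level.

## Site statistics

**Metagene.** Each site of a coding gene, exonic on the gene's canonical
transcript, maps to [0, 3): the 5′UTR, CDS and 3′UTR each rescale linearly
to one unit, measured 5′→3′ on the transcript strand; the CDS start maps to
exactly 1.0 and belongs to the CDS (half-open regions). Regions are
equal-width rather than rescaled by median region lengths — the profile is
a site-distribution summary, not a length-corrected density; intronic sites
are excluded (metagene space is exonic) but tallied. The canonical
transcript is the one with the longest CDS (ties: longest exonic length,
then smallest transcript id) — a stable, annotation-version-independent
choice.

**Distance to reference.** For each edit site, the signed offset to the
nearest same-contig, same-strand reference site within ±W (default 1000 nt;
positive = edit 3′ of reference on the transcript strand). Offsets are
genomic, not spliced: the references of interest (miCLIP-style single-base
calls) are overwhelmingly within the same exon as the edit. Ties in
absolute distance break toward the 5′ offset for determinism. Sites with no
reference in the window are excluded and counted.

**Shuffle null.** Sites are re-placed uniformly at random, without
replacement, over the exonic positions of their own transcript — conserving
per-transcript counts and exon containment, which is exactly what makes it
a null for *positional* association. No motif matching or coverage
weighting is imposed on the shuffle. Deterministic under a fixed seed.

**Edit-ratio comparison.** Two-sided Mann–Whitney U with midrank ties:
exact null distribution when `min(n, m) <= 8` and the data are tie-free,
otherwise the normal approximation with tie and continuity correction
(computed via scipy); degenerate all-tied samples return p = 1. ECDF tables
are emitted for plotting.

**Gene-set overlap.** Case-normalized string matching; consensus = genes in
≥ `min_support` sets, plus pairwise intersection counts. Identifier
mapping (e.g. Ensembl → symbol) is the caller's responsibility.

## The synthetic generator

`simulate_reference` lays out 30 genes (1–3 exons, UTR/CDS lengths drawn
from realistic ranges, both strands over 2 contigs) on a random genome and
plants 200 true sites, 60% in 3′UTRs and 30% in CDS — mirroring the known
concentration of m6A around stop codons and proximal 3′UTRs. Each C-to-U
truth site is written into the genome as an R-A-C context on the transcript
strand with the edited C one base 3′ of the methylated A (contexts are kept
within single exons so genomic and spliced context coincide, and sites are
spaced ≥ 6 nt apart within a transcript so contexts cannot collide).

Counts are drawn per position and replicate: coverage ~ NegBin(mean 50,
dispersion 10); edited reads ~ Binomial(coverage, rate) at positions whose
transcript-strand base is the source base, where the rate is background
(0.005) plus, at truth sites, the site's rate (Beta(3, 7), mean 0.3) in the
DART condition or 0.1× that rate in the control — modeling the
binding-deficient control's residual m6A affinity. Rates add and cap at 1.
Thirty artifact positions, drawn from eligible non-truth positions, carry
an additional 0.3 editing rate in the DART and deaminase-alone conditions
but not in the control. This asymmetry is a deliberate generator choice:
it makes blacklist subtraction the *only* mechanism that can remove those
positions, so the end-to-end tests exercise it; a generator that also
edited artifacts in the control would let the fold filter mask a broken
blacklist. `simulate_alignments` realizes the same rate model as fixed-
length, perfect-quality single-end reads placed within single exons, so
`build_pileup` can be tested end to end against the counts model.

What the generator does *not* emulate — sequencing errors, quality-score
variation, splice-junction reads, alignment artifacts, SNPs, expression-
level variation between genes, or positional autocorrelation of coverage.
Passing tests therefore demonstrate the correctness of the counting,
thresholding and filtering logic under the model the caller assumes, not
robustness to alignment pathologies in real libraries.

All randomness flows from a single seed through named `SeedSequence`
streams per (condition, replicate), so any subset of samples is
reproducible independently.

## Problem sizes and numerical choices

The default scenario (30 genes, ~45k exonic positions, 9 count matrices,
200 truth sites) is large enough that recovery metrics are stable to a few
sites across seeds (sensitivity 95–99%, FDR ≤ 1% in practice) while the
whole suite runs in well under a minute of simulation time. Ratios and
meta-coordinates are plain float64; site tables serialize floats via
`repr` so read(write(x)) == x exactly; fold enrichment at zero control
editing is stored as infinity and serialized as `inf`.

## Known limitations

- Read-strand-aware counting for directional libraries is not implemented;
  strand is resolved via annotation only.
- Distances are genomic; a transcript-space mode (bridging exon junctions)
  is not provided.
- BED12 input uses the name field as both transcript and gene id (the
  format carries no gene attribute).
- The caller loops over positions in Python; for transcriptome-scale
  matrices (~10^8 positions) a vectorized path would be needed.
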