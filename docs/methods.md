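# Methods

## Scope and model

`karyocut` implements the computational side of CRISPR/Cas9-mediated
whole-chromosome elimination: finding sequences that let one sgRNA (or a
small cocktail) cut a single chromosome many times, predicting where else
those guides could cut, and auditing edited samples by whole-genome
sequencing.  Wet-lab steps (delivery, FISH, karyotyping) and the upstream
read alignment / variant calling (e.g. speedseq, FreeBayes, LUMPY) are out
of scope; the audit consumes their outputs in standard formats.

## Target-site model

A target site is a 23-bp window: a 20-nt spacer immediately 5′ of a 3-nt
PAM on the targeted strand, with `NGG` as the SpCas9 default.  Both
strands are scanned; overlapping sites (including +/− pairs sharing bases)
are counted separately because each is an independent cleavage
opportunity.  The PAM pattern accepts IUPAC codes; an `N` *in the pattern*
matches any concrete base but never an assembly-gap `N` in the genome, and
spacers containing `N` are dropped — gaps never participate in matches.

**Chromosome specificity** is judged on exact matches only: a spacer
family is chromosome-specific when every exact occurrence lies on one
chromosome.  Mismatch-tolerant uniqueness is a separate audit
(`offtargets`), mirroring the separation between screening and off-target
prediction.  Families with ≥ 2 copies are the multi-cut substrate; the
`min_copies` filter is monotone by construction.

**Clustered vs scattered.**  A chromosome-specific multi-copy family is
*clustered* when its footprint (first occurrence start to last occurrence
end) is at most `max_span_fraction_clustered` (default 0.10) of the
chromosome length, otherwise *scattered*.  The underlying dichotomy is
qualitative; 10% reproduces the archetypes (a multi-copy gene cluster on
one arm vs a repeat family spread along the chromosome) and is exposed as
a knob.  A `max_region_span` bound (default 2 kb) additionally extracts
clustered families confined to small regions, useful for minimizing
collateral damage on a retained homologue when targeting non-coding DNA.

## Off-target search

For a spacer, every stranded window with a pattern-conformant PAM is
scored by Hamming distance over the 20-nt spacer region; hits within
`max_mismatches` (default 5) are reported with mismatch positions indexed
from the PAM-distal end.  Mismatches are counted uniformly — no
seed-region weighting — because the prediction step being reproduced is a
pure mismatch-count cutoff.  The PAM itself must match exactly; the
default off-target PAM is `NGG` (not the laxer `NRG`), configurable for
parity experiments.  The implementation is a vectorized full scan and is
required by the test suite to agree bit-exactly with a naive sliding
window on every input.

## Cocktail design

Given named loci on one chromosome, the designer selects up to
`guides_per_locus` sites per locus whose spacers are genome-unique (exact
copy number 1), taken leftmost-first with lexicographic tie-breaks, with
chosen start positions ≥ `min_pairwise_gap` apart (default 50 bp —
interpreted as start-to-start distance, which with 23-bp sites guarantees
non-overlapping cuts).  Ranking is positional, not efficiency-scored:
determinism is the design priority, and no on-target activity model is
assumed.  Loci with too few candidates contribute what they have plus a
warning.  An optional audit re-screens selected guides at ≤ 3 mismatches
and reports near-matches without rejecting guides.

## WGS audit cascade

Small variants (one record per ALT allele, 0-based positions converted
from VCF on read) pass through, in order:

1. **Germline subtraction** — removed iff a control sample has the exact
   (chrom, pos, ref, alt).  Allele-exact matching is deliberate; looser
   positional matching would need thresholds with no principled default.
2. **Repeat mask, then microsatellite mask** — removed iff the reference
   footprint `[pos, pos + len(ref))` (1-bp anchor for insertions) shares
   ≥ 1 base with a mask interval, half-open.
3. **Homopolymer-indel filter** — an indel is removed iff its
   inserted/deleted sequence is a single repeated base *and* the
   surrounding reference run of that base is ≥ `min_run` (default 3) bp.
   The underlying artifact class is mono-nucleotide slippage in
   homopolymer runs; the run threshold interprets a "unit length > 2 bp"
   rule that is literally contradictory for homopolymers (whose unit is
   1 bp) as the run-length criterion the indel-artifact literature
   intends.

Each record is removed by the first filter that fires, so fates partition
the input and per-stage counts are non-increasing; all filters are
idempotent.  Survivors are flagged (not removed) when their footprint
overlaps a predicted 23-bp off-target site; the flagged set is emitted as
a review list, standing in for the manual-inspection step that cannot be
automated.

Structural variants: control subtraction uses same SV type plus both
breakends within ±10 bp (SV callers report imprecise breakends; exact
matching would subtract nothing); masking removes SVs with *either*
breakend in a mask; survivors are flagged when a breakend falls within
`[site.start − 250, site.end + 250)` of an off-target site (boundary
inclusive at exactly 250 bp upstream, exclusive at 251), and the
on-target rearrangement check flags any surviving SV with a breakend
inside an on-target site, with no flank.

## Copy number from depth

Per chromosome, `copy = 2 · median(bin depths) / median(pooled autosomal
bin depths)`, reported raw and rounded half-up.  The autosomal median
anchors copy 2 exactly, which makes the estimator scale-invariant (any
global coverage factor cancels); a chromosome with no aligned reads
yields copy 0.  Medians rather than means keep single high-coverage bins
(collapsed repeats) from biasing whole-chromosome calls.

## Synthetic fixtures

The generator emulates the sequence architectures the screen must
resolve: clustered families (all copies inside a stated span), scattered
families (first and last copies pinned to the outer 5% of the chromosome
so the footprint always exceeds the clustered threshold, the rest
stratified), genome-unique sites grouped into loci, and decoys at an
exact Hamming distance with an intact PAM.  Background is i.i.d. uniform
base composition (configurable GC).

Two mechanisms keep truth tables exact rather than probably-right:

- **Collision-safe planting.**  A planted multi-copy site must not spawn
  *shifted* windows whose spacer recurs identically across copies (a GG
  or CC dinucleotide near a spacer end, or a PAM-adjacent G, can serve as
  the PAM of such a window).  Family spacers therefore exclude GG/CC
  dinucleotides, the PAM's first base is non-G, and each copy's two
  flanking bases per side are redrawn per copy (non-C left, non-G right in
  genome orientation, covering both planting strands by symmetry).
- **Emission-time rejection.**  After planting, the genome is re-scanned;
  if any truth entry disagrees with an actual screen, or the background
  produced an accidental multi-copy family, the whole genome is redrawn
  (bounded attempts).  Everything is reproducible from the seed.

Audit fixtures place masks, off-/on-target sites and per-branch variant
zones in fixed disjoint regions with randomized positions and alleles, so
every cascade branch fires at least `per_branch` (default 3) times with
known fates.  The hand-built `toy_audit` fixture (30 variants, 10 SVs on
two small chromosomes of known repeating sequence) enumerates every fate
and both window boundaries explicitly.  Depth tables draw each bin from
Poisson(`mean_depth · copy / 2`) with `mean_depth` = 30× diploid coverage
and 500 bins per chromosome, matching a standard binned-WGS readout.

What the fixtures do *not* emulate: real repeat-family sequence
divergence (planted copies are identical), GC-driven coverage waves and
mappability dropouts in depth, caller-specific artifact spectra in
variant/SV sets, and read-level data (no FASTQ/BAM; depth is simulated at
the bin level).  Passing tests therefore demonstrate algorithmic
correctness on the defined models, not robustness to every artifact of
real sequencing.

## Problem sizes and numerics

The test suite and acceptance script run on genomes of 40–160 kb, 20-seed
sweeps, and 500-bin depth tables — sizes at which the brute-force oracles
remain exact and the full suite completes in well under a minute, while
exercising every code path at realistic copy numbers (6–24 per family).
The scanner itself is vectorized and handles megabase-scale FASTA
directly; exact-copy counting on a real chromosome is the same
`count_cleavage_sites` code path.  All outputs are deterministically
ordered (lexicographic tie-breaks everywhere); rounding of copy numbers
is half-up; interval arithmetic is uniformly half-open.

## Known limitations

- No on-target efficiency scoring (Doench/Azimuth), no bulge-tolerant
  off-target matching, no CFD/MIT specificity scores, and no Cas variants
  beyond a configurable PAM pattern.
- Chromosome specificity treats every FASTA record as a chromosome;
  unplaced scaffolds, if present, count against specificity.
- The screen operates on the primary sequence as given (unmasked,
  case-insensitive); soft-masking information is ignored.
- SV mask overlap uses breakends only, not the full span; germline SV
  subtraction tolerance (±10 bp) is configurable but heuristic.
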