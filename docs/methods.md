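# Methods

## Overview

`stlfrasm` is a reference-assisted, haplotype-resolved local assembly
pipeline for stLFR linked-reads. The reference genome is used twice: to
place barcoded reads (and hence reconstruct the long fragments they came
from) and to call variants by comparing haploid contigs back against it. The
variants themselves, however, come from de novo assembled sequence, which is
what lets a short-read library express deletions and insertions far longer
than a read.

## Fragment reconstruction (barcode deconvolution)

Reads are grouped by (barcode, chromosome) — unmapped, secondary,
supplementary and unbarcoded records excluded and counted — and each group
is scanned in position order. A new fragment starts whenever

    next.start − footprint_end > boundary

where `footprint_end` is the running maximum alignment end of the current
fragment and `boundary` defaults to 50 kb. The gap is measured end-to-start
(the physical gap between molecules); the threshold is configurable and, as
the robustness suite shows, values from 20 to 80 kb move simulated deletion
recall by well under 5 percentage points. Fragments with fewer than
`min_reads = 2` members are dropped: a singleton carries no linking
information. Reads of one barcode on different chromosomes are always
separate fragments. Fragment span is the aligned footprint; no extrapolation
beyond the outermost reads.

stLFR's null barcode `0_0_0` is treated as unbarcoded (configurable set).

## Haplotype partitioning

For every het SNP inside a fragment's span, the member reads covering that
position (projected through their CIGARs) vote; a strict majority for the
ref or alt allele records allele 0 or 1 with the vote count as support. Ties
and third-allele majorities record nothing.

Every fragment observing a SNP pair increments the pair's cis count (equal
alleles) or trans count (opposite). Pairs with

    cis + trans ≥ min_support (2)   and   max(cis, trans)/(cis+trans) ≥ purity (0.8)

become phase edges (cis ⇒ same phase, trans ⇒ opposite). Connected
components are phase blocks; phases propagate by BFS from the lowest SNP
index (assigned phase 0 — tie-breaks are positional, never random). Edges
contradicting an already-assigned phase are dropped and counted; if more
than 20% of a component's edges conflict, the conflicted edges are removed
and the component re-partitioned. Each component is then re-clustered using
only fragments wholly internal to it, repeating until the assignment is
stable (depth cap 5). All truth comparisons are made up to a per-block flip,
the inherent symmetry of phasing.

Fragments vote within the block holding most of their observations:
`v0 > v1` ⇒ haplotype 0, `v1 > v0` ⇒ haplotype 1, ties and uninformative
fragments ⇒ *both*. "Both" fragments feed both assemblies — for stLFR's
short (100 bp) multi-mapping reads it is better to give a read to both
haplotypes than to lose it.

## Chunked assembly

Phase-block spans are extended outward to the chromosome ends and to the
midpoint between adjacent blocks (the flanks carry no het SNPs but still
deserve assembly), then tiled with 100 kb cores padded by 1 kb so
neighbouring chunks share sequence. For each chunk and haplotype, the read
set is: every read of a selected fragment overlapping the padded chunk, each
taken read's mate from the original FASTQ regardless of mapping status, and
every never-mapped read pair whose barcode belongs to a selected fragment.
The last rule matters: read pairs sampled wholly inside a long insertion map
nowhere, and only their barcode ties them to a locus.

The built-in assembler is a minimal canonical-k-mer de Bruijn unitig
assembler (k = 31, odd so no k-mer is its own reverse complement):

* count canonical k-mers (numpy-vectorised 2-bit packing); drop count < 2;
* at each (k−1)-mer node with multiple in- or out-edges, prune sibling
  edges whose count is below 0.25× the strongest — this removes the
  branches created by recurrent sequencing errors (two reads sharing an
  error pass the count filter and would otherwise fracture the graph every
  few tens of kb at a 10⁻³ error rate);
* compress unambiguous paths; emit unitigs ≥ 2k, deduplicated by canonical
  orientation, sorted by length. Output depends only on the read multiset.

It is deliberately minimal — adequate for desk-scale synthetic data, not a
production assembler; the `external_assembler_adapter` runs any command
template (writes paired FASTQ, parses a contig FASTA) when fidelity to a
full assembler is wanted.

Stitching keeps every mini-contig ≥ 1 kb, drops pieces contained in another
(pad duplicates), and iteratively merges any pair with a suffix/prefix
overlap ≥ 200 bp at ≥ 99% identity — or a shorter but perfectly exact
overlap of k−1 = 30 bp, which heals the two unitigs left when a graph fork
splits one path (their shared (k−1)-mer contains the junction, often exactly
at an SV breakpoint). Both orientations are tried; unmerged pieces become
separate contigs. An earlier design kept only each chunk's longest
mini-contig; any intra-chunk break then silently discarded a multi-kb
region and the SVs in it, which is why stitching now conserves all
assembled sequence.

## SV calling

The builtin aligner is a seed–chain–fill design for desk-scale inputs
(contig and target ≤ ~2 Mb): 31-mers unique in both contig and reference are
anchors; the longest collinear chain (strictly increasing on both axes,
better strand kept) is selected by patience LIS; consecutive anchors with
equal spacing on both axes form verified exact runs; the gaps between runs
are aligned with global affine-gap DP (match 1, mismatch −4, gap open −6,
extend −1 — mismatch and open costs high relative to extend so indels
consolidate rather than shatter). The DP is Gotoh with numpy-vectorised
rows; the horizontal gap state is computed with a prefix-max scan, which is
exact because extending a gap (−1) never costs more than re-opening one
(−7). Segments beyond 4M cells fall back to a prefix/suffix-trim coarse
fill (mismatch run plus one indel) with a warning; alignment ends are
extended by exact matching only.

Walking the operation list with reference and contig cursors yields DEL at
the current reference position (length L, anchor base before the event) for
each D op and INS with the contig slice as sequence for each I op; X runs
are ignored (SNVs are out of scope). Minus-strand alignments are computed on
the reverse complement so coordinates and inserted sequence are already on
the forward reference strand. Calls shorter than 50 bp are dropped and the
rest left-normalised by shifting through repeat context to the smallest
equivalent position (idempotent by construction). Near-identical calls
within one haplotype (pad-overlap duplicates) are collapsed, then the two
haplotypes are merged greedily by ascending breakpoint distance (same type,
distance ≤ 200, size ratio ≥ 0.7): matched ⇒ one 1/1 call, unmatched ⇒ 0/1.

Size bins close on the right: 50 ≤ L ≤ 1000, 1000 < L ≤ 10000, L > 10000.

## Benchmarking

Matching follows the Truvari conventions: same SV type, breakpoint distance
≤ `refdist` (200), size ratio ≥ `pctsize` (0.1), and for insertions with
both sequences present a normalised edit similarity ≥ `pctsim` (0.1,
computed with edlib); `passonly` drops non-PASS records first. Matching is
one-to-one, greedy by ascending distance with deterministic tie-breaks
(lower truth position, then lower call position). Reports bin each side by
its own length and disallow cross-bin matches — a documented divergence
from Truvari's edge-case behaviour, acceptable because `pctsize = 0.1`
makes cross-bin pairs rare. "Total call" is the binned call count before
matching. Precision is undefined (printed NAN) when no calls exist in a
bin.

## The simulator: what it emulates, and what it does not

The generator's defaults are the study conditions throughout the test
suite:

| parameter | default | rationale |
|---|---|---|
| read length | 100 bp | stLFR short-read length |
| fragment length | exponential, mean 30 kb, floor 1 kb | observed mean reconstructed LFR length; technology range 20–300 kb |
| fragments per barcode | uniform 1–3 | exercises deconvolution; the real distribution is not published |
| fragment coverage C_F | 40 per haplotype | ~8M × 30 kb fragments vs a 3 Gb genome ⇒ ~80X physical |
| read coverage within fragment C_R | 0.6 | C_F × C_R × 2 ≈ 48X total sequencing, matching the library |
| per-base error | 10⁻³ substitutions | typical Illumina; indel errors off |
| het SNP rate | 1/1500 bp | human-like heterozygosity |
| SVs | 5 DEL + 5 INS in 50–1000 bp and in 1–5 kb | populates both evaluated size bins |
| genome | 500 kb, uniform ACGT | desk scale |

Same-barcode fragments are kept ≥ 100 kb (2× boundary) apart: on a real
genome two co-barcoded molecules essentially never land adjacent, but on a
desk-scale chromosome unconstrained placement makes them collide constantly,
which no gap rule could deconvolve. Fragment starts may overhang chromosome
ends (clipped) so edge coverage matches the interior. Reads are placed in a
truth-position SAM (soft-clipped at planted SV boundaries, unmapped when
wholly inside insertions), which stands in for an external aligner; a real
BAM can be substituted for full fidelity.

Not emulated: GC bias, chimeric fragments, barcode sequencing errors, PCR
duplicates, repetitive sequence, and real aligner behaviour
(multi-mapping, mismapping). Passing tests therefore demonstrate the
pipeline's logic — deconvolution, phasing, haplotype-resolved assembly,
breakpoint recovery, benchmarking arithmetic — under an idealised but
realistically parameterised library, not performance on real human data,
where repeats and alignment noise dominate the error budget.

## Numerical and degenerate-input choices

* All internal coordinates 0-based half-open; conversions only at
  parse/write boundaries. Emitted VCF uses the 1-based anchor-base
  convention.
* Every randomized step takes the config seed; per-stage generators derive
  from `[seed, stage_index]`. Two runs with one config are byte-identical.
* Ties are positional everywhere (lowest SNP index, lexicographic contig
  order, lower truth position).
* Empty inputs: empty read set assembles to no contigs; empty callset
  writes a header-only VCF; `fragment_stats` of nothing is an error.
* Chromosomes with no phased SNPs are assembled unpartitioned (both
  haplotype read sets identical); a lone SNP forms no block and stays
  unphased.

## Known limitations

* The builtin aligner is quadratic between anchors and depends on unique
  31-mers; highly repetitive references need the PAF adapter and a real
  aligner.
* Only deletions and insertions are modelled; inversions, duplications and
  translocations are out of scope, as is re-genotyping from read support.
* The greedy matchers (diploid merge, benchmarking) are optimal only when
  events are separated relative to `refdist`; adversarially dense callsets
  can differ from exhaustive matching.
* Phase blocks end wherever no fragment bridges a SNP pair; SNP deserts
  longer than a fragment split blocks, and sequence beyond the outermost
  SNPs is assembled with the nearest block by construction.
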