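# stlfrasm

Diploid-assembly based structural variant calling for stLFR linked-reads.

stLFR (single tube long fragment read) libraries tag the short reads derived
from each long DNA molecule (20–300 kb) with a shared barcode, giving
long-range information at short-read cost. `stlfrasm` turns such a library
into genotyped deletion/insertion calls (SV ≥ 50 bp) by assembling each
parental haplotype separately:

1. **Fragment reconstruction (barcode deconvolution).** Reads sharing a
   barcode on one chromosome are grouped and split into long fragment reads
   (LFRs) wherever the gap between successive reads exceeds an empirical
   boundary threshold (50 kb by default) — two molecules that happened to
   receive the same barcode almost never sit side by side.
2. **Haplotype partitioning.** Each LFR is annotated with the alleles it
   carries at heterozygous SNPs from a small-variant VCF. Every LFR covering
   a SNP pair (i, j) votes it *cis* (0/0 or 1/1) or *trans* (0/1 or 1/0);
   pairs with support ≥ 2 and majority fraction ≥ 0.8 become phase edges,
   and connected components of phase edges are phase blocks with phases
   propagated by BFS. LFRs then join the haplotype the majority of their
   observations agree with; uninformative LFRs go to both.
3. **Chunked local assembly.** Each block is cut into 100 kb chunks (1 kb
   pad); each chunk's haplotype-specific read set — including mates and
   never-mapped pairs recruited by barcode — is assembled with a canonical
   k-mer de Bruijn unitig assembler (k = 31), and mini-contigs are stitched
   through their pad overlaps into haploid contigs.
4. **SV calling.** Contigs are aligned to the reference (unique 31-mer
   anchors, collinear chaining, affine-gap DP with match/mismatch/open/extend
   = 1/−4/−6/−1); insertions and deletions are read off the alignment,
   left-normalised, filtered at 50 bp, and the two haplotypes' calls are
   merged into genotyped (0/1, 1/1) diploid calls. A PAF adapter accepts
   minimap2 alignments instead of the builtin aligner, and an external
   assembler can replace the builtin one through a command template.

The package also ships a **linked-read simulator** (diploid genome with
planted SNPs/SVs, fragments, barcodes, reads, truth-position SAM — all
deterministic under a seed) and a **Truvari-style benchmarking engine**
(breakpoint distance ≤ `refdist` = 200, size ratio ≥ `pctsize` = 0.1,
insertion sequence similarity ≥ `pctsim` = 0.1, `--passonly`), reporting
precision = TP/(TP+FP) and recall = TP/(TP+FN) per size bin
(50–1k, 1k–10k, >10k).

## Worked example

`examples/04_assemble_and_call_svs.py` runs every stage on a 200 kb diploid
simulation with 6 planted SVs:

```
simulate     {'fragments': 680, 'read_pairs': 48500, ... 'planted_svs': 6, 'het_snps': 132}
reconstruct  {'alignments': 97000, 'fragments': 677, 'mean_fragment_length': 23231.4, ...}
phase        {'blocks': 1, 'n_snps_phased': 132, 'n50': 194025, ...}
assemble     {'chunks': 4, 'contigs': 2, 'contig_bases': 401566}
callsv       {'candidates_h0': 4, 'candidates_h1': 3, 'calls': 6}

Bin      Type Benchmark Total call     TP     FP     FN Precision  Recall
50-1k    DEL          2          2      2      0      0    100.0%  100.0%
50-1k    INS          1          1      1      0      0    100.0%  100.0%
1k-10k   DEL          1          1      1      0      0    100.0%  100.0%
1k-10k   INS          2          2      2      0      0    100.0%  100.0%
```

Read it bottom-up: the two haplotypes assembled into one contig each
(401,566 bases over a 2 × 200 kb diploid genome), the aligner produced 7
indel candidates, and after the ≥ 50 bp filter and diploid merging all 6
planted SVs are recovered with no false positives. The other examples
(`examples/01`–`05`) exercise each capability on its own and print what the
numbers mean.

The same pipeline is available from the shell:

```bash
stlfrasm run-all --out-dir out --seed 3        # synthetic end-to-end run
stlfrasm reconstruct --config cfg.yaml         # single stage, real inputs
```

Stage artifacts are plain TSV/FASTA/VCF/SAM, so any stage can be re-run
standalone or swapped for an external tool's output.

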