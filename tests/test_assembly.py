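"""Chunking, chunk-read extraction, the de Bruijn assembler and stitching."""
from __future__ import annotations

import random
import sys

import numpy as np
import pytest

from stlfrasm.assembly import (Chunk, MiniContig, assemble_chunk, cut_chunks,
                               external_assembler_adapter, extract_chunk_reads,
                               stitch_contigs)
from stlfrasm.phasing import PhaseBlock
from stlfrasm.fragments import LongFragment
from stlfrasm.util import revcomp

from conftest import make_aln


def block(start, end, bid="b0"):
    return PhaseBlock(bid, "chr1", start, end, snp_phase={})


def rand_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# chunking


def test_cut_chunks_250kb_block():
    per_hap = cut_chunks(block(0, 250_000), chunk_size=100_000, pad=1_000)
    for hap in (0, 1):
        cores = [(c.core_start, c.core_end) for c in per_hap[hap]]
        assert cores == [(0, 100_000), (100_000, 200_000), (200_000, 250_000)]
        assert per_hap[hap][1].start == 99_000
        assert per_hap[hap][1].end == 201_000
        assert per_hap[hap][0].start == 0  # pad clipped at the block edge


def test_cut_chunks_small_block_single_chunk():
    per_hap = cut_chunks(block(10_000, 90_000))
    assert len(per_hap[0]) == 1
    assert (per_hap[0][0].core_start, per_hap[0][0].core_end) == (10_000, 90_000)


def test_chunk_cores_tile_block_exactly():
    rng = random.Random(3)
    for _ in range(25):
        start = rng.randrange(0, 50_000)
        end = start + rng.randrange(1, 400_000)
        size = rng.choice([30_000, 100_000, 170_000])
        chunks = cut_chunks(block(start, end), chunk_size=size)[0]
        assert chunks[0].core_start == start
        assert chunks[-1].core_end == end
        for a, b in zip(chunks, chunks[1:]):
            assert a.core_end == b.core_start
        assert all(c.core_end - c.core_start <= size for c in chunks)


# ---------------------------------------------------------------------------
# read extraction


def _frag(fid, start, end, hap, reads):
    f = LongFragment(fid, f"bc_{fid}", "chr1", start, end, reads=reads)
    f.haplotype = hap
    return f


def test_extract_selects_by_haplotype_and_span():
    idx = {f"r{i}": (f"S{i}1", f"S{i}2") for i in range(6)}
    frs = [
        _frag("f0", 1000, 3000, "0", [make_aln("r0", 1000), make_aln("r1", 2500)]),
        _frag("f1", 1000, 3000, "1", [make_aln("r2", 1200)]),
        _frag("f2", 1000, 3000, "both", [make_aln("r3", 1400)]),
        _frag("f3", 90_000, 95_000, "0", [make_aln("r4", 90_000)]),
    ]
    chunk = Chunk("c", "b0", 0, "chr1", 0, 5_000, 0, 5_000)
    got = extract_chunk_reads(chunk, frs, idx)
    ids = [rid for rid, _, _ in got]
    assert ids == ["r0", "r1", "r3"]  # hap-0 + both; hap-1 and far ones out
    assert got[0][1:] == ("S01", "S02")  # mate comes along regardless


def test_extract_recruits_unmapped_pairs_by_barcode():
    idx = {"r0": ("A" * 10, "C" * 10), "lost": ("G" * 10, "T" * 10)}
    frs = [_frag("f0", 1000, 3000, "0", [make_aln("r0", 1000)])]
    chunk = Chunk("c", "b0", 0, "chr1", 0, 5_000, 0, 5_000)
    got = extract_chunk_reads(chunk, frs, idx,
                              unmapped_by_barcode={"bc_f0": ["lost"]})
    assert [rid for rid, _, _ in got] == ["lost", "r0"]


def test_extract_missing_fastq_entry_raises():
    frs = [_frag("f0", 0, 3000, "0", [make_aln("r0", 1000)])]
    chunk = Chunk("c", "b0", 0, "chr1", 0, 5_000, 0, 5_000)
    with pytest.raises(KeyError, match="FASTQ"):
        extract_chunk_reads(chunk, frs, {})


# ---------------------------------------------------------------------------
# assembler


def tiling_reads(src, stride=3, length=100):
    reads = [src[i:i + length] for i in range(0, len(src) - length + 1, stride)]
    # make sure the terminal k-mers are seen twice
    reads += [src[:length], src[:length], src[-length:], src[-length:]]
    return reads


def test_assembler_reconstructs_source_sequence():
    src = rand_seq(5000, seed=5)
    reads = tiling_reads(src)
    reads += [revcomp(r) for r in reads[::2]]  # mixed orientations
    contigs = assemble_chunk(reads)
    assert len(contigs) == 1
    assert contigs[0].sequence in (src, revcomp(src))


def test_assembler_keeps_haplotypes_separate():
    src0 = rand_seq(3000, seed=6)
    i = 1500
    src1 = src0[:i] + ("G" if src0[i] != "G" else "T") + src0[i + 1:]
    c0 = assemble_chunk(tiling_reads(src0))
    c1 = assemble_chunk(tiling_reads(src1))
    assert c0[0].sequence in (src0, revcomp(src0))
    assert c1[0].sequence in (src1, revcomp(src1))


def test_assembler_single_repeated_read():
    read = rand_seq(100, seed=7)
    contigs = assemble_chunk([read, read, read])
    assert len(contigs) == 1
    assert contigs[0].sequence in (read, revcomp(read))


def test_assembler_deterministic_under_read_order():
    src = rand_seq(2000, seed=8)
    reads = tiling_reads(src)
    shuffled = list(reads)
    random.Random(0).shuffle(shuffled)
    a = [c.sequence for c in assemble_chunk(reads)]
    b = [c.sequence for c in assemble_chunk(shuffled)]
    assert a == b


def test_assembler_empty_and_validation():
    assert assemble_chunk([]) == []
    with pytest.raises(ValueError):
        assemble_chunk(["ACGT" * 30], k=30)  # even k


def test_assembler_filters_low_count_kmers():
    src = rand_seq(500, seed=9)
    noise = rand_seq(200, seed=10)
    contigs = assemble_chunk(tiling_reads(src, stride=2) + [noise])
    assert len(contigs) == 1  # the singleton noise read contributes nothing
    assert contigs[0].sequence in (src, revcomp(src))


# ---------------------------------------------------------------------------
# stitching


def _chunks_for(n, bid="b0"):
    return [Chunk(f"{bid}.h0.c{i}", bid, 0, "chr1",
                  i * 10_000, (i + 1) * 10_000 + 1_000, i * 10_000,
                  (i + 1) * 10_000) for i in range(n)]


def test_stitch_merges_exact_overlap():
    src = rand_seq(8_000, seed=11)
    a, b = src[:5_000], src[4_000:]  # 1 kb shared overlap
    chunks = _chunks_for(2)
    minis = {chunks[0].chunk_id: [MiniContig("m0", "c0", a, 10.0)],
             chunks[1].chunk_id: [MiniContig("m1", "c1", b, 10.0)]}
    out = stitch_contigs(chunks, minis)
    assert len(out) == 1
    assert out[0].sequence in (src, revcomp(src))


def test_stitch_merges_reverse_complement_piece():
    src = rand_seq(8_000, seed=12)
    a, b = src[:5_000], revcomp(src[4_000:])
    chunks = _chunks_for(2)
    minis = {chunks[0].chunk_id: [MiniContig("m0", "c0", a, 10.0)],
             chunks[1].chunk_id: [MiniContig("m1", "c1", b, 10.0)]}
    out = stitch_contigs(chunks, minis)
    assert len(out) == 1
    assert out[0].sequence in (src, revcomp(src))


def test_stitch_gap_leaves_two_contigs():
    a, b = rand_seq(4_000, seed=13), rand_seq(4_000, seed=14)
    chunks = _chunks_for(2)
    minis = {chunks[0].chunk_id: [MiniContig("m0", "c0", a, 10.0)],
             chunks[1].chunk_id: [MiniContig("m1", "c1", b, 10.0)]}
    out = stitch_contigs(chunks, minis)
    assert sorted(len(c.sequence) for c in out) == [4_000, 4_000]


def test_stitch_drops_contained_pad_duplicates():
    src = rand_seq(6_000, seed=15)
    chunks = _chunks_for(2)
    minis = {chunks[0].chunk_id: [MiniContig("m0", "c0", src, 10.0)],
             chunks[1].chunk_id: [MiniContig("m1", "c1",
                                             revcomp(src[2_000:4_000]), 10.0)]}
    out = stitch_contigs(chunks, minis)
    assert len(out) == 1
    assert out[0].sequence in (src, revcomp(src))


def test_stitch_conserves_sequence_content():
    """Stitching introduces no sequence absent from the mini-contigs."""
    src = rand_seq(9_000, seed=16)
    pieces = [src[:4_000], src[3_500:7_000], src[6_500:]]
    chunks = _chunks_for(3)
    minis = {c.chunk_id: [MiniContig(f"m{i}", c.chunk_id, p, 5.0)]
             for i, (c, p) in enumerate(zip(chunks, pieces))}
    out = stitch_contigs(chunks, minis)
    assert len(out) == 1
    assert out[0].sequence in (src, revcomp(src))


# ---------------------------------------------------------------------------
# external adapter


def test_external_adapter_stub(tmp_path):
    fixture = tmp_path / "stub_contigs.fasta"
    fixture.write_text(">c1\nACGTACGTACGT\n")
    stub = tmp_path / "stub.py"
    stub.write_text(
        "import shutil, sys\nshutil.copy(sys.argv[1], sys.argv[2])\n")
    reads = [("r1", "ACGT", "ACGT")]
    contigs = external_assembler_adapter(
        reads, tmp_path / "work",
        f"{sys.executable} {stub} {fixture} {{out_fasta}}")
    assert [c.sequence for c in contigs] == ["ACGTACGTACGT"]


def test_external_adapter_missing_tool(tmp_path):
    with pytest.raises(RuntimeError):
        external_assembler_adapter([("r1", "ACGT", "ACGT")], tmp_path / "w",
                                   "definitely_not_a_real_assembler {out_fasta}")


def test_external_adapter_matches_builtin_on_clean_chunk(tmp_path):
    """Adapter seam and builtin agree when the 'external assembler' is the
    builtin run through the file interface."""
    src = rand_seq(2_000, seed=17)
    reads = [(f"r{i}", s, revcomp(s))
             for i, s in enumerate(tiling_reads(src, stride=4))]
    stub = tmp_path / "asm.py"
    stub.write_text(
        "import sys\n"
        "from stlfrasm.io_formats import parse_barcoded_fastq, write_fasta\n"
        "from stlfrasm.assembly import assemble_chunk\n"
        "seqs = [r.sequence for p in sys.argv[1:3]"
        " for r in parse_barcoded_fastq(p)]\n"
        "contigs = assemble_chunk(seqs)\n"
        "write_fasta([(c.contig_id or 'c%d' % i, c.sequence)"
        " for i, c in enumerate(contigs)], sys.argv[3])\n")
    got = external_assembler_adapter(
        reads, tmp_path / "work", f"{sys.executable} {stub} {{r1}} {{r2}} {{out_fasta}}")
    builtin = assemble_chunk([s for _, s1, s2 in reads for s in (s1, s2)])
    assert [c.sequence for c in got] == [c.sequence for c in builtin]
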