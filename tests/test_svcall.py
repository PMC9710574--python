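"""Contig alignment, variant extraction, normalisation and diploid merging."""
from __future__ import annotations

import random

import numpy as np
import pytest

from stlfrasm.io_formats import PafRecord, ReferenceGenome
from stlfrasm.svcall import (GAP_EXT, GAP_OPEN, MATCH, MISMATCH, SVCall,
                             ContigAlignment, align_contigs, classify_size_bin,
                             extract_variants, filter_svs, gotoh_align,
                             left_normalize, merge_diploid)
from stlfrasm.util import revcomp


def rand_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def ref_of(seq):
    return ReferenceGenome({"chr1": seq})


# ---------------------------------------------------------------------------
# affine DP vs an independent textbook implementation


def textbook_gotoh_score(a, b):
    """Plain three-matrix Gotoh, written independently of the row-vectorised
    implementation; returns the optimal global score only."""
    NEG = -(10 ** 9)
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming b
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap consuming a
    M[0][0] = 0
    for j in range(1, m + 1):
        Ix[0][j] = GAP_OPEN + GAP_EXT * j
    for i in range(1, n + 1):
        Iy[i][0] = GAP_OPEN + GAP_EXT * i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                          Iy[i - 1][j - 1]) + s
            best_prev_x = max(M[i][j - 1], Iy[i][j - 1])
            Ix[i][j] = max(best_prev_x + GAP_OPEN + GAP_EXT,
                           Ix[i][j - 1] + GAP_EXT)
            best_prev_y = max(M[i - 1][j], Ix[i - 1][j])
            Iy[i][j] = max(best_prev_y + GAP_OPEN + GAP_EXT,
                           Iy[i - 1][j] + GAP_EXT)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def score_ops(ops):
    s = 0
    for op, n in ops:
        if op == "=":
            s += MATCH * n
        elif op == "X":
            s += MISMATCH * n
        else:
            s += GAP_OPEN + GAP_EXT * n
    return s


def test_gotoh_matches_textbook_dp_on_random_pairs():
    rng = random.Random(19)
    for _ in range(60):
        n, m = rng.randrange(0, 25), rng.randrange(0, 25)
        a = "".join(rng.choice("ACGT") for _ in range(n))
        b = "".join(rng.choice("ACGT") for _ in range(m))
        ops = gotoh_align(a, b)
        assert sum(l for op, l in ops if op in "=XD") == n
        assert sum(l for op, l in ops if op in "=XI") == m
        if n and m:
            assert score_ops(ops) == textbook_gotoh_score(a, b)


def test_gotoh_prefers_consolidated_gap():
    a = "AAAATTTTGGGG"
    b = "AAAAGGGG"
    ops = gotoh_align(a, b)
    assert ("D", 4) in ops


# ---------------------------------------------------------------------------
# builtin alignment + extraction


def test_identity_alignment_single_match_op():
    ref = rand_seq(30_000, seed=20)
    contig = ref[10_000:20_000]
    (aln,) = align_contigs([("c1", contig)], ref_of(ref))
    assert aln.ops == [("=", 10_000)]
    assert (aln.ref_start, aln.ref_end) == (10_000, 20_000)
    assert extract_variants(aln, contig, ref_of(ref)) == []


def test_deletion_in_contig_recovered():
    ref = rand_seq(20_000, seed=21)
    contig = ref[2_000:9_000] + ref[9_100:16_000]  # ref[9000:9100] deleted
    (aln,) = align_contigs([("c1", contig)], ref_of(ref))
    dels = [(op, n) for op, n in aln.ops if op == "D"]
    assert dels == [("D", 100)]
    calls = [left_normalize(c, ref)
             for c in extract_variants(aln, contig, ref_of(ref))]
    want = left_normalize(SVCall("chr1", 8_999, "DEL", 100), ref)
    assert [(c.svtype, c.pos, c.svlen) for c in calls] == \
        [("DEL", want.pos, 100)]


def test_minus_strand_contig_aligned_and_normalized():
    ref = rand_seq(20_000, seed=22)
    contig = revcomp(ref[2_000:9_000] + ref[9_200:16_000])
    (aln,) = align_contigs([("c1", contig)], ref_of(ref))
    assert aln.strand == "-"
    calls = extract_variants(aln, contig, ref_of(ref))
    assert [(c.svtype, c.svlen) for c in calls] == [("DEL", 200)]


def test_paf_adapter_transcribes_cigar():
    rec = PafRecord("c1", 1000, 0, 1000, "+", "chr1", 5000, 100, 1080, 980,
                    1000, 60, cigar=[("=", 500), ("I", 20), ("=", 480)])
    (aln,) = align_contigs([], ref_of(rand_seq(5000)), mode="paf_adapter",
                           paf_records=[rec])
    assert aln.ops == [("=", 500), ("I", 20), ("=", 480)]
    assert (aln.ref_start, aln.contig_start, aln.strand) == (100, 0, "+")


def test_extract_cursor_arithmetic_del():
    ref = ref_of(rand_seq(2_000, seed=23))
    aln = ContigAlignment("c", "chr1", 1000, 1250, 0, 200, "+",
                          [("=", 100), ("D", 50), ("=", 100)])
    (call,) = extract_variants(aln, "A" * 200, ref)
    assert (call.svtype, call.pos, call.svlen) == ("DEL", 1099, 50)


def test_extract_cursor_arithmetic_ins():
    ref = ref_of(rand_seq(2_000, seed=24))
    contig = rand_seq(260, seed=25)
    aln = ContigAlignment("c", "chr1", 1000, 1200, 0, 260, "+",
                          [("=", 100), ("I", 60), ("=", 100)])
    (call,) = extract_variants(aln, contig, ref)
    assert (call.svtype, call.pos, call.svlen) == ("INS", 1099, 60)
    assert call.alt_seq == contig[100:160]


def test_extract_rejects_inconsistent_ops():
    ref = ref_of(rand_seq(2_000, seed=26))
    aln = ContigAlignment("c", "chr1", 0, 100, 0, 150, "+", [("=", 100)])
    with pytest.raises(ValueError):
        extract_variants(aln, "A" * 150, ref)


def test_plant_and_recover_20_indels():
    """20 planted 1-500 bp indels on 100 kb are recovered exactly by builtin
    alignment + extraction (noise-free)."""
    rng = random.Random(30)
    ref = rand_seq(100_000, seed=30)
    edits = []  # (pos, svtype, length, seq)
    pos = 3_000
    while len(edits) < 20 and pos < 95_000:
        svtype = rng.choice(["DEL", "INS"])
        length = rng.randrange(1, 501)
        seq = "".join(rng.choice("ACGT") for _ in range(length)) \
            if svtype == "INS" else ""
        edits.append((pos, svtype, length, seq))
        pos += 2_000 + length
    contig = []
    cur = 0
    for p, svtype, length, seq in edits:
        contig.append(ref[cur:p + 1])
        if svtype == "DEL":
            cur = p + 1 + length
        else:
            contig.append(seq)
            cur = p + 1
    contig.append(ref[cur:])
    contig = "".join(contig)
    genome = ref_of(ref)
    (aln,) = align_contigs([("c1", contig)], genome)
    got = filter_svs(extract_variants(aln, contig, genome), genome, min_len=1)
    truth = filter_svs(
        [SVCall("chr1", p, svtype, length, alt_seq=seq)
         for p, svtype, length, seq in edits], genome, min_len=1)
    assert [(c.svtype, c.pos, c.svlen, c.alt_seq) for c in got] == \
           [(c.svtype, c.pos, c.svlen, c.alt_seq) for c in truth]


def test_cursor_conservation_invariant():
    rng = random.Random(31)
    ref = ref_of(rand_seq(50_000, seed=31))
    for _ in range(20):
        ops = []
        r = c = 0
        for _ in range(rng.randrange(1, 8)):
            ops.append(("=", rng.randrange(50, 500)))
            r += ops[-1][1]
            c += ops[-1][1]
            kind = rng.choice(["D", "I", ""])
            if kind:
                n = rng.randrange(1, 300)
                ops.append((kind, n))
                if kind == "D":
                    r += n
                else:
                    c += n
        aln = ContigAlignment("c", "chr1", 100, 100 + r, 0, c, "+", ops)
        calls = extract_variants(aln, "A" * c, ref)
        net = sum(x.svlen if x.svtype == "INS" else -x.svlen for x in calls)
        assert net == c - r


# ---------------------------------------------------------------------------
# filtering / normalisation


def test_filter_sv_length_boundary():
    ref = ref_of(rand_seq(2_000, seed=32))
    calls = [SVCall("chr1", 100, "DEL", 49), SVCall("chr1", 600, "DEL", 50)]
    kept = filter_svs(calls, ref)
    assert [(c.pos, c.svlen) for c in kept] == [(600, 50)]


def exhaustive_leftmost_del(ref, pos, length):
    """Smallest p' such that deleting ref[p'+1 : p'+1+length] gives the same
    sequence as the original deletion (brute-force shift oracle)."""
    target = ref[:pos + 1] + ref[pos + 1 + length:]
    best = pos
    for p in range(pos, -1, -1):
        if ref[:p + 1] + ref[p + 1 + length:] == target:
            best = p
        else:
            break
    return best


def test_left_normalize_tandem_repeat_matches_shift_oracle():
    rng = random.Random(33)
    for _ in range(30):
        unit = "".join(rng.choice("ACGT") for _ in range(rng.randrange(1, 6)))
        copies = rng.randrange(3, 8)
        left = rand_seq(200, seed=rng.randrange(10_000))
        right = rand_seq(200, seed=rng.randrange(10_000))
        ref = left + unit * copies + right
        # delete the rightmost repeat unit
        pos = len(left) + (copies - 1) * len(unit) - 1
        call = SVCall("chr1", pos, "DEL", len(unit))
        norm = left_normalize(call, ref)
        assert norm.pos == exhaustive_leftmost_del(ref, pos, len(unit))


def test_left_normalize_idempotent():
    rng = random.Random(34)
    ref = rand_seq(5_000, seed=34)
    for _ in range(50):
        pos = rng.randrange(100, 4_000)
        if rng.random() < 0.5:
            call = SVCall("chr1", pos, "DEL", rng.randrange(1, 100))
        else:
            L = rng.randrange(1, 100)
            call = SVCall("chr1", pos, "INS", L,
                          alt_seq="".join(rng.choice("ACGT") for _ in range(L)))
        once = left_normalize(call, ref)
        twice = left_normalize(once, ref)
        assert (twice.pos, twice.alt_seq) == (once.pos, once.alt_seq)


# ---------------------------------------------------------------------------
# diploid merge + bins


def test_merge_identical_calls_become_homozygous():
    a = [SVCall("chr1", 1_000, "DEL", 100)]
    b = [SVCall("chr1", 1_000, "DEL", 100)]
    (m,) = merge_diploid(a, b)
    assert m.genotype == "1/1"
    assert m.haplotypes == frozenset({0, 1})


def test_merge_single_haplotype_stays_het():
    (m,) = merge_diploid([SVCall("chr1", 1_000, "DEL", 100)], [])
    assert m.genotype == "0/1"
    assert m.haplotypes == frozenset({0})


def test_merge_genotype_consistency_invariant():
    rng = random.Random(35)
    for _ in range(30):
        h0 = [SVCall("chr1", p, "DEL", rng.randrange(50, 200))
              for p in sorted(rng.sample(range(0, 100_000, 997), 5))]
        h1 = [SVCall("chr1", p + rng.randrange(-150, 150), "DEL",
                     rng.randrange(50, 200))
              for p in sorted(rng.sample(range(0, 100_000, 997), 5))]
        for m in merge_diploid(h0, h1):
            assert (m.genotype == "1/1") == (m.haplotypes == frozenset({0, 1}))


def optimal_match_count(h0, h1, refdist=200, size_sim=0.7):
    """Bitmask-DP maximum bipartite matching under the pairing predicate."""
    ok = [[a.svtype == b.svtype and abs(a.pos - b.pos) <= refdist
           and min(a.svlen, b.svlen) / max(a.svlen, b.svlen) >= size_sim
           for b in h1] for a in h0]
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i, used):
        if i == len(h0):
            return 0
        best = go(i + 1, used)
        for j in range(len(h1)):
            if ok[i][j] and not used >> j & 1:
                best = max(best, 1 + go(i + 1, used | 1 << j))
        return best

    return go(0, 0)


def test_merge_matches_exhaustive_optimum_on_small_instances():
    rng = random.Random(36)
    for _ in range(50):
        # well-separated events so the greedy pairing is unambiguous
        base = sorted(rng.sample(range(0, 500_000, 1_000), rng.randrange(0, 10)))
        h0 = [SVCall("chr1", p, "DEL", rng.randrange(50, 500)) for p in base]
        h1 = []
        for c in h0:
            if rng.random() < 0.7:
                h1.append(SVCall("chr1", c.pos + rng.randrange(-180, 181),
                                 "DEL", c.svlen))
        h1.sort(key=lambda c: c.pos)
        merged = merge_diploid(h0, h1)
        hom = sum(1 for m in merged if m.genotype == "1/1")
        assert hom == optimal_match_count(h0, h1)


@pytest.mark.parametrize("length,expected", [
    (50, "50-1k"), (500, "50-1k"), (1000, "50-1k"),
    (1001, "1k-10k"), (10_000, "1k-10k"), (10_001, ">10k"),
])
def test_size_bins(length, expected):
    assert classify_size_bin(length) == expected


def test_size_bin_below_floor_errors():
    with pytest.raises(ValueError):
        classify_size_bin(49)
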