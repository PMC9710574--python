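"""Fragment annotation, SNP-pair link graph and haplotype clustering."""
from __future__ import annotations

import random
from itertools import combinations

from stlfrasm.fragments import LongFragment
from stlfrasm.io_formats import HetSNP
from stlfrasm.phasing import (annotate_fragments, assign_fragments,
                              build_link_graph, build_phase_blocks,
                              emit_phase_blocks, phase_block_n50,
                              recursive_cluster)

from conftest import make_aln


def frag(fid, reads, chrom="chr1", start=None, end=None):
    start = start if start is not None else min(r.pos for r in reads)
    end = end if end is not None else max(r.ref_end for r in reads)
    return LongFragment(fid, "B", chrom, start, end, reads=list(reads))


SNPS = {"chr1": [HetSNP("chr1", 50, "A", "G", 0),
                 HetSNP("chr1", 150, "C", "T", 1)]}


def read_with_base(rid, pos, base_at, base, length=100):
    seq = ["A"] * length
    seq[base_at - pos] = base
    return make_aln(rid, pos, seq="".join(seq), length=length)


def test_annotate_single_alt_read():
    f = frag("f1", [read_with_base("r1", 0, 50, "G")])
    annotate_fragments([f], SNPS)
    assert f.allele_obs[0].allele == 1
    assert f.allele_obs[0].support == 1


def test_annotate_majority_vote():
    reads = [read_with_base("r1", 0, 50, "A"),
             read_with_base("r2", 10, 50, "A"),
             read_with_base("r3", 20, 50, "G")]
    f = frag("f1", reads)
    annotate_fragments([f], SNPS)
    assert f.allele_obs[0].allele == 0
    assert f.allele_obs[0].support == 2


def test_annotate_tie_records_nothing():
    reads = [read_with_base("r1", 0, 50, "A"),
             read_with_base("r2", 10, 50, "G")]
    f = frag("f1", reads)
    annotate_fragments([f], SNPS)
    assert 0 not in f.allele_obs


def test_annotate_snp_inside_deletion_not_observed():
    # CIGAR 50=10D50=: reference 100..210 with a hole at 145..155
    rec = make_aln("r1", 100, seq="G" * 100,
                   cigar=[("=", 50), ("D", 10), ("=", 50)])
    f = frag("f1", [rec], start=100, end=210)
    annotate_fragments([f], {"chr1": [HetSNP("chr1", 152, "A", "G", 0)]})
    assert f.allele_obs == {}


def test_annotate_non_ref_non_alt_base_ignored():
    f = frag("f1", [read_with_base("r1", 0, 50, "C")])  # SNP is A->G
    annotate_fragments([f], SNPS)
    assert 0 not in f.allele_obs


def obs_frag(fid, alleles: dict[int, int], chrom="chr1"):
    """Fragment with pre-filled allele observations."""
    from stlfrasm.phasing import AlleleObservation
    f = LongFragment(fid, "B", chrom, 0, 1000,
                     reads=[make_aln(fid + "r", 0)])
    f.allele_obs = {i: AlleleObservation(fid, i, a, 1)
                    for i, a in alleles.items()}
    return f


def test_link_graph_counting():
    frs = [obs_frag("a", {3: 1, 4: 1}),
           obs_frag("b", {3: 0, 4: 0}),
           obs_frag("c", {3: 0, 4: 1})]
    g = build_link_graph(frs)["chr1"]
    assert g.cis(3, 4) == 2
    assert g.trans(3, 4) == 1


def test_link_graph_matches_double_loop_oracle():
    rng = random.Random(4)
    frs = []
    for i in range(100):
        lo = rng.randrange(0, 30)
        snps = {j: rng.randrange(2) for j in range(lo, lo + rng.randrange(2, 6))}
        frs.append(obs_frag(f"f{i}", snps))
    g = build_link_graph(frs)["chr1"]
    expected: dict = {}
    for f in frs:
        for (i, oi), (j, oj) in combinations(sorted(f.allele_obs.items()), 2):
            slot = expected.setdefault((i, j), [0, 0])
            slot[0 if oi.allele == oj.allele else 1] += 1
    assert g.counts == expected


def test_two_snp_cis_cluster():
    frs = [obs_frag(f"f{i}", {0: a, 1: a}) for i, a in enumerate([0, 0, 1, 1])]
    comps = recursive_cluster(build_link_graph(frs)["chr1"])
    assert comps == [{0: 0, 1: 0}]


def test_two_snp_trans_cluster():
    frs = [obs_frag(f"f{i}", {0: a, 1: 1 - a}) for i, a in enumerate([0, 0, 1, 1])]
    comps = recursive_cluster(build_link_graph(frs)["chr1"])
    assert comps == [{0: 0, 1: 1}]


def test_low_support_pairs_form_no_edge():
    frs = [obs_frag("f0", {0: 0, 1: 0})]  # support 1 < min_support 2
    comps = recursive_cluster(build_link_graph(frs)["chr1"])
    assert comps == []


def test_noise_free_chain_phasing_and_assignment():
    """A chain of 30 SNPs phased from noise-free fragments is exact up to a
    global flip, and every informative fragment lands on its true side."""
    rng = random.Random(8)
    n = 30
    truth_phase = [rng.randrange(2) for _ in range(n)]
    snps = [HetSNP("chr1", 100 + 500 * i, "A", "G", i) for i in range(n)]
    frs = []
    truth_side = {}
    for i in range(120):
        hap = rng.randrange(2)
        lo = rng.randrange(0, n - 3)
        alleles = {j: truth_phase[j] if hap == 0 else 1 - truth_phase[j]
                   for j in range(lo, lo + 4)}
        f = obs_frag(f"f{i}", alleles)
        truth_side[f.fragment_id] = hap
        frs.append(f)
    comps = recursive_cluster(build_link_graph(frs)["chr1"], fragments=frs)
    assert len(comps) == 1
    comp = comps[0]
    assert set(comp) == set(range(n))
    agree = sum(1 for i, p in comp.items() if p == truth_phase[i])
    assert agree in (0, n)  # exact up to global flip
    blocks = build_phase_blocks(comps, snps, "chr1")
    assign_fragments(frs, blocks)
    flipped = agree == 0
    for f in frs:
        want = truth_side[f.fragment_id]
        got = int(f.haplotype)
        assert got == (1 - want if flipped else want)


def test_uninformative_fragment_goes_to_both():
    frs = [obs_frag(f"f{i}", {0: a, 1: a}) for i, a in enumerate([0, 0, 1, 1])]
    empty = obs_frag("empty", {})
    blocks = build_phase_blocks(
        recursive_cluster(build_link_graph(frs)["chr1"]),
        [HetSNP("chr1", 10, "A", "G", 0), HetSNP("chr1", 20, "C", "T", 1)],
        "chr1")
    assign_fragments(frs + [empty], blocks)
    assert empty.haplotype == "both"
    assert empty.fragment_id not in blocks[0].hap_fragments[0]
    assert empty.fragment_id not in blocks[0].hap_fragments[1]


def test_hap_fragment_sets_disjoint():
    frs = [obs_frag(f"f{i}", {0: a, 1: a}) for i, a in enumerate([0, 1, 0, 1])]
    blocks = build_phase_blocks(
        recursive_cluster(build_link_graph(frs)["chr1"]),
        [HetSNP("chr1", 10, "A", "G", 0), HetSNP("chr1", 20, "C", "T", 1)],
        "chr1")
    assign_fragments(frs, blocks)
    assert not (blocks[0].hap_fragments[0] & blocks[0].hap_fragments[1])


def test_phase_block_n50_examples(tmp_path):
    b1 = build_phase_blocks([{0: 0, 1: 0}],
                            [HetSNP("chr1", 0, "A", "G", 0),
                             HetSNP("chr1", 999_999, "C", "T", 1)], "chr1")
    assert phase_block_n50(b1) == 1_000_000
    b2 = build_phase_blocks(
        [{0: 0, 1: 0}, {2: 0, 3: 1}],
        [HetSNP("chr1", 0, "A", "G", 0), HetSNP("chr1", 999_999, "C", "T", 1),
         HetSNP("chr1", 2_000_000, "A", "G", 2),
         HetSNP("chr1", 4_999_999, "C", "T", 3)], "chr1")
    assert phase_block_n50(b2) == 3_000_000
    summary = emit_phase_blocks(b2, tmp_path / "blocks.tsv")
    assert summary["n_blocks"] == 2 and summary["n50"] == 3_000_000
    assert (tmp_path / "blocks.tsv").exists()


def test_snp_deserts_split_blocks():
    """Two SNP clusters farther apart than any fragment are never merged."""
    frs = ([obs_frag(f"a{i}", {0: 0, 1: 0}) for i in range(4)]
           + [obs_frag(f"b{i}", {2: 1, 3: 1}) for i in range(4)])
    comps = recursive_cluster(build_link_graph(frs)["chr1"])
    assert sorted(sorted(c) for c in comps) == [[0, 1], [2, 3]]
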