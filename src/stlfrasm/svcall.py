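"""Structural variant calling from haploid contigs vs the reference.

Each haploid contig is compared with the reference by a seed-chain-fill
aligner: unique 31-mers shared between contig and reference are chained
collinearly, verified exact runs become match ops, and inter-anchor gaps are
closed with affine-gap dynamic programming (match 1, mismatch -4, gap open
-6, extend -1 — scores that favor consolidated indels). Insertions and
deletions are read directly off the resulting operation list, left-normalised
through repeat context, filtered at 50 bp, and the two haplotypes' calls are
merged into genotyped diploid calls. A PAF adapter accepts external
minimap2-style alignments (with cg tags) in place of the builtin aligner.
"""
from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import PafRecord, ReferenceGenome
from .util import encode_seq, kmer_ints_from_codes, revcomp, valid_kmer_mask

log = logging.getLogger(__name__)

DEFAULT_MIN_SV_LEN = 50
DEFAULT_REFDIST = 200
DEFAULT_SIZE_SIM = 0.7
SIZE_BINS = ("50-1k", "1k-10k", ">10k")

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -4, -6, -1
MAX_DP_CELLS = 4_000_000
_NEG = np.int32(-(10 ** 7))


@dataclass
class SVCall:
    chrom: str
    pos: int  # 0-based position of the base BEFORE the event
    svtype: str  # DEL | INS
    svlen: int
    alt_seq: str = ""  # INS only
    haplotypes: frozenset[int] = frozenset()
    genotype: str = "0/1"
    filter: str = "PASS"
    contig_id: str = ""

    @property
    def end(self) -> int:
        """0-based exclusive reference end of the event."""
        return self.pos + 1 + (self.svlen if self.svtype == "DEL" else 0)


@dataclass
class ContigAlignment:
    contig_id: str
    chrom: str
    ref_start: int
    ref_end: int
    contig_start: int  # coordinates on the aligned orientation of the contig
    contig_end: int
    strand: str  # '+' or '-'
    ops: list[tuple[str, int]]
    score: int = 0

    def ref_span(self) -> int:
        return sum(n for op, n in self.ops if op in "M=XD")

    def contig_span(self) -> int:
        return sum(n for op, n in self.ops if op in "M=XI")


# ---------------------------------------------------------------------------
# affine-gap segment alignment (Gotoh, numpy rows)


def gotoh_align(a: str, b: str,
                match: int = MATCH, mismatch: int = MISMATCH,
                gap_open: int = GAP_OPEN, gap_ext: int = GAP_EXT
                ) -> list[tuple[str, int]]:
    """Global affine-gap alignment of ref segment ``a`` vs contig segment ``b``.

    Returns run-length ops over {=, X, I, D}; a gap of length L costs
    ``gap_open + gap_ext * L``.
    """
    n, m = len(a), len(b)
    if n == 0:
        return [("I", m)] if m else []
    if m == 0:
        return [("D", n)]
    ac = np.frombuffer(a.encode(), dtype=np.uint8)
    bc = np.frombuffer(b.encode(), dtype=np.uint8)
    go, ge = np.int32(gap_open), np.int32(gap_ext)
    M = np.full((n + 1, m + 1), _NEG, np.int32)
    E = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in ref: consumes b (I)
    F = np.full((n + 1, m + 1), _NEG, np.int32)  # gap in contig: consumes a (D)
    jar = np.arange(m + 1, dtype=np.int32)
    M[0, 0] = 0
    E[0, 1:] = go + ge * jar[1:]
    H_prev = np.maximum(M[0], np.maximum(E[0], F[0]))
    sub = np.where(ac[:, None] == bc[None, :], np.int32(match), np.int32(mismatch))
    for i in range(1, n + 1):
        F[i] = np.maximum(H_prev + go + ge, F[i - 1] + ge)
        F[i, 0] = go + ge * i
        M[i, 1:] = H_prev[:-1] + sub[i - 1]
        M[i, 0] = _NEG
        G = np.maximum(M[i], F[i])
        T = G - ge * jar
        P = np.maximum.accumulate(T)
        E[i, 1:] = go + ge * jar[1:] + P[:-1]
        E[i, 0] = _NEG
        H_prev = np.maximum(M[i], np.maximum(E[i], F[i]))
    # traceback
    ops: list[str] = []
    i, j = n, m
    vals = (M[i, j], F[i, j], E[i, j])
    state = ("M", "F", "E")[int(np.argmax(vals))]
    while i > 0 or j > 0:
        if i == 0:
            ops.append("I")
            j -= 1
            continue
        if j == 0:
            ops.append("D")
            i -= 1
            continue
        if state == "M":
            ops.append("=" if a[i - 1] == b[j - 1] else "X")
            i -= 1
            j -= 1
            vals = (M[i, j], F[i, j], E[i, j])
            state = ("M", "F", "E")[int(np.argmax(vals))]
        elif state == "E":
            ops.append("I")
            if E[i, j] == E[i, j - 1] + ge:
                j -= 1
            else:
                j -= 1
                state = "M" if M[i, j] >= F[i, j] else "F"
        else:  # F
            ops.append("D")
            if F[i, j] == F[i - 1, j] + ge:
                i -= 1
            else:
                i -= 1
                state = "M" if M[i, j] >= E[i, j] else "E"
    ops.reverse()
    return _runlength(ops)


def _runlength(ops: Sequence[str]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


def _merge_runs(ops: Iterable[tuple[str, int]]) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for op, n in ops:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def _align_segment(a: str, b: str) -> list[tuple[str, int]]:
    """Ops for an inter-anchor gap: trim shared ends, DP the middle."""
    if not a and not b:
        return []
    p = 0
    lim = min(len(a), len(b))
    while p < lim and a[p] == b[p]:
        p += 1
    s = 0
    while s < lim - p and a[len(a) - 1 - s] == b[len(b) - 1 - s]:
        s += 1
    core_a = a[p:len(a) - s]
    core_b = b[p:len(b) - s]
    if not core_a and not core_b:
        mid: list[tuple[str, int]] = []
    elif not core_a:
        mid = [("I", len(core_b))]
    elif not core_b:
        mid = [("D", len(core_a))]
    elif (len(core_a) + 1) * (len(core_b) + 1) <= MAX_DP_CELLS:
        mid = gotoh_align(core_a, core_b)
    else:
        log.warning("segment %d x %d beyond DP budget; coarse fill",
                    len(core_a), len(core_b))
        k = min(len(core_a), len(core_b))
        mid = [("X", k)]
        if len(core_a) > k:
            mid.append(("D", len(core_a) - k))
        elif len(core_b) > k:
            mid.append(("I", len(core_b) - k))
    return _merge_runs([("=", p)] + mid + [("=", s)])


# ---------------------------------------------------------------------------
# anchors + chaining


@dataclass
class RefKmerIndex:
    k: int
    kmers: np.ndarray  # sorted unique forward k-mers
    positions: np.ndarray


def build_ref_index(seq: str, k: int = 31) -> RefKmerIndex:
    codes = encode_seq(seq)
    km = kmer_ints_from_codes(codes, k)
    ok = valid_kmer_mask(codes, k)
    pos_all = np.flatnonzero(ok)
    km = km[ok]
    vals, idx, counts = np.unique(km, return_index=True, return_counts=True)
    uniq = counts == 1
    return RefKmerIndex(k, vals[uniq], pos_all[idx[uniq]].astype(np.int64))


def _contig_anchors(seq: str, index: RefKmerIndex):
    """(contig_pos, ref_pos) pairs of k-mers unique on both sides, by cpos."""
    codes = encode_seq(seq)
    km = kmer_ints_from_codes(codes, index.k)
    if km.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ok = valid_kmer_mask(codes, index.k)
    pos_all = np.flatnonzero(ok)
    km = km[ok]
    vals, idx, counts = np.unique(km, return_index=True, return_counts=True)
    u = counts == 1
    vals, cpos = vals[u], pos_all[idx[u]]
    loc = np.searchsorted(index.kmers, vals)
    loc_c = np.clip(loc, 0, max(index.kmers.size - 1, 0))
    hit = (index.kmers.size > 0) & (index.kmers[loc_c] == vals)
    cpos = cpos[hit].astype(np.int64)
    rpos = index.positions[loc_c[hit]]
    order = np.argsort(cpos, kind="stable")
    return cpos[order], rpos[order]


def _lis_chain(cpos: np.ndarray, rpos: np.ndarray, max_anchors: int = 120_000):
    """Longest chain with strictly increasing ref positions (contig-ordered)."""
    n = cpos.size
    if n == 0:
        return cpos, rpos
    if n > max_anchors:
        stride = n // max_anchors + 1
        cpos, rpos = cpos[::stride], rpos[::stride]
        n = cpos.size
    r = rpos.tolist()
    tails: list[int] = []
    tail_idx: list[int] = []
    parent = [-1] * n
    for i in range(n):
        x = r[i]
        j = bisect_left(tails, x)
        if j == len(tails):
            tails.append(x)
            tail_idx.append(i)
        else:
            tails[j] = x
            tail_idx[j] = i
        parent[i] = tail_idx[j - 1] if j > 0 else -1
    chain = []
    i = tail_idx[len(tails) - 1]
    while i != -1:
        chain.append(i)
        i = parent[i]
    chain.reverse()
    sel = np.array(chain, dtype=np.int64)
    return cpos[sel], rpos[sel]


def _ops_from_chain(chain_c, chain_r, contig: str, ref: str, k: int):
    """Exact runs + DP-filled gaps along a collinear anchor chain."""
    runs: list[tuple[int, int, int]] = []  # (cstart, rstart, match_len)
    cur_c, cur_r = int(chain_c[0]), int(chain_r[0])
    last_c, last_r = cur_c, cur_r
    cur_len = k
    for c, r in zip(chain_c[1:].tolist(), chain_r[1:].tolist()):
        dc, dr = c - last_c, r - last_r
        if dc == dr and (dc <= k or contig[last_c + k:c + k] == ref[last_r + k:r + k]):
            cur_len = c + k - cur_c
            last_c, last_r = c, r
            continue
        if dc != dr and (dc < k or dr < k):
            continue  # anchor overlaps the previous one across an indel; drop
        runs.append((cur_c, cur_r, cur_len))
        cur_c, cur_r, cur_len = c, r, k
        last_c, last_r = c, r
    runs.append((cur_c, cur_r, cur_len))

    # exact end extension
    c0, r0, _ = runs[0]
    ext = 0
    while c0 - ext - 1 >= 0 and r0 - ext - 1 >= 0 \
            and contig[c0 - ext - 1] == ref[r0 - ext - 1]:
        ext += 1
    contig_start, ref_start = c0 - ext, r0 - ext
    runs[0] = (c0 - ext, r0 - ext, runs[0][2] + ext)
    cl, rl, ll = runs[-1]
    ext = 0
    while cl + ll + ext < len(contig) and rl + ll + ext < len(ref) \
            and contig[cl + ll + ext] == ref[rl + ll + ext]:
        ext += 1
    runs[-1] = (cl, rl, ll + ext)

    ops: list[tuple[str, int]] = []
    for i, (c, r, ln) in enumerate(runs):
        if i > 0:
            pc, pr, pl = runs[i - 1]
            ops.extend(_align_segment(ref[pr + pl:r], contig[pc + pl:c]))
        ops.append(("=", ln))
    ops = _merge_runs(ops)
    contig_end = runs[-1][0] + runs[-1][2]
    ref_end = runs[-1][1] + runs[-1][2]
    return ops, contig_start, contig_end, ref_start, ref_end


def _score_ops(ops: Sequence[tuple[str, int]]) -> int:
    s = 0
    for op, n in ops:
        if op == "=":
            s += MATCH * n
        elif op == "X":
            s += MISMATCH * n
        elif op in "ID":
            s += GAP_OPEN + GAP_EXT * n
    return s


def align_contigs(
    contigs: Iterable,
    reference: ReferenceGenome,
    mode: str = "builtin",
    k: int = 31,
    paf_records: Sequence[PafRecord] | None = None,
    min_anchors: int = 3,
    ref_indexes: Mapping[str, RefKmerIndex] | None = None,
) -> list[ContigAlignment]:
    """Align haploid contigs to the reference.

    ``contigs`` yields objects with ``contig_id``/``sequence`` or (id, seq)
    pairs. In builtin mode each contig is anchored on unique shared 31-mers
    (both strands, best strand kept); in ``paf_adapter`` mode the supplied
    PAF records (with cg tags) are transcribed verbatim.
    """
    if mode == "paf_adapter":
        if paf_records is None:
            raise ValueError("paf_adapter mode requires paf_records")
        out = []
        for rec in paf_records:
            if rec.cigar is None:
                log.warning("PAF record %s lacks cg tag; skipped", rec.qname)
                continue
            out.append(
                ContigAlignment(
                    contig_id=rec.qname, chrom=rec.tname,
                    ref_start=rec.tstart, ref_end=rec.tend,
                    contig_start=rec.qstart, contig_end=rec.qend,
                    strand=rec.strand, ops=list(rec.cigar), score=rec.n_match,
                )
            )
        return out
    if mode != "builtin":
        raise ValueError(f"unknown alignment mode {mode!r}")

    indexes = dict(ref_indexes) if ref_indexes else {}
    alignments: list[ContigAlignment] = []
    for item in contigs:
        if hasattr(item, "contig_id"):
            cid, seq = item.contig_id, item.sequence
        else:
            cid, seq = item
        best = None
        for chrom in reference.chroms:
            if chrom not in indexes:
                indexes[chrom] = build_ref_index(reference[chrom], k)
            idx = indexes[chrom]
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                cpos, rpos = _contig_anchors(s, idx)
                if best is None or cpos.size > best[0]:
                    best = (cpos.size, chrom, strand, s, cpos, rpos)
        n_anchors, chrom, strand, s, cpos, rpos = best
        if n_anchors < min_anchors:
            log.info("contig %s: %d anchors; unaligned", cid, n_anchors)
            continue
        cc, rr = _lis_chain(cpos, rpos)
        ops, cs, ce, rs, re_ = _ops_from_chain(cc, rr, s, reference[chrom], k)
        alignments.append(
            ContigAlignment(
                contig_id=cid, chrom=chrom, ref_start=rs, ref_end=re_,
                contig_start=cs, contig_end=ce, strand=strand, ops=ops,
                score=_score_ops(ops),
            )
        )
    return alignments


# ---------------------------------------------------------------------------
# variant extraction + filtering


def extract_variants(
    alignment: ContigAlignment, contig_seq: str, reference: ReferenceGenome
) -> list[SVCall]:
    """Walk alignment ops, emitting every insertion/deletion (svlen >= 1).

    Coordinates and inserted sequence are reported on the reference forward
    strand; ``contig_seq`` is the contig as stored (minus-strand alignments
    are projected through its reverse complement). Mismatch runs are ignored
    (SNVs are out of scope).
    """
    seq = contig_seq if alignment.strand == "+" else revcomp(contig_seq)
    if alignment.ref_span() != alignment.ref_end - alignment.ref_start:
        raise ValueError("ops inconsistent with reference interval")
    if alignment.contig_span() != alignment.contig_end - alignment.contig_start:
        raise ValueError("ops inconsistent with contig interval")
    calls: list[SVCall] = []
    rc = alignment.ref_start
    cc = alignment.contig_start
    for op, n in alignment.ops:
        if op in "M=X":
            rc += n
            cc += n
        elif op == "D":
            calls.append(SVCall(alignment.chrom, max(rc - 1, 0), "DEL", n,
                                contig_id=alignment.contig_id))
            rc += n
        elif op == "I":
            calls.append(SVCall(alignment.chrom, max(rc - 1, 0), "INS", n,
                                alt_seq=seq[cc:cc + n],
                                contig_id=alignment.contig_id))
            cc += n
        elif op in "SH":
            if op == "S":
                cc += n
        else:
            raise ValueError(f"unsupported op {op!r}")
    return calls


def left_normalize(call: SVCall, ref_seq: str) -> SVCall:
    """Shift an indel through repeat context to its leftmost equivalent pos."""
    p = call.pos
    if call.svtype == "DEL":
        L = call.svlen
        while p > 0 and ref_seq[p] == ref_seq[p + L]:
            p -= 1
        return replace(call, pos=p) if p != call.pos else call
    alt = call.alt_seq
    while p > 0 and alt and ref_seq[p] == alt[-1]:
        alt = ref_seq[p] + alt[:-1]
        p -= 1
    if p != call.pos:
        return replace(call, pos=p, alt_seq=alt)
    return call


def filter_svs(
    candidates: Iterable[SVCall],
    reference: ReferenceGenome,
    min_len: int = DEFAULT_MIN_SV_LEN,
) -> list[SVCall]:
    """Keep calls of at least ``min_len`` and left-normalise them."""
    out = []
    for c in candidates:
        if c.svlen < min_len:
            continue
        out.append(left_normalize(c, reference[c.chrom]))
    out.sort(key=lambda c: (c.chrom, c.pos, c.svtype, c.svlen))
    return out


def dedupe_calls(
    calls: Sequence[SVCall], refdist: int = 20, size_sim: float = 0.9
) -> list[SVCall]:
    """Collapse near-identical calls within one haplotype (pad-overlap dups)."""
    kept: list[SVCall] = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.pos, -c.svlen)):
        dup = any(
            k.chrom == c.chrom and k.svtype == c.svtype
            and abs(k.pos - c.pos) <= refdist
            and min(k.svlen, c.svlen) / max(k.svlen, c.svlen) >= size_sim
            for k in kept
        )
        if not dup:
            kept.append(c)
    return kept


def merge_diploid(
    hap0_calls: Sequence[SVCall],
    hap1_calls: Sequence[SVCall],
    refdist: int = DEFAULT_REFDIST,
    size_sim: float = DEFAULT_SIZE_SIM,
) -> list[SVCall]:
    """Greedy best-pair matching of the two haplotypes' calls.

    Matched pairs become one homozygous (1/1) call on haplotypes {0,1};
    unmatched calls stay heterozygous (0/1).
    """
    cands = []
    for i, a in enumerate(hap0_calls):
        for j, b in enumerate(hap1_calls):
            if a.svtype != b.svtype or a.chrom != b.chrom:
                continue
            if abs(a.pos - b.pos) > refdist:
                continue
            if min(a.svlen, b.svlen) / max(a.svlen, b.svlen) < size_sim:
                continue
            cands.append((abs(a.pos - b.pos), a.pos, i, j))
    cands.sort()
    used0: set[int] = set()
    used1: set[int] = set()
    merged: list[SVCall] = []
    for _, _, i, j in cands:
        if i in used0 or j in used1:
            continue
        used0.add(i)
        used1.add(j)
        a = hap0_calls[i]
        merged.append(replace(a, haplotypes=frozenset({0, 1}), genotype="1/1"))
    for i, a in enumerate(hap0_calls):
        if i not in used0:
            merged.append(replace(a, haplotypes=frozenset({0}), genotype="0/1"))
    for j, b in enumerate(hap1_calls):
        if j not in used1:
            merged.append(replace(b, haplotypes=frozenset({1}), genotype="0/1"))
    merged.sort(key=lambda c: (c.chrom, c.pos, c.svtype, c.svlen))
    return merged


def classify_size_bin(sv: SVCall | int) -> str:
    length = sv if isinstance(sv, int) else sv.svlen
    if length < DEFAULT_MIN_SV_LEN:
        raise ValueError(f"SV length {length} below the {DEFAULT_MIN_SV_LEN} bp floor")
    if length <= 1000:
        return SIZE_BINS[0]
    if length <= 10_000:
        return SIZE_BINS[1]
    return SIZE_BINS[2]
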