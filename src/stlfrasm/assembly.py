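"""Chunked haplotype-resolved local assembly.

Each phase block is cut into chunks (100 kb cores by default, padded by 1 kb
so neighbours share sequence), each chunk's reads are gathered from the
haplotype-assigned fragments — pulling every taken read's mate from the
original FASTQ regardless of its mapping status — and assembled with a small
de Bruijn unitig assembler (canonical k-mers, count filter, relative-abundance
branch cleanup, unambiguous-path compression). Mini-contigs of consecutive
chunks are stitched through their shared pad overlap into haploid contigs.

The built-in assembler is a minimal unitig assembler adequate for desk-scale
data; an adapter seam runs an external assembler command instead when one is
configured.
"""
from __future__ import annotations

import logging
import shlex
import subprocess
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fragments import HAP_BOTH, LongFragment
from .io_formats import BarcodedRead, write_barcoded_fastq, load_fasta
from .phasing import PhaseBlock
from .util import kmer_matrix, revcomp, revcomp_kmer_ints

log = logging.getLogger(__name__)

DEFAULT_CHUNK_SIZE = 100_000
DEFAULT_PAD = 1_000
DEFAULT_K = 31
DEFAULT_MIN_KMER_COUNT = 2
DEFAULT_BRANCH_RATIO = 0.25
DEFAULT_MIN_OVERLAP = 200
DEFAULT_MIN_IDENTITY = 0.99


@dataclass
class Chunk:
    chunk_id: str
    block_id: str
    haplotype: int  # 0 or 1
    chrom: str
    start: int  # padded span
    end: int
    core_start: int
    core_end: int


@dataclass
class MiniContig:
    contig_id: str
    chunk_id: str
    sequence: str
    kmer_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HaploidContig:
    contig_id: str
    haplotype: int
    chrom: str  # provenance only
    sequence: str


# ---------------------------------------------------------------------------
# chunking


def cut_chunks(
    phase_block: PhaseBlock,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    pad: int = DEFAULT_PAD,
    region: tuple[int, int] | None = None,
) -> dict[int, list[Chunk]]:
    """Tile the block span into chunk cores, padded on both sides.

    Cores partition ``[start, end)`` without gaps or overlap; pads are clipped
    at the region edges. ``region`` overrides the block's own span (used by
    the pipeline to extend assembly into SNP-free flanks).
    """
    start, end = region if region is not None else (phase_block.start, phase_block.end)
    if end <= start:
        raise ValueError("phase block span must be positive")
    out: dict[int, list[Chunk]] = {0: [], 1: []}
    for hap in (0, 1):
        i = 0
        core = start
        while core < end:
            core_end = min(core + chunk_size, end)
            out[hap].append(
                Chunk(
                    chunk_id=f"{phase_block.block_id}.h{hap}.c{i}",
                    block_id=phase_block.block_id,
                    haplotype=hap,
                    chrom=phase_block.chrom,
                    start=max(start, core - pad),
                    end=min(end, core_end + pad),
                    core_start=core,
                    core_end=core_end,
                )
            )
            core = core_end
            i += 1
    return out


def extract_chunk_reads(
    chunk: Chunk,
    fragments: Sequence[LongFragment],
    fastq_index: Mapping[str, tuple[str, str]],
    alignments=None,
    unmapped_by_barcode: Mapping[str, Sequence[str]] | None = None,
) -> list[tuple[str, str, str]]:
    """Reads (both mates, full sequences) for one chunk.

    Selects fragments on the chunk's haplotype (or assigned to both) whose
    span intersects the padded chunk; every member read overlapping the chunk
    is taken and its mate is pulled from the FASTQ index even if that mate
    never mapped. When ``unmapped_by_barcode`` is given, read pairs that never
    mapped at all but share a selected fragment's barcode are recruited too —
    this is what recovers reads buried inside long insertions. Returns
    (read_id, mate1_seq, mate2_seq) sorted by read id.
    """
    del alignments
    want = {str(chunk.haplotype), HAP_BOTH}
    taken: dict[str, tuple[str, str]] = {}
    barcodes: set[str] = set()
    for frag in fragments:
        if frag.chrom != chunk.chrom or frag.haplotype not in want:
            continue
        if frag.end <= chunk.start or frag.start >= chunk.end:
            continue
        barcodes.add(frag.barcode)
        for rec in frag.reads:
            if rec.ref_end <= chunk.start or rec.pos >= chunk.end:
                continue
            if rec.read_id in taken:
                continue
            try:
                taken[rec.read_id] = fastq_index[rec.read_id]
            except KeyError:
                raise KeyError(
                    f"read {rec.read_id!r} missing from FASTQ index "
                    "(alignment/FASTQ mismatch)"
                ) from None
    if unmapped_by_barcode is not None:
        for bc in barcodes:
            for rid in unmapped_by_barcode.get(bc, ()):
                if rid not in taken:
                    try:
                        taken[rid] = fastq_index[rid]
                    except KeyError:
                        raise KeyError(
                            f"read {rid!r} missing from FASTQ index "
                            "(alignment/FASTQ mismatch)"
                        ) from None
    return [(rid, s1, s2) for rid, (s1, s2) in sorted(taken.items())]


# ---------------------------------------------------------------------------
# de Bruijn unitig assembler


def _count_canonical_kmers(seqs: Iterable[str], k: int):
    by_len: dict[int, list[str]] = defaultdict(list)
    for s in seqs:
        if len(s) >= k:
            by_len[len(s)].append(s)
    chunks = []
    from .util import BASE_CODES
    for L, group in sorted(by_len.items()):
        buf = np.frombuffer("".join(group).encode(), dtype=np.uint8)
        codes = BASE_CODES[buf].reshape(len(group), L)
        if (codes > 3).any():
            # rare path: drop reads with ambiguous bases
            ok = ~(codes > 3).any(axis=1)
            codes = codes[ok]
            if codes.size == 0:
                continue
        fwd = kmer_matrix(codes, k).ravel()
        if fwd.size == 0:
            continue
        rc = revcomp_kmer_ints(fwd, k)
        chunks.append(np.minimum(fwd, rc))
    if not chunks:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    allk = np.concatenate(chunks)
    vals, counts = np.unique(allk, return_counts=True)
    return vals, counts


def _decode_kmer(val: int, k: int) -> str:
    return "".join("ACGT"[(val >> (2 * (k - 1 - i))) & 3] for i in range(k))


def assemble_chunk(
    reads: Iterable[str],
    k: int = DEFAULT_K,
    min_kmer_count: int = DEFAULT_MIN_KMER_COUNT,
    branch_ratio: float = DEFAULT_BRANCH_RATIO,
    chunk_id: str = "chunk",
) -> list[MiniContig]:
    """Assemble a read set into unitigs.

    Canonical k-mers with count below ``min_kmer_count`` are dropped; at graph
    forks, sibling edges weaker than ``branch_ratio`` times the strongest are
    pruned (suppresses recurrent sequencing errors that survive the count
    filter). Unambiguous paths over (k-1)-mer nodes are compressed; unitigs
    shorter than 2k are discarded. Deterministic: output depends only on the
    read multiset.
    """
    if k % 2 == 0 or k < 5:
        raise ValueError("k must be odd and >= 5")
    seqs = [s for s in reads if s]
    if not seqs:
        log.info("assemble_chunk %s: empty read set", chunk_id)
        return []
    vals, counts = _count_canonical_kmers(seqs, k)
    keep = counts >= min_kmer_count
    vals, counts = vals[keep], counts[keep]
    if vals.size == 0:
        return []
    count_of = dict(zip(vals.tolist(), counts.tolist()))
    rcs = revcomp_kmer_ints(vals, k)
    oriented = np.unique(np.concatenate([vals, rcs]))
    mask_km1 = (1 << (2 * (k - 1))) - 1

    # adjacency over (k-1)-mer nodes
    out_adj: dict[int, list[int]] = defaultdict(list)
    in_adj: dict[int, list[int]] = defaultdict(list)
    canon_map: dict[int, int] = {}
    rc_all = revcomp_kmer_ints(oriented, k)
    for e, r in zip(oriented.tolist(), rc_all.tolist()):
        canon_map[e] = min(e, r)
    edges: set[int] = set(oriented.tolist())
    for e in edges:
        out_adj[e >> 2].append(e)
        in_adj[e & mask_km1].append(e)

    # branch cleanup by relative abundance
    drop: set[int] = set()
    for adj in (out_adj, in_adj):
        for node, lst in adj.items():
            if len(lst) < 2:
                continue
            cnts = [count_of[canon_map[e]] for e in lst]
            mx = max(cnts)
            for e, c in zip(lst, cnts):
                if c < branch_ratio * mx:
                    drop.add(e)
    if drop:
        # drop both orientations of a pruned k-mer
        rc_drop = {int(x) for x in
                   revcomp_kmer_ints(np.fromiter(drop, np.uint64, len(drop)), k)}
        drop |= rc_drop
        edges -= drop
        out_adj = defaultdict(list)
        in_adj = defaultdict(list)
        for e in edges:
            out_adj[e >> 2].append(e)
            in_adj[e & mask_km1].append(e)
    for lst in out_adj.values():
        lst.sort()
    for lst in in_adj.values():
        lst.sort()

    def simple(node: int) -> bool:
        return len(out_adj.get(node, ())) == 1 and len(in_adj.get(node, ())) == 1

    visited: set[int] = set()
    paths: list[list[int]] = []
    for e in sorted(edges):
        u = e >> 2
        if simple(u) or e in visited:
            continue
        path = [e]
        visited.add(e)
        v = e & mask_km1
        while simple(v):
            nxt = out_adj[v][0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            v = nxt & mask_km1
        paths.append(path)
    for e in sorted(edges):  # isolated cycles
        if e in visited:
            continue
        path = [e]
        visited.add(e)
        v = e & mask_km1
        while True:
            cands = [x for x in out_adj.get(v, ()) if x not in visited]
            if not cands:
                break
            nxt = cands[0]
            path.append(nxt)
            visited.add(nxt)
            v = nxt & mask_km1
        paths.append(path)

    seen: set[str] = set()
    contigs: list[MiniContig] = []
    for path in paths:
        seq = _decode_kmer(path[0] >> 2, k - 1) + "".join(
            "ACGT"[e & 3] for e in path)
        if len(seq) < 2 * k:
            continue
        cseq = min(seq, revcomp(seq))
        if cseq in seen:
            continue
        seen.add(cseq)
        cov = float(np.mean([count_of[canon_map[e]] for e in path]))
        contigs.append(MiniContig("", chunk_id, cseq, cov))
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    for i, c in enumerate(contigs):
        c.contig_id = f"{chunk_id}.u{i}"
    return contigs


# ---------------------------------------------------------------------------
# stitching


def _best_overlap(cur: str, nxt: str, min_overlap: int, min_identity: float,
                  seed_len: int = 48, window: int = 8_000) -> int:
    """Largest suffix(cur)/prefix(nxt) overlap passing the identity bar, or 0."""
    if len(nxt) < min_overlap or len(cur) < min_overlap:
        return 0
    seed = nxt[:min(seed_len, min_overlap)]
    tail_start = max(0, len(cur) - window)
    tail = cur[tail_start:]
    best = 0
    idx = tail.find(seed)
    while idx != -1:
        ov = len(tail) - idx
        if ov >= min_overlap and ov <= len(nxt):
            mism = sum(a != b for a, b in zip(cur[len(cur) - ov:], nxt[:ov]))
            if mism <= (1 - min_identity) * ov:
                best = max(best, ov)
        idx = tail.find(seed, idx + 1)
    return best


def _try_merge(a: str, b: str, min_overlap: int, min_identity: float,
               exact_min_overlap: int = 0) -> str | None:
    """Merge two pieces through their best suffix/prefix overlap, trying both
    relative orders and both orientations of ``b``.

    ``exact_min_overlap``, when positive, additionally allows shorter but
    perfectly exact overlaps — the k-1 base overlap left behind when a graph
    fork splits one path into two unitigs.
    """
    for bb in (b, revcomp(b)):
        for first, second in ((a, bb), (bb, a)):
            ov = _best_overlap(first, second, min_overlap, min_identity)
            if not ov and exact_min_overlap:
                ov = _best_overlap(first, second, exact_min_overlap, 1.0)
            if ov:
                return first + second[ov:]
    return None


def stitch_contigs(
    chunks_in_order: Sequence[Chunk],
    minicontigs: Mapping[str, list[MiniContig]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_keep: int = 1_000,
    exact_min_overlap: int = DEFAULT_K - 1,
) -> list[HaploidContig]:
    """Iteratively concatenate mini-contigs of a block's chunks into
    full-length haploid contigs.

    All mini-contigs of at least ``min_keep`` bases are kept; pieces fully
    contained in another (pad-region duplicates) are dropped, and any pair
    sharing a suffix/prefix overlap of ``min_overlap`` bases at
    ``min_identity`` — or an exact overlap of ``exact_min_overlap`` bases,
    which heals fork-splits sharing a (k-1)-mer — is merged (both
    orientations tried, longest pieces first) until no merge applies.
    Unmerged pieces — assembly gaps — become separate contigs, so no
    assembled sequence is lost.
    """
    if not chunks_in_order:
        return []
    hap = chunks_in_order[0].haplotype
    block_id = chunks_in_order[0].block_id
    chrom = chunks_in_order[0].chrom
    pieces: list[str] = [
        m.sequence
        for chunk in chunks_in_order
        for m in minicontigs.get(chunk.chunk_id, [])
        if len(m.sequence) >= min_keep
    ]
    changed = True
    while changed:
        changed = False
        pieces.sort(key=lambda s: (-len(s), s))
        kept: list[str] = []
        for s in pieces:  # containment (incl. reverse complement) dedup
            rc = revcomp(s)
            if any(s in t or rc in t for t in kept):
                continue
            kept.append(s)
        pieces = kept
        for i in range(len(pieces)):
            if changed:
                break
            for j in range(i + 1, len(pieces)):
                merged = _try_merge(pieces[i], pieces[j], min_overlap,
                                    min_identity, exact_min_overlap)
                if merged is not None:
                    pieces = [p for k, p in enumerate(pieces) if k not in (i, j)]
                    pieces.append(merged)
                    changed = True
                    break
    pieces.sort(key=lambda s: (-len(s), s))
    return [
        HaploidContig(
            contig_id=f"{block_id}.h{hap}.s{i}",
            haplotype=hap,
            chrom=chrom,
            sequence=s,
        )
        for i, s in enumerate(pieces)
    ]


# ---------------------------------------------------------------------------
# external assembler adapter


def external_assembler_adapter(
    reads: Sequence[tuple[str, str, str]],
    workdir: str | Path,
    command_template: str,
    chunk_id: str = "chunk",
) -> list[MiniContig]:
    """Run an external assembler on a chunk's reads.

    ``command_template`` may reference ``{r1}``, ``{r2}``, ``{out_fasta}`` and
    ``{workdir}``; the command must write contigs to ``{out_fasta}``.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    r1 = workdir / "reads_1.fastq"
    r2 = workdir / "reads_2.fastq"
    out_fasta = workdir / "contigs.fasta"
    write_barcoded_fastq(
        (BarcodedRead(rid, "", 1, s1, "I" * len(s1)) for rid, s1, _ in reads), r1)
    write_barcoded_fastq(
        (BarcodedRead(rid, "", 2, s2, "I" * len(s2)) for rid, _, s2 in reads), r2)
    cmd = command_template.format(r1=r1, r2=r2, out_fasta=out_fasta, workdir=workdir)
    log_path = workdir / "assembler.log"
    try:
        with open(log_path, "w") as lf:
            proc = subprocess.run(shlex.split(cmd), stdout=lf,
                                  stderr=subprocess.STDOUT)
    except FileNotFoundError as exc:
        raise RuntimeError(f"external assembler not found: {exc}") from exc
    if proc.returncode != 0 or not out_fasta.exists():
        raise RuntimeError(
            f"external assembler failed (exit {proc.returncode}); log: {log_path}")
    genome = load_fasta(out_fasta)
    contigs = [
        MiniContig(f"{chunk_id}.x{i}", chunk_id, genome[name], 0.0)
        for i, name in enumerate(genome.chroms)
    ]
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs
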