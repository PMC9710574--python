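"""Haplotype partitioning of long fragments via SNP-pair clustering.

Each reconstructed fragment is annotated with the alleles it carries at
heterozygous SNPs (majority vote of its member reads, projected through the
read CIGARs). Every fragment covering a pair of het SNPs then votes the pair
*cis* (same alleles, 0/0 or 1/1) or *trans* (opposite). Pairs with enough,
sufficiently pure support become phase edges; connected components of phase
edges are phase blocks, with phases propagated by breadth-first traversal
from the lowest-index SNP. Fragments are finally assigned to the haplotype
the majority of their allele observations agree with; ties and uninformative
fragments go to both haplotypes so their reads stay available to both local
assemblies.
"""
from __future__ import annotations

import logging
from bisect import bisect_left
from collections import defaultdict, deque
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .fragments import HAP_BOTH, LongFragment
from .io_formats import AlignmentRecord, HetSNP
from .util import n50

log = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 2
DEFAULT_PURITY = 0.8
CONFLICT_SPLIT_RATE = 0.2


@dataclass(frozen=True)
class AlleleObservation:
    fragment_id: str
    snp_index: int
    allele: int  # 0 = ref, 1 = alt
    support: int  # reads backing the majority call


@dataclass
class LinkGraph:
    """cis/trans fragment support for every covered het-SNP pair (one chrom)."""

    chrom: str
    counts: dict[tuple[int, int], list[int]] = field(default_factory=dict)

    def add(self, i: int, j: int, same: bool) -> None:
        key = (i, j) if i < j else (j, i)
        slot = self.counts.setdefault(key, [0, 0])
        slot[0 if same else 1] += 1

    def cis(self, i: int, j: int) -> int:
        return self.counts.get((min(i, j), max(i, j)), (0, 0))[0]

    def trans(self, i: int, j: int) -> int:
        return self.counts.get((min(i, j), max(i, j)), (0, 0))[1]

    @property
    def nodes(self) -> set[int]:
        out = set()
        for i, j in self.counts:
            out.add(i)
            out.add(j)
        return out


@dataclass
class PhaseBlock:
    block_id: str
    chrom: str
    start: int
    end: int
    snp_phase: dict[int, int]  # snp index -> allele carried by haplotype 0
    hap_fragments: tuple[set[str], set[str]] = field(
        default_factory=lambda: (set(), set()))
    both_fragments: set[str] = field(default_factory=set)

    @property
    def n_snps(self) -> int:
        return len(self.snp_phase)

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# annotation


def _project_read(rec: AlignmentRecord, positions: Sequence[int]) -> dict[int, str]:
    """Reference position -> read base for the requested positions.

    Positions falling in deletions/skips or outside aligned segments are
    absent from the result.
    """
    out: dict[int, str] = {}
    if not positions or not rec.seq:
        return out
    ref = rec.pos
    read = 0
    pi = 0
    npos = len(positions)
    while pi < npos and positions[pi] < ref:
        pi += 1
    for op, length in rec.cigar:
        if pi >= npos:
            break
        if op in "M=X":
            seg_end = ref + length
            while pi < npos and positions[pi] < seg_end:
                p = positions[pi]
                if p >= ref:
                    out[p] = rec.seq[read + (p - ref)]
                pi += 1
            ref = seg_end
            read += length
        elif op in "DN":
            seg_end = ref + length
            while pi < npos and positions[pi] < seg_end:
                pi += 1
            ref = seg_end
        elif op in "IS":
            read += length
        # H, P consume nothing relevant
    return out


def annotate_fragments(
    fragments: Iterable[LongFragment],
    het_snps: Mapping[str, list[HetSNP]],
    alignments: Iterable[AlignmentRecord] | None = None,
    reference=None,
) -> int:
    """Fill ``allele_obs`` on each fragment; returns number of observations.

    Member reads vote on every het SNP inside the fragment span; a strict
    majority for the ref (alt) allele records allele 0 (1) with the vote count
    as support. Ties and majorities for neither allele record nothing.
    ``alignments`` is accepted for API symmetry but fragments already carry
    their member read placements; ``reference`` is unused (ref/alt come from
    the SNP table).
    """
    del alignments, reference
    pos_cache: dict[str, list[int]] = {
        chrom: [s.pos for s in snps] for chrom, snps in het_snps.items()
    }
    n_obs = 0
    uncallable = 0
    for frag in fragments:
        snps = het_snps.get(frag.chrom)
        if not snps:
            continue
        positions = pos_cache[frag.chrom]
        lo = bisect_left(positions, frag.start)
        hi = bisect_left(positions, frag.end)
        if lo == hi:
            continue
        window = positions[lo:hi]
        votes: dict[int, list[int]] = defaultdict(lambda: [0, 0])
        for rec in frag.reads:
            based = _project_read(rec, window)
            for p, base in based.items():
                idx = lo + bisect_left(window, p)
                snp = snps[idx]
                if base == snp.ref_allele:
                    votes[snp.index][0] += 1
                elif base == snp.alt_allele:
                    votes[snp.index][1] += 1
        frag.allele_obs = {}
        for snp_index, (vref, valt) in votes.items():
            if vref > valt:
                frag.allele_obs[snp_index] = AlleleObservation(
                    frag.fragment_id, snp_index, 0, vref)
            elif valt > vref:
                frag.allele_obs[snp_index] = AlleleObservation(
                    frag.fragment_id, snp_index, 1, valt)
            else:
                uncallable += 1
        n_obs += len(frag.allele_obs)
    if uncallable:
        log.info("annotate_fragments: %d tied/uncallable sites skipped", uncallable)
    return n_obs


# ---------------------------------------------------------------------------
# link graph + clustering


def build_link_graph(fragments: Iterable[LongFragment]) -> dict[str, LinkGraph]:
    """Per-chromosome cis/trans pair counts from annotated fragments."""
    graphs: dict[str, LinkGraph] = {}
    for frag in fragments:
        if len(frag.allele_obs) < 2:
            continue
        g = graphs.setdefault(frag.chrom, LinkGraph(frag.chrom))
        obs = sorted(frag.allele_obs.items())
        for (i, oi), (j, oj) in combinations(obs, 2):
            g.add(i, j, oi.allele == oj.allele)
    return graphs


def _phase_edges(graph: LinkGraph, min_support: int, purity: float):
    edges: dict[tuple[int, int], int] = {}
    for (i, j), (c, t) in graph.counts.items():
        tot = c + t
        if tot >= min_support and max(c, t) / tot >= purity:
            edges[(i, j)] = 0 if c >= t else 1  # 0 = same phase, 1 = opposite
    return edges


def _partition(edges: Mapping[tuple[int, int], int]):
    """BFS phase propagation; returns (component phase maps, conflict edges)."""
    adj: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for (i, j), rel in edges.items():
        adj[i].append((j, rel))
        adj[j].append((i, rel))
    phase: dict[int, int] = {}
    comps: list[dict[int, int]] = []
    conflicts: list[tuple[int, int]] = []
    for start in sorted(adj):
        if start in phase:
            continue
        comp = {start: 0}
        phase[start] = 0
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v, rel in sorted(adj[u]):
                want = comp[u] ^ rel
                if v in comp:
                    if comp[v] != want:
                        conflicts.append((min(u, v), max(u, v)))
                else:
                    comp[v] = want
                    phase[v] = want
                    queue.append(v)
        comps.append(comp)
    return comps, conflicts


def recursive_cluster(
    graph: LinkGraph,
    min_support: int = DEFAULT_MIN_SUPPORT,
    purity: float = DEFAULT_PURITY,
    fragments: Sequence[LongFragment] | None = None,
    max_depth: int = 5,
) -> list[dict[int, int]]:
    """Cluster het SNPs of one chromosome into phased components.

    SNP pairs with ``cis+trans >= min_support`` and majority fraction
    ``>= purity`` become phase edges (cis => same phase, trans => opposite).
    Components of phase edges are phased by BFS from the lowest SNP index
    (assigned phase 0); contradicting edges are dropped and counted, and a
    component whose conflict rate exceeds 20% is re-partitioned without its
    conflicted edges. When ``fragments`` are supplied, each component is
    re-clustered from the fragments wholly internal to it until the
    assignment is stable (depth-capped).
    """
    edges = _phase_edges(graph, min_support, purity)
    comps, conflicts = _partition(edges)
    if conflicts:
        n_edges = max(len(edges), 1)
        if len(conflicts) / n_edges > CONFLICT_SPLIT_RATE:
            log.warning("phase component conflict rate %.2f > %.2f; splitting",
                        len(conflicts) / n_edges, CONFLICT_SPLIT_RATE)
            for e in set(conflicts):
                edges.pop(e, None)
            comps, conflicts = _partition(edges)
        else:
            log.info("recursive_cluster: dropped %d conflicting edges", len(conflicts))
    if fragments is None or max_depth <= 0:
        return comps
    out: list[dict[int, int]] = []
    for comp in comps:
        out.extend(_refine_component(comp, fragments, graph.chrom,
                                     min_support, purity, max_depth))
    return out


def _refine_component(
    comp: dict[int, int],
    fragments: Sequence[LongFragment],
    chrom: str,
    min_support: int,
    purity: float,
    depth: int,
) -> list[dict[int, int]]:
    """Re-cluster one component using only fragments wholly internal to it,
    repeating until the assignment is stable (or the depth cap is hit)."""
    if depth <= 0 or len(comp) < 3:
        return [comp]
    members = set(comp)
    internal = [
        f for f in fragments
        if len(f.allele_obs) >= 2 and set(f.allele_obs) <= members
    ]
    sub = LinkGraph(chrom)
    for f in internal:
        obs = sorted(f.allele_obs.items())
        for (i, oi), (j, oj) in combinations(obs, 2):
            sub.add(i, j, oi.allele == oj.allele)
    refined = recursive_cluster(sub, min_support, purity,
                                fragments=None, max_depth=0)
    if not refined or (len(refined) == 1 and refined[0] == comp):
        return [comp]
    result: list[dict[int, int]] = []
    covered: set[int] = set()
    for r in refined:
        covered |= set(r)
        result.extend(
            _refine_component(r, internal, chrom, min_support, purity, depth - 1))
    # SNPs with no wholly-internal support stay unphased (singleton components)
    for i in sorted(members - covered):
        result.append({i: comp[i]})
    return result


def build_phase_blocks(
    comps: list[dict[int, int]], het_snps: list[HetSNP], chrom: str
) -> list[PhaseBlock]:
    by_index = {s.index: s for s in het_snps}
    blocks = []
    for comp in sorted(comps, key=lambda c: min(c)):
        if len(comp) < 2:
            continue
        positions = [by_index[i].pos for i in comp]
        blocks.append(
            PhaseBlock(
                block_id=f"{chrom}.b{len(blocks)}",
                chrom=chrom,
                start=min(positions),
                end=max(positions) + 1,
                snp_phase=dict(sorted(comp.items())),
            )
        )
    return blocks


def phase_chromosome(
    fragments: Sequence[LongFragment],
    het_snps: list[HetSNP],
    chrom: str,
    min_support: int = DEFAULT_MIN_SUPPORT,
    purity: float = DEFAULT_PURITY,
) -> list[PhaseBlock]:
    chrom_frags = [f for f in fragments if f.chrom == chrom]
    graphs = build_link_graph(chrom_frags)
    if chrom not in graphs:
        return []
    comps = recursive_cluster(graphs[chrom], min_support, purity,
                              fragments=chrom_frags)
    return build_phase_blocks(comps, het_snps, chrom)


def assign_fragments(
    fragments: Sequence[LongFragment], phase_blocks: Sequence[PhaseBlock]
) -> None:
    """Set each fragment's haplotype by majority agreement with block phases.

    A fragment votes within the single block holding most of its observations;
    ``v0 > v1`` => haplotype "0", ``v1 > v0`` => "1", ties (including no
    informative observation) => "both".
    """
    snp_map: dict[tuple[str, int], tuple[int, int]] = {}
    for bi, block in enumerate(phase_blocks):
        for snp_index, phase in block.snp_phase.items():
            snp_map[(block.chrom, snp_index)] = (bi, phase)
    for frag in fragments:
        votes: dict[int, list[int]] = defaultdict(lambda: [0, 0])
        for snp_index, obs in frag.allele_obs.items():
            hit = snp_map.get((frag.chrom, snp_index))
            if hit is None:
                continue
            bi, phase = hit
            if obs.allele == phase:
                votes[bi][0] += 1
            else:
                votes[bi][1] += 1
        if not votes:
            frag.haplotype = HAP_BOTH
            continue
        bi = max(sorted(votes), key=lambda b: sum(votes[b]))
        v0, v1 = votes[bi]
        if v0 > v1:
            frag.haplotype = "0"
            phase_blocks[bi].hap_fragments[0].add(frag.fragment_id)
        elif v1 > v0:
            frag.haplotype = "1"
            phase_blocks[bi].hap_fragments[1].add(frag.fragment_id)
        else:
            frag.haplotype = HAP_BOTH
            phase_blocks[bi].both_fragments.add(frag.fragment_id)


def phase_block_n50(blocks: Sequence[PhaseBlock]) -> int:
    return n50([b.span for b in blocks])


def emit_phase_blocks(
    blocks: Sequence[PhaseBlock], path: str | Path | None = None
) -> dict:
    """Phase-block report: per-block TSV plus summary with block N50."""
    if path is not None:
        with open(path, "w") as fh:
            fh.write("block_id\tchrom\tstart\tend\tn_snps\t"
                     "n_frag_h0\tn_frag_h1\tn_frag_both\n")
            for b in blocks:
                fh.write(f"{b.block_id}\t{b.chrom}\t{b.start}\t{b.end}\t"
                         f"{b.n_snps}\t{len(b.hap_fragments[0])}\t"
                         f"{len(b.hap_fragments[1])}\t{len(b.both_fragments)}\n")
    return {
        "n_blocks": len(blocks),
        "n_snps_phased": sum(b.n_snps for b in blocks),
        "total_span": sum(b.span for b in blocks),
        "n50": phase_block_n50(blocks) if blocks else 0,
    }
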