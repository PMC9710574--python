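"""Long-fragment (LFR) reconstruction from barcoded alignments.

Reads sharing a barcode on one chromosome are assumed to come from a small
number of long DNA molecules. The barcode deconvolution rule is a gap
threshold: walking position-sorted reads of one (barcode, chromosome) group,
a new fragment starts whenever the physical gap between the aligned footprint
so far and the next read exceeds ``boundary_bp`` (50 kb by default). The gap
is measured end-to-start — from the rightmost aligned base seen so far to the
start of the next read.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io_formats import AlignmentRecord
from .util import n50

log = logging.getLogger(__name__)

HAP_UNASSIGNED = "unassigned"
HAP_BOTH = "both"

DEFAULT_BOUNDARY_BP = 50_000
DEFAULT_MIN_READS = 2


@dataclass
class LongFragment:
    fragment_id: str
    barcode: str
    chrom: str
    start: int
    end: int
    reads: list[AlignmentRecord] = field(default_factory=list)
    allele_obs: dict = field(default_factory=dict)  # snp index -> AlleleObservation
    haplotype: str = HAP_UNASSIGNED  # "0" | "1" | "both" | "unassigned"

    @property
    def read_ids(self) -> set[str]:
        return {r.read_id for r in self.reads}

    @property
    def n_reads(self) -> int:
        return len(self.reads)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentStats:
    count: int
    mean_length: float
    n50: int
    mean_reads: float


def group_reads_by_barcode(
    alignments: Iterable[AlignmentRecord],
) -> dict[tuple[str, str], list[AlignmentRecord]]:
    """Position-sorted alignment lists keyed by (barcode, chrom).

    Unmapped, secondary/supplementary and unbarcoded records are excluded
    (counted in a log line).
    """
    groups: dict[tuple[str, str], list[AlignmentRecord]] = {}
    dropped = 0
    for rec in alignments:
        if rec.is_unmapped or rec.is_secondary or not rec.barcode:
            dropped += 1
            continue
        groups.setdefault((rec.barcode, rec.chrom), []).append(rec)
    for lst in groups.values():
        lst.sort(key=lambda r: (r.pos, r.read_id, r.mate))
    if dropped:
        log.info("group_reads_by_barcode: excluded %d records", dropped)
    return groups


def split_barcode_group(
    sorted_alignments: list[AlignmentRecord],
    boundary_bp: int = DEFAULT_BOUNDARY_BP,
    barcode: str | None = None,
    chrom: str | None = None,
    id_prefix: str | None = None,
) -> list[LongFragment]:
    """Split one position-sorted (barcode, chrom) group into fragments.

    A break is placed between successive reads whenever
    ``next.pos - footprint_end > boundary_bp``, where ``footprint_end`` is the
    running maximum alignment end within the current fragment.
    """
    if not sorted_alignments:
        return []
    barcode = barcode if barcode is not None else sorted_alignments[0].barcode
    chrom = chrom if chrom is not None else sorted_alignments[0].chrom
    prefix = id_prefix if id_prefix is not None else f"{barcode}.{chrom}"
    fragments: list[LongFragment] = []
    cur: list[AlignmentRecord] = []
    cur_end = None
    for rec in sorted_alignments:
        if cur and rec.pos - cur_end > boundary_bp:
            fragments.append(_make_fragment(prefix, len(fragments), barcode, chrom, cur))
            cur = []
            cur_end = None
        cur.append(rec)
        end = rec.ref_end
        cur_end = end if cur_end is None else max(cur_end, end)
    fragments.append(_make_fragment(prefix, len(fragments), barcode, chrom, cur))
    return fragments


def _make_fragment(prefix, ordinal, barcode, chrom, reads) -> LongFragment:
    start = reads[0].pos
    end = max(r.ref_end for r in reads)
    return LongFragment(
        fragment_id=f"{prefix}.{ordinal}",
        barcode=barcode,
        chrom=chrom,
        start=start,
        end=max(end, start + 1),
        reads=list(reads),
    )


def reconstruct_fragments(
    alignments: Iterable[AlignmentRecord],
    boundary_bp: int = DEFAULT_BOUNDARY_BP,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[LongFragment]:
    """Group + split + size filter; the main fragment-reconstruction entry.

    Fragments with fewer than ``min_reads`` member reads carry no linking
    information and are discarded (set ``min_reads=1`` to keep singletons).
    """
    groups = group_reads_by_barcode(alignments)
    fragments: list[LongFragment] = []
    small = 0
    for (barcode, chrom) in sorted(groups):
        frs = split_barcode_group(groups[(barcode, chrom)], boundary_bp,
                                  barcode=barcode, chrom=chrom)
        for fr in frs:
            if fr.n_reads < min_reads:
                small += 1
            else:
                fragments.append(fr)
    if small:
        log.info("reconstruct_fragments: dropped %d fragments with < %d reads",
                 small, min_reads)
    if not fragments:
        log.warning("reconstruct_fragments: no fragments reconstructed")
    fragments.sort(key=lambda f: (f.chrom, f.start, f.fragment_id))
    return fragments


def fragment_stats(fragments: list[LongFragment]) -> FragmentStats:
    if not fragments:
        raise ValueError("fragment_stats of an empty fragment list")
    lengths = [f.length for f in fragments]
    return FragmentStats(
        count=len(fragments),
        mean_length=sum(lengths) / len(lengths),
        n50=n50(lengths),
        mean_reads=sum(f.n_reads for f in fragments) / len(fragments),
    )


def write_fragment_tsv(fragments: list[LongFragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_id\tbarcode\tchrom\tstart\tend\tn_reads\thaplotype\n")
        for f in fragments:
            fh.write(f"{f.fragment_id}\t{f.barcode}\t{f.chrom}\t{f.start}\t"
                     f"{f.end}\t{f.n_reads}\t{f.haplotype}\n")
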