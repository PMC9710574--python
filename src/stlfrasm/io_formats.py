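"""Readers and writers for the interchange formats the pipeline touches.

Conventions honored throughout:

* stLFR barcodes travel as a whitespace-delimited ``BX:Z:<barcode>`` token in
  FASTQ header lines and as a ``BX`` tag in SAM records; both map onto the
  same ``barcode`` field. A configurable null-barcode set (stLFR's ``0_0_0``)
  is treated as unbarcoded.
* All internal coordinates are 0-based half-open. 1-based conventions (SAM
  POS, VCF POS) are converted at the parse/write boundary and nowhere else.
* Emitted VCFs use the anchor-base convention: POS is the base before the
  event and REF/ALT carry the anchor base.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pysam
from pyfaidx import Fasta

log = logging.getLogger(__name__)

DEFAULT_NULL_BARCODES = frozenset({"0_0_0"})

CIGAR_OPS = "MIDNSHP=X"
REF_CONSUMING = frozenset("MDN=X")
QUERY_CONSUMING = frozenset("MIS=X")


class FormatError(ValueError):
    """A file violated the format contract of its parser."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class BarcodedRead:
    read_id: str
    barcode: str  # "" = unbarcoded
    mate: int  # 1 or 2
    sequence: str
    qualities: str


@dataclass
class AlignmentRecord:
    read_id: str
    barcode: str
    chrom: str
    pos: int  # 0-based leftmost reference coordinate
    mapq: int
    cigar: list[tuple[str, int]]
    is_unmapped: bool = False
    is_secondary: bool = False
    mate: int = 1
    seq: str = ""

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned reference footprint."""
        return self.pos + sum(n for op, n in self.cigar if op in REF_CONSUMING)


@dataclass(frozen=True)
class HetSNP:
    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    index: int  # ordinal within chrom, in position order


@dataclass
class ReferenceGenome:
    sequences: dict[str, str]

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    n_match: int
    aln_len: int
    mapq: int
    cigar: list[tuple[str, int]] | None = None


# ---------------------------------------------------------------------------
# FASTQ


def _open_maybe(source, mode="r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def parse_barcoded_fastq(
    source: str | Path | IO[str],
    mate: int | None = None,
    null_barcodes: frozenset[str] = DEFAULT_NULL_BARCODES,
) -> Iterator[BarcodedRead]:
    """Iterate 4-line FASTQ records, lifting the ``BX:Z:`` barcode token.

    Mate is taken from a ``/1`` / ``/2`` read-id suffix when present,
    otherwise from the ``mate`` argument (for separate R1/R2 files), defaulting
    to 1.
    """
    fh, close = _open_maybe(source)
    try:
        it = iter(fh)
        idx = 0
        for header in it:
            header = header.rstrip("\n")
            try:
                seq = next(it).rstrip("\n")
                plus = next(it)
                qual = next(it).rstrip("\n")
            except StopIteration:
                raise FormatError(f"truncated FASTQ record {idx}") from None
            if not header.startswith("@") or not plus.startswith("+"):
                raise FormatError(f"malformed FASTQ record {idx}: bad markers")
            tokens = header[1:].split()
            if not tokens:
                raise FormatError(f"malformed FASTQ record {idx}: empty header")
            read_id = tokens[0]
            m = mate
            if read_id.endswith(("/1", "/2")):
                m = int(read_id[-1])
                read_id = read_id[:-2]
            if m is None:
                m = 1
            if len(seq) != len(qual):
                raise FormatError(
                    f"FASTQ record {idx} ({read_id}): sequence/quality length mismatch"
                )
            barcode = ""
            for tok in tokens[1:]:
                if tok.startswith("BX:Z:"):
                    barcode = tok[5:]
                    break
            if barcode in null_barcodes:
                barcode = ""
            yield BarcodedRead(read_id, barcode, m, seq.upper(), qual)
            idx += 1
    finally:
        if close:
            fh.close()


def write_barcoded_fastq(reads: Iterable[BarcodedRead], dest: str | Path | IO[str]) -> int:
    fh, close = _open_maybe(dest, "w")
    n = 0
    try:
        for r in reads:
            bx = f" BX:Z:{r.barcode}" if r.barcode else ""
            fh.write(f"@{r.read_id}/{r.mate}{bx}\n{r.sequence}\n+\n{r.qualities}\n")
            n += 1
    finally:
        if close:
            fh.close()
    return n


def build_read_index(
    r1: str | Path, r2: str | Path | None = None
) -> dict[str, tuple[str, str]]:
    """Map read_id -> (mate1 sequence, mate2 sequence) from FASTQ file(s)."""
    index: dict[str, list[str]] = {}
    for path, default_mate in ((r1, 1), (r2, 2)):
        if path is None:
            continue
        for rec in parse_barcoded_fastq(path, mate=default_mate):
            slot = index.setdefault(rec.read_id, ["", ""])
            slot[rec.mate - 1] = rec.sequence
    return {rid: (s1, s2) for rid, (s1, s2) in index.items()}


# ---------------------------------------------------------------------------
# SAM


def parse_alignments(
    source: str | Path,
    null_barcodes: frozenset[str] = DEFAULT_NULL_BARCODES,
) -> Iterator[AlignmentRecord]:
    """Iterate SAM (or BAM, via pysam) records as :class:`AlignmentRecord`.

    SAM 1-based POS becomes a 0-based internal coordinate. Records without a
    ``BX`` tag get ``barcode == ""``. Supplementary records are flagged
    secondary for the purposes of fragment reconstruction.
    """
    with pysam.AlignmentFile(str(source), "r", check_sq=False) as af:
        i = 0
        it = iter(af)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(f"malformed SAM near record {i}: {exc}") from exc
            cigar = [(CIGAR_OPS[op], n) for op, n in (rec.cigartuples or [])]
            barcode = rec.get_tag("BX") if rec.has_tag("BX") else ""
            if barcode in null_barcodes:
                barcode = ""
            unmapped = rec.is_unmapped
            yield AlignmentRecord(
                read_id=rec.query_name,
                barcode=barcode,
                chrom=rec.reference_name or "",
                pos=0 if unmapped else rec.reference_start,
                mapq=rec.mapping_quality,
                cigar=[] if unmapped else cigar,
                is_unmapped=unmapped,
                is_secondary=rec.is_secondary or rec.is_supplementary,
                mate=2 if rec.is_read2 else 1,
                seq=rec.query_sequence or "",
            )
            i += 1


# ---------------------------------------------------------------------------
# VCF (small variants in, SVs out/in)


_HET_GTS = {(0, 1), (1, 0)}
_BASES = {"A", "C", "G", "T"}


def parse_het_snps(
    vcf_path: str | Path, sample_index: int = 0
) -> dict[str, list[HetSNP]]:
    """Heterozygous biallelic SNPs per chromosome, position-sorted, 0-based.

    Multiallelic records, indels, homozygous and missing genotypes are
    skipped (counted in a log line). Unsorted input is sorted with a warning.
    """
    per_chrom: dict[str, list[tuple[int, str, str]]] = {}
    skipped = 0
    unsorted = False
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1 or rec.ref not in _BASES or alts[0] not in _BASES:
                skipped += 1
                continue
            try:
                sample = rec.samples[sample_index]
                gt = tuple(sample["GT"])
            except (IndexError, KeyError):
                skipped += 1
                continue
            if None in gt or tuple(gt) not in _HET_GTS:
                skipped += 1
                continue
            lst = per_chrom.setdefault(rec.chrom, [])
            pos0 = rec.pos - 1
            if lst and lst[-1][0] > pos0:
                unsorted = True
            lst.append((pos0, rec.ref, alts[0]))
    if unsorted:
        log.warning("het-SNP VCF was not position-sorted; sorting internally")
    if skipped:
        log.info("parse_het_snps: skipped %d non-het/non-SNP records", skipped)
    out: dict[str, list[HetSNP]] = {}
    for chrom, lst in per_chrom.items():
        lst.sort()
        out[chrom] = [
            HetSNP(chrom, pos, ref, alt, i) for i, (pos, ref, alt) in enumerate(lst)
        ]
    return out


# ---------------------------------------------------------------------------
# PAF


_CG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_paf(source: str | Path | IO[str]) -> list[PafRecord]:
    """Parse minimap2-style PAF; keeps 0-based half-open coordinates as-is."""
    fh, close = _open_maybe(source)
    records = []
    try:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"PAF line {ln}: fewer than 12 columns")
            cigar = None
            for tag in cols[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = [(m.group(2), int(m.group(1)))
                             for m in _CG_RE.finditer(tag[5:])]
                    break
            try:
                records.append(
                    PafRecord(
                        qname=cols[0], qlen=int(cols[1]), qstart=int(cols[2]),
                        qend=int(cols[3]), strand=cols[4], tname=cols[5],
                        tlen=int(cols[6]), tstart=int(cols[7]), tend=int(cols[8]),
                        n_match=int(cols[9]), aln_len=int(cols[10]),
                        mapq=int(cols[11]), cigar=cigar,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"PAF line {ln}: {exc}") from exc
    finally:
        if close:
            fh.close()
    return records


# ---------------------------------------------------------------------------
# SV VCF


VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the event">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="1-based end of the event on the reference">',
    '##INFO=<ID=HAP,Number=.,Type=String,Description="Supporting haplotypes">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_vcf(sv_calls: Sequence, reference: ReferenceGenome, out_path: str | Path) -> None:
    """Write DEL/INS calls as VCF v4.2 with the anchor-base convention.

    Calls must be sorted by (chrom, pos); internal pos is the 0-based base
    before the event, so VCF POS (1-based) equals internal pos + 1.
    """
    prev = None
    for c in sv_calls:
        key = (c.chrom, c.pos)
        if prev is not None and key < prev:
            raise FormatError("SV calls must be sorted by (chrom, pos)")
        prev = key
    lines = list(VCF_HEADER_LINES)
    for chrom in reference.chroms:
        lines.append(f"##contig=<ID={chrom},length={reference.length(chrom)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE")
    for i, c in enumerate(sv_calls):
        seq = reference[c.chrom]
        p = c.pos
        anchor = seq[p]
        if c.svtype == "DEL":
            ref_field = seq[p:p + c.svlen + 1]
            alt_field = anchor
            svlen = -c.svlen
            end = p + 1 + c.svlen  # 1-based inclusive end
        elif c.svtype == "INS":
            ref_field = anchor
            alt_field = anchor + c.alt_seq
            svlen = c.svlen
            end = p + 1
        else:
            raise FormatError(f"unsupported svtype {c.svtype!r}")
        hap = ",".join(str(h) for h in sorted(c.haplotypes)) if c.haplotypes else "."
        info = f"SVTYPE={c.svtype};SVLEN={svlen};END={end};HAP={hap}"
        lines.append(
            f"{c.chrom}\t{p + 1}\t{c.svtype}_{i}\t{ref_field}\t{alt_field}"
            f"\t.\tPASS\t{info}\tGT\t{c.genotype}"
        )
    Path(out_path).write_text("\n".join(lines) + "\n")


def read_sv_vcf(path: str | Path) -> list:
    """Read an SV VCF written by :func:`write_vcf` (or similar) back to calls."""
    from .svcall import SVCall  # local import to avoid a cycle

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in ("DEL", "INS"):
                continue
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svlen is None:
                svlen = len(rec.alts[0]) - len(rec.ref)
            svlen = abs(int(svlen))
            alt_seq = rec.alts[0][1:] if svtype == "INS" else ""
            hap_info = rec.info.get("HAP", ".")
            if isinstance(hap_info, tuple):
                haps = frozenset(int(h) for h in hap_info if h != ".")
            elif hap_info in (".", None):
                haps = frozenset()
            else:
                haps = frozenset(int(h) for h in str(hap_info).split(","))
            gt = "0/1"
            if rec.samples:
                gtt = rec.samples[0].get("GT")
                if gtt and None not in gtt:
                    gt = "1/1" if all(a == 1 for a in gtt) else "0/1"
            filt = list(rec.filter) or ["PASS"]
            calls.append(
                SVCall(
                    chrom=rec.chrom, pos=rec.pos - 1, svtype=svtype, svlen=svlen,
                    alt_seq=alt_seq, haplotypes=haps, genotype=gt,
                    filter=filt[0],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(
    records: Mapping[str, str] | Iterable[tuple[str, str]],
    out_path: str | Path,
    width: int = 60,
) -> None:
    items = records.items() if isinstance(records, Mapping) else records
    with open(out_path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def load_fasta(path: str | Path) -> ReferenceGenome:
    fa = Fasta(str(path))
    seqs = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    if not seqs:
        raise FormatError(f"no sequences in {path}")
    return ReferenceGenome(seqs)
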