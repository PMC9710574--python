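"""Synthetic diploid genomes and stLFR-style linked-reads with full truth.

The generator emulates the salient features of an stLFR library: a diploid
genome with planted het SNPs and DEL/INS structural variants; long DNA
fragments (exponential lengths, 30 kb mean, 1 kb floor) sampled from each
haplotype; several fragments sharing one triplet barcode (``a_b_c``), which
creates the barcode deconvolution problem; 100 bp paired reads sampled within
fragments at a configurable within-fragment coverage, with substitution
errors; and a truth-position SAM so the pipeline runs without an external
aligner. Defaults give ~48X total sequencing coverage (fragment coverage 10
per haplotype x within-fragment read coverage 2.4), matching a production
stLFR library at desk scale.

Everything is deterministic under the config seed.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import HetSNP, ReferenceGenome, write_fasta
from .svcall import SVCall
from .util import BASE_CODES, revcomp

log = logging.getLogger(__name__)

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SVSpec:
    svtype: str  # DEL | INS
    count: int
    min_len: int
    max_len: int


@dataclass
class SimConfig:
    seed: int = 0
    ref_length: int = 500_000
    n_chroms: int = 1
    snp_rate: float = 1 / 1500
    sv_specs: tuple[SVSpec, ...] = (
        SVSpec("DEL", 5, 50, 1000),
        SVSpec("DEL", 5, 1000, 5000),
        SVSpec("INS", 5, 50, 1000),
        SVSpec("INS", 5, 1000, 5000),
    )
    hom_sv_fraction: float = 0.2
    fragment_mean_length: int = 30_000
    fragment_min_length: int = 1_000
    fragments_per_barcode: tuple[int, int] = (1, 3)  # uniform inclusive range
    read_length: int = 100
    insert_mean: int = 400
    insert_sd: int = 50
    error_rate: float = 0.001
    # a production stLFR library co-barcodes ~8M fragments of ~30 kb mean
    # against a 3 Gb genome: ~80X physical coverage, i.e. ~40X per haplotype,
    # with ~0.6X read coverage inside each fragment -- giving ~48X total
    # sequencing coverage
    fragment_coverage: float = 40.0  # C_F: fragment bases per haplotype base
    read_coverage: float = 0.6  # C_R: read bases per fragment base
    edge_margin: int = 2_000
    sv_snp_clearance: int = 150
    # genomic separation enforced between fragments sharing a barcode; on a
    # genome-scale library collisions essentially never land adjacent, so the
    # desk-scale emulation keeps them at least twice the deconvolution
    # boundary apart
    barcode_collision_min_sep: int = 100_000


@dataclass(frozen=True)
class TruthSNP:
    chrom: str
    pos: int  # 0-based reference coordinate
    ref: str
    alt: str
    hap0_allele: int  # 1 if haplotype 0 carries the alt


@dataclass(frozen=True)
class TruthSV:
    chrom: str
    pos: int  # base before the event, 0-based
    svtype: str
    length: int
    seq: str  # inserted sequence (INS only)
    haplotypes: frozenset[int]


@dataclass
class TruthFragment:
    fragment_id: str
    barcode: str
    haplotype: int
    chrom: str
    hap_start: int
    hap_end: int
    ref_start: int
    ref_end: int


@dataclass
class ReadOrigin:
    read_id: str
    barcode: str
    fragment_id: str
    haplotype: int
    chrom: str
    start1: int  # haplotype coordinate of mate-1 window (forward)
    start2: int  # haplotype coordinate of mate-2 window (forward)
    seq1: str  # as sequenced (mate 2 is reverse-complemented)
    seq2: str


@dataclass
class DiploidTruth:
    config: SimConfig
    reference: ReferenceGenome
    haplotypes: dict[str, tuple[str, str]]
    snps: dict[str, list[TruthSNP]]
    svs: list[TruthSV]
    # (chrom, hap) -> list of (hap_start, hap_end, ref_start | None); None
    # marks inserted sequence with no reference image
    segment_maps: dict[tuple[str, int], list[tuple[int, int, int | None]]]

    def het_snps(self) -> dict[str, list[HetSNP]]:
        return {
            chrom: [HetSNP(chrom, s.pos, s.ref, s.alt, i)
                    for i, s in enumerate(snps)]
            for chrom, snps in self.snps.items()
        }

    def sv_truth_calls(self) -> list[SVCall]:
        calls = []
        for sv in sorted(self.svs, key=lambda s: (s.chrom, s.pos)):
            gt = "1/1" if sv.haplotypes == frozenset({0, 1}) else "0/1"
            calls.append(SVCall(sv.chrom, sv.pos, sv.svtype, sv.length,
                                alt_seq=sv.seq, haplotypes=sv.haplotypes,
                                genotype=gt))
        return calls

    def hap_to_ref(self, chrom: str, hap: int, pos: int) -> int | None:
        """Project a haplotype coordinate to the reference (None = inserted)."""
        segs = self.segment_maps[(chrom, hap)]
        starts = [s[0] for s in segs]
        i = bisect_right(starts, pos) - 1
        if i < 0:
            return None
        hs, he, rs = segs[i]
        if pos >= he or rs is None:
            return None
        return rs + (pos - hs)


# ---------------------------------------------------------------------------
# genome


def _rand_codes(rng, n) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def simulate_diploid_genome(config: SimConfig) -> DiploidTruth:
    """Random reference + phased SNPs + placed SVs + haplotype sequences.

    SVs are rejection-sampled with a minimum separation of twice the largest
    SV length; SNPs are kept clear of SV footprints so every VCF SNP is a
    clean phasing signal.
    """
    rng = np.random.default_rng([config.seed, 0])
    reference: dict[str, str] = {}
    haplotypes: dict[str, tuple[str, str]] = {}
    snps: dict[str, list[TruthSNP]] = {}
    svs: list[TruthSV] = []
    segment_maps: dict[tuple[str, int], list] = {}
    max_len = max((s.max_len for s in config.sv_specs), default=0)
    min_sep = 2 * max_len
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.ref_length
        ref_codes = _rand_codes(rng, L)
        reference[chrom] = _decode(ref_codes)

        placed: list[TruthSV] = []
        for spec in config.sv_specs:
            for _ in range(spec.count):
                length = int(rng.integers(spec.min_len, spec.max_len + 1))
                ok = False
                for _attempt in range(1000):
                    pos = int(rng.integers(
                        config.edge_margin, L - config.edge_margin - length - 1))
                    if all(abs(pos - p.pos) >= min_sep + p.length + length
                           for p in placed):
                        ok = True
                        break
                if not ok:
                    raise ValueError(
                        "could not place SVs without overlap; increase ref_length")
                if rng.random() < config.hom_sv_fraction:
                    haps = frozenset({0, 1})
                else:
                    haps = frozenset({int(rng.integers(0, 2))})
                seq = _decode(_rand_codes(rng, length)) if spec.svtype == "INS" else ""
                placed.append(TruthSV(chrom, pos, spec.svtype, length, seq, haps))
        placed.sort(key=lambda s: s.pos)
        svs.extend(placed)

        # SNPs clear of SV footprints and chromosome edges
        footprints = []
        for sv in placed:
            end = sv.pos + 1 + (sv.length if sv.svtype == "DEL" else 0)
            footprints.append((sv.pos - config.sv_snp_clearance,
                               end + config.sv_snp_clearance))
        hits = np.flatnonzero(rng.random(L) < config.snp_rate)
        chrom_snps: list[TruthSNP] = []
        for p in hits.tolist():
            if p < config.edge_margin or p >= L - config.edge_margin:
                continue
            if any(lo <= p < hi for lo, hi in footprints):
                continue
            ref_b = reference[chrom][p]
            alt_code = (int(ref_codes[p]) + int(rng.integers(1, 4))) % 4
            chrom_snps.append(TruthSNP(chrom, p, ref_b, "ACGT"[alt_code],
                                       int(rng.integers(0, 2))))
        snps[chrom] = chrom_snps

        haps = []
        for hap in (0, 1):
            codes = ref_codes.copy()
            sub_pos = [s.pos for s in chrom_snps
                       if (s.hap0_allele if hap == 0 else 1 - s.hap0_allele) == 1]
            if sub_pos:
                alt_codes = np.array(
                    ["ACGT".index(s.alt) for s in chrom_snps
                     if (s.hap0_allele if hap == 0 else 1 - s.hap0_allele) == 1],
                    dtype=np.uint8)
                codes[np.array(sub_pos)] = alt_codes
            for sv in sorted((s for s in placed if hap in s.haplotypes),
                             key=lambda s: -s.pos):
                if sv.svtype == "DEL":
                    codes = np.delete(codes, np.s_[sv.pos + 1:sv.pos + 1 + sv.length])
                else:
                    ins_codes = BASE_CODES[
                        np.frombuffer(sv.seq.encode(), dtype=np.uint8)]
                    codes = np.insert(codes, sv.pos + 1, ins_codes)
            haps.append(_decode(codes))
            segment_maps[(chrom, hap)] = _segments_for_hap(
                L, [s for s in placed if hap in s.haplotypes])
        haplotypes[chrom] = (haps[0], haps[1])
    return DiploidTruth(config, ReferenceGenome(reference), haplotypes,
                        snps, svs, segment_maps)


def _segments_for_hap(ref_len: int, hap_svs: Sequence[TruthSV]):
    """Matched (hap_start, hap_end, ref_start) blocks; insertions map to None."""
    segs = []
    ref_cur = 0
    hap_cur = 0
    for sv in sorted(hap_svs, key=lambda s: s.pos):
        span = sv.pos + 1 - ref_cur
        if span > 0:
            segs.append((hap_cur, hap_cur + span, ref_cur))
            hap_cur += span
        ref_cur = sv.pos + 1
        if sv.svtype == "DEL":
            ref_cur += sv.length
        else:
            segs.append((hap_cur, hap_cur + sv.length, None))
            hap_cur += sv.length
    if ref_cur < ref_len:
        segs.append((hap_cur, hap_cur + (ref_len - ref_cur), ref_cur))
    return segs


# ---------------------------------------------------------------------------
# fragments


def simulate_fragments(truth: DiploidTruth, config: SimConfig) -> list[TruthFragment]:
    """Sample fragments per haplotype to the configured physical coverage and
    assign shared barcodes (uniform 1..3 fragments per barcode by default)."""
    rng = np.random.default_rng([config.seed, 1])
    frags: list[TruthFragment] = []
    for chrom in truth.reference.chroms:
        for hap in (0, 1):
            hap_len = len(truth.haplotypes[chrom][hap])
            target = config.fragment_coverage * hap_len
            acc = 0.0
            while acc < target:
                length = int(rng.exponential(config.fragment_mean_length))
                length = max(config.fragment_min_length, min(length, hap_len))
                # starts may overhang the chromosome ends (clipped), so edge
                # positions see the same physical coverage as the interior
                raw = int(rng.integers(-(length - 1), hap_len))
                start = max(0, raw)
                end = min(hap_len, raw + length)
                length = end - start
                if length < 2 * config.read_length:
                    continue
                rs = truth.hap_to_ref(chrom, hap, start)
                re_ = truth.hap_to_ref(chrom, hap, start + length - 1)
                frags.append(TruthFragment(
                    fragment_id=f"F{len(frags):06d}",
                    barcode="", haplotype=hap, chrom=chrom,
                    hap_start=start, hap_end=start + length,
                    ref_start=rs if rs is not None else -1,
                    ref_end=re_ + 1 if re_ is not None else -1,
                ))
                acc += length
    # barcode assignment: k ~ uniform fragments share one triplet barcode,
    # kept mutually separated so deconvolution is well-posed (see SimConfig)
    order = rng.permutation(len(frags)).tolist()
    lo, hi = config.fragments_per_barcode
    sep = config.barcode_collision_min_sep
    used: set[str] = set()
    unassigned = order
    while unassigned:
        k = int(rng.integers(lo, hi + 1))
        bc = "_".join(str(int(x)) for x in rng.integers(1, 1537, 3))
        while bc in used:
            bc = "_".join(str(int(x)) for x in rng.integers(1, 1537, 3))
        used.add(bc)
        group = [unassigned[0]]
        rest = unassigned[1:]
        if k > 1:
            kept = []
            def far_enough(a: TruthFragment, b: TruthFragment) -> bool:
                if a.chrom != b.chrom:
                    return True
                if a.ref_start < 0 or b.ref_start < 0:
                    return False
                gap = max(b.ref_start - a.ref_end, a.ref_start - b.ref_end)
                return gap >= sep

            for j in rest:
                if len(group) < k and all(
                    far_enough(frags[j], frags[g]) for g in group
                ):
                    group.append(j)
                else:
                    kept.append(j)
            rest = kept
        for j in group:
            frags[j].barcode = bc
        unassigned = rest
    return frags


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    truth: DiploidTruth,
    fragments: Sequence[TruthFragment],
    config: SimConfig,
    r1_path: str | Path | None = None,
    r2_path: str | Path | None = None,
) -> list[ReadOrigin]:
    """Paired reads within fragments; writes R1/R2 FASTQ when paths given.

    Insert starts are uniform within the fragment, insert sizes normal
    (clipped to [2 x read length, fragment length]); mate 2 is
    reverse-complemented; substitution errors at the configured rate. Headers
    carry ``BX:Z:<barcode>``.
    """
    rng = np.random.default_rng([config.seed, 2])
    rl = config.read_length
    origins: list[ReadOrigin] = []
    skipped = 0
    hap_codes: dict[tuple[str, int], np.ndarray] = {}
    for chrom in truth.reference.chroms:
        for hap in (0, 1):
            seq = truth.haplotypes[chrom][hap]
            hap_codes[(chrom, hap)] = BASE_CODES[
                np.frombuffer(seq.encode(), dtype=np.uint8)]
    r1_lines: list[str] = []
    r2_lines: list[str] = []
    qual = "I" * rl
    for frag in fragments:
        L = frag.hap_end - frag.hap_start
        min_insert = 2 * rl
        if L < min_insert:
            skipped += 1
            continue
        n_pairs = int(round(L * config.read_coverage / (2 * rl)))
        if n_pairs <= 0:
            continue
        inserts = np.clip(
            rng.normal(config.insert_mean, config.insert_sd, n_pairs),
            min_insert, L).astype(np.int64)
        starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(np.int64)
        codes = hap_codes[(frag.chrom, frag.haplotype)]
        abs1 = frag.hap_start + starts
        abs2 = frag.hap_start + starts + inserts - rl
        win = np.arange(rl, dtype=np.int64)
        m1 = codes[abs1[:, None] + win[None, :]].copy()
        m2f = codes[abs2[:, None] + win[None, :]]
        m2 = (3 - m2f[:, ::-1]).copy()  # sequenced orientation (reverse strand)
        if config.error_rate > 0:
            for mat in (m1, m2):
                mask = rng.random(mat.shape) < config.error_rate
                n_err = int(mask.sum())
                if n_err:
                    mat[mask] = (mat[mask] + rng.integers(
                        1, 4, n_err, dtype=np.uint8)) % 4
        s1 = _DECODE[m1]
        s2 = _DECODE[m2]
        for j in range(n_pairs):
            rid = f"{frag.fragment_id}p{j}"
            seq1 = s1[j].tobytes().decode()
            seq2 = s2[j].tobytes().decode()
            bx = f" BX:Z:{frag.barcode}" if frag.barcode else ""
            r1_lines.append(f"@{rid}/1{bx}\n{seq1}\n+\n{qual}")
            r2_lines.append(f"@{rid}/2{bx}\n{seq2}\n+\n{qual}")
            origins.append(ReadOrigin(rid, frag.barcode, frag.fragment_id,
                                      frag.haplotype, frag.chrom,
                                      int(abs1[j]), int(abs2[j]), seq1, seq2))
    if skipped:
        log.info("simulate_reads: %d fragments shorter than one insert skipped",
                 skipped)
    if r1_path is not None:
        Path(r1_path).write_text("\n".join(r1_lines) + ("\n" if r1_lines else ""))
    if r2_path is not None:
        Path(r2_path).write_text("\n".join(r2_lines) + ("\n" if r2_lines else ""))
    return origins


# ---------------------------------------------------------------------------
# truth-position SAM


def _place_read(truth: DiploidTruth, chrom: str, hap: int, start: int, rl: int):
    """(pos, cigar) at the true reference position, soft-clipping across
    planted SV boundaries; None if the read lies wholly in inserted sequence."""
    segs = truth.segment_maps[(chrom, hap)]
    starts = [s[0] for s in segs]
    end = start + rl
    i = max(bisect_right(starts, start) - 1, 0)
    best = None  # (overlap_len, ov_start, ref_pos_of_ov_start)
    while i < len(segs):
        hs, he, rs = segs[i]
        if hs >= end:
            break
        ov_s, ov_e = max(start, hs), min(end, he)
        if ov_e > ov_s and rs is not None:
            ov = ov_e - ov_s
            if best is None or ov > best[0]:
                best = (ov, ov_s, rs + (ov_s - hs))
        i += 1
    if best is None:
        return None
    ov, ov_s, ref_pos = best
    pre = ov_s - start
    post = end - (ov_s + ov)
    cigar = ""
    if pre:
        cigar += f"{pre}S"
    cigar += f"{ov}M"
    if post:
        cigar += f"{post}S"
    return ref_pos, cigar


def align_truth(
    origins: Sequence[ReadOrigin],
    truth: DiploidTruth,
    config: SimConfig,
    sam_path: str | Path,
) -> int:
    """Emit reads as a coordinate-sorted SAM at their true positions.

    Reads crossing a planted SV boundary are soft-clipped at the boundary;
    reads wholly inside inserted sequence are emitted unmapped. Lets the
    pipeline run end-to-end without an external aligner (a real BAM can be
    substituted for full fidelity).
    """
    rl = config.read_length
    qual = "I" * rl
    rows = []
    for o in origins:
        for mate, (start, seq_stored) in enumerate(
                ((o.start1, o.seq1), (o.start2, o.seq2)), start=1):
            flag = 0x1 | (0x40 if mate == 1 else 0x80)
            fwd_seq = seq_stored if mate == 1 else revcomp(seq_stored)
            if mate == 2:
                flag |= 0x10
            placed = _place_read(truth, o.chrom, o.haplotype, start, rl)
            bx = f"\tBX:Z:{o.barcode}" if o.barcode else ""
            if placed is None:
                rows.append((o.chrom, 1 << 40,
                             f"{o.read_id}\t{flag | 0x4}\t*\t0\t0\t*\t*\t0\t0\t"
                             f"{fwd_seq}\t{qual}{bx}"))
            else:
                pos, cigar = placed
                rows.append((o.chrom, pos,
                             f"{o.read_id}\t{flag}\t{o.chrom}\t{pos + 1}\t60\t"
                             f"{cigar}\t*\t0\t0\t{fwd_seq}\t{qual}{bx}"))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom in truth.reference.chroms:
        header.append(f"@SQ\tSN:{chrom}\tLN:{truth.reference.length(chrom)}")
    with open(sam_path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for _, _, line in rows:
            fh.write(line + "\n")
    return len(rows)


# ---------------------------------------------------------------------------
# on-disk truth artifacts


def write_snp_vcf(truth: DiploidTruth, path: str | Path) -> None:
    """Phased het-SNP VCF (GT a|b with the haplotype-0 allele first)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in truth.reference.chroms:
        lines.append(f"##contig=<ID={chrom},length={truth.reference.length(chrom)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSIM")
    for chrom in truth.reference.chroms:
        for s in truth.snps.get(chrom, []):
            gt = f"{s.hap0_allele}|{1 - s.hap0_allele}"
            lines.append(f"{chrom}\t{s.pos + 1}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t."
                         f"\tGT\t{gt}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth_files(
    truth: DiploidTruth,
    fragments: Sequence[TruthFragment],
    outdir: str | Path,
) -> dict[str, Path]:
    """Reference/haplotype FASTAs, SNP VCF, truth-SV VCF and fragment TSV."""
    from .io_formats import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "hap0": outdir / "haplotype0.fasta",
        "hap1": outdir / "haplotype1.fasta",
        "snp_vcf": outdir / "het_snps.vcf",
        "sv_vcf": outdir / "truth_svs.vcf",
        "fragments": outdir / "truth_fragments.tsv",
    }
    write_fasta(truth.reference.sequences, paths["reference"])
    write_fasta({c: truth.haplotypes[c][0] for c in truth.reference.chroms},
                paths["hap0"])
    write_fasta({c: truth.haplotypes[c][1] for c in truth.reference.chroms},
                paths["hap1"])
    write_snp_vcf(truth, paths["snp_vcf"])
    write_vcf(truth.sv_truth_calls(), truth.reference, paths["sv_vcf"])
    with open(paths["fragments"], "w") as fh:
        fh.write("fragment_id\tbarcode\thaplotype\tchrom\thap_start\thap_end"
                 "\tref_start\tref_end\n")
        for f in fragments:
            fh.write(f"{f.fragment_id}\t{f.barcode}\t{f.haplotype}\t{f.chrom}"
                     f"\t{f.hap_start}\t{f.hap_end}\t{f.ref_start}\t{f.ref_end}\n")
    return paths
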