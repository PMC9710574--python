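"""End-to-end orchestration of the linked-read assembly SV pipeline.

Stages (each also runnable standalone from the previous stage's on-disk
artifacts, which are all plain TSV/FASTA/VCF/SAM):

    simulate    -> reference/haplotype FASTAs, barcoded FASTQ, truth SAM/VCFs
    reconstruct -> fragment TSV
    phase       -> phase-block TSV + fragment haplotype assignments
    assemble    -> per-haplotype contig FASTAs + chunk manifest
    callsv      -> diploid SV VCF + BED
    bench       -> size-binned precision/recall report

A JSON run manifest records per-stage inputs (checksummed), outputs,
parameters, counts and wall time; ``--resume`` skips stages whose inputs are
unchanged and whose outputs exist.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import assembly, bench, fragments as frag_mod, phasing, simulate, svcall
from .io_formats import (build_read_index, load_fasta, parse_alignments,
                         parse_het_snps, parse_paf, read_sv_vcf, write_fasta,
                         write_vcf)
from .util import sha256_file

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "stlfrasm_out"
    fastq_r1: str | None = None
    fastq_r2: str | None = None
    alignments: str | None = None
    vcf: str | None = None
    reference: str | None = None
    truth_sv_vcf: str | None = None
    boundary_kb: float = 50.0
    chunk_kb: float = 100.0
    pad_bp: int = 1_000
    min_sv_len: int = 50
    min_reads: int = 2
    assembler: str = "builtin"  # builtin | external
    assembler_command: str | None = None
    aligner: str = "builtin"  # builtin | paf
    paf: str | None = None
    refdist: int = 200
    pctsize: float = 0.1
    pctsim: float = 0.1
    passonly: bool = True
    threads: int = 1
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    @property
    def boundary_bp(self) -> int:
        return int(self.boundary_kb * 1000)

    @property
    def chunk_bp(self) -> int:
        return int(self.chunk_kb * 1000)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def sim_config(self) -> simulate.SimConfig:
        overrides = dict(self.sim)
        if "sv_specs" in overrides:
            overrides["sv_specs"] = tuple(
                simulate.SVSpec(**s) if isinstance(s, dict) else simulate.SVSpec(*s)
                for s in overrides["sv_specs"])
        return simulate.SimConfig(seed=self.seed, **overrides)

    def match_params(self) -> bench.MatchParams:
        return bench.MatchParams(refdist=self.refdist, pctsize=self.pctsize,
                                 pctsim=self.pctsim, passonly=self.passonly)


def _require(cfg_field: str, path: str | None) -> Path:
    if path is None:
        raise FileNotFoundError(f"pipeline input {cfg_field!r} is not configured")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"pipeline input {cfg_field!r} missing: {p}")
    return p


# ---------------------------------------------------------------------------
# manifest


class RunManifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}}

    @classmethod
    def load_or_new(cls, path: Path, resume: bool) -> "RunManifest":
        man = cls(path)
        if resume and path.exists():
            man.data = json.loads(path.read_text())
            man.data.setdefault("stages", {})
        return man

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))

    def stage_done(self, name: str, inputs: dict, params: dict) -> bool:
        st = self.data["stages"].get(name)
        if not st:
            return False
        return (st.get("inputs") == inputs and st.get("params") == params
                and all(Path(o).exists() for o in st.get("outputs", [])))

    def record(self, name: str, inputs: dict, outputs: Sequence[str],
               params: dict, counts: dict, seconds: float,
               skipped: bool = False) -> None:
        self.data["stages"][name] = {
            "inputs": inputs, "outputs": [str(o) for o in outputs],
            "params": params, "counts": counts,
            "seconds": round(seconds, 3), "skipped": skipped,
        }
        self.save()


def _hash_inputs(paths: Sequence[str | Path | None]) -> dict:
    out = {}
    for p in paths:
        if p and Path(p).exists():
            out[str(p)] = sha256_file(p)
    return out


# ---------------------------------------------------------------------------
# stages


def cmd_simulate(cfg: PipelineConfig):
    """Generate the synthetic dataset and point the config's inputs at it."""
    sim_dir = Path(cfg.out_dir) / "sim"
    sim_cfg = cfg.sim_config()
    truth = simulate.simulate_diploid_genome(sim_cfg)
    truth_frags = simulate.simulate_fragments(truth, sim_cfg)
    sim_dir.mkdir(parents=True, exist_ok=True)
    r1 = sim_dir / "reads_R1.fastq"
    r2 = sim_dir / "reads_R2.fastq"
    origins = simulate.simulate_reads(truth, truth_frags, sim_cfg, r1, r2)
    sam = sim_dir / "alignments.sam"
    n_records = simulate.align_truth(origins, truth, sim_cfg, sam)
    paths = simulate.write_truth_files(truth, truth_frags, sim_dir)
    cfg.fastq_r1 = str(r1)
    cfg.fastq_r2 = str(r2)
    cfg.alignments = str(sam)
    cfg.vcf = str(paths["snp_vcf"])
    cfg.reference = str(paths["reference"])
    cfg.truth_sv_vcf = str(paths["sv_vcf"])
    counts = {"fragments": len(truth_frags), "read_pairs": len(origins),
              "sam_records": n_records, "planted_svs": len(truth.svs),
              "het_snps": sum(len(s) for s in truth.snps.values())}
    outputs = [r1, r2, sam, *paths.values()]
    return truth, truth_frags, origins, counts, outputs


def cmd_reconstruct(cfg: PipelineConfig):
    """Reconstruct long fragments from the barcoded alignments."""
    sam = _require("alignments", cfg.alignments)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alns = list(parse_alignments(sam))
    frags = frag_mod.reconstruct_fragments(
        alns, boundary_bp=cfg.boundary_bp, min_reads=cfg.min_reads)
    tsv = out / "fragments.tsv"
    frag_mod.write_fragment_tsv(frags, tsv)
    stats = frag_mod.fragment_stats(frags) if frags else None
    counts = {"alignments": len(alns), "fragments": len(frags)}
    if stats:
        counts.update(mean_fragment_length=round(stats.mean_length, 1),
                      fragment_n50=stats.n50)
    log.info("reconstruct: %s", counts)
    return frags, counts, [tsv]


def cmd_phase(cfg: PipelineConfig, frags=None):
    """Annotate fragments with het-SNP alleles and partition into haplotypes."""
    vcf = _require("vcf", cfg.vcf)
    out = Path(cfg.out_dir)
    if frags is None:
        frags, _, _ = cmd_reconstruct(cfg)
    het = parse_het_snps(vcf)
    phasing.annotate_fragments(frags, het)
    blocks: list[phasing.PhaseBlock] = []
    for chrom in sorted(het):
        blocks.extend(phasing.phase_chromosome(frags, het[chrom], chrom))
    phasing.assign_fragments(frags, blocks)
    tsv = out / "phase_blocks.tsv"
    summary = phasing.emit_phase_blocks(blocks, tsv)
    assign_tsv = out / "fragments.tsv"
    frag_mod.write_fragment_tsv(frags, assign_tsv)  # now with haplotypes
    counts = {"blocks": len(blocks), **summary,
              "frag_h0": sum(1 for f in frags if f.haplotype == "0"),
              "frag_h1": sum(1 for f in frags if f.haplotype == "1"),
              "frag_both": sum(1 for f in frags if f.haplotype == "both")}
    log.info("phase: %s", counts)
    return frags, blocks, het, counts, [tsv, assign_tsv]


def _assembly_regions(blocks: Sequence[phasing.PhaseBlock],
                      chrom_len: int) -> list[tuple[phasing.PhaseBlock, int, int]]:
    """Extend block spans into SNP-free flanks: to the chromosome ends and to
    the midpoint between adjacent blocks (the reference guides assembly, so
    unphased flanking sequence is still assembled with the nearest block)."""
    ordered = sorted(blocks, key=lambda b: b.start)
    out = []
    for i, b in enumerate(ordered):
        start = 0 if i == 0 else (ordered[i - 1].end + b.start) // 2
        end = chrom_len if i == len(ordered) - 1 \
            else (b.end + ordered[i + 1].start) // 2
        out.append((b, start, end))
    return out


def cmd_assemble(cfg: PipelineConfig, frags=None, blocks=None):
    """Chunked local assembly of both haplotypes, stitched per block."""
    r1 = _require("fastq_r1", cfg.fastq_r1)
    ref_path = _require("reference", cfg.reference)
    out = Path(cfg.out_dir)
    if frags is None or blocks is None:
        frags, blocks, _, _, _ = cmd_phase(cfg)
    reference = load_fasta(ref_path)
    fastq_index = build_read_index(r1, cfg.fastq_r2)
    # read pairs that never mapped can still be recruited by barcode
    # (the reads buried inside long insertions live here)
    mapped_ids: set[str] = set()
    unmapped: list[tuple[str, str]] = []
    for rec in parse_alignments(_require("alignments", cfg.alignments)):
        if rec.is_unmapped:
            if rec.barcode:
                unmapped.append((rec.read_id, rec.barcode))
        elif not rec.is_secondary:
            mapped_ids.add(rec.read_id)
    unmapped_by_barcode: dict[str, list[str]] = {}
    for rid, bc in unmapped:
        if rid not in mapped_ids:
            unmapped_by_barcode.setdefault(bc, []).append(rid)
    contigs: list[assembly.HaploidContig] = []
    chunk_rows = []
    by_chrom: dict[str, list[phasing.PhaseBlock]] = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom, []).append(b)
    for chrom in reference.chroms:
        chrom_blocks = by_chrom.get(chrom, [])
        if not chrom_blocks:
            # no phased SNPs: assemble the whole chromosome unpartitioned
            chrom_blocks = [phasing.PhaseBlock(
                block_id=f"{chrom}.unphased", chrom=chrom, start=0,
                end=reference.length(chrom), snp_phase={})]
        for block, rstart, rend in _assembly_regions(chrom_blocks,
                                                     reference.length(chrom)):
            per_hap = assembly.cut_chunks(block, cfg.chunk_bp, cfg.pad_bp,
                                          region=(rstart, rend))
            for hap in (0, 1):
                minis: dict[str, list[assembly.MiniContig]] = {}
                for chunk in per_hap[hap]:
                    reads = assembly.extract_chunk_reads(
                        chunk, frags, fastq_index,
                        unmapped_by_barcode=unmapped_by_barcode)
                    if cfg.assembler == "external":
                        mcs = assembly.external_assembler_adapter(
                            reads, out / "asm_work" / chunk.chunk_id,
                            cfg.assembler_command, chunk_id=chunk.chunk_id)
                    else:
                        seqs = [s for _, s1, s2 in reads for s in (s1, s2) if s]
                        mcs = assembly.assemble_chunk(seqs, chunk_id=chunk.chunk_id)
                    minis[chunk.chunk_id] = mcs
                    chunk_rows.append((chunk, len(reads), len(mcs)))
                contigs.extend(assembly.stitch_contigs(per_hap[hap], minis))
    fasta_paths = []
    for hap in (0, 1):
        path = out / f"contigs_hap{hap}.fasta"
        write_fasta([(c.contig_id, c.sequence) for c in contigs
                     if c.haplotype == hap], path)
        fasta_paths.append(path)
    manifest_tsv = out / "chunks.tsv"
    with open(manifest_tsv, "w") as fh:
        fh.write("chunk_id\tchrom\thaplotype\tstart\tend\tcore_start\tcore_end"
                 "\tn_reads\tn_minicontigs\n")
        for chunk, n_reads, n_mc in chunk_rows:
            fh.write(f"{chunk.chunk_id}\t{chunk.chrom}\t{chunk.haplotype}\t"
                     f"{chunk.start}\t{chunk.end}\t{chunk.core_start}\t"
                     f"{chunk.core_end}\t{n_reads}\t{n_mc}\n")
    counts = {"chunks": len(chunk_rows), "contigs": len(contigs),
              "contig_bases": sum(len(c.sequence) for c in contigs)}
    log.info("assemble: %s", counts)
    return contigs, counts, [*fasta_paths, manifest_tsv]


def cmd_callsv(cfg: PipelineConfig, contigs=None):
    """Align contigs to the reference and emit genotyped diploid SV calls."""
    ref_path = _require("reference", cfg.reference)
    out = Path(cfg.out_dir)
    reference = load_fasta(ref_path)
    if contigs is None:
        contigs = []
        for hap in (0, 1):
            path = out / f"contigs_hap{hap}.fasta"
            if path.exists():
                genome = load_fasta(path)
                contigs.extend(
                    assembly.HaploidContig(name, hap, "", genome[name])
                    for name in genome.chroms)
    seq_of = {c.contig_id: c.sequence for c in contigs}
    per_hap_calls: dict[int, list[svcall.SVCall]] = {0: [], 1: []}
    if cfg.aligner == "paf":
        paf = parse_paf(_require("paf", cfg.paf))
        alns = svcall.align_contigs([], reference, mode="paf_adapter",
                                    paf_records=paf)
        hap_of = {c.contig_id: c.haplotype for c in contigs}
        for aln in alns:
            hap = hap_of.get(aln.contig_id, 1 if ".h1." in aln.contig_id else 0)
            cands = svcall.extract_variants(aln, seq_of.get(aln.contig_id, ""),
                                            reference)
            per_hap_calls[hap].extend(cands)
    else:
        indexes: dict[str, svcall.RefKmerIndex] = {}
        for hap in (0, 1):
            hap_contigs = [c for c in contigs if c.haplotype == hap]
            alns = svcall.align_contigs(hap_contigs, reference,
                                        ref_indexes=indexes)
            for aln in alns:
                per_hap_calls[hap].extend(
                    svcall.extract_variants(aln, seq_of[aln.contig_id], reference))
    filtered = {
        hap: svcall.dedupe_calls(
            svcall.filter_svs(per_hap_calls[hap], reference, cfg.min_sv_len))
        for hap in (0, 1)
    }
    calls = svcall.merge_diploid(filtered[0], filtered[1])
    vcf_path = out / "svs.vcf"
    write_vcf(calls, reference, vcf_path)
    bed_path = out / "svs.bed"
    with open(bed_path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.pos}\t{c.end}\t{c.svtype}\t{c.svlen}\t"
                     f"{c.genotype}\n")
    counts = {"candidates_h0": len(per_hap_calls[0]),
              "candidates_h1": len(per_hap_calls[1]),
              "calls": len(calls)}
    log.info("callsv: %s", counts)
    return calls, counts, [vcf_path, bed_path]


def cmd_bench(cfg: PipelineConfig, calls=None):
    """Compare the callset with the truth set, Table-style binned report."""
    truth_vcf = _require("truth_sv_vcf", cfg.truth_sv_vcf)
    out = Path(cfg.out_dir)
    if calls is None:
        calls = read_sv_vcf(_require("calls", str(out / "svs.vcf")))
    truth = read_sv_vcf(truth_vcf)
    report = bench.bin_report(calls, truth, cfg.match_params())
    tsv = out / "bench.tsv"
    report.to_tsv(tsv)
    txt = out / "bench.txt"
    txt.write_text(report.table() + "\n")
    counts = {"n_calls": len(calls), "n_truth": len(truth)}
    log.info("bench:\n%s", report.table())
    return report, counts, [tsv, txt]


# ---------------------------------------------------------------------------
# run-all


@dataclass
class RunResult:
    config: PipelineConfig
    manifest: RunManifest
    report: bench.BinnedMetrics | None
    truth: simulate.DiploidTruth | None
    blocks: list | None
    counts: dict


def run_all(cfg: PipelineConfig, resume: bool = False,
            with_simulation: bool | None = None) -> RunResult:
    """Run every stage in order, recording a manifest.

    ``with_simulation`` defaults to True when no alignments path is
    configured (synthetic mode); set it False to run on real inputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = RunManifest.load_or_new(out / "manifest.json", resume)
    all_counts: dict[str, dict] = {}
    if with_simulation is None:
        with_simulation = cfg.alignments is None
    truth = None
    frags = blocks = contigs = calls = None

    def run(name, inputs, params, fn):
        nonlocal all_counts
        in_hash = _hash_inputs(inputs)
        if resume and man.stage_done(name, in_hash, params):
            st = man.data["stages"][name]
            man.record(name, in_hash, st["outputs"], params,
                       st.get("counts", {}), 0.0, skipped=True)
            all_counts[name] = st.get("counts", {})
            return None
        t0 = time.time()
        data, counts, outputs = fn()
        man.record(name, in_hash, [str(o) for o in outputs], params, counts,
                   time.time() - t0)
        all_counts[name] = counts
        return data

    if with_simulation:
        sim_params = {"seed": cfg.seed, "sim": cfg.sim}

        def _sim():
            nonlocal truth
            truth, tfrags, origins, counts, outputs = cmd_simulate(cfg)
            return (truth, tfrags), counts, outputs

        run("simulate", [], sim_params, _sim)
        if cfg.alignments is None:  # resumed: restore paths
            sim_dir = out / "sim"
            cfg.fastq_r1 = str(sim_dir / "reads_R1.fastq")
            cfg.fastq_r2 = str(sim_dir / "reads_R2.fastq")
            cfg.alignments = str(sim_dir / "alignments.sam")
            cfg.vcf = str(sim_dir / "het_snps.vcf")
            cfg.reference = str(sim_dir / "reference.fasta")
            cfg.truth_sv_vcf = str(sim_dir / "truth_svs.vcf")

    rec_params = {"boundary_kb": cfg.boundary_kb, "min_reads": cfg.min_reads}

    def _rec():
        nonlocal frags
        frags, counts, outputs = cmd_reconstruct(cfg)
        return frags, counts, outputs

    run("reconstruct", [cfg.alignments], rec_params, _rec)

    phase_params = dict(rec_params)

    def _phase():
        nonlocal frags, blocks
        frags, blocks, _, counts, outputs = cmd_phase(cfg, frags)
        return blocks, counts, outputs

    run("phase", [cfg.alignments, cfg.vcf], phase_params, _phase)

    asm_params = {"chunk_kb": cfg.chunk_kb, "pad_bp": cfg.pad_bp,
                  "assembler": cfg.assembler, **phase_params}

    def _needs_frags():
        nonlocal frags, blocks
        if frags is None or blocks is None:
            frags2, blocks2, _, _, _ = cmd_phase(cfg)
            frags, blocks = frags2, blocks2

    def _asm():
        nonlocal contigs
        _needs_frags()
        contigs, counts, outputs = cmd_assemble(cfg, frags, blocks)
        return contigs, counts, outputs

    run("assemble", [cfg.alignments, cfg.vcf, cfg.fastq_r1, cfg.fastq_r2],
        asm_params, _asm)

    sv_params = {"min_sv_len": cfg.min_sv_len, "aligner": cfg.aligner,
                 **asm_params}

    def _sv():
        nonlocal calls
        calls, counts, outputs = cmd_callsv(cfg, contigs)
        return calls, counts, outputs

    run("callsv", [str(out / "contigs_hap0.fasta"),
                   str(out / "contigs_hap1.fasta"), cfg.reference],
        sv_params, _sv)

    report = None
    if cfg.truth_sv_vcf:
        bench_params = {"refdist": cfg.refdist, "pctsize": cfg.pctsize,
                        "pctsim": cfg.pctsim, "passonly": cfg.passonly}

        def _bench():
            r, counts, outputs = cmd_bench(cfg, calls)
            return r, counts, outputs

        report = run("bench", [str(out / "svs.vcf"), cfg.truth_sv_vcf],
                     bench_params, _bench)
        if report is None and (out / "svs.vcf").exists():
            # skipped on resume; recompute the in-memory report cheaply
            report = bench.bin_report(read_sv_vcf(out / "svs.vcf"),
                                      read_sv_vcf(cfg.truth_sv_vcf),
                                      cfg.match_params())
    return RunResult(cfg, man, report, truth, blocks, all_counts)
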