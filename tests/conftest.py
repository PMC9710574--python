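"""Shared fixtures: hand-built alignment records and session-scoped pipeline
runs reused by the heavier end-to-end tests."""
from __future__ import annotations

import pytest

from stlfrasm.io_formats import AlignmentRecord
from stlfrasm.pipeline import PipelineConfig, cmd_phase, cmd_simulate, run_all


def make_aln(read_id, pos, chrom="chr1", barcode="B", length=100, seq="",
             mapq=60, cigar=None, **kw):
    """A mapped primary alignment with a simple CIGAR."""
    return AlignmentRecord(
        read_id=read_id, barcode=barcode, chrom=chrom, pos=pos, mapq=mapq,
        cigar=cigar if cigar is not None else [("M", length)], seq=seq, **kw)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full default pipeline on the 500 kb / 20-SV study conditions, seed 1."""
    out = tmp_path_factory.mktemp("run50a")
    cfg = PipelineConfig(out_dir=str(out), seed=1)
    return run_all(cfg)


@pytest.fixture(scope="session")
def pipeline_run_repeat(tmp_path_factory):
    """Second run of the identical configuration (determinism check)."""
    out = tmp_path_factory.mktemp("run50b")
    cfg = PipelineConfig(out_dir=str(out), seed=1)
    return run_all(cfg)


@pytest.fixture(scope="session")
def boundary_sweep(tmp_path_factory, pipeline_run):
    """Overall deletion recall for boundary thresholds 20..80 kb (50 reuses
    the main run)."""
    def del_recall(report):
        tp = sum(r.tp for (t, _), r in report.rows.items() if t == "DEL")
        fn = sum(r.fn for (t, _), r in report.rows.items() if t == "DEL")
        return 100.0 * tp / (tp + fn)

    recalls = {50.0: del_recall(pipeline_run.report)}
    for kb in (20, 40, 60, 80):
        out = tmp_path_factory.mktemp(f"run_b{kb}")
        cfg = PipelineConfig(out_dir=str(out), seed=1, boundary_kb=kb)
        res = run_all(cfg)
        recalls[float(kb)] = del_recall(res.report)
    return recalls


@pytest.fixture(scope="session")
def phasing_study(tmp_path_factory):
    """1 Mb chromosome, het SNPs every ~1.5 kb, 30 kb fragments at >= 10x
    fragment coverage, 1% per-base (allele) error, fixed seed — simulated,
    reconstructed and phased once for the phasing-recovery checks."""
    out = tmp_path_factory.mktemp("phasing1mb")
    cfg = PipelineConfig(out_dir=str(out), seed=11,
                         sim={"ref_length": 1_000_000, "error_rate": 0.01,
                              "sv_specs": []})
    truth, truth_frags, origins, counts, _ = cmd_simulate(cfg)
    frags, blocks, het, phase_counts, _ = cmd_phase(cfg)
    return {"cfg": cfg, "truth": truth, "truth_frags": truth_frags,
            "origins": origins, "frags": frags, "blocks": blocks, "het": het,
            "counts": counts, "phase_counts": phase_counts}
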