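"""Reconstruct long fragments (LFRs) from barcoded alignments.

Groups reads by (barcode, chromosome) and splits each group wherever two
successive reads are more than 50 kb apart — the barcode deconvolution rule.
Run 01_simulate_library.py first (or this script will build its own input).
"""
from pathlib import Path

from stlfrasm.fragments import fragment_stats
from stlfrasm.pipeline import PipelineConfig, cmd_reconstruct, cmd_simulate

out = Path("scratch/examples/simulate")
cfg = PipelineConfig(out_dir=str(out), seed=7, sim={
    "ref_length": 150_000,
    "sv_specs": [{"svtype": "DEL", "count": 2, "min_len": 100, "max_len": 900},
                 {"svtype": "INS", "count": 2, "min_len": 100, "max_len": 900}],
})
if not (out / "sim" / "alignments.sam").exists():
    cmd_simulate(cfg)
else:
    cfg.alignments = str(out / "sim" / "alignments.sam")

fragments, counts, _ = cmd_reconstruct(cfg)
stats = fragment_stats(fragments)
print(f"alignments read     : {counts['alignments']:,}")
print(f"fragments recovered : {stats.count}")
print(f"mean length         : {stats.mean_length:,.0f} bp  (library mean 30 kb)")
print(f"length N50          : {stats.n50:,} bp")
print(f"reads per fragment  : {stats.mean_reads:.1f}")
# The mean tracks the 30 kb library setting (clipped at chromosome ends);
# every fragment pools the reads that share one barcode within one locus.
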