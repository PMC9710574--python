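"""Simulate a small stLFR-style linked-read library with full ground truth.

Builds a 150 kb diploid genome with planted het SNPs and SVs, samples long
fragments with shared barcodes, sequences 100 bp read pairs inside them and
writes FASTQ/SAM/VCF truth files.
"""
from pathlib import Path

from stlfrasm.pipeline import PipelineConfig, cmd_simulate

out = Path("scratch/examples/simulate")
cfg = PipelineConfig(out_dir=str(out), seed=7, sim={
    "ref_length": 150_000,
    "sv_specs": [{"svtype": "DEL", "count": 2, "min_len": 100, "max_len": 900},
                 {"svtype": "INS", "count": 2, "min_len": 100, "max_len": 900}],
})
truth, fragments, origins, counts, paths = cmd_simulate(cfg)

print(f"reference length : {truth.reference.length('chr1'):,} bp")
print(f"het SNPs planted : {counts['het_snps']}")
print(f"SVs planted      : {counts['planted_svs']}")
print(f"fragments        : {counts['fragments']}")
print(f"read pairs       : {counts['read_pairs']:,}")
print(f"files in         : {out}")
# Sequencing depth = read bases over the haploid reference length; each
# barcode tags 1-3 fragments, mimicking stLFR co-barcoding.
cov = counts["read_pairs"] * 2 * 100 / 150_000
print(f"sequencing depth : {cov:.1f}X (target ~48X)")
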