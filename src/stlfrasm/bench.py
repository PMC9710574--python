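"""Truvari-style SV benchmarking: call-vs-truth matching and binned metrics.

A call matches a truth entry of the same SV type when the breakpoint distance
is within ``refdist`` (200 bp default), the size ratio min(L1,L2)/max(L1,L2)
is at least ``pctsize`` (0.1), and — for insertions with both sequences
available — the normalised edit similarity is at least ``pctsim`` (0.1).
Matching is greedy by ascending breakpoint distance, one-to-one. Metrics are
reported per size bin (50-1k, 1k-10k, >10k), with each side binned by its own
length and cross-bin matches disallowed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import edlib

from .svcall import SIZE_BINS, SVCall, classify_size_bin

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchParams:
    refdist: int = 200
    pctsize: float = 0.1
    pctsim: float = 0.1
    passonly: bool = True

    def __post_init__(self):
        if self.refdist < 0 or not (0 <= self.pctsize <= 1) \
                or not (0 <= self.pctsim <= 1):
            raise ValueError("invalid match parameters")


@dataclass
class MatchResult:
    tp_pairs: list[tuple[SVCall, SVCall]]  # (call, truth)
    fp_calls: list[SVCall]
    fn_truth: list[SVCall]

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)


@dataclass
class MetricsRow:
    n_benchmark: int
    n_call: int
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None


@dataclass
class BinnedMetrics:
    rows: dict[tuple[str, str], MetricsRow] = field(default_factory=dict)

    def row(self, svtype: str, size_bin: str) -> MetricsRow:
        return self.rows[(svtype, size_bin)]

    def table(self) -> str:
        lines = [f"{'Bin':8s} {'Type':4s} {'Benchmark':>9s} {'Total call':>10s} "
                 f"{'TP':>6s} {'FP':>6s} {'FN':>6s} {'Precision':>9s} {'Recall':>7s}"]
        for (svtype, size_bin), r in sorted(
                self.rows.items(), key=lambda kv: (SIZE_BINS.index(kv[0][1]),
                                                   kv[0][0])):
            prec = "NAN" if r.precision is None else f"{r.precision:.1f}%"
            rec = "NAN" if r.recall is None else f"{r.recall:.1f}%"
            lines.append(f"{size_bin:8s} {svtype:4s} {r.n_benchmark:9d} "
                         f"{r.n_call:10d} {r.tp:6d} {r.fp:6d} {r.fn:6d} "
                         f"{prec:>9s} {rec:>7s}")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("size_bin\tsvtype\tn_benchmark\tn_call\ttp\tfp\tfn"
                     "\tprecision\trecall\n")
            for (svtype, size_bin), r in sorted(
                    self.rows.items(), key=lambda kv: (SIZE_BINS.index(kv[0][1]),
                                                       kv[0][0])):
                prec = "NAN" if r.precision is None else f"{r.precision:.1f}"
                rec = "NAN" if r.recall is None else f"{r.recall:.1f}"
                fh.write(f"{size_bin}\t{svtype}\t{r.n_benchmark}\t{r.n_call}\t"
                         f"{r.tp}\t{r.fp}\t{r.fn}\t{prec}\t{rec}\n")


def _seq_similarity(a: str, b: str) -> float:
    if not a or not b:
        return 1.0  # sequence check skipped when either side lacks one
    d = edlib.align(a, b)["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _is_pass(call: SVCall) -> bool:
    return getattr(call, "filter", "PASS") in ("PASS", ".")


def match_calls(
    calls: Sequence[SVCall],
    truth: Sequence[SVCall],
    params: MatchParams = MatchParams(),
) -> MatchResult:
    """One-to-one greedy matching by ascending breakpoint distance.

    Tie-break is deterministic: lower truth position, then lower call
    position. ``passonly`` drops non-PASS records from both sides before
    matching.
    """
    calls = [c for c in calls if not params.passonly or _is_pass(c)]
    truth = [t for t in truth if not params.passonly or _is_pass(t)]
    cands = []
    for ci, c in enumerate(calls):
        for ti, t in enumerate(truth):
            if c.svtype != t.svtype or c.chrom != t.chrom:
                continue
            dist = abs(c.pos - t.pos)
            if dist > params.refdist:
                continue
            if min(c.svlen, t.svlen) / max(c.svlen, t.svlen) < params.pctsize:
                continue
            if c.svtype == "INS" and \
                    _seq_similarity(c.alt_seq, t.alt_seq) < params.pctsim:
                continue
            cands.append((dist, t.pos, c.pos, ci, ti))
    cands.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    tp_pairs = []
    for _, _, _, ci, ti in cands:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        tp_pairs.append((calls[ci], truth[ti]))
    fp = [c for i, c in enumerate(calls) if i not in used_c]
    fn = [t for i, t in enumerate(truth) if i not in used_t]
    return MatchResult(tp_pairs, fp, fn)


def compute_metrics(tp: int, fp: int, fn: int) -> tuple[float | None, float | None]:
    """Precision/recall as percentages rounded to one decimal.

    Undefined ratios (zero denominator) are returned as None — rendered as
    "NAN" in reports.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("negative counts")
    precision = round(100 * tp / (tp + fp), 1) if tp + fp > 0 else None
    recall = round(100 * tp / (tp + fn), 1) if tp + fn > 0 else None
    return precision, recall


def bin_report(
    calls: Sequence[SVCall],
    truth: Sequence[SVCall],
    params: MatchParams = MatchParams(),
) -> BinnedMetrics:
    """Size-binned precision/recall; both sides binned by their own svlen and
    matched within bins only."""
    out = BinnedMetrics()
    svtypes = sorted({c.svtype for c in calls} | {t.svtype for t in truth})
    for svtype in svtypes:
        for size_bin in SIZE_BINS:
            cs = [c for c in calls
                  if c.svtype == svtype and classify_size_bin(c) == size_bin]
            ts = [t for t in truth
                  if t.svtype == svtype and classify_size_bin(t) == size_bin]
            res = match_calls(cs, ts, params)
            tp, fp, fn = res.tp, len(res.fp_calls), len(res.fn_truth)
            precision, recall = compute_metrics(tp, fp, fn)
            out.rows[(svtype, size_bin)] = MetricsRow(
                n_benchmark=len(ts), n_call=len(cs), tp=tp, fp=fp, fn=fn,
                precision=precision, recall=recall)
    return out
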