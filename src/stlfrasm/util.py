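"""Small shared numeric/sequence helpers used across the pipeline."""
from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import numpy as np

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# byte value -> 2-bit code; 255 marks a non-ACGT byte
BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODES[_b] = _i
for _i, _b in enumerate(b"acgt"):
    BASE_CODES[_b] = _i
CODE_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# byte -> byte with its four 2-bit fields reversed (for k-mer reverse complement)
_REV2 = np.array(
    [((b & 3) << 6) | ((b >> 2 & 3) << 4) | ((b >> 4 & 3) << 2) | (b >> 6 & 3)
     for b in range(256)],
    dtype=np.uint8,
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def n50(lengths: Iterable[int]) -> int:
    """Weighted-median N50: smallest L with >= half the total in pieces >= L."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("N50 of an empty length set")
    half = sum(ls) / 2
    acc = 0
    for l in ls:
        acc += l
        if acc >= half:
            return l
    return ls[-1]


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 2-bit codes (255 for non-ACGT)."""
    return BASE_CODES[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode_codes(codes: np.ndarray) -> str:
    return CODE_BASES[codes].tobytes().decode()


def kmer_ints_from_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """All k-mer windows of a 1-D code array as uint64 integers.

    Window i covers codes[i:i+k]. Windows containing a non-ACGT byte get an
    arbitrary value; use :func:`valid_kmer_mask` to exclude them.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    c = np.where(codes > 3, 0, codes).astype(np.uint64)
    mask = np.uint64((1 << (2 * k)) - 1)
    two = np.uint64(2)
    acc = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        acc = (acc << two) | c[j:j + n - k + 1]
    return acc & mask


def valid_kmer_mask(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over k-mer windows that contain only ACGT."""
    n = codes.size
    keep = np.ones(max(n - k + 1, 0), dtype=bool)
    for bi in np.flatnonzero(codes > 3):
        keep[max(0, bi - k + 1):min(keep.size, bi + 1)] = False
    return keep


def kmer_matrix(codes2d: np.ndarray, k: int) -> np.ndarray:
    """(n_reads, L) code matrix -> (n_reads, L-k+1) uint64 k-mer matrix."""
    n, L = codes2d.shape
    if L < k:
        return np.empty((n, 0), dtype=np.uint64)
    c = codes2d.astype(np.uint64)
    out = np.zeros((n, L - k + 1), dtype=np.uint64)
    two = np.uint64(2)
    for j in range(k):
        out = (out << two) | c[:, j:j + L - k + 1]
    return out


def revcomp_kmer_ints(vals: np.ndarray, k: int) -> np.ndarray:
    """Vectorised reverse complement of 2-bit packed k-mer integers."""
    comp = vals ^ np.uint64((1 << (2 * k)) - 1)
    b = comp[:, None].copy().view(np.uint8).reshape(-1, 8)
    if vals.dtype.byteorder == ">":  # pragma: no cover
        b = b[:, ::-1]
    # little-endian: byte 0 is least significant
    rev = _REV2[b][:, ::-1].copy().view(np.uint64).ravel()
    return rev >> np.uint64(64 - 2 * k)


def revcomp_kmer_int(val: int, k: int) -> int:
    return int(revcomp_kmer_ints(np.array([val], dtype=np.uint64), k)[0])


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
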