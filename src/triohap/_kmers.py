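"""Vectorized k-mer machinery shared by the locus scorer and the mini aligner.

Sequences are 2-bit encoded with numpy; windows containing N are excluded
from k-mer codes.  Codes are scrambled with a fixed multiplicative hash so
minimizer selection is not biased toward poly-A runs.
"""

from __future__ import annotations

import numpy as np

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_HASH_MULT = np.uint64(0x9E3779B97F4A7C15)


def encode(seq: str) -> np.ndarray:
    """2-bit encode a sequence; N (or anything non-ACGT) becomes -1."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer code of every k-mer; -1 where the window contains an N.

    Returns an int64 array of length ``len(seq) - k + 1`` (empty if the
    sequence is shorter than k).
    """
    codes = encode(seq).astype(np.int64)
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = windows @ powers
    bad = np.lib.stride_tricks.sliding_window_view(codes < 0, k).any(axis=1)
    vals[bad] = -1
    return vals


def _hash_codes(vals: np.ndarray) -> np.ndarray:
    h = vals.astype(np.uint64) * _HASH_MULT
    h[vals < 0] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return h


def minimizer_set(seq: str, k: int = 15, w: int = 10) -> frozenset[int]:
    """Set of minimizing k-mer codes over windows of ``w`` consecutive k-mers."""
    vals = kmer_codes(seq, k)
    if vals.size == 0:
        return frozenset()
    h = _hash_codes(vals)
    if h.size <= w:
        idx = np.array([int(np.argmin(h))])
    else:
        wins = np.lib.stride_tricks.sliding_window_view(h, w)
        idx = np.unique(wins.argmin(axis=1) + np.arange(wins.shape[0]))
    chosen = vals[idx]
    return frozenset(int(v) for v in chosen[chosen >= 0])


def shared_unique_anchors(seq_a: str, seq_b: str, k: int = 21):
    """Positions of k-mers occurring exactly once in each sequence and shared.

    Returns two equally long int arrays ``(pos_a, pos_b)`` sorted by
    ``pos_a``; these are the anchor candidates for chaining.
    """
    va, vb = kmer_codes(seq_a, k), kmer_codes(seq_b, k)

    def _unique(vals):
        order = np.argsort(vals, kind="stable")
        sv = vals[order]
        keep = np.ones(sv.size, dtype=bool)
        keep[1:] &= sv[1:] != sv[:-1]
        keep[:-1] &= sv[:-1] != sv[1:]
        keep &= sv >= 0
        return sv[keep], order[keep]

    ua, pa = _unique(va)
    ub, pb = _unique(vb)
    common, ia, ib = np.intersect1d(ua, ub, assume_unique=True, return_indices=True)
    pos_a, pos_b = pa[ia], pb[ib]
    order = np.argsort(pos_a, kind="stable")
    return pos_a[order], pos_b[order]
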