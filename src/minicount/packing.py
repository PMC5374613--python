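"""Bit-packing helpers shared by the counting phase.

A k-mer is packed into W = ceil(k/32) little-endian-ordered 64-bit words:
word 0 holds bases 0..31 with base 0 in the two most significant bits, and
the final word is zero-padded in its low bits.  With that left-justified
layout, comparing rows of words column by column is exactly lexicographic
comparison of the base strings (A < C < G < T), so canonicalization of a
whole batch of windows reduces to an elementwise word-vector minimum.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "n_words",
    "codes_to_words",
    "words_to_codes",
    "canonical_words",
    "pack_codes_to_bytes",
    "unpack_bytes_to_codes",
]


def n_words(k: int) -> int:
    """Number of 64-bit words needed for a k-mer key."""
    return (k + 31) // 32


def codes_to_words(codes: np.ndarray) -> np.ndarray:
    """Pack an (n, k) batch of 2-bit base codes into (n, W) uint64 words.

    A 1-D input of length k is treated as a single row and returns (1, W).
    """
    codes = np.asarray(codes, dtype=np.uint64)
    if codes.ndim == 1:
        codes = codes[None, :]
    n, k = codes.shape
    W = n_words(k)
    padded = np.zeros((n, W * 32), dtype=np.uint64)
    padded[:, :k] = codes
    padded = padded.reshape(n, W, 32)
    shifts = np.arange(62, -2, -2, dtype=np.uint64)  # base j -> bits 62-2j
    return np.bitwise_or.reduce(padded << shifts, axis=2)


def words_to_codes(words: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`codes_to_words`; returns an (n, k) uint8 array."""
    words = np.asarray(words, dtype=np.uint64)
    if words.ndim == 1:
        words = words[None, :]
    n, W = words.shape
    shifts = np.arange(62, -2, -2, dtype=np.uint64)
    codes = ((words[:, :, None] >> shifts) & np.uint64(3)).reshape(n, W * 32)
    return codes[:, :k].astype(np.uint8)


def canonical_words(fwd: np.ndarray, rev: np.ndarray) -> np.ndarray:
    """Row-wise lexicographic minimum of two (n, W) word arrays."""
    out = fwd.copy()
    undecided = np.ones(fwd.shape[0], dtype=bool)
    for w in range(fwd.shape[1]):
        take_rev = undecided & (rev[:, w] < fwd[:, w])
        out[take_rev] = rev[take_rev]
        undecided &= fwd[:, w] == rev[:, w]
    return out


def pack_codes_to_bytes(codes: np.ndarray) -> bytes:
    """Pack a 1-D code vector into ceil(len/4) bytes, first base in the MSBs."""
    codes = np.asarray(codes, dtype=np.uint8)
    L = codes.size
    nbytes = (L + 3) // 4
    padded = np.zeros(nbytes * 4, dtype=np.uint8)
    padded[:L] = codes
    padded = padded.reshape(nbytes, 4)
    shifts = np.array([6, 4, 2, 0], dtype=np.uint8)
    return np.bitwise_or.reduce(padded << shifts, axis=1).astype(np.uint8).tobytes()


def unpack_bytes_to_codes(data: bytes, length: int) -> np.ndarray:
    """Inverse of :func:`pack_codes_to_bytes`."""
    raw = np.frombuffer(data, dtype=np.uint8)
    shifts = np.array([6, 4, 2, 0], dtype=np.uint8)
    codes = ((raw[:, None] >> shifts) & 3).reshape(-1)
    return codes[:length].astype(np.uint8)
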