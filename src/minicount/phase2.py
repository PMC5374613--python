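"""Phase two: per-bin k-mer counting in open-addressing hash tables.

Each temporary bin file is re-read, its super-mers are split back into
k-mers (canonicalized unless disabled), and the k-mers are inserted into an
open-addressing table with bounded quadratic probing.  Two independent hash
functions drive the machinery:

``probe_hash(x, i)``
    Probing hash.  Mixes the k-mer's 64-bit blocks (32 bases per block)
    through a splitmix64-style avalanche, so its cost grows linearly with k,
    then offsets by the triangular number i(i+1)/2 — the classic quadratic
    schedule that visits every slot of a power-of-two table.
``part_hash(x)``
    Partition hash.  Reads only the first four 16-bit blocks (8 bases each),
    so its cost is constant in k, and returns a value in [0, 2^16).  It
    routes k-mers to shards (``part_hash(x) mod N``) and to passes
    (``part_hash(x) mod p``), guaranteeing that all occurrences of a k-mer
    meet in the same table.

Probing stops after ``i_max`` trials; k-mers that fail are spilled to a
failure buffer and recounted afterwards in a dedicated table, so no k-mer
is ever lost or double counted.  Tables are sized |T| = alpha * n / beta,
where n is the k-mer total known from phase one, alpha estimates the
distinct/total ratio (carried over from the previously processed bin), and
beta is the target fill level.  A bin whose n exceeds the table budget
T_max is processed in p = ceil(n / T_max) passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .dna_codec import EncodedSeq
from .packing import canonical_words, codes_to_words, n_words, words_to_codes
from .phase1 import BinFile, read_bin_records

__all__ = [
    "InsertStatus",
    "CountTable",
    "AlphaEstimator",
    "FailureBuffer",
    "PassPlan",
    "Phase2Config",
    "probe_hash",
    "part_hash",
    "table_size",
    "shard_id",
    "plan_passes",
    "update_alpha",
    "count_bin",
    "count_bin_arrays",
]

_U64 = (1 << 64) - 1
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB
_GOLDEN = 0x9E3779B97F4A7C15
_SEED = 0x8445D61A4E774912
_COUNTER_MAX = 0xFFFFFFFF  # u32 saturation


def _mix64(z: int) -> int:
    """splitmix64 finalizer (scalar)."""
    z &= _U64
    z = ((z ^ (z >> 30)) * _MIX1) & _U64
    z = ((z ^ (z >> 27)) * _MIX2) & _U64
    return z ^ (z >> 31)


def _mix64_vec(z: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        z = (z ^ (z >> np.uint64(30))) * np.uint64(_MIX1)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(_MIX2)
        return z ^ (z >> np.uint64(31))


def _as_words(x: "EncodedSeq | np.ndarray | Sequence[int]") -> np.ndarray:
    """Coerce a k-mer (EncodedSeq or word vector) to a 1-D uint64 word array."""
    if isinstance(x, EncodedSeq):
        return codes_to_words(x.codes)[0]
    return np.asarray(x, dtype=np.uint64).reshape(-1)


def probe_hash0(x) -> int:
    """Base probing hash h0(x); the i-th probe adds the triangular offset."""
    words = _as_words(x)
    h = _SEED
    for w in words.tolist():
        h = _mix64(h ^ _mix64((w + _GOLDEN) & _U64))
    return h


def probe_hash0_vec(words: np.ndarray) -> np.ndarray:
    """Vectorized :func:`probe_hash0` over an (n, W) word array."""
    h = np.full(words.shape[0], _SEED, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for w in range(words.shape[1]):
            h = _mix64_vec(h ^ _mix64_vec(words[:, w] + np.uint64(_GOLDEN)))
    return h


def probe_hash(x, i: int) -> int:
    """The i-th probe value for k-mer x: h0(x) + i(i+1)/2 (mod 2^64).

    Reduced mod |T| by the table; for power-of-two capacities the schedule
    visits every slot within |T| probes.
    """
    if i < 0:
        raise ValueError("probe index must be >= 0")
    return (probe_hash0(x) + (i * (i + 1)) // 2) & _U64


def part_hash(x) -> int:
    """Constant-time partition hash over the first four 16-bit base blocks."""
    word0 = int(_as_words(x)[0])
    h = 0
    for j in range(4):
        block = (word0 >> (48 - 16 * j)) & 0xFFFF
        h ^= _mix64(block + (j + 1) * _GOLDEN)
    return h & 0xFFFF


def part_hash_vec(words: np.ndarray) -> np.ndarray:
    """Vectorized :func:`part_hash`; returns uint64 values in [0, 2^16)."""
    word0 = words[:, 0]
    h = np.zeros(words.shape[0], dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(4):
            block = (word0 >> np.uint64(48 - 16 * j)) & np.uint64(0xFFFF)
            h = h ^ _mix64_vec(block + np.uint64(((j + 1) * _GOLDEN) & _U64))
    return h & np.uint64(0xFFFF)


class InsertStatus(Enum):
    COUNTED = "counted"
    FAILED = "failed"


class CountTable:
    """Open-addressing (key, counter) table with bounded quadratic probing.

    Slots are EMPTY while their counter is 0; a stored key always has a
    counter >= 1, saturating at 2^32 - 1.  Insertion probes slots
    ``(h0 + i(i+1)/2) mod |T|`` for i = 0..i_max-1 and gives up (returning
    :data:`InsertStatus.FAILED`, table untouched) if every probed slot is
    occupied by a different key.
    """

    def __init__(self, capacity: int, k: int, i_max: int = 30, beta: float = 0.4):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        if i_max < 0:
            raise ValueError("i_max must be >= 0")
        self.capacity = int(capacity)
        self.k = int(k)
        self.i_max = int(i_max)
        self.beta = float(beta)
        self.W = n_words(k)
        self._keys = np.zeros((self.capacity, self.W), dtype=np.uint64)
        self._counts = np.zeros(self.capacity, dtype=np.uint64)
        self.inserted = 0  # distinct keys stored
        self.total_probes = 0
        self.total_insertions = 0

    @property
    def fill_level(self) -> float:
        return self.inserted / self.capacity

    @property
    def mean_probes(self) -> float:
        return self.total_probes / max(1, self.total_insertions)

    def insert(self, x, count: int = 1) -> InsertStatus:
        """Insert one k-mer occurrence (or ``count`` identical occurrences)."""
        words = _as_words(x)
        if words.size != self.W:
            raise ValueError(f"key has {words.size} words, table expects {self.W}")
        ok = self._insert_many(words[None, :], np.array([probe_hash0(words)], dtype=np.uint64),
                               np.array([count], dtype=np.uint64))
        return InsertStatus.COUNTED if bool(ok[0]) else InsertStatus.FAILED

    def _insert_many(
        self, keys: np.ndarray, h0: np.ndarray, counts: np.ndarray
    ) -> np.ndarray:
        """Insert distinct keys with multiplicities; returns a success mask.

        Equivalent to inserting each occurrence individually: a key whose
        probe window is fully occupied by foreign keys can never succeed
        later (probed slots never re-empty), so failure is all-or-nothing
        per key and multiplicities can be applied in one shot.
        """
        T = self.capacity
        i_max = self.i_max
        tab_counts = self._counts
        tab_keys = self._keys
        ok = np.zeros(keys.shape[0], dtype=bool)
        self.total_insertions += keys.shape[0]
        if self.W == 1:
            key_list = keys[:, 0].tolist()
            h0_list = h0.tolist()
            cnt_list = counts.tolist()
            tri = [(i * (i + 1)) // 2 for i in range(i_max)]
            for j, (kk, hh, cc) in enumerate(zip(key_list, h0_list, cnt_list)):
                for i in range(i_max):
                    slot = (hh + tri[i]) % T
                    c = tab_counts[slot]
                    if c == 0:
                        tab_keys[slot, 0] = kk
                        tab_counts[slot] = min(cc, _COUNTER_MAX)
                        self.inserted += 1
                        self.total_probes += i + 1
                        ok[j] = True
                        break
                    if tab_keys[slot, 0] == kk:
                        tab_counts[slot] = min(int(c) + cc, _COUNTER_MAX)
                        self.total_probes += i + 1
                        ok[j] = True
                        break
                else:
                    self.total_probes += i_max
        else:
            for j in range(keys.shape[0]):
                kk = keys[j]
                hh = int(h0[j])
                cc = int(counts[j])
                for i in range(i_max):
                    slot = (hh + (i * (i + 1)) // 2) % T
                    c = tab_counts[slot]
                    if c == 0:
                        tab_keys[slot] = kk
                        tab_counts[slot] = min(cc, _COUNTER_MAX)
                        self.inserted += 1
                        self.total_probes += i + 1
                        ok[j] = True
                        break
                    if (tab_keys[slot] == kk).all():
                        tab_counts[slot] = min(int(c) + cc, _COUNTER_MAX)
                        self.total_probes += i + 1
                        ok[j] = True
                        break
                else:
                    self.total_probes += i_max
        return ok

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(keys, counts) of the occupied slots, in slot order."""
        occ = self._counts > 0
        return self._keys[occ], self._counts[occ]

    def items(self) -> Iterator[tuple[EncodedSeq, int]]:
        keys, counts = self.to_arrays()
        for row, c in zip(keys, counts.tolist()):
            yield EncodedSeq(words_to_codes(row, self.k)[0]), int(c)


@dataclass(frozen=True)
class AlphaEstimator:
    """Running estimate of the distinct/total k-mer ratio of a bin.

    alpha sizes the next bin's tables; it is refreshed from each processed
    bin (the ratios of neighbouring bins are assumed similar).
    """

    alpha: float = 0.5
    alpha_prev: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} outside (0, 1]")


def update_alpha(est: AlphaEstimator, distinct_observed: int, total: int) -> AlphaEstimator:
    """Shift alpha to the observed ratio d/n; an empty bin leaves it alone."""
    if total == 0:
        return est
    if not 0 <= distinct_observed <= total:
        raise ValueError("need 0 <= d <= n")
    return AlphaEstimator(alpha=max(distinct_observed / total, 1e-12), alpha_prev=est.alpha)


def table_size(n: int, est: "AlphaEstimator | float", beta: float) -> int:
    """Slots for n k-mers: ceil(alpha * n / beta), at least 1."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta={beta} outside (0, 1)")
    alpha = est.alpha if isinstance(est, AlphaEstimator) else float(est)
    return max(1, math.ceil(alpha * n / beta))


def shard_id(x, N: int) -> int:
    """Deterministic shard of a k-mer: part_hash(x) mod N."""
    if N < 1:
        raise ValueError("shard count N must be >= 1")
    return part_hash(x) % N


@dataclass(frozen=True)
class PassPlan:
    """p = ceil(n / T_max) passes; pass i takes part_hash(x) == i (mod p)."""

    p: int

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("pass count must be >= 1")


def plan_passes(n: int, T_max: int) -> PassPlan:
    if T_max < 1:
        raise ValueError("T_max must be >= 1")
    return PassPlan(p=max(1, math.ceil(n / T_max)))


class FailureBuffer:
    """File-backed spill of k-mers that exceeded the probe cap.

    Append-only during a pass; drained completely (and the file removed)
    before the bin is finalized.  Records are (W x u64 key, u64 count).
    """

    def __init__(self, path: Path | str, W: int):
        self.path = Path(path)
        self.W = W
        self._handle = open(self.path, "wb")
        self.n_records = 0

    def spill_batch(self, keys: np.ndarray, counts: np.ndarray) -> None:
        if keys.shape[0] == 0:
            return
        rec = np.column_stack([keys.astype(np.uint64), counts.astype(np.uint64)])
        self._handle.write(rec.tobytes())
        self.n_records += keys.shape[0]

    def __len__(self) -> int:
        return self.n_records

    def drain(self) -> tuple[np.ndarray, np.ndarray]:
        """Read everything back, delete the file, return (keys, counts)."""
        self._handle.close()
        raw = np.fromfile(self.path, dtype=np.uint64).reshape(self.n_records, self.W + 1)
        self.path.unlink()
        return raw[:, : self.W].copy(), raw[:, self.W].copy()


@dataclass
class Phase2Config:
    k: int
    canonical: bool = True
    T_max: int = 1 << 30
    i_max: int = 30
    beta: float = 0.4
    n_shards: int = 1
    temp_dir: Path | str = "."
    alpha0: float = 0.5

    def __post_init__(self) -> None:
        self.temp_dir = Path(self.temp_dir)
        if self.T_max < 1:
            raise ValueError("T_max must be >= 1")
        if self.n_shards < 1:
            raise ValueError("shard count must be >= 1")


def _next_pow2(x: int) -> int:
    return 1 << max(0, (x - 1).bit_length())


def _expand_bin_windows(bin: BinFile, k: int) -> np.ndarray:
    """All k-mer windows of a bin's super-mers as an (n, k) code matrix."""
    chunks: list[np.ndarray] = []
    lengths: list[int] = []
    try:
        for codes, _rank in read_bin_records(bin.path):
            chunks.append(codes)
            lengths.append(codes.size)
    except ValueError as exc:
        raise ValueError(f"corrupt bin {bin.file_id}: {exc}") from exc
    if not chunks:
        return np.zeros((0, k), dtype=np.uint8)
    big = np.concatenate(chunks)
    lens = np.array(lengths, dtype=np.int64)
    wins = lens - k + 1
    if (wins < 1).any():
        bad = int(np.argmax(wins < 1))
        raise ValueError(f"corrupt bin {bin.file_id}: record {bad} shorter than k")
    offsets = np.concatenate(([0], np.cumsum(lens)[:-1]))
    # Ragged range: window start positions of every record, concatenated.
    starts = np.repeat(offsets, wins) + (
        np.arange(wins.sum()) - np.repeat(np.concatenate(([0], np.cumsum(wins)[:-1])), wins)
    )
    return np.lib.stride_tricks.sliding_window_view(big, k)[starts]


def _drain_failures(
    fb: FailureBuffer, k: int, i_max: int, beta: float
) -> tuple[np.ndarray, np.ndarray, int]:
    """Recount spilled k-mers exactly; returns (keys, counts, probes used).

    The first attempt reuses a doubled probe cap; persistent failures fall
    back to a power-of-two table probed exhaustively, which must succeed.
    """
    keys, counts = fb.drain()
    out_k: list[np.ndarray] = []
    out_c: list[np.ndarray] = []
    probes = 0
    cap = _next_pow2(table_size(keys.shape[0], 1.0, beta))
    i_max_d = max(1, 2 * i_max)
    while keys.shape[0]:
        table = CountTable(cap, k, i_max=min(i_max_d, cap), beta=beta)
        ok = table._insert_many(keys, probe_hash0_vec(keys), counts)
        probes += table.total_probes
        tk, tc = table.to_arrays()
        out_k.append(tk)
        out_c.append(tc)
        keys, counts = keys[~ok], counts[~ok]
        cap *= 2
        i_max_d = cap  # exhaustive coverage on retry: pow2 + full schedule
    W = n_words(k)
    if not out_k:
        return np.zeros((0, W), dtype=np.uint64), np.zeros(0, dtype=np.uint64), probes
    return np.concatenate(out_k), np.concatenate(out_c), probes


def count_bin_arrays(
    bin: BinFile,
    cfg: Phase2Config,
    est: AlphaEstimator | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Count one bin; returns (distinct keys (d, W), counts (d,), stats).

    Implements the full per-bin pipeline: expand super-mers into k-mer
    windows, canonicalize, select the current pass by part_hash mod p,
    route to shards by part_hash mod N, insert with bounded probing, spill
    failures, and drain the failure buffers before finalizing.
    """
    est = est or AlphaEstimator(alpha=cfg.alpha0)
    k = cfg.k
    windows = _expand_bin_windows(bin, k)
    n_total = windows.shape[0]
    if bin.n_kmers and bin.n_kmers != n_total:
        raise ValueError(
            f"bin {bin.file_id}: manifest says {bin.n_kmers} k-mers, found {n_total}"
        )
    if n_total == 0:
        W = n_words(k)
        return (
            np.zeros((0, W), dtype=np.uint64),
            np.zeros(0, dtype=np.uint64),
            {"n": 0, "d": 0, "passes": 1, "spilled": 0, "probes": 0, "insertions": 0},
        )

    fwd = codes_to_words(windows)
    if cfg.canonical:
        rc = (3 - windows)[:, ::-1]
        words = canonical_words(fwd, codes_to_words(rc))
    else:
        words = fwd
    ph = part_hash_vec(words)

    p = plan_passes(n_total, cfg.T_max).p
    N = cfg.n_shards
    out_k: list[np.ndarray] = []
    out_c: list[np.ndarray] = []
    stats = {"n": int(n_total), "passes": p, "spilled": 0, "probes": 0, "insertions": 0}
    pp = np.uint64(p)
    nn = np.uint64(N)

    for i in range(p):
        pass_mask = ph % pp == np.uint64(i)
        for s in range(N):
            mask = pass_mask if N == 1 else pass_mask & (ph % nn == np.uint64(s))
            kw = words[mask]
            if kw.shape[0] == 0:
                continue
            uniq, first_idx, counts = np.unique(
                kw, axis=0, return_index=True, return_counts=True
            )
            order = np.argsort(first_idx, kind="stable")  # first-occurrence order
            uniq = uniq[order]
            counts = counts[order].astype(np.uint64)
            cap = table_size(kw.shape[0], est, cfg.beta)
            table = CountTable(cap, k, i_max=cfg.i_max, beta=cfg.beta)
            ok = table._insert_many(uniq, probe_hash0_vec(uniq), counts)
            stats["probes"] += table.total_probes
            stats["insertions"] += table.total_insertions
            tk, tc = table.to_arrays()
            out_k.append(tk)
            out_c.append(tc)
            if not ok.all():
                fb = FailureBuffer(
                    Path(cfg.temp_dir) / f"fail_{bin.file_id:04d}_{i}_{s}.kmf",
                    table.W,
                )
                fb.spill_batch(uniq[~ok], counts[~ok])
                stats["spilled"] += len(fb)
                dk, dc, dprobes = _drain_failures(fb, k, cfg.i_max, cfg.beta)
                stats["probes"] += dprobes
                out_k.append(dk)
                out_c.append(dc)

    keys = np.concatenate(out_k)
    cnts = np.concatenate(out_c)
    stats["d"] = int(keys.shape[0])
    return keys, cnts, stats


def count_bin(
    bin: BinFile,
    cfg: Phase2Config,
    est: AlphaEstimator | None = None,
) -> Iterator[tuple[EncodedSeq, int]]:
    """Stream (canonical k-mer, exact count) for every distinct k-mer of a bin."""
    keys, counts, _ = count_bin_arrays(bin, cfg, est)
    for row, c in zip(keys, counts.tolist()):
        yield EncodedSeq(words_to_codes(row, cfg.k)[0]), int(c)
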