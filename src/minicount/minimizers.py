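"""Total orderings on m-mers, minimizer computation, super-mer decomposition.

A minimizer of a k-mer is the length-m substring that is minimal under a
chosen total ordering (a bijective rank over all 4^m m-mers).  Runs of
consecutive k-mers of a read that share the same minimizer occurrence are
joined into a super-mer — a maximal substring whose every k-mer window has
that minimizer — which is the unit written to the temporary bin files.

Six ordering strategies are provided:

``lex``
    Plain lexicographic with A < C < G < T (the baseline ordering).
``cgat``
    Lexicographic with base order C < G < A < T.
``roberts``
    Lexicographic with C < A < T < G after complementing the bases at even
    (0-based) positions, which makes low-complexity m-mers rank late.
``kmc2``
    Lexicographic with A < C < G < T, except that m-mers starting with AAA
    or ACA are demoted after all others (relative order within the demoted
    class stays lexicographic).  This is the default.
``random``
    A seeded uniform permutation of all 4^m m-mers.
``dfp``
    Distance-from-pivot: m-mers are sorted ascending by sampled frequency,
    then re-sorted by |initial_position - 4^m * p| for a pivot factor
    p in [0, 1]; ties break lexicographically (A < C < G < T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .dna_codec import EncodedSeq, ReadRecord, fragment_codes

__all__ = [
    "STRATEGIES",
    "MinimizerOrdering",
    "SuperMer",
    "build_ordering",
    "sample_frequencies",
    "minimizer_of",
    "super_mers",
]

STRATEGIES = ("lex", "cgat", "roberts", "kmc2", "random", "dfp")


@dataclass(frozen=True)
class MinimizerOrdering:
    """A total ordering over all 4^m m-mers.

    ``rank[v]`` is the rank (0 = most preferred) of the m-mer whose packed
    2-bit value is ``v``; it is a bijection onto [0, 4^m).
    """

    m: int
    strategy: str
    rank: np.ndarray
    params: Mapping[str, object] = field(default_factory=dict)

    @property
    def label(self) -> str:
        extra = ",".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.strategy}({extra})" if extra else self.strategy


@dataclass(frozen=True)
class SuperMer:
    """A maximal read substring whose k-mers all share one minimizer."""

    bases: EncodedSeq
    minimizer_rank: int
    kmer_count: int


def _digits(m: int) -> np.ndarray:
    """(4^m, m) matrix of base codes; row v spells the m-mer with value v."""
    vals = np.arange(4**m, dtype=np.int64)
    shifts = np.arange(2 * (m - 1), -2, -2, dtype=np.int64)
    return (vals[:, None] >> shifts) & 3


def _rank_from_keys(keys: np.ndarray) -> np.ndarray:
    """Invert a sort: rank[v] = position of m-mer v under ascending keys."""
    order = np.argsort(keys, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size, dtype=np.int64)
    return rank


def build_ordering(
    strategy: str,
    m: int,
    *,
    seed: int | None = None,
    frequencies: np.ndarray | None = None,
    pivot: float | None = None,
) -> MinimizerOrdering:
    """Construct the rank table of an ordering strategy.

    Parameters
    ----------
    strategy
        One of :data:`STRATEGIES`.
    m
        Minimizer length, 1 <= m <= 15 (the dense rank table has 4^m entries).
    seed
        Required for ``random``.
    frequencies, pivot
        Required for ``dfp``: an m-mer frequency table (e.g. from
        :func:`sample_frequencies`) and the pivot factor p in [0, 1].
    """
    if not 1 <= m <= 15:
        raise ValueError(f"minimizer length m={m} outside [1, 15]")
    strategy = strategy.lower()
    size = 4**m
    params: dict[str, object] = {}

    if strategy == "lex":
        # Plain lexicographic A<C<G<T: rank equals the packed m-mer value.
        rank = np.arange(size, dtype=np.int64)
    elif strategy == "cgat":
        # C<G<A<T: per-base order C=0, G=1, A=2, T=3.
        order = np.array([2, 0, 1, 3], dtype=np.int64)  # indexed by code A,C,G,T
        digits = _digits(m)
        shifts = np.arange(2 * (m - 1), -2, -2, dtype=np.int64)
        rank = (order[digits] << shifts).sum(axis=1)
    elif strategy == "roberts":
        # Complement bases at even positions, then lexicographic C<A<T<G.
        order = np.array([1, 0, 3, 2], dtype=np.int64)  # A=1, C=0, G=3, T=2
        digits = _digits(m)
        even = np.arange(m) % 2 == 0
        digits[:, even] = 3 - digits[:, even]
        shifts = np.arange(2 * (m - 1), -2, -2, dtype=np.int64)
        rank = _rank_from_keys((order[digits] << shifts).sum(axis=1))
    elif strategy == "kmc2":
        vals = np.arange(size, dtype=np.int64)
        demoted = np.zeros(size, dtype=bool)
        if m >= 3:
            prefix = vals >> (2 * (m - 3))  # value of the first three bases
            aaa = 0  # A,A,A
            aca = (0 << 4) | (1 << 2) | 0  # A,C,A
            demoted = (prefix == aaa) | (prefix == aca)
        rank = _rank_from_keys(demoted.astype(np.int64) * size + vals)
    elif strategy == "random":
        if seed is None:
            raise ValueError("random ordering requires a seed")
        rng = np.random.default_rng(seed)
        rank = rng.permutation(size).astype(np.int64)
        params["seed"] = int(seed)
    elif strategy == "dfp":
        if frequencies is None or pivot is None:
            raise ValueError("dfp ordering requires frequencies and a pivot factor")
        if not 0.0 <= float(pivot) <= 1.0:
            raise ValueError(f"dfp pivot {pivot} outside [0, 1]")
        freq = np.asarray(frequencies, dtype=np.int64)
        if freq.shape != (size,):
            raise ValueError(f"frequency table must have 4^m = {size} entries")
        vals = np.arange(size, dtype=np.int64)
        # Initial position: ascending frequency, lexicographic tie-break.
        order = np.lexsort((vals, freq))
        initial = np.empty(size, dtype=np.int64)
        initial[order] = vals
        dist = np.abs(initial - size * float(pivot))
        final = np.lexsort((vals, dist))
        rank = np.empty(size, dtype=np.int64)
        rank[final] = vals
        params["pivot"] = float(pivot)
    else:
        raise ValueError(f"unknown ordering strategy {strategy!r}")

    return MinimizerOrdering(m=m, strategy=strategy, rank=rank, params=params)


def sample_frequencies(
    reads: Iterable[ReadRecord],
    m: int,
    sample_size: int = 100_000,
) -> np.ndarray:
    """Count m-mer occurrences over the first ``sample_size`` read fragments.

    Returns a dense (4^m,) table; m-mers never seen get count 0.  Used to
    seed the ``dfp`` ordering without a full pass over the data.
    """
    if sample_size < 1:
        raise ValueError("sample_size must be >= 1")
    freq = np.zeros(4**m, dtype=np.int64)
    seen = 0
    for read in reads:
        for codes in fragment_codes(read):
            if codes.size >= m:
                np.add.at(freq, _mmer_values(codes, m), 1)
            seen += 1
            if seen >= sample_size:
                return freq
    return freq


def _mmer_values(codes: np.ndarray, m: int) -> np.ndarray:
    """Packed value of the m-mer starting at each position of a code vector."""
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), m)
    pows = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64)
    return win @ pows


def _rc_mmer_values(codes: np.ndarray, m: int) -> np.ndarray:
    """Packed value of the reverse complement of the m-mer at each position."""
    comp = 3 - codes.astype(np.int64)
    win = np.lib.stride_tricks.sliding_window_view(comp, m)
    pows = 4 ** np.arange(m, dtype=np.int64)  # rc reverses the read order
    return win @ pows


def _window_minimizers(
    codes: np.ndarray,
    k: int,
    ordering: MinimizerOrdering,
    canonical_mode: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimizer of every k-mer window of a fragment.

    Returns ``(occ, rank, mval)`` arrays of length L-k+1: the occurrence key
    (2 * position + strand, strand 1 = reverse), the minimizer rank, and the
    packed value of the minimizer m-mer itself.
    """
    m = ordering.m
    w = k - m + 1  # m-mer positions per k-mer window
    fvals = _mmer_values(codes, m)
    franks = ordering.rank[fvals]
    fwin = np.lib.stride_tricks.sliding_window_view(franks, w)
    fam = fwin.argmin(axis=1)  # argmin takes the leftmost on ties
    rows = np.arange(fwin.shape[0])
    frank = fwin[rows, fam]

    if not canonical_mode:
        pos = rows + fam
        return 2 * pos, frank, fvals[pos]

    rvals = _rc_mmer_values(codes, m)
    rranks = ordering.rank[rvals]
    rwin = np.lib.stride_tricks.sliding_window_view(rranks, w)
    ram = rwin.argmin(axis=1)
    rrank = rwin[rows, ram]

    use_rev = rrank < frank  # forward strand wins ties
    pos = np.where(use_rev, rows + ram, rows + fam)
    rank = np.where(use_rev, rrank, frank)
    mval = np.where(use_rev, rvals[pos], fvals[pos])
    return 2 * pos + use_rev, rank, mval


def minimizer_of(
    kmer: EncodedSeq,
    ordering: MinimizerOrdering,
    canonical_mode: bool = False,
) -> tuple[EncodedSeq, int]:
    """The minimal-rank m-mer of a k-mer (and that rank).

    In canonical mode the minimum is taken over the m-mer windows of both
    the k-mer and its reverse complement; ties prefer the forward strand,
    then the leftmost position.
    """
    m = ordering.m
    if kmer.length < m:
        raise ValueError(f"k-mer length {kmer.length} < minimizer length {m}")
    occ, rank, mval = _window_minimizers(kmer.codes, kmer.length, ordering, canonical_mode)
    pos, strand = divmod(int(occ[0]), 2)
    seg = kmer.codes[pos : pos + m]
    mmer = EncodedSeq(seg) if strand == 0 else EncodedSeq((3 - seg)[::-1])
    return mmer, int(rank[0])


def decompose_codes(
    codes: np.ndarray,
    k: int,
    ordering: MinimizerOrdering,
    canonical_mode: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Super-mer boundaries of a fragment, as arrays (fast path).

    Returns ``(starts, ends, ranks)`` where super-mer i spans base positions
    ``starts[i]:ends[i]`` and carries minimizer rank ``ranks[i]``.  A new
    super-mer begins exactly where the minimizer occurrence changes.
    """
    if codes.size < k:
        raise ValueError(f"fragment length {codes.size} < k={k}")
    occ, rank, _ = _window_minimizers(codes, k, ordering, canonical_mode)
    breaks = np.flatnonzero(np.diff(occ)) + 1
    starts = np.concatenate(([0], breaks))
    last_window = np.concatenate((breaks, [occ.size])) - 1
    return starts, last_window + k, rank[starts]


def super_mers(
    fragment: EncodedSeq,
    k: int,
    ordering: MinimizerOrdering,
    canonical_mode: bool = False,
) -> list[SuperMer]:
    """Decompose a fragment into its ordered super-mers.

    The decomposition is exhaustive and overlap-exact: concatenating the
    k-mer windows of the returned super-mers reproduces the fragment's
    window sequence exactly once each.
    """
    starts, ends, ranks = decompose_codes(fragment.codes, k, ordering, canonical_mode)
    return [
        SuperMer(
            bases=EncodedSeq(fragment.codes[s:e]),
            minimizer_rank=int(r),
            kmer_count=int(e - s) - k + 1,
        )
        for s, e, r in zip(starts.tolist(), ends.tolist(), ranks.tolist())
    ]
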