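"""Quantitative comparison of minimizer ordering strategies.

An ordering is scored along two competing axes measured on a read set:

* ``total_supermers`` — the number of super-mers the decomposition
  produces; fewer super-mers mean less temporary disk space.
* ``max_distinct_per_minimizer`` — the largest number of distinct k-mers
  that share one minimizer; a small maximum means the k-mers spread evenly
  over bins and bounds the per-bin memory peak.

A good ordering keeps both small; the two goals pull in opposite
directions, which is why several strategies are worth comparing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dna_codec import ReadRecord, fragment_codes, read_many
from .minimizers import MinimizerOrdering, _window_minimizers
from .packing import canonical_words, codes_to_words

__all__ = ["OrderingMetrics", "evaluate_ordering", "compare_orderings"]


@dataclass(frozen=True)
class OrderingMetrics:
    strategy: str
    total_supermers: int
    max_distinct_per_minimizer: int
    distinct_kmers: int
    per_minimizer: "dict[int, int] | None" = None


def _resolve_reads(reads) -> Iterable[ReadRecord]:
    if isinstance(reads, (str, Path)):
        return read_many([reads])
    if isinstance(reads, (list, tuple)) and reads and isinstance(reads[0], (str, Path)):
        return read_many(reads)
    return reads


def evaluate_ordering(
    reads,
    k: int,
    ordering: MinimizerOrdering,
    canonical_mode: bool = True,
    keep_per_minimizer: bool = False,
) -> OrderingMetrics:
    """Score one ordering on a read set in a single streaming scan.

    ``reads`` may be file path(s) or an iterable of :class:`ReadRecord`.
    Distinct k-mer sets per minimizer are exact (no sketching).
    """
    total_supermers = 0
    rank_chunks: list[np.ndarray] = []
    word_chunks: list[np.ndarray] = []
    for read in _resolve_reads(reads):
        for codes in fragment_codes(read):
            if codes.size < k:
                continue
            occ, rank, _ = _window_minimizers(codes, k, ordering, canonical_mode)
            total_supermers += 1 + int(np.count_nonzero(np.diff(occ)))
            windows = np.lib.stride_tricks.sliding_window_view(codes, k)
            fwd = codes_to_words(windows)
            if canonical_mode:
                words = canonical_words(fwd, codes_to_words((3 - windows)[:, ::-1]))
            else:
                words = fwd
            rank_chunks.append(rank.astype(np.uint64))
            word_chunks.append(words)

    if not rank_chunks:
        return OrderingMetrics(ordering.label, 0, 0, 0, {} if keep_per_minimizer else None)

    ranks = np.concatenate(rank_chunks)
    words = np.concatenate(word_chunks)
    pairs = np.column_stack([ranks[:, None], words])
    uniq = np.unique(pairs, axis=0)  # distinct (minimizer, k-mer) pairs
    per_rank, per_count = np.unique(uniq[:, 0], return_counts=True)
    distinct = int(np.unique(uniq[:, 1:], axis=0).shape[0])
    table = (
        dict(zip(per_rank.astype(int).tolist(), per_count.astype(int).tolist()))
        if keep_per_minimizer
        else None
    )
    return OrderingMetrics(
        strategy=ordering.label,
        total_supermers=total_supermers,
        max_distinct_per_minimizer=int(per_count.max()),
        distinct_kmers=distinct,
        per_minimizer=table,
    )


def compare_orderings(
    reads,
    k: int,
    orderings: Sequence[MinimizerOrdering],
    canonical_mode: bool = True,
) -> pd.DataFrame:
    """One metrics row per ordering, as a DataFrame (tab-separable report).

    ``reads`` must be re-scannable: file path(s) or a materialized list of
    records (a one-shot generator would be exhausted after the first row).
    """
    if not isinstance(reads, (str, Path, list, tuple)):
        reads = list(reads)
    rows = []
    for ordering in orderings:
        m = evaluate_ordering(reads, k, ordering, canonical_mode)
        rows.append(
            {
                "strategy": m.strategy,
                "m": ordering.m,
                "total_supermers": m.total_supermers,
                "max_distinct_per_minimizer": m.max_distinct_per_minimizer,
                "distinct_kmers": m.distinct_kmers,
            }
        )
    return pd.DataFrame(rows)
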