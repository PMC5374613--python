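"""End-to-end orchestration: phase one -> phase two -> sorted output.

`run_count` is what the CLI's ``count`` command calls: it validates the
configuration, builds the minimizer ordering (sampling m-mer frequencies
first when the distance-from-pivot strategy is requested), distributes
super-mers into bins, counts each bin, and writes the merged counts sorted
lexicographically so identical inputs always give byte-identical output.
"""

from __future__ import annotations

import math
import shutil
import struct
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .dna_codec import EncodedSeq, encode, read_many
from .minimizers import MinimizerOrdering, build_ordering, sample_frequencies
from .packing import n_words, pack_codes_to_bytes, unpack_bytes_to_codes, words_to_codes
from .phase1 import Phase1Config, run_phase1
from .phase2 import AlphaEstimator, Phase2Config, count_bin_arrays, update_alpha

__all__ = ["RunConfig", "RunReport", "run_count", "write_counts", "read_counts"]

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RunConfig:
    """Everything a counting run needs.

    The hash-table budget T_max is derived from ``memory_cap`` divided by
    the slot byte size (ceil(2k/64) 64-bit key words + a 32-bit counter)
    unless ``T_max`` is given explicitly.
    """

    k: int
    m: int = 7
    ordering: str = "kmc2"
    dfp_pivot: float | None = None
    canonical: bool = True
    F: int = 512
    memory_cap: int = 1 << 30
    T_max: int | None = None
    i_max: int = 30
    beta: float = 0.4
    min_count: int = 1
    shards: int = 1
    temp_dir: Path | str | None = None
    output: Path | str = "counts.tsv"
    output_format: str = "tsv"
    keep_temp: bool = False
    seed: int = 0
    alpha0: float = 0.5
    freq_sample_size: int = 100_000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k < self.m:
            raise ValueError(f"k={self.k} must be >= m={self.m}")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.F < 1 or self.shards < 1 or self.i_max < 0:
            raise ValueError("F, shards must be >= 1 and i_max >= 0")
        if not 0.0 < self.beta < 1.0:
            raise ValueError("beta must lie in (0, 1)")
        if self.output_format not in ("tsv", "binary"):
            raise ValueError(f"unknown output format {self.output_format!r}")
        slot = n_words(self.k) * 8 + 4
        if self.T_max is None:
            self.T_max = max(1, self.memory_cap // slot)
        if self.T_max < 1:
            raise ValueError("memory cap below the one-slot minimum")


@dataclass
class RunReport:
    """Observables of a run: per-bin totals, alpha trajectory, timings."""

    k: int
    ordering_label: str
    canonical: bool
    total_kmers: int = 0
    distinct_kmers: int = 0
    written_kmers: int = 0
    bins: list[dict] = field(default_factory=list)
    alpha_trajectory: list[float] = field(default_factory=list)
    passes_used: int = 0
    failures_spilled: int = 0
    total_probes: int = 0
    total_insertions: int = 0
    timings: dict[str, float] = field(default_factory=dict)
    output: Path | None = None

    @property
    def mean_probes(self) -> float:
        return self.total_probes / max(1, self.total_insertions)

    def summary(self) -> str:
        lines = [
            f"k={self.k} ordering={self.ordering_label} canonical={self.canonical}",
            f"total k-mers     {self.total_kmers}",
            f"distinct k-mers  {self.distinct_kmers}",
            f"written (>= min) {self.written_kmers}",
            f"passes used      {self.passes_used}",
            f"failures spilled {self.failures_spilled}",
            f"mean probes      {self.mean_probes:.3f}",
            "phase timings    "
            + " ".join(f"{k}={v:.2f}s" for k, v in self.timings.items()),
        ]
        return "\n".join(lines)


def _build_run_ordering(cfg: RunConfig, inputs) -> MinimizerOrdering:
    if cfg.ordering == "random":
        return build_ordering("random", cfg.m, seed=cfg.seed)
    if cfg.ordering == "dfp":
        pivot = 0.5 if cfg.dfp_pivot is None else cfg.dfp_pivot
        freqs = sample_frequencies(read_many(inputs), cfg.m, cfg.freq_sample_size)
        return build_ordering("dfp", cfg.m, frequencies=freqs, pivot=pivot)
    return build_ordering(cfg.ordering, cfg.m)


def run_count(cfg: RunConfig, inputs: Sequence[Path | str]) -> RunReport:
    """Count the k-mers of the input files; returns the run report.

    Output is every distinct (canonical) k-mer with exact count >=
    ``cfg.min_count``, sorted lexicographically, in TSV or binary form.
    """
    inputs = [Path(p) for p in inputs]
    for p in inputs:
        if not p.exists():
            raise FileNotFoundError(p)

    temp_dir = (
        Path(tempfile.mkdtemp(prefix="minicount_"))
        if cfg.temp_dir is None
        else Path(cfg.temp_dir)
    )
    temp_dir.mkdir(parents=True, exist_ok=True)

    report = RunReport(k=cfg.k, ordering_label="", canonical=cfg.canonical)
    t0 = time.perf_counter()
    try:
        ordering = _build_run_ordering(cfg, inputs)
        report.ordering_label = ordering.label

        p1 = Phase1Config(
            k=cfg.k, ordering=ordering, canonical=cfg.canonical, F=cfg.F, temp_dir=temp_dir
        )
        bins, _manifest = run_phase1(inputs, p1)
        t1 = time.perf_counter()
        report.timings["phase1"] = t1 - t0

        p2 = Phase2Config(
            k=cfg.k,
            canonical=cfg.canonical,
            T_max=cfg.T_max,
            i_max=cfg.i_max,
            beta=cfg.beta,
            n_shards=cfg.shards,
            temp_dir=temp_dir,
            alpha0=cfg.alpha0,
        )
        est = AlphaEstimator(alpha=cfg.alpha0)
        key_chunks: list[np.ndarray] = []
        count_chunks: list[np.ndarray] = []
        for b in bins:
            keys, counts, stats = count_bin_arrays(b, p2, est)
            key_chunks.append(keys)
            count_chunks.append(counts)
            report.bins.append({"file_id": b.file_id, **stats})
            report.total_kmers += stats["n"]
            report.passes_used += stats["passes"]
            report.failures_spilled += stats["spilled"]
            report.total_probes += stats["probes"]
            report.total_insertions += stats["insertions"]
            if stats["n"] > 0:
                est = update_alpha(est, stats["d"], stats["n"])
                report.alpha_trajectory.append(est.alpha)
        t2 = time.perf_counter()
        report.timings["phase2"] = t2 - t1

        keys = np.concatenate(key_chunks) if key_chunks else np.zeros((0, n_words(cfg.k)), np.uint64)
        counts = np.concatenate(count_chunks) if count_chunks else np.zeros(0, np.uint64)
        report.distinct_kmers = int(keys.shape[0])

        if cfg.min_count > 1:
            keep = counts >= cfg.min_count
            keys, counts = keys[keep], counts[keep]
        if keys.shape[0]:
            order = np.lexsort(keys.T[::-1])  # word 0 is the primary sort key
            keys, counts = keys[order], counts[order]
        report.written_kmers = int(keys.shape[0])

        out = Path(cfg.output)
        _write_sorted_arrays(keys, counts, cfg.k, out, cfg.output_format)
        report.output = out
        report.timings["write"] = time.perf_counter() - t2
    finally:
        if not cfg.keep_temp:
            shutil.rmtree(temp_dir, ignore_errors=True)
    return report


def _decode_rows(keys: np.ndarray, k: int) -> list[str]:
    codes = words_to_codes(keys, k)
    blob = _BASE_ARR[codes].tobytes()
    return [blob[i * k : (i + 1) * k].decode() for i in range(keys.shape[0])]


def _write_sorted_arrays(
    keys: np.ndarray, counts: np.ndarray, k: int, path: Path, fmt: str
) -> None:
    if fmt == "tsv":
        lines = _decode_rows(keys, k)
        with open(path, "w") as out:
            for s, c in zip(lines, counts.tolist()):
                out.write(f"{s}\t{c}\n")
    else:
        codes = words_to_codes(keys, k)
        with open(path, "wb") as out:
            out.write(struct.pack("<Q", keys.shape[0]))
            for i in range(keys.shape[0]):
                out.write(pack_codes_to_bytes(codes[i]))
                out.write(struct.pack("<I", min(int(counts[i]), 0xFFFFFFFF)))


def write_counts(
    entries: Iterable[tuple["EncodedSeq | str", int]],
    path: Path | str,
    fmt: str = "tsv",
    k: int | None = None,
) -> Path:
    """Write (k-mer, count) pairs to ``path``.

    tsv: one ``<k-mer><TAB><count>`` line per entry.  binary: a u64 LE
    record-count header, then per record ceil(k/4) bytes of 2-bit packed
    bases and a u32 LE count.  Both round-trip via :func:`read_counts`.
    """
    path = Path(path)
    entries = list(entries)
    if fmt == "tsv":
        with open(path, "w") as out:
            for kmer, c in entries:
                out.write(f"{kmer}\t{c}\n")
        return path
    if fmt != "binary":
        raise ValueError(f"unknown output format {fmt!r}")
    with open(path, "wb") as out:
        out.write(struct.pack("<Q", len(entries)))
        for kmer, c in entries:
            es = kmer if isinstance(kmer, EncodedSeq) else encode(str(kmer))
            if k is not None and es.length != k:
                raise ValueError(f"k-mer length {es.length} != k={k}")
            out.write(pack_codes_to_bytes(es.codes))
            out.write(struct.pack("<I", min(int(c), 0xFFFFFFFF)))
    return path


def read_counts(path: Path | str, k: int | None = None, fmt: str = "tsv") -> dict[str, int]:
    """Read a counts file written by :func:`write_counts` back into a dict."""
    path = Path(path)
    if fmt == "tsv":
        out: dict[str, int] = {}
        with open(path) as handle:
            for line in handle:
                if not line.strip():
                    continue
                kmer, c = line.rstrip("\n").split("\t")
                out[kmer] = int(c)
        return out
    if fmt != "binary":
        raise ValueError(f"unknown output format {fmt!r}")
    if k is None:
        raise ValueError("binary format requires k")
    data = path.read_bytes()
    (n,) = struct.unpack_from("<Q", data, 0)
    off = 8
    nbytes = (k + 3) // 4
    out = {}
    for _ in range(n):
        codes = unpack_bytes_to_codes(data[off : off + nbytes], k)
        off += nbytes
        (c,) = struct.unpack_from("<I", data, off)
        off += 4
        out[str(EncodedSeq(codes))] = c
    return out
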