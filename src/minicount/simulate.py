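"""Seeded genome/read simulation and the brute-force counting oracle.

The simulator emulates shotgun sequencing of a uniform random genome:
fixed-length reads drawn from uniform start positions and strands, with
independent per-base substitution errors and sporadic N-masking.  It does
not model indels, quality-dependent error profiles, GC bias or repeat
structure — it exists to exercise the counting machinery (including the
multi-pass and failure paths) with known ground truth, not to mimic any
particular instrument.

:func:`oracle_count` is the independent reference: a plain dictionary count
over every ACGT window, written in terms of Python strings with no code
shared with the two-phase pipeline.
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .dna_codec import ReadRecord

__all__ = ["SimSpec", "simulate_genome", "simulate_reads", "oracle_count"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TABLE = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of a simulated sequencing run.

    coverage is the expected mean depth; the read count is
    ceil(coverage * genome_length / read_length).
    """

    genome_length: int = 100_000
    read_length: int = 100
    coverage: float = 10.0
    substitution_error_rate: float = 0.01
    n_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.read_length < 1:
            raise ValueError("lengths must be >= 1")
        for name in ("coverage", "substitution_error_rate", "n_rate"):
            v = getattr(self, name)
            if name == "coverage":
                if v <= 0:
                    raise ValueError("coverage must be positive")
            elif not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def n_reads(self) -> int:
        return math.ceil(self.coverage * self.genome_length / self.read_length)


def simulate_genome(spec: SimSpec) -> str:
    """A uniform random ACGT string of the requested length."""
    rng = np.random.default_rng([spec.seed, 0])
    codes = rng.integers(0, 4, size=spec.genome_length)
    return _BASES[codes].tobytes().decode()


def simulate_reads(
    genome: str,
    spec: SimSpec,
    path: Path | str,
    fmt: str = "fastq",
    compress: bool = False,
) -> Path:
    """Write simulated reads of ``genome`` to a FASTA/FASTQ(.gz) file."""
    if spec.read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    if fmt not in ("fastq", "fasta"):
        raise ValueError(f"unknown format {fmt!r}")
    rng = np.random.default_rng([spec.seed, 1])
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    rl = spec.read_length
    n = spec.n_reads
    starts = rng.integers(0, len(genome) - rl + 1, size=n)
    strands = rng.integers(0, 2, size=n)

    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b

    qual = "I" * rl
    path = Path(path)
    opener = gzip.open if compress else open
    with opener(path, "wt") as out:
        for idx in range(n):
            seq = g[starts[idx] : starts[idx] + rl].copy()
            if strands[idx]:
                seq = comp[seq[::-1]]
            if spec.substitution_error_rate > 0:
                err = rng.random(rl) < spec.substitution_error_rate
                if err.any():
                    # Substitute with one of the three other bases.
                    shift = rng.integers(1, 4, size=int(err.sum()))
                    codes = np.searchsorted(_BASES, seq[err])
                    seq[err] = _BASES[(codes + shift) % 4]
            if spec.n_rate > 0:
                mask = rng.random(rl) < spec.n_rate
                seq[mask] = ord("N")
            s = seq.tobytes().decode()
            if fmt == "fastq":
                out.write(f"@read_{idx}\n{s}\n+\n{qual}\n")
            else:
                out.write(f">read_{idx}\n{s}\n")
    return path


def oracle_count(
    reads: "Iterable[ReadRecord | str] | str | Path",
    k: int,
    canonical_mode: bool = True,
) -> dict[str, int]:
    """Brute-force dictionary count of all k-mers — the reference oracle.

    ``reads`` may be a FASTA/FASTQ(.gz) path, an iterable of
    :class:`ReadRecord`, or bare sequence strings.  Reads are split at
    non-ACGT characters; every window of length k of every fragment is
    counted, canonicalized (min of window and its reverse complement) when
    requested.
    """
    if isinstance(reads, (str, Path)) and Path(str(reads)).exists():
        from .dna_codec import read_sequences

        reads = read_sequences(reads)
    counts: dict[str, int] = {}
    for item in reads:
        seq = item.seq if isinstance(item, ReadRecord) else str(item)
        seq = seq.upper()
        for frag in _split_acgt(seq):
            for j in range(len(frag) - k + 1):
                w = frag[j : j + k]
                if canonical_mode:
                    rc = w.translate(_RC_TABLE)[::-1]
                    if rc < w:
                        w = rc
                counts[w] = counts.get(w, 0) + 1
    return counts


def _split_acgt(seq: str) -> list[str]:
    return re.findall("[ACGT]+", seq)
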