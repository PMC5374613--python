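"""Phase one: stream reads, cut super-mers, distribute them into bin files.

The bins partition the k-mer content of the input: all occurrences of a
k-mer (of its canonical form, in canonical mode) carry the same minimizer
and therefore land in the same temporary file, so phase two can count each
bin independently under a small memory footprint.

Bin record format (little-endian, bit-exact across runs):

    u16  super-mer length in bases (L)
    u32  minimizer rank
    ceil(L/4) bytes of 2-bit packed bases, first base in the MSBs

A sidecar ``manifest.tsv`` lists per-bin k-mer and super-mer totals plus the
ordering parameters of the run.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .dna_codec import ReadRecord, fragment_codes, read_many
from .minimizers import MinimizerOrdering, SuperMer, decompose_codes
from .packing import pack_codes_to_bytes, unpack_bytes_to_codes

__all__ = [
    "BinFile",
    "Phase1Config",
    "assign_file",
    "write_supermer",
    "read_bin_records",
    "run_phase1",
]

_HEADER = struct.Struct("<HI")  # u16 length, u32 minimizer rank

MAX_SUPERMER_LEN = 0xFFFF  # u16 length field


@dataclass
class BinFile:
    """A temporary on-disk file of super-mers for a subset of minimizers."""

    path: Path
    file_id: int
    n_kmers: int = 0
    n_supermers: int = 0
    byte_size: int = 0


@dataclass
class Phase1Config:
    k: int
    ordering: MinimizerOrdering
    canonical: bool = True
    F: int = 512
    temp_dir: Path | str = "."

    def __post_init__(self) -> None:
        self.temp_dir = Path(self.temp_dir)
        if self.k < self.ordering.m:
            raise ValueError(f"k={self.k} must be >= m={self.ordering.m}")
        if self.F < 1:
            raise ValueError("number of bin files F must be >= 1")

    @property
    def m(self) -> int:
        return self.ordering.m


def assign_file(minimizer_rank: int, F: int) -> int:
    """Map a minimizer rank to a bin file id in [0, F).

    The map is ``rank % F``: deterministic, and exactly balanced whenever F
    divides 4^m (F and m are powers of two / of four by default), which
    keeps the worst bin close to the mean without any frequency feedback.
    """
    return int(minimizer_rank) % F


def write_supermer(handle, sm: SuperMer) -> int:
    """Append one super-mer record; returns the bytes written."""
    L = sm.bases.length
    if L > MAX_SUPERMER_LEN:
        raise ValueError(f"super-mer length {L} exceeds the u16 record limit")
    payload = _HEADER.pack(L, sm.minimizer_rank) + pack_codes_to_bytes(sm.bases.codes)
    handle.write(payload)
    return len(payload)


def read_bin_records(path: Path | str) -> Iterator[tuple[np.ndarray, int]]:
    """Yield (base codes, minimizer rank) for every record of a bin file."""
    path = Path(path)
    data = path.read_bytes()
    off = 0
    idx = 0
    total = len(data)
    while off < total:
        if off + _HEADER.size > total:
            raise ValueError(f"{path.name}: truncated header at record {idx}")
        L, rank = _HEADER.unpack_from(data, off)
        off += _HEADER.size
        nbytes = (L + 3) // 4
        if off + nbytes > total:
            raise ValueError(f"{path.name}: truncated bases at record {idx}")
        yield unpack_bytes_to_codes(data[off : off + nbytes], L), rank
        off += nbytes
        idx += 1


def _write_manifest(path: Path, bins: Sequence[BinFile], cfg: Phase1Config) -> None:
    lines = [
        f"#k={cfg.k}",
        f"#m={cfg.m}",
        f"#ordering={cfg.ordering.label}",
        f"#canonical={int(cfg.canonical)}",
        f"#F={cfg.F}",
        "file_id\tn_kmers\tn_supermers\tbyte_size",
    ]
    for b in bins:
        lines.append(f"{b.file_id}\t{b.n_kmers}\t{b.n_supermers}\t{b.byte_size}")
    path.write_text("\n".join(lines) + "\n")


def run_phase1(
    inputs: Sequence[Path | str] | Iterable[ReadRecord],
    cfg: Phase1Config,
) -> tuple[list[BinFile], Path]:
    """Distribute the super-mers of the input reads into F bin files.

    ``inputs`` is either a list of FASTA/FASTQ(.gz) paths or an iterable of
    already-parsed :class:`ReadRecord`.  Every k-mer window of every
    ACGT-fragment of length >= k ends up in exactly one super-mer record in
    exactly one bin.  Returns the bin descriptors and the manifest path.
    """
    cfg.temp_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(inputs, (list, tuple)) and inputs and isinstance(inputs[0], (str, Path)):
        reads: Iterable[ReadRecord] = read_many(inputs)
    else:
        reads = inputs  # type: ignore[assignment]

    k = cfg.k
    buffers: list[list[bytes]] = [[] for _ in range(cfg.F)]
    bins = [
        BinFile(path=cfg.temp_dir / f"bin_{fid:04d}.smr", file_id=fid)
        for fid in range(cfg.F)
    ]

    for read in reads:
        for codes in fragment_codes(read):
            if codes.size < k:
                continue
            starts, ends, ranks = decompose_codes(codes, k, cfg.ordering, cfg.canonical)
            fids = ranks % cfg.F
            for s, e, r, fid in zip(
                starts.tolist(), ends.tolist(), ranks.tolist(), fids.tolist()
            ):
                rec = _HEADER.pack(e - s, r) + pack_codes_to_bytes(codes[s:e])
                buffers[fid].append(rec)
                b = bins[fid]
                b.n_supermers += 1
                b.n_kmers += e - s - k + 1
                b.byte_size += len(rec)

    for b in bins:
        b.path.write_bytes(b"".join(buffers[b.file_id]))

    manifest = cfg.temp_dir / "manifest.tsv"
    _write_manifest(manifest, bins, cfg)
    return bins, manifest
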