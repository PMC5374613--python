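"""DNA alphabet encoding, canonicalization, and FASTA/FASTQ ingestion.

Every piece of k-mer and minimizer arithmetic in this package operates on
2-bit base codes with the fixed map A=0, C=1, G=2, T=3.  Because the code
order equals the lexicographic order A < C < G < T, comparing packed code
vectors (or the integers they spell) is the same as comparing the base
strings, which makes canonicalization a plain integer/byte comparison.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "BASES",
    "EncodedSeq",
    "ReadRecord",
    "encode",
    "decode",
    "reverse_complement",
    "canonical",
    "iter_fragments",
    "read_sequences",
]

BASES = "ACGT"

_CODE_OF = {b: i for i, b in enumerate(BASES)}
_BASE_ARR = np.frombuffer(BASES.encode(), dtype=np.uint8)

# Build an ASCII -> code lookup; 255 marks a non-ACGT byte.
_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE_OF.items():
    _LUT[ord(_b)] = _c
    _LUT[ord(_b.lower())] = _c

_FRAGMENT_RE = re.compile("[ACGT]+")


class EncodedSeq:
    """A DNA string over {A,C,G,T} held as a vector of 2-bit base codes.

    Instances are immutable value objects: equality, ordering and hashing
    follow the underlying base string (lexicographic, A < C < G < T).
    """

    __slots__ = ("codes", "_value")

    def __init__(self, codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 1:
            raise ValueError("codes must be one-dimensional")
        if codes.size and codes.max() > 3:
            raise ValueError("base codes must be in {0,1,2,3}")
        self.codes = codes
        self.codes.setflags(write=False)
        self._value: int | None = None

    @property
    def length(self) -> int:
        return self.codes.size

    def __len__(self) -> int:
        return self.codes.size

    @property
    def value(self) -> int:
        """The packed integer: first base in the most significant 2 bits."""
        if self._value is None:
            v = 0
            for c in self.codes.tolist():
                v = (v << 2) | c
            self._value = v
        return self._value

    def __str__(self) -> str:
        return _BASE_ARR[self.codes].tobytes().decode()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        s = str(self)
        return f"EncodedSeq({s if len(s) <= 40 else s[:37] + '...'})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EncodedSeq):
            return NotImplemented
        return self.codes.size == other.codes.size and bool(
            np.array_equal(self.codes, other.codes)
        )

    def __lt__(self, other: "EncodedSeq") -> bool:
        return self.codes.tobytes() < other.codes.tobytes()

    def __le__(self, other: "EncodedSeq") -> bool:
        return self.codes.tobytes() <= other.codes.tobytes()

    def __hash__(self) -> int:
        return hash((self.codes.size, self.codes.tobytes()))

    def reverse_complement(self) -> "EncodedSeq":
        return EncodedSeq((3 - self.codes)[::-1])

    def canonical(self) -> "EncodedSeq":
        rc = self.reverse_complement()
        return self if self <= rc else rc


@dataclass(frozen=True)
class ReadRecord:
    """A raw sequencing read: free-text id plus the base string as given.

    The sequence may contain non-ACGT symbols (N and friends); those are
    resolved downstream by :func:`iter_fragments`.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r} has an empty sequence")


def encode(seq: str) -> EncodedSeq:
    """Encode an ACGT string (case-insensitive) into 2-bit codes."""
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _LUT[raw]
    if codes.max() > 3:
        bad = seq[int(np.argmax(codes > 3))]
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return EncodedSeq(codes)


def decode(x: EncodedSeq) -> str:
    return str(x)


def reverse_complement(x: EncodedSeq) -> EncodedSeq:
    """Reverse the sequence and swap A<->T, C<->G."""
    return x.reverse_complement()


def canonical(x: EncodedSeq) -> EncodedSeq:
    """The lexicographically lesser of x and its reverse complement."""
    return x.canonical()


def iter_fragments(read: ReadRecord) -> Iterator[EncodedSeq]:
    """Yield the maximal ACGT-only substrings of a read, uppercased.

    Ambiguous bases split the read; fragments shorter than k are skipped by
    callers, not here.
    """
    for match in _FRAGMENT_RE.finditer(read.seq.upper()):
        yield encode(match.group())


def fragment_codes(read: ReadRecord) -> Iterator[np.ndarray]:
    """Like :func:`iter_fragments` but yields bare code arrays (fast path)."""
    raw = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    codes = _LUT[raw]
    if codes.max(initial=0) <= 3:
        if codes.size:
            yield codes
        return
    bad = np.flatnonzero(codes > 3)
    prev = 0
    for b in bad.tolist():
        if b > prev:
            yield codes[prev:b]
        prev = b + 1
    if prev < codes.size:
        yield codes[prev:]


_FASTA_EXT = {".fa", ".fasta", ".fna", ".ffn", ".frn"}
_FASTQ_EXT = {".fq", ".fastq"}


def _detect(path: Path) -> tuple[str, bool]:
    compressed = path.suffix == ".gz"
    stem = path.with_suffix("") if compressed else path
    ext = stem.suffix.lower()
    if ext in _FASTA_EXT:
        return "fasta", compressed
    if ext in _FASTQ_EXT:
        return "fastq", compressed
    raise ValueError(f"cannot detect format from extension of {path.name!r}")


def _iter_fastq(handle: io.TextIOBase, name: str) -> Iterator[ReadRecord]:
    # Strict 4-line records so malformed input can be reported by line.
    lineno = 0
    while True:
        header = handle.readline()
        if not header:
            return
        lineno += 1
        if not header.strip():
            continue  # tolerate trailing blank lines
        if not header.startswith("@"):
            raise ValueError(f"{name}: line {lineno}: FASTQ header must start with '@'")
        seq = handle.readline().rstrip("\n")
        plus = handle.readline()
        qual = handle.readline().rstrip("\n")
        if not qual and not plus:
            raise ValueError(f"{name}: line {lineno}: truncated FASTQ record")
        lineno += 3
        if not plus.startswith("+"):
            raise ValueError(f"{name}: line {lineno - 1}: expected '+' separator")
        if len(qual) != len(seq):
            raise ValueError(
                f"{name}: line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        yield ReadRecord(id=header[1:].strip(), seq=seq)


def read_sequences(
    path: str | Path,
    format: str = "auto",
    compressed: bool | None = None,
) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTA/FASTQ file, transparently gunzipping.

    Parameters
    ----------
    path
        Input file.  With ``format="auto"`` the format is inferred from the
        extension (``.fa/.fasta/...`` vs ``.fq/.fastq``, optionally ``.gz``).
    format
        One of ``{"fasta", "fastq", "auto"}``.
    compressed
        Force gzip on/off; default inspects the ``.gz`` extension.

    FASTQ quality strings are validated for length and then discarded.
    """
    path = Path(path)
    if format == "auto" or compressed is None:
        fmt, comp = _detect(path)
        if format == "auto":
            format = fmt
        if compressed is None:
            compressed = comp
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")

    opener = gzip.open if compressed else open
    with opener(path, "rt") as handle:
        if format == "fastq":
            yield from _iter_fastq(handle, path.name)
        else:
            for rec in SeqIO.parse(handle, "fasta"):
                seq = str(rec.seq)
                if not seq:
                    raise ValueError(f"{path.name}: record {rec.id!r} has an empty sequence")
                yield ReadRecord(id=rec.id, seq=seq)


def read_many(paths: Iterable[str | Path], **kwargs) -> Iterator[ReadRecord]:
    """Chain :func:`read_sequences` over several input files."""
    for p in paths:
        yield from read_sequences(p, **kwargs)
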