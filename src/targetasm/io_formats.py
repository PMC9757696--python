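"""Streaming sequence I/O: FASTA and FASTQ, plain or gzip-compressed.

All readers yield lightweight :class:`SequenceRecord` objects with uppercased
sequences and never buffer whole files.  Gzip input is detected by magic bytes,
so renamed files are handled transparently.  Interleaved FASTQ is not
supported: paired input is always two synchronized files.
"""

from __future__ import annotations

import gzip
import io
import itertools
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Iterator, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "ReadPair",
    "FormatError",
    "PairingError",
    "reverse_complement",
    "read_fasta",
    "read_fastq",
    "read_fastq_pairs",
    "write_fasta",
    "write_fastq",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

GZIP_MAGIC = b"\x1f\x8b"


class FormatError(ValueError):
    """A sequence file violates its format (FASTA/FASTQ)."""


class PairingError(ValueError):
    """Two mate files cannot be synchronized into read pairs."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(slots=True)
class SequenceRecord:
    """One identified nucleotide sequence, the currency of FASTA/FASTQ I/O.

    ``id`` is the first whitespace-delimited token of the header,
    ``description`` the remainder (possibly empty).  ``qual`` is the
    per-base quality string for FASTQ records, same length as ``seq``.
    """

    id: str
    seq: str
    description: str = ""
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass(slots=True)
class ReadPair:
    """A read and its optional mate (r2 is None for single-end data)."""

    r1: SequenceRecord
    r2: Optional[SequenceRecord] = None


def _strip_mate_suffix(read_id: str) -> str:
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def _open_text(path: str | PathLike) -> io.TextIOBase:
    """Open a possibly gzip-compressed text file, sniffing magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _open_out(path: str | PathLike) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "wb"))
    return open(path, "w")


def _split_title(title: str) -> tuple[str, str]:
    parts = title.split(None, 1)
    if not parts:
        return "", ""
    return parts[0], (parts[1] if len(parts) > 1 else "")


def read_fasta(path: str | PathLike) -> Iterator[SequenceRecord]:
    """Stream records from a (possibly gzipped) FASTA file.

    Sequences are uppercased and line wrapping is concatenated away.
    Raises :class:`FormatError` if sequence data precedes the first header.
    """
    with _open_text(path) as handle:
        # peek for leading junk so the error can name the offending line
        lineno = 0
        first = None
        buffered: list[str] = []
        for line in handle:
            lineno += 1
            buffered.append(line)
            if line.strip():
                first = line
                break
        if first is None:
            return
        if not first.lstrip().startswith(">"):
            raise FormatError(
                f"{path}: line {lineno}: sequence data before first '>' header"
            )
        chained = itertools.chain(buffered, handle)
        for title, seq in SimpleFastaParser(chained):
            rec_id, desc = _split_title(title)
            yield SequenceRecord(id=rec_id, seq=seq.upper(), description=desc)


def read_fastq(path: str | PathLike) -> Iterator[SequenceRecord]:
    """Stream records from a (possibly gzipped) FASTQ file."""
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                rec_id, desc = _split_title(title)
                yield SequenceRecord(
                    id=rec_id, seq=seq.upper(), description=desc, qual=qual
                )
        except ValueError as exc:  # truncated / malformed 4-line record
            raise FormatError(f"{path}: {exc}") from exc


def read_fastq_pairs(
    path1: str | PathLike, path2: Optional[str | PathLike] = None
) -> Iterator[ReadPair]:
    """Stream synchronized read pairs from one or two FASTQ files.

    With a single file, yields single-end pairs (``r2 is None``).  With two
    files, the streams are zipped record-by-record; a record-count mismatch
    raises :class:`PairingError`.
    """
    if path2 is None:
        for rec in read_fastq(path1):
            yield ReadPair(r1=rec)
        return
    it1 = read_fastq(path1)
    it2 = read_fastq(path2)
    sentinel = object()
    n = 0
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            short = path2 if r2 is sentinel else path1
            raise PairingError(
                f"mate files out of sync: {short} ended after {n} records "
                f"while its mate continues"
            )
        yield ReadPair(r1=r1, r2=r2)
        n += 1


def write_fasta(
    records: Iterable[SequenceRecord], path: str | PathLike, wrap: int = 60
) -> int:
    """Write records as wrapped FASTA; returns the number written.

    Round-trip stable with :func:`read_fasta` for (id, seq).
    """
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    n = 0
    with _open_out(path) as out:
        for rec in records:
            header = f"{rec.id} {rec.description}".rstrip()
            out.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                out.write(rec.seq[i : i + wrap])
                out.write("\n")
            n += 1
    return n


def write_fastq(records: Iterable[SequenceRecord], path: str | PathLike) -> int:
    """Write 4-line FASTQ records; constant 'I' quality if a record has none."""
    n = 0
    with _open_out(path) as out:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            header = f"{rec.id} {rec.description}".rstrip()
            out.write(f"@{header}\n{rec.seq}\n+\n{qual}\n")
            n += 1
    return n
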