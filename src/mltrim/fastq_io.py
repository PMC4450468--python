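"""Streaming FASTQ input/output with transparent gzip and phred decoding.

Only the 4-line FASTQ dialect is supported (one record = header, sequence,
'+' separator, quality string); wrapped multi-line records are rejected with
a clear error.  gzip compression is detected from the file's magic bytes, so
renamed files behave correctly.  Quality strings are decoded with a phred
offset of 33 (Sanger / Illumina 1.8+) by default, or 64 for legacy Illumina
data.  Readers stream: memory use is constant in the file size.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import numpy as np

from .segmentation import Read

GZIP_MAGIC = b"\x1f\x8b"

PathLike = Union[str, Path]


@dataclass
class FastqRecord:
    """One raw FASTQ record; quality kept as the original ASCII string."""

    id: str
    sequence: str
    plus: str
    quality_string: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality_string):
            raise FastqFormatError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality_string)}"
            )


@dataclass(frozen=True)
class PhredEncoding:
    """Phred ASCII offset: 33 (Sanger/modern Illumina) or 64 (legacy)."""

    offset: int = 33

    def __post_init__(self) -> None:
        if self.offset not in (33, 64):
            raise ValueError(f"phred offset must be 33 or 64, got {self.offset}")

    def decode(self, quality_string: str, record_id: str = "") -> np.ndarray:
        scores = np.frombuffer(
            quality_string.encode("ascii"), dtype=np.uint8
        ).astype(np.int64) - self.offset
        if scores.size and scores.min() < 0:
            other = 97 - self.offset
            raise FastqFormatError(
                f"record {record_id!r}: quality character below offset "
                f"{self.offset}; the file may use phred offset {other}"
            )
        return scores

    def encode(self, qualities: np.ndarray) -> str:
        scores = np.asarray(qualities, dtype=np.int64) + self.offset
        return scores.astype(np.uint8).tobytes().decode("ascii")


class FastqFormatError(ValueError):
    """Malformed FASTQ input (truncation, length mismatch, bad encoding)."""


def _open_text_auto(path: PathLike) -> IO[str]:
    """Open plain or gzipped text for reading, sniffing the gzip magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw, mode="rb"))
    return io.TextIOWrapper(raw)


def iter_records(path: PathLike) -> Iterator[FastqRecord]:
    """Yield raw FASTQ records from a plain or gzip-compressed file."""
    with _open_text_auto(path) as handle:
        index = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lines = [header, handle.readline(), handle.readline(), handle.readline()]
            if not lines[3]:
                raise FastqFormatError(
                    f"{path}: truncated record at index {index} (EOF mid-record)"
                )
            header, seq, plus, qual = (line.rstrip("\n") for line in lines)
            if not header.startswith("@"):
                raise FastqFormatError(
                    f"{path}: record {index} header does not start with '@' "
                    f"(multi-line FASTQ is not supported)"
                )
            if not plus.startswith("+"):
                raise FastqFormatError(
                    f"{path}: record {index} separator line does not start with "
                    f"'+' (multi-line FASTQ is not supported)"
                )
            yield FastqRecord(
                id=header[1:], sequence=seq, plus=plus[1:], quality_string=qual
            )
            index += 1


def read_fastq(
    path: PathLike, encoding: PhredEncoding = PhredEncoding(33)
) -> Iterator[tuple[FastqRecord, Read]]:
    """Stream (raw record, decoded read) pairs in file order."""
    for record in iter_records(path):
        read = Read(
            id=record.id,
            sequence=record.sequence,
            qualities=encoding.decode(record.quality_string, record.id),
        )
        yield record, read


def write_fastq(
    records: Iterable[FastqRecord], path: PathLike, gzip_output: bool = False
) -> int:
    """Write records as 4-line FASTQ; the '+' line is written bare.

    Returns the number of records written.
    """
    opener = gzip.open if gzip_output else open
    n = 0
    with opener(path, "wt") as handle:
        for record in records:
            handle.write(f"@{record.id}\n{record.sequence}\n+\n{record.quality_string}\n")
            n += 1
    return n


def paired_stream(
    path1: PathLike,
    path2: PathLike,
    encoding: PhredEncoding = PhredEncoding(33),
) -> Iterator[tuple[tuple[FastqRecord, Read], tuple[FastqRecord, Read]]]:
    """Iterate two FASTQ files in lockstep, pairing records by position.

    Identifiers are not required to match (no /1 and /2 parsing); an unequal
    record count raises at the first missing index.
    """
    it1 = read_fastq(path1, encoding)
    it2 = read_fastq(path2, encoding)
    index = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = path1 if r1 is None else path2
            raise FastqFormatError(
                f"paired files out of sync: {short} has no record at index {index}"
            )
        yield r1, r2
        index += 1
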