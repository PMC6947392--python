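"""FASTQ records and gzip-transparent reading/writing."""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO

PHRED_OFFSET = 33


class FastqParseError(ValueError):
    """Malformed FASTQ input; message names the offending record."""


@dataclass(frozen=True)
class FastqRecord:
    """A single read: id, sequence and Phred qualities (Sanger offset 33)."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FastqParseError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if self.qualities else 0.0

    @property
    def quality_string(self) -> str:
        return "".join(chr(q + PHRED_OFFSET) for q in self.qualities)


def _open(path: str | Path, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")  # type: ignore[return-value]
    return open(path, mode)


def read_fastq(path: str | Path) -> list[FastqRecord]:
    """Parse a FASTQ file (gzipped if the name ends in .gz)."""
    records: list[FastqRecord] = []
    with _open(path, "r") as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
                quals = tuple(rec.letter_annotations["phred_quality"])
                records.append(FastqRecord(rec.id, str(rec.seq), quals))
        except ValueError as exc:
            raise FastqParseError(
                f"{path}: malformed FASTQ near record {len(records) + 1}: {exc}"
            ) from exc
    return records


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> int:
    """Write 4-line FASTQ (gzipped if the name ends in .gz); returns count."""
    n = 0
    with _open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality_string}\n")
            n += 1
    return n


def iter_fastq(path: str | Path) -> Iterator[FastqRecord]:
    yield from read_fastq(path)
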