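"""Genomics file I/O and coordinate conventions.

All coordinates in the package are 0-based half-open (BED-native); FASTA
sequences are uppercased at load so downstream code sees one alphabet.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "Genome",
    "CagePeak",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "write_samples_tsv",
    "read_samples_tsv",
]

SAMPLES_TSV_HEADER = ("chrom", "start", "end", "label", "sequence")


class FastaParseError(ValueError):
    pass


class BedParseError(ValueError):
    pass


@dataclass
class Genome:
    """An in-memory genome: ordered chromosome names and their sequences.

    Sequences are uppercase strings over {A, C, G, T, N}.  ``extract``
    returns exactly ``end - start`` characters.
    """

    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def extract(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if not (0 <= start < end <= len(seq)):
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start:end]


@dataclass(frozen=True)
class CagePeak:
    """A CAGE peak (or any genomic interval), 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")


def read_fasta(path: str | os.PathLike) -> Genome:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Headers are parsed up to the first whitespace and must be unique.
    Soft-masked lowercase bases are uppercased, never filtered.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first "
                    f"'>' header"
                )
            break
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FastaParseError(
                f"{path}: duplicate FASTA header {record.id!r}"
            )
        sequences[record.id] = str(record.seq).upper()
    return Genome(sequences=sequences)


def write_fasta(path: str | os.PathLike, genome: Genome, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | os.PathLike) -> list[CagePeak]:
    """Read BED3/BED6 intervals in file order (0-based half-open)."""
    peaks: list[CagePeak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise BedParseError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 else "."
            peaks.append(CagePeak(chrom, start, end, name, strand))
    return peaks


def write_bed(path: str | os.PathLike, peaks: Iterable[CagePeak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name or '.'}\t0\t{p.strand}\n")


def write_samples_tsv(path: str | os.PathLike, samples: Sequence) -> None:
    """Write labelled samples as TSV (header: chrom start end label sequence).

    All samples must share one window length and carry labels in {0, 1}.
    """
    lengths = {len(s.sequence) for s in samples}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    for s in samples:
        if s.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {s.label!r}")
    with open(path, "w") as fh:
        fh.write("\t".join(SAMPLES_TSV_HEADER) + "\n")
        for s in samples:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.label}\t{s.sequence}\n")


def read_samples_tsv(path: str | os.PathLike) -> list:
    from .dataset_builder import LabeledSample

    samples: list[LabeledSample] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SAMPLES_TSV_HEADER:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            chrom, start, end, label, seq = line.rstrip("\n").split("\t")
            samples.append(
                LabeledSample(chrom, int(start), int(end), int(label), seq)
            )
    return samples
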