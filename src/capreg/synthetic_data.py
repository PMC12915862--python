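"""Seeded synthetic genomes with implanted capping motifs.

The generator emulates FANTOM5-style inputs at desk scale: an i.i.d.
random genome, CAGE-like peaks placed along each chromosome, and a known
octamer written into the sequence near each peak start, so that every
pipeline stage — dataset construction, training, attention-based motif
recovery — can be exercised against a known ground truth with no
downloads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .genome_io import CagePeak, Genome, write_bed, write_fasta

__all__ = [
    "SimConfig",
    "SimTruth",
    "TruthRecord",
    "generate_genome",
    "implant_peaks",
    "make_benchmark",
]

#: TTTTTATT is one of the discriminative capping-region octamers recovered
#: from attention peaks at full scale; implanting it makes recovery testable.
DEFAULT_MOTIF = "TTTTTATT"


@dataclass
class SimConfig:
    """Synthetic benchmark parameters (desk scale by default).

    Peaks are placed at least ``min_spacing`` apart and at least 20 kb from
    the chromosome start so every peak has a full upstream negative band.
    Spacings below 20 kb + window mean negative windows may fall near
    *other* peaks; the dataset builder's overlap filter keeps them clean of
    implants (implants lie strictly inside positive windows).
    """

    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_peaks: int = 250  # per chromosome
    min_spacing: int = 600
    peak_width: int = 1
    motif: str = DEFAULT_MOTIF
    jitter: int = 20  # implant start is peak start + U(-jitter, jitter)
    implant_prob: float = 1.0
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    context_window: int = 128
    seed: int = 0

    def __post_init__(self):
        if len(self.motif) != 8 or set(self.motif) - set("ACGT"):
            raise ValueError("motif must be an 8-mer over ACGT")
        if not 1 <= self.peak_width <= 50:
            raise ValueError("peak_width must be in 1..50")
        if self.jitter >= self.context_window // 2 - len(self.motif):
            raise ValueError(
                "jitter too large: implant could leave the positive window"
            )
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    peak_start: int
    motif_start: int | None  # None when the implant coin-flip failed


@dataclass
class SimTruth:
    records: list[TruthRecord] = field(default_factory=list)

    def for_chrom(self, chrom: str) -> list[TruthRecord]:
        return [r for r in self.records if r.chrom == chrom]


def generate_genome(config: SimConfig) -> Genome:
    """An i.i.d. random genome at the configured base composition."""
    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    sequences = {}
    for c in range(config.n_chromosomes):
        draw = rng.choice(4, size=config.chrom_length, p=list(config.composition))
        sequences[f"chr{c + 1}"] = "".join(bases[draw])
    return Genome(sequences=sequences)


#: upstream room required so the first peak keeps a full negative band
_UPSTREAM_MARGIN = 20_000


def implant_peaks(
    genome: Genome, config: SimConfig
) -> tuple[Genome, list[CagePeak], SimTruth]:
    """Place peaks, write the motif near each peak start, record the truth.

    Peak starts are spaced >= min_spacing apart (uniform slack within each
    stride keeps placement irregular) and >= 20 kb from the chromosome
    start.  The motif is written at peak start + U(-jitter, +jitter) with
    probability ``implant_prob``; BED records are ``peak_width`` wide.
    """
    rng = np.random.default_rng(config.seed + 1)
    w = config.context_window
    peaks: list[CagePeak] = []
    truth = SimTruth()
    new_sequences: dict[str, str] = {}
    for chrom in genome.chrom_names:
        length = genome.length(chrom)
        span = length - _UPSTREAM_MARGIN - w
        step = span // config.n_peaks
        if step < config.min_spacing:
            raise ValueError(
                f"cannot place {config.n_peaks} peaks {config.min_spacing} nt "
                f"apart on a {length} nt chromosome"
            )
        seq = list(genome.sequences[chrom])
        slack = step - config.min_spacing
        for i in range(config.n_peaks):
            start = _UPSTREAM_MARGIN + i * step + int(rng.integers(0, slack + 1))
            peaks.append(
                CagePeak(chrom, start, start + config.peak_width, f"peak_{chrom}_{i}")
            )
            motif_start: int | None = None
            if rng.random() < config.implant_prob:
                motif_start = start + int(rng.integers(-config.jitter, config.jitter + 1))
                seq[motif_start : motif_start + len(config.motif)] = config.motif
            truth.records.append(TruthRecord(chrom, start, motif_start))
        new_sequences[chrom] = "".join(seq)
    return Genome(sequences=new_sequences), peaks, truth


def make_benchmark(
    config: SimConfig, out_dir: str | os.PathLike
) -> tuple[str, str, str]:
    """Write FASTA + BED + truth TSV consumable by the dataset builder."""
    os.makedirs(out_dir, exist_ok=True)
    genome, peaks, truth = implant_peaks(generate_genome(config), config)
    fasta_path = os.path.join(out_dir, "genome.fasta")
    bed_path = os.path.join(out_dir, "peaks.bed")
    truth_path = os.path.join(out_dir, "truth.tsv")
    write_fasta(fasta_path, genome)
    write_bed(bed_path, peaks)
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpeak_start\tmotif_start\n")
        for r in truth.records:
            ms = "" if r.motif_start is None else str(r.motif_start)
            fh.write(f"{r.chrom}\t{r.peak_start}\t{ms}\n")
    return fasta_path, bed_path, truth_path
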