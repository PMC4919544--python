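"""Alignment and read record types plus their plain-text I/O dialects.

Alignments travel as 6-column BED (chrom, start, end, name, mapq, strand)
with up to two extra tagged columns (``species=...``, ``barcode=...``).
FASTQ is standard 4-line.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List, Optional

SPECIES_LABELS = ("target", "reference", "orthologous")


@dataclass(frozen=True)
class AlignmentRecord:
    """A single-end alignment in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 60
    read_id: str = ""
    species: Optional[str] = None
    barcode: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"record {self.read_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"record {self.read_id!r}: invalid strand {self.strand!r}")
        if self.mapq < 0:
            raise ValueError(f"record {self.read_id!r}: negative mapq {self.mapq}")
        if self.species is not None and self.species not in SPECIES_LABELS:
            raise ValueError(f"record {self.read_id!r}: unknown species {self.species!r}")
        if self.barcode is not None and len(self.barcode) != 6:
            raise ValueError(f"record {self.read_id!r}: barcode must be 6 bp")

    @property
    def five_prime(self) -> int:
        """5' alignment coordinate: start for +, end-1 for - strand."""
        return self.start if self.strand == "+" else self.end - 1

    def with_barcode(self, barcode: str) -> "AlignmentRecord":
        return replace(self, barcode=barcode)


@dataclass(frozen=True)
class FastqRead:
    """A raw FASTQ read (id line without the leading '@')."""

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.read_id!r}: sequence/quality length mismatch")


# --------------------------------------------------------------------- BED I/O


def write_alignments(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [r.chrom, str(r.start), str(r.end), r.read_id, str(r.mapq), r.strand]
            if r.species is not None:
                cols.append(f"species={r.species}")
            if r.barcode is not None:
                cols.append(f"barcode={r.barcode}")
            fh.write("\t".join(cols) + "\n")


def read_alignments(path: str | Path) -> List[AlignmentRecord]:
    out: List[AlignmentRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            species = barcode = None
            for extra in cols[6:]:
                key, _, val = extra.partition("=")
                if key == "species":
                    species = val
                elif key == "barcode":
                    barcode = val
                else:
                    raise ValueError(f"unknown extra column {extra!r}")
            out.append(
                AlignmentRecord(
                    chrom=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    read_id=cols[3],
                    mapq=int(cols[4]),
                    strand=cols[5],
                    species=species,
                    barcode=barcode,
                )
            )
    return out


# ------------------------------------------------------------------- FASTQ I/O


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> List[FastqRead]:
    """Parse FASTQ via Biopython, preserving full id lines (incl. barcodes)."""
    from Bio import SeqIO

    out: List[FastqRead] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(FastqRead(read_id=rec.description, sequence=str(rec.seq), quality=qual))
    return out
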