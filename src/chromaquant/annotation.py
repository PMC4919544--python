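"""Gene annotation model: intervals with strand, derived TSS and rate classes.

Coordinates are 0-based, half-open everywhere ([start, end)); the TSS of a
plus-strand gene is ``start`` and of a minus-strand gene is ``end - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence

import pandas as pd

#: Transcription-rate classes (mRNA/h), low to high.
RATE_CLASSES = ("<1", "1-3.9", "4-15.9", "16-50", ">50")

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class Gene:
    """A gene interval on a chromosome.

    Parameters
    ----------
    gene_id
        Unique identifier.
    chrom
        Chromosome name.
    start, end
        0-based half-open interval; ``start < end``.
    strand
        ``"+"`` or ``"-"``.
    rate_class
        Optional transcription-rate class, one of :data:`RATE_CLASSES`.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rate_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"gene {self.gene_id}: negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.rate_class is not None and self.rate_class not in RATE_CLASSES:
            raise ValueError(
                f"gene {self.gene_id}: unknown rate class {self.rate_class!r}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (0-based base coordinate)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


class GeneAnnotation:
    """An ordered collection of unique genes, optionally with chromosome sizes."""

    def __init__(
        self,
        genes: Sequence[Gene],
        chrom_sizes: Optional[Dict[str, int]] = None,
    ) -> None:
        self.genes: List[Gene] = list(genes)
        self._by_id = {g.gene_id: g for g in self.genes}
        if len(self._by_id) != len(self.genes):
            seen: set = set()
            for g in self.genes:
                if g.gene_id in seen:
                    raise ValueError(f"duplicate gene_id {g.gene_id!r}")
                seen.add(g.gene_id)
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes is not None else None
        if self.chrom_sizes is not None:
            for g in self.genes:
                size = self.chrom_sizes.get(g.chrom)
                if size is None:
                    raise ValueError(f"gene {g.gene_id}: chromosome {g.chrom} not in sizes")
                if g.end > size:
                    raise ValueError(
                        f"gene {g.gene_id}: end {g.end} beyond chromosome size {size}"
                    )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    def genes_on(self, chrom: str) -> List[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def rate_class_map(self) -> Dict[str, str]:
        """gene_id -> rate_class for every gene that has one."""
        return {g.gene_id: g.rate_class for g in self.genes if g.rate_class is not None}

    # ------------------------------------------------------------------ I/O

    def to_bed(self, path: str | Path, sidecar: Optional[str | Path] = None) -> None:
        """Write 6-column BED; rate classes go to a TSV ``sidecar`` if given."""
        df = pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "name": [g.gene_id for g in self.genes],
                "score": 0,
                "strand": [g.strand for g in self.genes],
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False)
        if sidecar is not None:
            rc = pd.DataFrame(
                [(g.gene_id, g.rate_class) for g in self.genes if g.rate_class],
                columns=["gene_id", "rate_class"],
            )
            rc.to_csv(sidecar, sep="\t", index=False)

    @classmethod
    def from_bed(
        cls,
        path: str | Path,
        sidecar: Optional[str | Path] = None,
        chrom_sizes: Optional[Dict[str, int]] = None,
    ) -> "GeneAnnotation":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "name": str, "strand": str},
        )
        rates: Dict[str, str] = {}
        if sidecar is not None:
            rc = pd.read_csv(sidecar, sep="\t", dtype=str)
            rates = dict(zip(rc["gene_id"], rc["rate_class"]))
        genes = [
            Gene(
                gene_id=row.name_,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                rate_class=rates.get(row.name_),
            )
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
        ]
        return cls(genes, chrom_sizes=chrom_sizes)


def read_chrom_sizes(path: str | Path) -> Dict[str, int]:
    """Read a two-column (chrom, size) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: Dict[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(sizes.items())).to_csv(path, sep="\t", header=False, index=False)
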