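"""Coverage tracks, difference maps and TSS-relative window matrices.

Reads are extended to a fixed fragment length and piled into per-base (or
binned) coverage, normalized to reads per million, and mapped onto
strand-oriented windows around gene TSSs (default 20 bp windows spanning
-800..+800), with windows overlapping neighbouring genes masked out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from chromaquant.annotation import Gene, GeneAnnotation
from chromaquant.records import AlignmentRecord


# ----------------------------------------------------------------- basic types


@dataclass
class WindowSpec:
    """Geometry of TSS-relative windows: ``n_windows = 2*span/width``."""

    span: int = 800
    width: int = 20

    def __post_init__(self) -> None:
        if self.span <= 0 or self.width <= 0:
            raise ValueError("span and width must be positive")
        if self.span % self.width != 0:
            raise ValueError(f"span {self.span} not divisible by width {self.width}")

    @property
    def n_windows(self) -> int:
        return 2 * self.span // self.width

    def midpoints(self) -> np.ndarray:
        """Signed window midpoints relative to the TSS (gene orientation)."""
        return np.arange(self.n_windows) * self.width - self.span + self.width // 2


@dataclass
class CoverageTrack:
    """Per-base or binned numeric signal across chromosomes.

    ``values[chrom][i]`` is the mean per-base signal in bin ``i`` (bin_size 1
    means per-base). ``normalization`` tracks provenance: raw read piles,
    reads-per-million, calibrated (spike-in scaled), or derived tracks.
    """

    values: Dict[str, np.ndarray]
    chrom_sizes: Dict[str, int]
    bin_size: int = 1
    normalization: str = "raw"
    total_reads: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, arr in self.values.items():
            expect = math.ceil(self.chrom_sizes[chrom] / self.bin_size)
            if len(arr) != expect:
                raise ValueError(
                    f"{chrom}: expected {expect} bins for size "
                    f"{self.chrom_sizes[chrom]}, got {len(arr)}"
                )

    def same_bins(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
            and set(self.values) == set(other.values)
        )

    def base_values(self, chrom: str) -> np.ndarray:
        """Per-base expansion of a chromosome's signal."""
        arr = self.values[chrom]
        if self.bin_size == 1:
            return arr
        return np.repeat(arr, self.bin_size)[: self.chrom_sizes[chrom]]

    def scaled(self, factor: float, normalization: Optional[str] = None) -> "CoverageTrack":
        return CoverageTrack(
            values={c: v * factor for c, v in self.values.items()},
            chrom_sizes=dict(self.chrom_sizes),
            bin_size=self.bin_size,
            normalization=normalization or self.normalization,
            total_reads=self.total_reads,
        )

    def flat(self) -> np.ndarray:
        """All bin values concatenated in sorted chromosome order."""
        return np.concatenate([self.values[c] for c in sorted(self.values)])

    # -------------------------------------------------------------- bedGraph

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# normalization={self.normalization} bin_size={self.bin_size}\n")
            for chrom in sorted(self.values):
                arr = self.values[chrom]
                size = self.chrom_sizes[chrom]
                # run-length encode identical neighbouring bins
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(arr)]))
                for s, e in zip(starts, ends):
                    fh.write(
                        f"{chrom}\t{s * self.bin_size}\t{min(e * self.bin_size, size)}"
                        f"\t{arr[s]:.10g}\n"
                    )

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        chrom_sizes: Dict[str, int],
        bin_size: int = 1,
        normalization: str = "raw",
        total_reads: int = 0,
    ) -> "CoverageTrack":
        values = {
            c: np.zeros(math.ceil(size / bin_size)) for c, size in chrom_sizes.items()
        }
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        for row in df.itertuples(index=False):
            if row.start % bin_size:
                raise ValueError(f"interval start {row.start} not on bin grid")
            values[row.chrom][row.start // bin_size : math.ceil(row.end / bin_size)] = row.value
        return cls(values, dict(chrom_sizes), bin_size, normalization, total_reads)


@dataclass
class TSSMatrix:
    """Genes x windows signal matrix, strand-oriented (window 0 = most upstream).

    Masked cells (neighbour overlap or chromosome edge) hold NaN in ``values``
    and True in ``mask``.
    """

    gene_ids: List[str]
    values: np.ndarray
    mask: np.ndarray
    window_spec: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        n = self.window_spec.n_windows
        if self.values.shape != (len(self.gene_ids), n):
            raise ValueError(f"values shape {self.values.shape} != ({len(self.gene_ids)}, {n})")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._index[gene_id]]

    def row_mask(self, gene_id: str) -> np.ndarray:
        return self.mask[self._index[gene_id]]

    def congruent(self, other: "TSSMatrix") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.window_spec == other.window_spec
            and bool(np.array_equal(self.mask, other.mask))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.window_spec.midpoints()
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", na_rep="NA")


# ------------------------------------------------------------------ operations


def mapq_filter(
    records: Sequence[AlignmentRecord], min_mapq: int = 13
) -> List[AlignmentRecord]:
    """Keep records with ``mapq >= min_mapq`` (order preserved)."""
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    return [r for r in records if r.mapq >= min_mapq]


def extend_and_pile(
    records: Sequence[AlignmentRecord],
    chrom_sizes: Dict[str, int],
    extension: int = 148,
    bin_size: int = 1,
) -> CoverageTrack:
    """Extend reads to ``extension`` bp and pile into (binned) coverage.

    Plus-strand reads extend rightward from their start; minus-strand reads
    extend leftward from their alignment end. Extended fragments are clipped
    at chromosome edges; coverage is the count of fragments overlapping each
    base, averaged within bins.
    """
    if extension < 1:
        raise ValueError("extension must be >= 1")
    diffs = {c: np.zeros(size + 1) for c, size in chrom_sizes.items()}
    for r in records:
        size = chrom_sizes.get(r.chrom)
        if size is None:
            raise ValueError(f"record {r.read_id!r}: unknown chromosome {r.chrom!r}")
        if r.start < 0 or r.end > size:
            raise ValueError(
                f"record {r.read_id!r}: interval [{r.start}, {r.end}) outside "
                f"{r.chrom} (size {size})"
            )
        if r.strand == "+":
            s, e = r.start, r.start + extension
        else:
            s, e = r.end - extension, r.end
        s, e = max(s, 0), min(e, size)
        diffs[r.chrom][s] += 1.0
        diffs[r.chrom][e] -= 1.0
    values: Dict[str, np.ndarray] = {}
    for chrom, diff in diffs.items():
        base = np.cumsum(diff[:-1])
        values[chrom] = _bin_mean(base, bin_size)
    return CoverageTrack(
        values=values,
        chrom_sizes=dict(chrom_sizes),
        bin_size=bin_size,
        normalization="raw",
        total_reads=len(records),
    )


def _bin_mean(base: np.ndarray, bin_size: int) -> np.ndarray:
    if bin_size == 1:
        return base
    edges = np.arange(0, len(base), bin_size)
    sums = np.add.reduceat(base, edges)
    widths = np.minimum(edges + bin_size, len(base)) - edges
    return sums / widths


def rpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Scale to reads per million mapped reads."""
    if track.total_reads <= 0:
        raise ValueError("cannot RPM-normalize a track with total_reads == 0")
    return track.scaled(1e6 / track.total_reads, normalization="rpm")


def difference_track(mutant: CoverageTrack, wt: CoverageTrack) -> CoverageTrack:
    """Signed per-bin difference mutant - WT (both depth-normalized alike)."""
    if not mutant.same_bins(wt):
        raise ValueError("difference_track: tracks have mismatched bins")
    if mutant.normalization != wt.normalization or mutant.normalization == "raw":
        raise ValueError(
            "difference_track requires both tracks normalized the same way "
            f"(got {mutant.normalization!r} vs {wt.normalization!r})"
        )
    return CoverageTrack(
        values={c: mutant.values[c] - wt.values[c] for c in mutant.values},
        chrom_sizes=dict(mutant.chrom_sizes),
        bin_size=mutant.bin_size,
        normalization="difference",
        total_reads=0,
    )


def replicate_pearson(track_a: CoverageTrack, track_b: CoverageTrack) -> float:
    """Pearson correlation between two tracks over all bins."""
    if not track_a.same_bins(track_b):
        raise ValueError("replicate_pearson: tracks have mismatched bins")
    a, b = track_a.flat(), track_b.flat()
    if len(a) < 2:
        raise ValueError("need at least 2 bins")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson r undefined: zero variance track")
    return float(np.corrcoef(a, b)[0, 1])


# ----------------------------------------------------- TSS window construction


def window_bounds(tss: int, strand: str, spec: WindowSpec) -> List[Tuple[int, int]]:
    """Genomic [start, end) of each window, ordered upstream -> downstream.

    Window 0 is the most upstream window in gene orientation for either
    strand, so a minus-strand gene's windows run right-to-left genomically.
    """
    w, span, n = spec.width, spec.span, spec.n_windows
    if strand == "+":
        return [(tss - span + i * w, tss - span + (i + 1) * w) for i in range(n)]
    return [(tss + span - (i + 1) * w + 1, tss + span - i * w + 1) for i in range(n)]


def window_index(pos: int, tss: int, strand: str, spec: WindowSpec) -> Optional[int]:
    """Window index containing base ``pos``, or None if outside the span."""
    rel = pos - tss if strand == "+" else tss - pos
    if rel < -spec.span or rel >= spec.span:
        return None
    return (rel + spec.span) // spec.width


def neighbour_mask(annotation: GeneAnnotation, spec: WindowSpec) -> np.ndarray:
    """Boolean (genes x windows) mask: True where a window must be excluded.

    A window is masked when it falls (partly) outside the chromosome or
    overlaps any base of a different gene's body.
    """
    if annotation.chrom_sizes is None:
        raise ValueError("annotation must carry chromosome sizes")
    n = spec.n_windows
    mask = np.zeros((len(annotation), n), dtype=bool)
    by_chrom: Dict[str, List[Gene]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    for gi, g in enumerate(annotation):
        size = annotation.chrom_sizes[g.chrom]
        others = [o for o in by_chrom[g.chrom] if o.gene_id != g.gene_id]
        starts = np.array([o.start for o in others])
        ends = np.array([o.end for o in others])
        for wi, (ws, we) in enumerate(window_bounds(g.tss, g.strand, spec)):
            if ws < 0 or we > size:
                mask[gi, wi] = True
            elif len(others) and bool(np.any((starts < we) & (ends > ws))):
                mask[gi, wi] = True
    return mask


def tss_window_matrix(
    track: CoverageTrack,
    annotation: GeneAnnotation,
    window_spec: Optional[WindowSpec] = None,
) -> TSSMatrix:
    """Mean coverage per TSS-relative window for every gene.

    Window 0 is most-upstream regardless of strand; windows overlapping a
    neighbouring gene body or the chromosome edge are masked (NaN).
    """
    spec = window_spec or WindowSpec()
    if track.bin_size != 1 and spec.width % track.bin_size != 0:
        raise ValueError(
            f"track bin_size {track.bin_size} does not divide window width {spec.width}"
        )
    mask = neighbour_mask(annotation, spec)
    values = np.full((len(annotation), spec.n_windows), np.nan)
    base_cache: Dict[str, np.ndarray] = {}
    for gi, g in enumerate(annotation):
        if g.chrom not in base_cache:
            base_cache[g.chrom] = track.base_values(g.chrom)
        base = base_cache[g.chrom]
        for wi, (ws, we) in enumerate(window_bounds(g.tss, g.strand, spec)):
            if not mask[gi, wi]:
                values[gi, wi] = base[ws:we].mean()
    return TSSMatrix(
        gene_ids=annotation.gene_ids, values=values, mask=mask, window_spec=spec
    )


def mean_profile(matrix: TSSMatrix, gene_set: Iterable[str]) -> np.ndarray:
    """Per-window mean over a gene set, ignoring masked cells.

    A window with every cell masked yields NaN.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("mean_profile: empty gene set")
    rows = np.stack([matrix.row(g) for g in genes])
    with np.errstate(invalid="ignore"):
        out = np.full(rows.shape[1], np.nan)
        counts = np.sum(~np.isnan(rows), axis=0)
        sums = np.nansum(rows, axis=0)
        np.divide(sums, counts, out=out, where=counts > 0)
    return out
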