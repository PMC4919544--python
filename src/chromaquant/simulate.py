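"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline is exercised against data produced
here: a toy genome annotation, condition-specific mononucleosome fragments
with planted occupancy changes, two-species spike-in ChIP/input mixtures
with a known global scaling, dual-tag (new/old histone) barcoded reads with
planted duplicates, and stranded negative-binomial count matrices with
planted differentially expressed genes. All generators are deterministic
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from chromaquant.annotation import RATE_CLASSES, Gene, GeneAnnotation
from chromaquant.coverage import WindowSpec, window_bounds
from chromaquant.records import AlignmentRecord, FastqRead

NUCLEOSOME_BP = 148  # fragment length for MNase reads
CHIP_READ_BP = 50  # single-end ChIP/nexus read length


class CapacityError(ValueError):
    """Gene placement is infeasible for the requested genome parameters."""


@dataclass
class SyntheticTruth:
    """Planted ground truth shared by the generators.

    ``occupancy_fold`` maps gene_id -> per-window mutant/WT occupancy fold
    (vector of length ``window_spec.n_windows``; 1.0 = no change).
    ``global_scaling`` maps spike-in condition name -> true ChIP signal
    scale. ``new_fraction_regions`` are (chrom, start, end, f) intervals
    overriding the default new-histone fraction. ``de_log2fc`` maps
    (gene_id, strand_class) -> planted log2 fold change (mutant vs WT).
    """

    seed: int = 0
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    occupancy_fold: Dict[str, np.ndarray] = field(default_factory=dict)
    global_scaling: Dict[str, float] = field(default_factory=lambda: {"A": 1.0, "B": 1.0})
    input_mix_target: float = 2.0  # target:reference cell ratio in the input
    orthologous_fraction: float = 0.0
    reference_chrom: Tuple[str, int] = ("refchr1", 100_000)
    new_fraction_default: float = 0.5
    new_fraction_regions: List[Tuple[str, int, int, float]] = field(default_factory=list)
    de_log2fc: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, s in self.global_scaling.items():
            if s <= 0:
                raise ValueError(f"global scaling for {cond!r} must be > 0")
        if self.input_mix_target <= 0:
            raise ValueError("input mix ratio must be > 0")
        if not 0 <= self.orthologous_fraction < 1:
            raise ValueError("orthologous fraction must be in [0, 1)")
        if not 0 <= self.new_fraction_default <= 1:
            raise ValueError("new-histone fraction must be in [0, 1]")
        for chrom, start, end, f in self.new_fraction_regions:
            if start >= end:
                raise ValueError(f"empty region {chrom}:{start}-{end}")
            if not 0 <= f <= 1:
                raise ValueError(f"new-histone fraction {f} outside [0, 1]")
        for gid, profile in self.occupancy_fold.items():
            arr = np.asarray(profile, dtype=float)
            if arr.shape != (self.window_spec.n_windows,):
                raise ValueError(
                    f"occupancy fold profile for {gid} must have "
                    f"{self.window_spec.n_windows} windows"
                )
            if np.any(arr <= 0):
                raise ValueError(f"occupancy folds for {gid} must be positive")


# ------------------------------------------------------------------ toy genome


def make_toy_genome(
    n_genes: int,
    chrom_length: int = 200_000,
    min_gap: int = 2_000,
    seed: int = 0,
    chrom: str = "chrI",
    margin: int = 1_000,
) -> GeneAnnotation:
    """Place non-overlapping genes on one chromosome, both strands, rated.

    Consecutive genes are separated by at least ``min_gap`` bases and kept
    ``margin`` bases clear of the chromosome ends. Raises
    :class:`CapacityError` when the genes cannot fit.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    sizes = {chrom: chrom_length}
    if n_genes == 0:
        return GeneAnnotation([], chrom_sizes=sizes)
    rng = np.random.default_rng(seed)
    max_len = 2_000
    needed = margin * 2 + n_genes * max_len + (n_genes - 1) * min_gap
    if needed > chrom_length:
        raise CapacityError(
            f"cannot place {n_genes} genes (worst case {needed} bp) on a "
            f"{chrom_length} bp chromosome with min_gap={min_gap}"
        )
    lengths = rng.integers(500, max_len + 1, size=n_genes)
    slack = chrom_length - margin * 2 - int(lengths.sum()) - (n_genes - 1) * min_gap
    # spread the slack over the inter-gene gaps
    extra = rng.multinomial(slack, np.ones(n_genes) / n_genes) if slack > 0 else np.zeros(n_genes, dtype=int)
    strands = rng.choice(["+", "-"], size=n_genes)
    if n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "-" if strands[0] == "+" else "+"
    classes = rng.choice(RATE_CLASSES, size=n_genes)
    genes: List[Gene] = []
    pos = margin + int(extra[0] // 2)
    width = len(str(n_genes))
    for i in range(n_genes):
        start = pos
        end = start + int(lengths[i])
        genes.append(
            Gene(
                gene_id=f"g{i + 1:0{width}d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=str(strands[i]),
                rate_class=str(classes[i]),
            )
        )
        pos = end + min_gap + int(extra[i] // 2)
    if genes and genes[-1].end > chrom_length - margin:
        raise CapacityError("gene placement overflowed the chromosome")
    return GeneAnnotation(genes, chrom_sizes=sizes)


# ------------------------------------------------------------ MNase fragments


def _occupancy_weights(
    annotation: GeneAnnotation, truth: SyntheticTruth, condition: str
) -> Dict[str, np.ndarray]:
    """Per-base sampling weights; the mutant carries the planted folds."""
    if annotation.chrom_sizes is None:
        raise ValueError("annotation must carry chromosome sizes")
    weights = {c: np.ones(size) for c, size in annotation.chrom_sizes.items()}
    if condition == "mutant":
        for gid, profile in truth.occupancy_fold.items():
            g = annotation[gid]
            bounds = window_bounds(g.tss, g.strand, truth.window_spec)
            for fold, (ws, we) in zip(np.asarray(profile, dtype=float), bounds):
                lo, hi = max(ws, 0), min(we, len(weights[g.chrom]))
                if lo < hi:
                    weights[g.chrom][lo:hi] *= fold
    return weights


def simulate_mnase_fragments(
    annotation: GeneAnnotation,
    truth: SyntheticTruth,
    n_fragments: int,
    condition: str = "WT",
    seed: int = 0,
) -> List[AlignmentRecord]:
    """Draw 148 bp mononucleosome fragments with planted occupancy folds.

    Fragment dyads are sampled proportionally to the per-base occupancy
    weight so that extended-fragment coverage expectation tracks the
    planted profile; WT and mutant differ only by the planted folds.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    if condition not in ("WT", "mutant"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    weights = _occupancy_weights(annotation, truth, condition)
    half = NUCLEOSOME_BP // 2
    chroms = sorted(weights)
    concat = np.concatenate([weights[c] for c in chroms])
    offsets: Dict[str, int] = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        # forbid dyads whose fragment would clip at the chromosome edge
        concat[off : off + half] = 0.0
        size = annotation.chrom_sizes[c]
        concat[off + size - half : off + size] = 0.0
        off += size
    probs = concat / concat.sum()
    dyads = rng.choice(len(concat), size=n_fragments, p=probs)
    strands = rng.choice(["+", "-"], size=n_fragments)
    bounds = [(c, offsets[c], offsets[c] + annotation.chrom_sizes[c]) for c in chroms]
    records: List[AlignmentRecord] = []
    for i, (dyad, strand) in enumerate(zip(dyads, strands)):
        chrom = next(c for c, lo, hi in bounds if lo <= dyad < hi)
        local = int(dyad) - offsets[chrom]
        records.append(
            AlignmentRecord(
                chrom=chrom,
                start=local - half,
                end=local + half,
                strand=str(strand),
                mapq=60,
                read_id=f"mnase_{condition}_{i}",
                species="target",
            )
        )
    return records


# ------------------------------------------------------------- spike-in ChIP


def simulate_spikein_chip(
    annotation: GeneAnnotation,
    truth: SyntheticTruth,
    n_reads_chip: int,
    n_reads_input: int,
    condition: str = "A",
    seed: int = 0,
) -> Tuple[List[AlignmentRecord], List[AlignmentRecord]]:
    """Two-species ChIP and input read sets with a known true global scaling.

    The input mixes target and reference chromatin at the truth's cell
    ratio m; per-cell ChIP yield from the target genome scales with the
    condition's true factor s while the reference yield is constant, so the
    expected ChIP target-read share is m*s / (m*s + 1). Sequencing depth is
    fixed, which masks the global change from plain RPM coverage; a random
    ``orthologous_fraction`` of reads is relabelled orthologous.
    """
    if n_reads_chip <= 0 or n_reads_input <= 0:
        raise ValueError("read counts must be > 0")
    if condition not in truth.global_scaling:
        raise ValueError(f"condition {condition!r} has no global scaling in truth")
    if annotation.chrom_sizes is None:
        raise ValueError("annotation must carry chromosome sizes")
    rng = np.random.default_rng(seed)
    s = truth.global_scaling[condition]
    m = truth.input_mix_target
    p_chip = (m * s) / (m * s + 1.0)
    p_input = m / (m + 1.0)
    chip = _spikein_reads(annotation, truth, rng, n_reads_chip, p_chip, f"chip_{condition}")
    inp = _spikein_reads(annotation, truth, rng, n_reads_input, p_input, f"input_{condition}")
    return chip, inp


def _spikein_reads(
    annotation: GeneAnnotation,
    truth: SyntheticTruth,
    rng: np.random.Generator,
    n_reads: int,
    p_target: float,
    prefix: str,
) -> List[AlignmentRecord]:
    ref_chrom, ref_size = truth.reference_chrom
    target_chroms = sorted(annotation.chrom_sizes)
    target_sizes = np.array([annotation.chrom_sizes[c] for c in target_chroms], dtype=float)
    target_p = target_sizes / target_sizes.sum()
    is_target = rng.random(n_reads) < p_target
    is_orth = rng.random(n_reads) < truth.orthologous_fraction
    records: List[AlignmentRecord] = []
    for i in range(n_reads):
        if is_target[i]:
            chrom = target_chroms[int(rng.choice(len(target_chroms), p=target_p))]
            size = annotation.chrom_sizes[chrom]
            species = "target"
        else:
            chrom, size = ref_chrom, ref_size
            species = "reference"
        start = int(rng.integers(0, size - CHIP_READ_BP + 1))
        records.append(
            AlignmentRecord(
                chrom=chrom,
                start=start,
                end=start + CHIP_READ_BP,
                strand="+" if rng.random() < 0.5 else "-",
                mapq=60,
                read_id=f"{prefix}_{i}",
                species="orthologous" if is_orth[i] else species,
            )
        )
    return records


# ------------------------------------------------------- RITE / nexus reads


@dataclass
class RiteReads:
    """Simulated dual-tag barcoded read set plus its ground truth.

    ``truth`` columns: read_id, tag (Flag/V5), chrom, start, end, strand,
    barcode, is_duplicate, dup_of (read_id of the copied original or "").
    """

    fastq: List[FastqRead]
    alignments: List[AlignmentRecord]
    truth: pd.DataFrame
    n_duplicates: int

    def alignments_by_tag(self) -> Tuple[List[AlignmentRecord], List[AlignmentRecord]]:
        tag_of = dict(zip(self.truth["read_id"], self.truth["tag"]))
        flag = [r for r in self.alignments if tag_of[r.read_id] == "Flag"]
        v5 = [r for r in self.alignments if tag_of[r.read_id] == "V5"]
        return flag, v5


def _new_fraction_at(truth: SyntheticTruth, chrom: str, pos: int) -> float:
    f = truth.new_fraction_default
    for rchrom, start, end, rf in truth.new_fraction_regions:
        if rchrom == chrom and start <= pos < end:
            f = rf
    return f


_BASES = np.array(list("ACGT"))


def simulate_rite_reads(
    annotation: GeneAnnotation,
    truth: SyntheticTruth,
    n_reads: int,
    dup_rate: float = 0.0,
    seed: int = 0,
    fixed_barcode: str = "CTGA",
) -> RiteReads:
    """Barcoded Flag/V5 reads with planted exact duplicates.

    Read positions are uniform over the target genome; each read's tag is
    Flag with the local planted new-histone fraction f (so the regional
    Flag:V5 count ratio has expectation f/(1-f)). A ``dup_rate`` fraction
    of reads are exact coordinate+barcode+tag copies of earlier reads,
    recorded in the truth table. Raw FASTQ sequences carry the 6 bp random
    plus 4 bp fixed barcode prefix.
    """
    from chromaquant.nexus import _check_fixed_spec

    _check_fixed_spec(fixed_barcode)
    if not 0 <= dup_rate < 1:
        raise ValueError("dup_rate must be in [0, 1)")
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if annotation.chrom_sizes is None:
        raise ValueError("annotation must carry chromosome sizes")
    rng = np.random.default_rng(seed)
    n_dup = int(round(n_reads * dup_rate))
    n_unique = n_reads - n_dup
    if n_unique < 1:
        raise ValueError("dup_rate leaves no unique reads")
    chroms = sorted(annotation.chrom_sizes)
    sizes = np.array([annotation.chrom_sizes[c] for c in chroms], dtype=float)
    chrom_p = sizes / sizes.sum()
    body_len = CHIP_READ_BP - 10

    seen: set = set()
    rows: List[dict] = []
    fastq: List[FastqRead] = []
    alignments: List[AlignmentRecord] = []
    width = len(str(n_reads))

    def emit(i: int, chrom: str, start: int, strand: str, barcode: str, tag: str,
             body: str, dup_of: str) -> None:
        read_id = f"rite_{i:0{width}d}"
        end = start + CHIP_READ_BP
        rows.append(
            {
                "read_id": read_id,
                "tag": tag,
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "barcode": barcode,
                "is_duplicate": bool(dup_of),
                "dup_of": dup_of,
            }
        )
        fastq.append(
            FastqRead(
                read_id=read_id,
                sequence=barcode + fixed_barcode + body,
                quality="I" * CHIP_READ_BP,
            )
        )
        alignments.append(
            AlignmentRecord(
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                mapq=60,
                read_id=read_id,
                barcode=barcode,
            )
        )

    uniques: List[Tuple[str, int, str, str, str, str]] = []
    for i in range(n_unique):
        while True:
            ci = int(rng.choice(len(chroms), p=chrom_p))
            chrom = chroms[ci]
            start = int(rng.integers(0, annotation.chrom_sizes[chrom] - CHIP_READ_BP + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            barcode = "".join(rng.choice(_BASES, size=6))
            five_prime = start if strand == "+" else start + CHIP_READ_BP - 1
            key = (chrom, strand, five_prime, barcode)
            if key not in seen:
                seen.add(key)
                break
        f = _new_fraction_at(truth, chrom, five_prime)
        tag = "Flag" if rng.random() < f else "V5"
        body = "".join(rng.choice(_BASES, size=body_len))
        uniques.append((chrom, start, strand, barcode, tag, body))
        emit(i, chrom, start, strand, barcode, tag, body, dup_of="")

    origins = rng.integers(0, n_unique, size=n_dup)
    for j, oi in enumerate(origins):
        chrom, start, strand, barcode, tag, body = uniques[int(oi)]
        emit(n_unique + j, chrom, start, strand, barcode, tag, body,
             dup_of=f"rite_{int(oi):0{width}d}")

    return RiteReads(
        fastq=fastq,
        alignments=alignments,
        truth=pd.DataFrame(rows),
        n_duplicates=n_dup,
    )


# --------------------------------------------------------- stranded NB counts


def simulate_stranded_counts(
    annotation: GeneAnnotation,
    truth: SyntheticTruth,
    n_replicates: int = 3,
    dispersion: float = 0.05,
    seed: int = 0,
) -> Dict[str, Dict[str, pd.DataFrame]]:
    """Negative-binomial sense/antisense count matrices for WT and mutant.

    Per-gene base means are drawn from the truth's own seed (so both
    conditions share them); planted genes get mutant mean * 2^log2fc. The
    NB parameterization is var = mu + dispersion * mu^2.

    Returns ``{"sense"|"antisense": {"wt"|"mut": genes x replicates frame}}``.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    mean_rng = np.random.default_rng(truth.seed)
    count_rng = np.random.default_rng(seed)
    genes = annotation.gene_ids
    base = {
        "sense": np.exp(mean_rng.normal(np.log(300.0), 0.8, size=len(genes))),
        "antisense": np.exp(mean_rng.normal(np.log(30.0), 0.8, size=len(genes))),
    }
    out: Dict[str, Dict[str, pd.DataFrame]] = {}
    size_param = 1.0 / dispersion
    for strand_class in ("sense", "antisense"):
        mu_wt = base[strand_class]
        lfc = np.array(
            [truth.de_log2fc.get((g, strand_class), 0.0) for g in genes]
        )
        mu_mut = mu_wt * np.power(2.0, lfc)
        frames: Dict[str, pd.DataFrame] = {}
        for cond, mu in (("wt", mu_wt), ("mut", mu_mut)):
            p = size_param / (size_param + mu)
            counts = count_rng.negative_binomial(
                size_param, p[:, None], size=(len(genes), n_replicates)
            )
            frames[cond] = pd.DataFrame(
                counts,
                index=genes,
                columns=[f"{cond}_{r + 1}" for r in range(n_replicates)],
            )
        out[strand_class] = frames
    return out
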