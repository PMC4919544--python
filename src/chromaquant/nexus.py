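"""ChIP-nexus read preprocessing and barcode-aware duplicate removal.

Raw nexus reads begin with a 6 bp random barcode followed by a 4 bp fixed
barcode; both are stripped before alignment and the random barcode is kept
in the read name. After alignment, reads sharing (chrom, strand, 5'
coordinate) AND an identical random barcode are collapsed to the best
alignment; distinct barcodes at the same coordinate all survive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from chromaquant.records import AlignmentRecord, FastqRead

RANDOM_BARCODE_LEN = 6
FIXED_BARCODE_LEN = 4
DEFAULT_FIXED_BARCODE = "CTGA"

_ACGT = set("ACGT")


@dataclass(frozen=True)
class NexusRead:
    """A barcode-stripped nexus read; the random barcode rides in the id."""

    read_id: str
    sequence: str
    quality: str
    random_barcode: str
    fixed_barcode: str

    def __post_init__(self) -> None:
        if len(self.random_barcode) != RANDOM_BARCODE_LEN:
            raise ValueError("random barcode must be 6 bp")
        if len(self.fixed_barcode) != FIXED_BARCODE_LEN:
            raise ValueError("fixed barcode must be 4 bp")


def _check_fixed_spec(expected_fixed: str) -> None:
    if len(expected_fixed) != FIXED_BARCODE_LEN or not set(expected_fixed) <= _ACGT:
        raise ValueError(
            f"fixed barcode spec must be a 4-mer over ACGT, got {expected_fixed!r}"
        )


def strip_barcodes(
    read: FastqRead, expected_fixed: str = DEFAULT_FIXED_BARCODE
) -> Tuple[Optional[NexusRead], Optional[str]]:
    """Strip the 10 bp barcode prefix from one read.

    Returns (NexusRead, None) on success or (None, reason) on rejection;
    reasons: ``too_short``, ``fixed_mismatch``, ``barcode_non_acgt``.
    """
    _check_fixed_spec(expected_fixed)
    prefix = RANDOM_BARCODE_LEN + FIXED_BARCODE_LEN
    if len(read.sequence) <= prefix:
        return None, "too_short"
    random_bc = read.sequence[:RANDOM_BARCODE_LEN]
    fixed_bc = read.sequence[RANDOM_BARCODE_LEN:prefix]
    if fixed_bc != expected_fixed:
        return None, "fixed_mismatch"
    if not set(random_bc) <= _ACGT:
        return None, "barcode_non_acgt"
    return (
        NexusRead(
            read_id=f"{read.read_id}:{random_bc}",
            sequence=read.sequence[prefix:],
            quality=read.quality[prefix:],
            random_barcode=random_bc,
            fixed_barcode=fixed_bc,
        ),
        None,
    )


def preprocess_fastq(
    reads: Iterable[FastqRead], expected_fixed: str = DEFAULT_FIXED_BARCODE
) -> Tuple[List[NexusRead], Counter]:
    """Strip barcodes from a read stream; returns kept reads + rejection tally."""
    _check_fixed_spec(expected_fixed)
    kept: List[NexusRead] = []
    rejections: Counter = Counter()
    for read in reads:
        stripped, reason = strip_barcodes(read, expected_fixed)
        if stripped is None:
            rejections[reason] += 1
        else:
            kept.append(stripped)
    return kept, rejections


def barcode_dedup(
    records: Sequence[AlignmentRecord],
) -> Tuple[List[AlignmentRecord], Dict[str, int]]:
    """Collapse identical-barcode duplicates at identical coordinates.

    Grouping key is (chrom, strand, 5' coordinate, barcode); within a group
    the best alignment survives (highest mapq, ties broken by
    lexicographically smallest read_id). Output preserves input order.

    Returns (survivors, report) where report counts inputs, survivors,
    removed reads, and groups that actually contained duplicates.
    """
    best: Dict[Tuple[str, str, int, str], AlignmentRecord] = {}
    group_sizes: Counter = Counter()
    for r in records:
        if r.barcode is None:
            raise ValueError(f"record {r.read_id!r} is missing its random barcode")
        key = (r.chrom, r.strand, r.five_prime, r.barcode)
        group_sizes[key] += 1
        cur = best.get(key)
        if cur is None or (-r.mapq, r.read_id) < (-cur.mapq, cur.read_id):
            best[key] = r
    survivor_ids = {r.read_id for r in best.values()}
    survivors = [r for r in records if r.read_id in survivor_ids]
    report = {
        "n_input": len(records),
        "n_kept": len(survivors),
        "n_removed": len(records) - len(survivors),
        "n_duplicate_groups": sum(1 for n in group_sizes.values() if n > 1),
    }
    return survivors, report
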