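"""Spike-in (reference epigenome) calibration of ChIP coverage.

The calibration factor is computed from the four non-orthologous alignment
tallies as (input_ref x chip_target) / (input_target x chip_ref); reads
mapping to both genomes ("orthologous") are excluded from every tally.
RPM coverage multiplied by the factor yields calibrated occupancy.
Fold-enrichment and bidirectional Poisson q-value tracks follow, with zero
bins substituted by 1 before any ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats

from chromaquant.coverage import CoverageTrack
from chromaquant.records import AlignmentRecord
from chromaquant.turnover import bh_qvalues


@dataclass(frozen=True)
class CalibrationCounts:
    """Non-orthologous read tallies (target = Sc role, reference = Cg role)."""

    chip_sc: int
    chip_cg: int
    input_sc: int
    input_cg: int

    def __post_init__(self) -> None:
        for name in ("chip_sc", "chip_cg", "input_sc", "input_cg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"calibration count {name} must be > 0")


@dataclass
class EnrichmentTrack:
    """Per-bin fold enrichment plus a signed significance track.

    ``neglog_q[chrom]`` holds -log10 q of the more significant direction,
    ``enriched[chrom]`` is True where that direction is enrichment.
    """

    fold: Dict[str, np.ndarray]
    neglog_q: Dict[str, np.ndarray]
    enriched: Dict[str, np.ndarray]
    bin_size: int = 1


def species_tally(records: Sequence[AlignmentRecord]) -> Tuple[int, int, int]:
    """(n_target, n_reference, n_orthologous); errors on unlabeled records."""
    n_t = n_r = n_o = 0
    for r in records:
        if r.species is None:
            raise ValueError(f"record {r.read_id!r} has no species label")
        if r.species == "target":
            n_t += 1
        elif r.species == "reference":
            n_r += 1
        else:
            n_o += 1
    return n_t, n_r, n_o


def partition_species(
    chip_records: Sequence[AlignmentRecord],
    input_records: Sequence[AlignmentRecord],
) -> CalibrationCounts:
    """Tally non-orthologous reads per (sample role, species).

    Orthologous reads are excluded from both the target and the reference
    tallies. Any zero tally makes the factor undefined and raises.
    """
    chip_sc, chip_cg, _ = species_tally(chip_records)
    input_sc, input_cg, _ = species_tally(input_records)
    if min(chip_sc, chip_cg, input_sc, input_cg) == 0:
        raise ValueError(
            "calibration undefined: zero non-orthologous reads in some tally "
            f"(chip_sc={chip_sc}, chip_cg={chip_cg}, "
            f"input_sc={input_sc}, input_cg={input_cg})"
        )
    return CalibrationCounts(
        chip_sc=chip_sc, chip_cg=chip_cg, input_sc=input_sc, input_cg=input_cg
    )


def calibration_factor(counts: CalibrationCounts) -> float:
    """(input_cg x chip_sc) / (input_sc x chip_cg)."""
    return (counts.input_cg * counts.chip_sc) / (counts.input_sc * counts.chip_cg)


def calibrate_track(track: CoverageTrack, factor: float) -> CoverageTrack:
    """Scale an RPM track by the calibration factor."""
    if factor <= 0:
        raise ValueError("calibration factor must be > 0")
    if track.normalization != "rpm":
        raise ValueError(
            f"calibrate_track expects an rpm track, got {track.normalization!r}"
        )
    return track.scaled(factor, normalization="calibrated")


def _substitute_zeros(arr: np.ndarray) -> np.ndarray:
    out = arr.copy()
    out[out == 0] = 1.0
    return out


def fold_enrichment(chip: CoverageTrack, control: CoverageTrack) -> CoverageTrack:
    """Per-bin chip/control ratio with zero bins set to 1 beforehand."""
    if not chip.same_bins(control):
        raise ValueError("fold_enrichment: tracks have mismatched bins")
    values = {
        c: _substitute_zeros(chip.values[c]) / _substitute_zeros(control.values[c])
        for c in chip.values
    }
    return CoverageTrack(
        values=values,
        chrom_sizes=dict(chip.chrom_sizes),
        bin_size=chip.bin_size,
        normalization="fold",
        total_reads=0,
    )


def bidirectional_q(
    chip_counts: np.ndarray, lambda_control: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-direction Poisson significance per bin, BH-corrected genome-wide.

    Enrichment p = P(X >= obs | lambda), depletion p = P(X <= obs | lambda);
    each direction's p-vector is converted to q over all bins, and per bin
    the direction with the larger -log10 q wins (ties break to enriched).

    Returns (-log10 q, enriched?) arrays.
    """
    obs = np.asarray(chip_counts, dtype=float)
    lam = np.asarray(lambda_control, dtype=float)
    if obs.shape != lam.shape:
        raise ValueError("bidirectional_q: shape mismatch")
    if np.any(obs < 0):
        raise ValueError("bidirectional_q: negative counts")
    if np.any(lam <= 0):
        raise ValueError("bidirectional_q: lambda must be > 0 (apply zero substitution)")
    p_enr = np.clip(stats.poisson.sf(obs - 1, lam), 1e-300, 1.0)
    p_dep = np.clip(stats.poisson.cdf(obs, lam), 1e-300, 1.0)
    q_enr = bh_qvalues(p_enr)
    q_dep = bh_qvalues(p_dep)
    enriched = q_enr <= q_dep  # tie -> enriched
    q = np.where(enriched, q_enr, q_dep)
    return -np.log10(q), enriched


def compare_tracks(
    chip: CoverageTrack,
    control: CoverageTrack,
    chip_total: int,
    control_total: int,
) -> EnrichmentTrack:
    """Fold enrichment plus bidirectional q tracks for a chip/control pair.

    The Poisson lambda per bin is the control bin count scaled to the ChIP
    library depth (after zero substitution); BH correction runs over all
    bins genome-wide per direction.
    """
    fold = fold_enrichment(chip, control)
    if control_total <= 0 or chip_total <= 0:
        raise ValueError("library totals must be positive")
    chroms = sorted(chip.values)
    obs = np.concatenate([_substitute_zeros(chip.values[c]) for c in chroms])
    lam = np.concatenate(
        [_substitute_zeros(control.values[c]) for c in chroms]
    ) * (chip_total / control_total)
    neglog, enr = bidirectional_q(obs, lam)
    out_q: Dict[str, np.ndarray] = {}
    out_e: Dict[str, np.ndarray] = {}
    offset = 0
    for c in chroms:
        n = len(chip.values[c])
        out_q[c] = neglog[offset : offset + n]
        out_e[c] = enr[offset : offset + n]
        offset += n
    return EnrichmentTrack(
        fold=fold.values, neglog_q=out_q, enriched=out_e, bin_size=chip.bin_size
    )
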