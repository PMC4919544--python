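"""Histone turnover (new/old tag) window statistics.

New-histone (Flag) and old-histone (V5) ChIP read counts are summed in
TSS-relative windows after depth normalization, turned into per-window
new/old ratios, and WT-vs-mutant differences per gene group are tested with
a window-paired repeated-measures contrast (two conditions reduce to the
paired t, F = t^2). P-values across groups convert to q-values by
Benjamini-Hochberg.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from chromaquant.annotation import GeneAnnotation
from chromaquant.coverage import (
    TSSMatrix,
    WindowSpec,
    mean_profile,
    neighbour_mask,
    window_index,
)
from chromaquant.records import AlignmentRecord

_TINY_P = 1e-300


def window_tag_counts(
    flag_records: Sequence[AlignmentRecord],
    v5_records: Sequence[AlignmentRecord],
    annotation: GeneAnnotation,
    window_spec: Optional[WindowSpec] = None,
) -> Tuple[TSSMatrix, TSSMatrix]:
    """Depth-normalized per-window read-count sums for each tag library.

    Each read contributes 1e6/total_library_reads to the window containing
    its 5' position; neighbour-overlapping windows are masked as in
    :func:`chromaquant.coverage.tss_window_matrix`.
    """
    if len(annotation) == 0:
        raise ValueError("window_tag_counts: empty annotation")
    spec = window_spec or WindowSpec()
    mask = neighbour_mask(annotation, spec)
    flag = _tag_matrix(flag_records, annotation, spec, mask)
    v5 = _tag_matrix(v5_records, annotation, spec, mask)
    return flag, v5


def _tag_matrix(
    records: Sequence[AlignmentRecord],
    annotation: GeneAnnotation,
    spec: WindowSpec,
    mask: np.ndarray,
) -> TSSMatrix:
    weight = 1e6 / len(records) if records else 0.0
    values = np.zeros((len(annotation), spec.n_windows))
    by_chrom: Dict[str, list] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r.five_prime)
    pos_by_chrom = {c: np.sort(np.asarray(p)) for c, p in by_chrom.items()}
    for gi, g in enumerate(annotation):
        pos = pos_by_chrom.get(g.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, g.tss - spec.span - 1)
        hi = np.searchsorted(pos, g.tss + spec.span + 1, side="right")
        for p in pos[lo:hi]:
            wi = window_index(int(p), g.tss, g.strand, spec)
            if wi is not None:
                values[gi, wi] += weight
    values[mask] = np.nan
    return TSSMatrix(
        gene_ids=annotation.gene_ids, values=values, mask=mask.copy(), window_spec=spec
    )


def turnover_ratio(
    flag_matrix: TSSMatrix, v5_matrix: TSSMatrix, pseudocount: float = 1.0
) -> TSSMatrix:
    """Per-cell (flag + pc) / (v5 + pc) ratio on congruent matrices."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not flag_matrix.congruent(v5_matrix):
        raise ValueError("turnover_ratio: matrices are not congruent")
    values = (flag_matrix.values + pseudocount) / (v5_matrix.values + pseudocount)
    values[flag_matrix.mask] = np.nan
    return TSSMatrix(
        gene_ids=list(flag_matrix.gene_ids),
        values=values,
        mask=flag_matrix.mask.copy(),
        window_spec=flag_matrix.window_spec,
    )


def group_rm_anova(
    wt_ratios: TSSMatrix, mut_ratios: TSSMatrix, gene_group: Iterable[str]
) -> Tuple[float, float]:
    """Window-paired repeated-measures test of a WT vs mutant group difference.

    For each window the group-mean turnover is computed in both conditions;
    windows act as matched subjects, condition as the repeated factor. With
    two conditions the F statistic equals the square of the paired t on the
    per-window differences, df = (1, W-1). Returns (F, two-sided p).
    """
    group = list(gene_group)
    if not group:
        raise ValueError("group_rm_anova: empty gene group")
    prof_wt = mean_profile(wt_ratios, group)
    prof_mut = mean_profile(mut_ratios, group)
    ok = np.isfinite(prof_wt) & np.isfinite(prof_mut)
    d = (prof_mut - prof_wt)[ok]
    n = d.size
    if n < 3:
        raise ValueError(f"group_rm_anova: only {n} usable windows (need >= 3)")
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        return (0.0, 1.0) if mean == 0.0 else (float("inf"), _TINY_P)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return float(t * t), max(min(p, 1.0), _TINY_P)


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
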