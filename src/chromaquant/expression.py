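"""Strand-specific counting, NB differential expression and qPCR fold change.

The differential test is a documented stand-in for the original external
tool: median-of-ratios library normalization, method-of-moments NB
dispersion shrunk toward the trimmed-mean dispersion, and a Wald test on
the log2 ratio of normalized means (pseudocount 0.5). Thresholds reproduce
the operative rule exactly: FDR < 5% and |log2 ratio| >= 0.585.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from chromaquant.annotation import GeneAnnotation
from chromaquant.records import AlignmentRecord
from chromaquant.turnover import bh_qvalues

FDR_THRESHOLD = 0.05
LFC_THRESHOLD = 0.585  # log2(1.5), the 1.5-fold rule


def count_stranded(
    records: Sequence[AlignmentRecord],
    annotation: GeneAnnotation,
    orientation: str = "reverse",
    multi: str = "all",
) -> Tuple[pd.Series, pd.Series]:
    """Per-gene sense and antisense read counts for one library.

    Under the default dUTP-style ``reverse`` orientation a read whose strand
    is opposite the gene's counts as sense; ``forward`` flips that. A read
    overlapping several gene bodies counts once per gene (``multi="all"``)
    or is skipped entirely (``multi="exclusive"``).
    """
    if orientation not in ("reverse", "forward"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if multi not in ("all", "exclusive"):
        raise ValueError(f"unknown multi mode {multi!r}")
    for r in records:
        if r.strand not in ("+", "-"):
            raise ValueError(f"record {r.read_id!r} is unstranded")
    sense = pd.Series(0, index=annotation.gene_ids, dtype=int)
    antisense = pd.Series(0, index=annotation.gene_ids, dtype=int)
    genes_by_chrom: Dict[str, List] = {}
    for g in annotation:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    # per-read gene hits, then assign (needed for the exclusive mode)
    hits: List[List] = [[] for _ in records]
    for ri, r in enumerate(records):
        for g in genes_by_chrom.get(r.chrom, ()):
            if r.start < g.end and r.end > g.start:
                hits[ri].append(g)
    for r, genes in zip(records, hits):
        if multi == "exclusive" and len(genes) > 1:
            continue
        for g in genes:
            opposite = r.strand != g.strand
            is_sense = opposite if orientation == "reverse" else not opposite
            if is_sense:
                sense[g.gene_id] += 1
            else:
                antisense[g.gene_id] += 1
    return sense, antisense


# ------------------------------------------------------------------ NB DE test


def _size_factors(counts: pd.DataFrame) -> np.ndarray:
    """DESeq-style median-of-ratios size factors."""
    mat = counts.to_numpy(dtype=float)
    positive = np.all(mat > 0, axis=1)
    if positive.sum() == 0:
        # degenerate fallback: library-size factors
        totals = mat.sum(axis=0)
        return totals / np.exp(np.mean(np.log(totals)))
    log_ref = np.mean(np.log(mat[positive]), axis=1)
    sf = np.exp(np.median(np.log(mat[positive]) - log_ref[:, None], axis=0))
    return sf


def nb_de_test(
    counts_wt: pd.DataFrame,
    counts_mut: pd.DataFrame,
    prior_df: float = 20.0,
) -> pd.DataFrame:
    """Per-gene negative-binomial Wald test between two replicate groups.

    Per-gene method-of-moments dispersions are shrunk (``prior_df`` pseudo
    degrees of freedom) toward a pooled trend estimated by an unbiased
    moment regression across genes; the Wald statistic is the log2 ratio of
    normalized means over its delta-method standard error, referred to the
    standard normal.

    Returns a frame indexed by gene with ``base_mean``, ``log2fc``,
    ``dispersion`` and ``p`` columns. ``log2fc`` is the log2 ratio of
    normalized condition means with pseudocount 0.5 (mutant over WT).
    """
    if not counts_wt.index.equals(counts_mut.index):
        raise ValueError("nb_de_test: gene index mismatch between conditions")
    if counts_wt.shape[1] < 2 or counts_mut.shape[1] < 2:
        raise ValueError("nb_de_test: need >= 2 replicates per condition")
    for name, df in (("WT", counts_wt), ("mutant", counts_mut)):
        if np.all(df.to_numpy().sum(axis=0) == 0):
            raise ValueError(f"nb_de_test: {name} condition has all-zero libraries")
    combined = pd.concat([counts_wt, counts_mut], axis=1)
    sf = _size_factors(combined)
    n_wt = counts_wt.shape[1]
    norm = combined.to_numpy(dtype=float) / sf[None, :]
    y_wt, y_mut = norm[:, :n_wt], norm[:, n_wt:]
    n1, n2 = y_wt.shape[1], y_mut.shape[1]

    m1, m2 = y_wt.mean(axis=1), y_mut.mean(axis=1)
    v1 = y_wt.var(axis=1, ddof=1)
    v2 = y_mut.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        d1 = np.where(m1 > 0, (v1 - m1) / np.square(m1), np.nan)
        d2 = np.where(m2 > 0, (v2 - m2) / np.square(m2), np.nan)
    raw = np.nanmean(np.stack([d1, d2]), axis=0)
    raw = np.clip(np.nan_to_num(raw, nan=0.0), 0.0, None)
    base_mean = (m1 + m2) / 2
    # pooled moment regression for the dispersion trend: E[v - m] = disp*mu^2
    # with m^2 - v/n as the unbiased estimator of mu^2
    num = (v1 - m1) + (v2 - m2)
    den = np.maximum((np.square(m1) - v1 / n1) + (np.square(m2) - v2 / n2), 0.0)
    trend = max(float(num.sum()) / max(float(den.sum()), 1e-12), 1e-8)
    df_resid = (n1 - 1) + (n2 - 1)
    disp = (df_resid * raw + prior_df * trend) / (df_resid + prior_df)
    disp = np.maximum(disp, 1e-8)

    log2fc = np.log2((m2 + 0.5) / (m1 + 0.5))
    var_log_m1 = (m1 + disp * np.square(m1)) / (n1 * np.square(m1 + 0.5))
    var_log_m2 = (m2 + disp * np.square(m2)) / (n2 * np.square(m2 + 0.5))
    se = np.sqrt(var_log_m1 + var_log_m2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.clip(p, 1e-300, 1.0)
    zero = (m1 == 0) & (m2 == 0)
    p[zero] = 1.0
    log2fc[zero] = 0.0
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "dispersion": disp,
            "p": p,
        },
        index=counts_wt.index,
    )


def threshold_filter(
    results: pd.DataFrame,
    fdr_threshold: float = FDR_THRESHOLD,
    lfc_threshold: float = LFC_THRESHOLD,
) -> pd.DataFrame:
    """Assign up/down/ns status: FDR strictly < threshold, |log2fc| attained.

    Adds an ``fdr`` column (BH over ``p``) when absent, then ``status``:
    up iff fdr < fdr_threshold and log2fc >= lfc_threshold; down symmetric
    with log2fc <= -lfc_threshold; ns otherwise.
    """
    out = results.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_qvalues(out["p"].to_numpy())
    sig = out["fdr"] < fdr_threshold
    up = sig & (out["log2fc"] >= lfc_threshold)
    down = sig & (out["log2fc"] <= -lfc_threshold)
    out["status"] = np.select([up, down], ["up", "down"], default="ns")
    return out


# ---------------------------------------------------------------- qPCR 2^-ddCt


@dataclass(frozen=True)
class DdctInput:
    """Ct values (cycles) for target/reference genes in mutant and WT."""

    ct_target_mut: float
    ct_reference_mut: float
    ct_target_wt: float
    ct_reference_wt: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_mut",
            "ct_reference_mut",
            "ct_target_wt",
            "ct_reference_wt",
        ):
            val = getattr(self, name)
            if val is None or not np.isfinite(val):
                raise ValueError(f"missing or non-finite Ct value: {name}")
            if val <= 0:
                raise ValueError(f"Ct must be positive: {name}={val}")


def ddct_fold_change(inp: DdctInput) -> float:
    """Relative expression by the 2^-ddCt method (mutant vs WT)."""
    dct_mut = inp.ct_target_mut - inp.ct_reference_mut
    dct_wt = inp.ct_target_wt - inp.ct_reference_wt
    return float(2.0 ** (-(dct_mut - dct_wt)))
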