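"""Stage specificity, putative enhancers, eRNAs, ZGA genes, and
fold-change differential calls.

The specificity statistic is Shannon entropy over stage shares: for a
feature with signal E_i at stage i, R_i = E_i / sum(E) and
H = -sum(R_i log2 R_i), which runs from 0 (perfectly stage-specific) to
log2(N) (uniform across N stages). Features with H < 0.5 bits are called
stage-specific and assigned to their argmax stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import IntervalSet
from .domains import PeakSet
from .io import GeneModel

__all__ = [
    "entropy_score",
    "entropy_table",
    "select_stage_specific",
    "define_putative_enhancers",
    "call_ernas",
    "define_zga_genes",
    "fold_change_differential",
]


def entropy_score(values: Sequence[float]) -> Tuple[np.ndarray, float]:
    """Stage shares R_i and entropy H (bits) for one feature.

    0 * log2(0) is taken as 0. An all-zero feature has undefined shares and
    H = NaN (flagged, never silently scored).
    """
    e = np.asarray(values, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("need a 1-D vector over at least two stages")
    if np.any(e < 0):
        raise ValueError("stage values must be non-negative")
    total = e.sum()
    if total == 0:
        return np.full(e.size, np.nan), float("nan")
    r = e / total
    nz = r > 0
    h = float(-(r[nz] * np.log2(r[nz])).sum()) + 0.0  # normalize -0.0
    return r, h


def entropy_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Entropy per feature of a feature x stage matrix.

    Returns feature-indexed DataFrame with H, the argmax stage, and a
    ``defined`` flag (False for all-zero features, which are excluded from
    specificity calls).
    """
    vals = matrix.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("matrix must have at least two stage columns")
    if np.any(vals < 0):
        raise ValueError("matrix values must be non-negative")
    totals = vals.sum(axis=1)
    defined = totals > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = vals / totals[:, None]
        logr = np.where(r > 0, np.log2(np.where(r > 0, r, 1.0)), 0.0)
        h = -(r * logr).sum(axis=1) + 0.0  # normalize -0.0
    h[~defined] = np.nan
    peak_stage = matrix.columns.to_numpy()[np.argmax(vals, axis=1)]
    return pd.DataFrame(
        {"H": h, "peak_stage": peak_stage, "defined": defined}, index=matrix.index
    )


def select_stage_specific(
    matrix: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Features with H < threshold bits (defined features only), with their
    assigned (argmax-share) stage."""
    tab = entropy_table(matrix)
    sel = tab[tab["defined"] & (tab["H"] < threshold)]
    return sel[["H", "peak_stage"]]


def define_putative_enhancers(
    distal_peaks: PeakSet, dhs: IntervalSet, radius: int = 500
) -> PeakSet:
    """Distal peaks with an open-chromatin site (DHS) overlapping the peak or
    lying within ``radius`` bp of either edge."""
    keep = []
    for i, iv in enumerate(distal_peaks):
        starts, ends = dhs.arrays(iv.chrom)
        if starts.size:
            # gap between peak and DHS (<= 0 means overlap)
            gap = np.maximum(starts - iv.end, iv.start - ends)
            if gap.min() <= radius:
                keep.append(i)
    return PeakSet(distal_peaks.df.iloc[keep], distal_peaks.stage)


def call_ernas(
    k27_peaks: PeakSet,
    k4_peaks: PeakSet,
    genes: Sequence[GeneModel],
    rna_fpkm: pd.DataFrame,
    threshold: float = 0.5,
    genome=None,
) -> Dict[str, pd.Index]:
    """Enhancer RNAs per stage.

    Eligible peaks carry no H3K4me3 overlap and do not overlap promoters or
    exons; an eligible peak is an eRNA at every stage where its RNA FPKM is
    strictly above ``threshold``. ``rna_fpkm`` is peak-indexed (index aligned
    with k27_peaks row order) with one column per stage.
    """
    if len(rna_fpkm) != len(k27_peaks):
        raise ValueError("rna_fpkm must have one row per peak")
    no_k4 = ~k27_peaks.overlaps_mask(k4_peaks, min_overlap=1)
    excluded = IntervalSet.from_intervals(
        [g.promoter(genome) for g in genes]
        + [ex for g in genes for ex in g.exons]
    )
    clean = np.array(
        [
            _no_overlap(iv, excluded)
            for iv in k27_peaks
        ]
    )
    eligible = no_k4 & clean
    out = {}
    for stage in rna_fpkm.columns:
        mask = eligible & (rna_fpkm[stage].to_numpy() > threshold)
        out[stage] = rna_fpkm.index[mask]
    return out


def _no_overlap(iv, elements: IntervalSet) -> bool:
    starts, ends = elements.arrays(iv.chrom)
    if not starts.size:
        return True
    ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
    return bool(ov.max() <= 0)


def define_zga_genes(
    expr: pd.DataFrame,
    pre_stage: str,
    post_stage: str,
    fpkm_min: float = 1.0,
    fold_min: float = 3.0,
    pseudocount: float = 0.1,
) -> pd.Index:
    """Zygotic genome activation genes: expression above ``fpkm_min`` at the
    post-ZGA stage and fold change above ``fold_min`` versus the pre-ZGA
    stage (pseudocount guards zero denominators)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    pre = expr[pre_stage].to_numpy(dtype=float)
    post = expr[post_stage].to_numpy(dtype=float)
    fold = (post + pseudocount) / (pre + pseudocount)
    return expr.index[(post > fpkm_min) & (fold > fold_min)]


def fold_change_differential(
    a,
    b,
    fold_min: float = 2.0,
    fdr_max: Optional[float] = None,
    pseudocount: float = 0.1,
    library_sizes: Optional[Tuple[float, float]] = None,
) -> pd.DataFrame:
    """Differential features between two conditions.

    Fold-only mode (``fdr_max=None``): ``a`` and ``b`` are per-feature
    signal Series; a feature is up (in b over a) when
    (b + c) / (a + c) > fold_min, down when < 1/fold_min.

    Statistical mode: ``a`` and ``b`` are feature x replicate count
    DataFrames (>= 2 replicates each). A conditional binomial test on pooled
    counts with library-size offsets — a simplified two-sample count test —
    yields p-values, Benjamini-Hochberg adjusted; calls require both the
    fold and the FDR threshold (fold > 2 and FDR < 0.05 by default;
    a fold-only > 3 preset serves simpler designs).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if fdr_max is None:
        a = pd.Series(a, dtype=float)
        b = pd.Series(b, dtype=float)
        fold = (b + pseudocount) / (a + pseudocount)
        call = np.where(
            fold > fold_min, "up", np.where(fold < 1.0 / fold_min, "down", "ns")
        )
        return pd.DataFrame({"fold": fold, "call": call}, index=a.index)

    a = pd.DataFrame(a)
    b = pd.DataFrame(b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("statistical mode requires >= 2 replicates per condition")
    ka = a.sum(axis=1).to_numpy(dtype=float)
    kb = b.sum(axis=1).to_numpy(dtype=float)
    if library_sizes is None:
        # median-of-ratios size factors: robust to a minority of strongly
        # changed features inflating one library's total
        both = (ka > 0) & (kb > 0)
        if both.sum() >= 10:
            ref = np.sqrt(ka[both] * kb[both])
            na = float(np.median(ka[both] / ref))
            nb = float(np.median(kb[both] / ref))
        else:
            na, nb = float(ka.sum()), float(kb.sum())
    else:
        na, nb = library_sizes
    # normalized means for the fold, pooled conditional binomial for the p
    mean_a = ka / na
    mean_b = kb / nb
    fold = (mean_b + pseudocount) / (mean_a + pseudocount)
    prob_b = nb / (na + nb)
    pvals = np.array(
        [
            stats.binomtest(int(x_b), int(x_a + x_b), prob_b).pvalue
            if (x_a + x_b) > 0
            else 1.0
            for x_a, x_b in zip(ka, kb)
        ]
    )
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    up = (fold > fold_min) & (padj < fdr_max)
    down = (fold < 1.0 / fold_min) & (padj < fdr_max)
    call = np.where(up, "up", np.where(down, "down", "ns"))
    return pd.DataFrame(
        {"fold": fold, "pvalue": pvals, "padj": padj, "call": call}, index=a.index
    )
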