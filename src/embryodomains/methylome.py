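"""Partially methylated domain (PMD) detection and region methylation summaries.

PMDs are called on a fixed 10-kb tiling: a window qualifies when its mean
CpG methylation is below 0.5 and it has more than 20 covered CpGs; adjacent
qualifying windows merge into PMDs. The window mean is the unweighted mean
over covered CpGs ("covered" = coverage >= 1 by default).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet
from .io import CpGTable

__all__ = ["call_pmds", "methyl_windows", "cpg_density", "region_methylation"]


def methyl_windows(
    cpgs: CpGTable,
    genome: ChromSizes,
    window: int = 10_000,
    min_coverage: int = 1,
) -> pd.DataFrame:
    """Per-window mean methylation and covered-CpG count over a fixed tiling
    from coordinate 0 (the terminal partial window uses its actual content).

    Returns a DataFrame with chrom, start, end, mean_meth (NaN when no
    covered CpG), n_covered.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    df = cpgs.df
    for chrom, length in genome.items():
        sub = df[df["chrom"] == chrom]
        covered = sub[sub["cov"] >= min_coverage]
        pos = covered["pos"].to_numpy()
        meth = covered["meth"].to_numpy()
        n_windows = -(-length // window)
        idx = pos // window
        sums = np.zeros(n_windows)
        counts = np.zeros(n_windows, dtype=np.int64)
        np.add.at(sums, idx, meth)
        np.add.at(counts, idx, 1)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        starts = np.arange(n_windows) * window
        ends = np.minimum(starts + window, length)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "mean_meth": means,
                    "n_covered": counts,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def call_pmds(
    cpgs: CpGTable,
    genome: ChromSizes,
    window: int = 10_000,
    max_meth: float = 0.5,
    min_cpgs: int = 20,
    min_coverage: int = 1,
) -> IntervalSet:
    """Call PMDs: windows with mean methylation < max_meth and strictly more
    than min_cpgs covered CpGs, merged when adjacent (gap 0)."""
    win = methyl_windows(cpgs, genome, window, min_coverage)
    sel = win[(win["mean_meth"] < max_meth) & (win["n_covered"] > min_cpgs)]
    if sel.empty:
        return IntervalSet()
    s = IntervalSet.from_arrays(
        sel["chrom"].to_numpy(), sel["start"].to_numpy(), sel["end"].to_numpy()
    )
    return s.merge(gap=0)


def cpg_density(region: GenomicInterval, cpgs: CpGTable) -> float:
    """Average number of CpG sites per 100 bp in the region (all sites,
    regardless of coverage)."""
    if region.length <= 0:
        raise ValueError("zero-length region")
    n = len(cpgs.in_region(region))
    return n * 100.0 / region.length


def region_methylation(region: GenomicInterval, cpgs: CpGTable) -> float:
    """Unweighted mean methylation over CpGs in the region; NaN when the
    region contains no CpG (the flag propagates rather than erroring)."""
    sub = cpgs.in_region(region)
    if sub.empty:
        return float("nan")
    return float(sub["meth"].mean())
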