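"""Allele-specific peak classification.

Peaks with at least 10 SNP-informative reads per kb are tested for
parent-of-origin bias with a one-degree-of-freedom chi-square against the
dataset-wide maternal:paternal background ratio; p-values are
Benjamini-Hochberg adjusted, and a peak is called maternal (or paternal)
when the adjusted p-value is below 0.001 and the allelic read ratio exceeds
5-fold.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["classify_allelic", "informative_density"]

REQUIRED = ("peak_id", "length", "maternal", "paternal")


def informative_density(table: pd.DataFrame) -> np.ndarray:
    """SNP-informative reads per kb of peak."""
    return (
        (table["maternal"] + table["paternal"]).to_numpy(dtype=float)
        * 1000.0
        / table["length"].to_numpy(dtype=float)
    )


def classify_allelic(
    table: pd.DataFrame,
    rho: Optional[float] = None,
    alpha: float = 0.001,
    fold_min: float = 5.0,
    min_density: float = 10.0,
    yates: bool = False,
) -> pd.DataFrame:
    """Classify peaks as maternal / paternal / biallelic / untested.

    Parameters
    ----------
    table : DataFrame with columns peak_id, length (bp), maternal, paternal
        (SNP-informative read counts).
    rho : expected maternal fraction under no bias. Default: estimated from
        the table's own read totals (the dataset-wide background).
    alpha : adjusted p-value cutoff.
    fold_min : minimum allelic read ratio (either direction); a zero
        denominator counts as infinite fold and qualifies.
    min_density : minimum informative reads per kb to test a peak.
    yates : apply the continuity correction to the chi-square statistic.
    """
    for col in REQUIRED:
        if col not in table.columns:
            raise ValueError(f"allelic table missing column {col!r}")
    out = table.copy().reset_index(drop=True)
    m = out["maternal"].to_numpy(dtype=float)
    p = out["paternal"].to_numpy(dtype=float)
    if np.any(m < 0) or np.any(p < 0):
        raise ValueError("read counts must be non-negative")
    if rho is None:
        total = m.sum() + p.sum()
        if total == 0:
            raise ValueError("cannot estimate background from an empty table")
        rho = float(m.sum() / total)
    if not 0 < rho < 1:
        raise ValueError(f"background maternal fraction must be in (0, 1), got {rho}")

    out["density"] = informative_density(out)
    tested = (out["density"] >= min_density) & ((m + p) > 0)

    n = m + p
    exp_m = n * rho
    exp_p = n * (1 - rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_m = np.abs(m - exp_m)
        dev_p = np.abs(p - exp_p)
        if yates:
            dev_m = np.maximum(dev_m - 0.5, 0.0)
            dev_p = np.maximum(dev_p - 0.5, 0.0)
        chi2 = dev_m**2 / exp_m + dev_p**2 / exp_p
    pvals = stats.chi2.sf(chi2, df=1)

    out["chi2"] = np.where(tested, chi2, np.nan)
    out["pvalue"] = np.where(tested, pvals, np.nan)
    out["padj"] = np.nan
    if tested.any():
        _, padj, _, _ = multipletests(pvals[tested.to_numpy()], method="fdr_bh")
        out.loc[tested, "padj"] = padj

    with np.errstate(divide="ignore", invalid="ignore"):
        fold_m = np.where(p > 0, m / np.where(p > 0, p, 1), np.inf)
        fold_p = np.where(m > 0, p / np.where(m > 0, m, 1), np.inf)
    fold = np.maximum(fold_m, fold_p)
    out["fold"] = fold

    sig = tested.to_numpy() & (out["padj"].to_numpy() < alpha)
    maternal = sig & (fold_m > fold_min)
    paternal = sig & (fold_p > fold_min)
    call = np.full(len(out), "biallelic", dtype=object)
    call[maternal] = "maternal"
    call[paternal] = "paternal"
    call[~tested.to_numpy()] = "untested"
    out["call"] = call
    return out
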