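"""Enriched-domain calling and the peak/domain layer.

The caller is a deliberately simplified local-Poisson re-expression of
broad-mode peak calling: per 100-bp bin, the background rate is the maximum
of the genome-wide fragment rate and depth-scaled input means over local
windows (5 kb and 10 kb); bins are scored by the upper-tail Poisson p-value;
weak bins (p <= 0.01) are linked across gaps up to 500 bp and a candidate is
kept when it contains at least one strong bin (p <= 1e-3). All constants
live in :class:`CallerParams`.

Downstream, peaks are scored by their FPKM over 100-bp bins (signal = sum,
per-domain level = mean), filtered to the top 75% by signal, merged within
5 kb, classified by length (typical <= 10 kb; broad > 10 kb, > 20 kb,
> 50 kb strictly), and cross-stage normalized so the median signal of the
top-25% peaks matches a reference stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import ChromSizes, GenomicInterval, IntervalSet, intersect_length
from .tracks import BinnedTrack

__all__ = [
    "CallerParams",
    "PeakSet",
    "bin_pvalues",
    "call_enriched_domains",
    "score_peaks",
    "filter_top_signal",
    "merge_within_gap",
    "summarize_peaks",
    "overlap_table",
    "classify_inheritance",
    "stage_scale_factor",
    "length_class",
]

LENGTH_CLASSES = ("typical", "broad", "broad20", "broad50")


def length_class(length: int) -> str:
    """Strict-threshold length taxonomy: > 50 kb, > 20 kb, > 10 kb, else typical."""
    if length > 50_000:
        return "broad50"
    if length > 20_000:
        return "broad20"
    if length > 10_000:
        return "broad"
    return "typical"


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the simplified broad caller (defaults follow broad-mode
    peak-calling practice: strong cutoff 1e-3, weak/broad cutoff 0.01,
    500-bp gap linking)."""

    p_strong: float = 1e-3
    p_weak: float = 0.01
    max_gap: int = 500
    bin_width: int = 100
    local_windows: tuple = (5_000, 10_000)

    def __post_init__(self):
        if not (0 < self.p_strong <= self.p_weak < 1):
            raise ValueError("require 0 < p_strong <= p_weak < 1")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")

    @classmethod
    def narrow_preset(cls) -> "CallerParams":
        """Stringent preset for narrow putative-enhancer calling."""
        return cls(p_strong=1e-5, p_weak=1e-5, max_gap=100)


class PeakSet:
    """Scored, sorted, non-overlapping peaks for one sample/stage.

    Backed by a DataFrame with columns chrom, start, end, signal_sum,
    signal_mean (NaN until :func:`score_peaks` runs).
    """

    COLUMNS = ["chrom", "start", "end", "signal_sum", "signal_mean"]

    def __init__(self, df: pd.DataFrame, stage: Optional[str] = None):
        df = df.copy()
        for col in ("signal_sum", "signal_mean"):
            if col not in df.columns:
                df[col] = np.nan
        df = df[self.COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if ((df["start"] < 0) | (df["start"] >= df["end"])).any():
            raise ValueError("peak with start >= end")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        same = df["chrom"].to_numpy()[1:] == df["chrom"].to_numpy()[:-1]
        if np.any(same & (df["start"].to_numpy()[1:] < df["end"].to_numpy()[:-1])):
            raise ValueError("peaks within a set must be non-overlapping")
        self.df = df
        self.stage = stage

    @classmethod
    def from_intervals(cls, intervals: IntervalSet, stage=None) -> "PeakSet":
        rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]), stage)

    @classmethod
    def empty(cls, stage=None) -> "PeakSet":
        return cls(pd.DataFrame(columns=["chrom", "start", "end"]), stage)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for r in self.df.itertuples():
            yield GenomicInterval(r.chrom, int(r.start), int(r.end))

    @property
    def scored(self) -> bool:
        return len(self.df) == 0 or not self.df["signal_sum"].isna().any()

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def classes(self) -> pd.Series:
        return pd.Series([length_class(l) for l in self.lengths], index=self.df.index)

    def intervals(self) -> IntervalSet:
        return IntervalSet.from_arrays(
            self.df["chrom"].to_numpy(),
            self.df["start"].to_numpy(),
            self.df["end"].to_numpy(),
        )

    def centers(self) -> pd.DataFrame:
        out = self.df[["chrom"]].copy()
        out["center"] = (self.df["start"] + self.df["end"]) // 2
        return out

    def overlaps_mask(self, other: "PeakSet", min_overlap: int = 1) -> np.ndarray:
        """Boolean per-peak: overlaps any peak of ``other`` by >= min_overlap bp."""
        mask = np.zeros(len(self.df), dtype=bool)
        other_iv = other.intervals()
        for chrom, sub in self.df.groupby("chrom"):
            os_, oe_ = other_iv.arrays(chrom)
            if not os_.size:
                continue
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            # candidate other-peaks bracketing each peak
            for i, (a, b) in zip(sub.index, zip(s, e)):
                lo = np.searchsorted(oe_, a, side="right")
                hi = np.searchsorted(os_, b, side="left")
                if lo < hi:
                    ov = np.minimum(oe_[lo:hi], b) - np.maximum(os_[lo:hi], a)
                    if ov.max() >= min_overlap:
                        mask[self.df.index.get_loc(i)] = True
        return mask

    def to_bed(self, path) -> Path:
        """BED6+: name = length class, score = signal_sum (blank if unscored)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tclass\tsignal_sum\tsignal_mean\n")
            for r, cls_ in zip(self.df.itertuples(), self.classes):
                ss = "" if pd.isna(r.signal_sum) else f"{r.signal_sum:.6g}"
                sm = "" if pd.isna(r.signal_mean) else f"{r.signal_mean:.6g}"
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{cls_}\t{ss}\t{sm}\n")
        return path

    def __eq__(self, other) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)


def _local_means(values: np.ndarray, half_bins: int) -> np.ndarray:
    """Mean of ``values`` over a window of +/- half_bins around each index,
    truncated at the array edges."""
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half_bins, 0)
    hi = np.minimum(idx + half_bins + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def bin_pvalues(
    chip: BinnedTrack,
    input_track: BinnedTrack,
    params: CallerParams = CallerParams(),
) -> Dict[str, np.ndarray]:
    """Per-bin upper-tail Poisson p-values of chip counts against the local
    background rate (the caller's scoring stage, exposed for calibration
    checks)."""
    if chip.bin_width != params.bin_width or input_track.bin_width != params.bin_width:
        raise ValueError(
            f"track bin width must equal params.bin ({params.bin_width} bp)"
        )
    if not chip.same_shape(input_track):
        raise ValueError("chip and input tracks have mismatched binning")
    if chip.semantics != "counts" or input_track.semantics != "counts":
        raise ValueError("caller expects raw count tracks")
    chip_total = chip.total()
    input_total = input_track.total()
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("both libraries must be non-empty")
    scale = chip_total / input_total
    n_total_bins = sum(chip.n_bins(c) for c in chip.genome)
    genome_rate = chip_total / n_total_bins
    out = {}
    for chrom in chip.genome:
        cvals = chip.values[chrom]
        ivals = input_track.values[chrom] * scale
        lam = np.full(cvals.size, genome_rate)
        for window in params.local_windows:
            half_bins = window // (2 * params.bin_width)
            lam = np.maximum(lam, _local_means(ivals, half_bins))
        out[chrom] = stats.poisson.sf(cvals - 1, lam)
    return out


def call_enriched_domains(
    chip: BinnedTrack,
    input_track: BinnedTrack,
    params: CallerParams = CallerParams(),
    stage: Optional[str] = None,
) -> PeakSet:
    """Call enriched regions from chip vs input fragment-count tracks.

    Normative algorithm: (1) scale input counts to the chip library depth;
    (2) per bin, background rate lambda = max(genome-wide mean chip rate,
    scaled-input mean over each local window centered on the bin); (3) upper
    tail Poisson p-value of the chip count given lambda; (4) strong bins
    p <= p_strong, weak bins p <= p_weak; (5) link weak bins across gaps
    <= max_gap into candidates; (6) keep candidates containing >= 1 strong
    bin.
    """
    pvalues = bin_pvalues(chip, input_track, params)
    rows = []
    for chrom in chip.genome:
        pvals = pvalues[chrom]
        weak = pvals <= params.p_weak
        strong = pvals <= params.p_strong
        if not weak.any():
            continue
        # runs of weak bins -> bp intervals, linked across gaps <= max_gap
        idx = np.flatnonzero(weak)
        run_break = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate([[idx[0]], idx[run_break + 1]])
        run_ends = np.concatenate([idx[run_break], [idx[-1]]]) + 1
        bw = params.bin_width
        runs = IntervalSet({chrom: (run_starts * bw, run_ends * bw)})
        linked = runs.merge(gap=params.max_gap)
        s_idx = np.flatnonzero(strong)
        ls, le = linked.arrays(chrom)
        for a, b in zip(ls, le):
            lo = np.searchsorted(s_idx, a // bw, side="left")
            hi = np.searchsorted(s_idx, (b - 1) // bw, side="right")
            if hi > lo:
                rows.append((chrom, int(a), int(min(b, chip.genome[chrom]))))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), stage)


def score_peaks(peaks: PeakSet, fpkm100: BinnedTrack) -> PeakSet:
    """Attach signal_sum and signal_mean over the 100-bp FPKM bins whose
    midpoints fall inside each peak."""
    if fpkm100.bin_width != 100:
        raise ValueError("peak scoring requires a 100-bp FPKM track")
    df = peaks.df.copy()
    sums = np.zeros(len(df))
    means = np.zeros(len(df))
    for chrom, sub in df.groupby("chrom"):
        vals = fpkm100.values[chrom]
        bw = fpkm100.bin_width
        mids = np.arange(vals.size) * bw + bw // 2
        lo = np.searchsorted(mids, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(mids, sub["end"].to_numpy(), side="left")
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        s = csum[hi] - csum[lo]
        n = np.maximum(hi - lo, 1)
        pos = [df.index.get_loc(i) for i in sub.index]
        sums[pos] = s
        means[pos] = s / n
    df["signal_sum"] = sums
    df["signal_mean"] = means
    return PeakSet(df, peaks.stage)


def filter_top_signal(peaks: PeakSet, keep_fraction: float = 0.75) -> PeakSet:
    """Keep the top fraction of peaks by signal_sum (nearest-rank quantile,
    ties at the threshold kept). Empty input passes through."""
    if not 0 <= keep_fraction <= 1:
        raise ValueError("keep_fraction must be in [0, 1]")
    if len(peaks) == 0:
        return peaks
    if not peaks.scored:
        raise ValueError("peaks must be scored before filtering")
    if keep_fraction == 0:
        return PeakSet.empty(peaks.stage)
    k = math.ceil(keep_fraction * len(peaks))
    threshold = np.sort(peaks.df["signal_sum"].to_numpy())[::-1][k - 1]
    return PeakSet(peaks.df[peaks.df["signal_sum"] >= threshold], peaks.stage)


def merge_within_gap(
    peaks: PeakSet, gap: int = 5_000, fpkm100: Optional[BinnedTrack] = None
) -> PeakSet:
    """Merge peaks separated by at most ``gap`` bp; re-score afterwards if a
    100-bp FPKM track is supplied (signals are invalid after a merge)."""
    merged = PeakSet.from_intervals(peaks.intervals().merge(gap), peaks.stage)
    if fpkm100 is not None:
        merged = score_peaks(merged, fpkm100)
    return merged


def summarize_peaks(peaks: PeakSet, genome: ChromSizes) -> Dict[str, float]:
    """Counts per length class (nested: broad includes broad20 includes
    broad50) and the genome fraction covered."""
    lengths = peaks.lengths
    from .intervals import coverage_fraction

    cov = coverage_fraction(peaks.intervals(), genome) if len(peaks) else 0.0
    return {
        "n_peaks": int(len(peaks)),
        "typical": int(np.sum(lengths <= 10_000)),
        "broad": int(np.sum(lengths > 10_000)),
        "broad20": int(np.sum(lengths > 20_000)),
        "broad50": int(np.sum(lengths > 50_000)),
        "coverage_fraction": cov,
    }


def overlap_table(
    a: PeakSet,
    b: PeakSet,
    criterion: str = "any",
    fraction: float = 0.5,
) -> Dict[str, int]:
    """Venn-style overlap counts between two peak sets.

    criterion ``any``: >= 1 bp overlap (symmetric notion). criterion
    ``fraction``: an a-peak counts as overlapping when >= ``fraction`` of its
    own length is covered by b (and vice versa for b) — not symmetric.
    """
    if criterion not in ("any", "fraction"):
        raise ValueError(f"unknown overlap criterion {criterion!r}")
    if criterion == "any":
        a_hit = a.overlaps_mask(b, min_overlap=1)
        b_hit = b.overlaps_mask(a, min_overlap=1)
    else:
        a_hit = _fraction_overlap_mask(a, b, fraction)
        b_hit = _fraction_overlap_mask(b, a, fraction)
    return {
        "a_total": len(a),
        "b_total": len(b),
        "a_overlap": int(a_hit.sum()),
        "b_overlap": int(b_hit.sum()),
        "a_only": int((~a_hit).sum()),
        "b_only": int((~b_hit).sum()),
    }


def _fraction_overlap_mask(a: PeakSet, b: PeakSet, fraction: float) -> np.ndarray:
    b_merged = b.intervals().merge()
    mask = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        single = IntervalSet({iv.chrom: (np.array([iv.start]), np.array([iv.end]))})
        ov = intersect_length(single, b_merged)
        mask[i] = ov >= fraction * iv.length
    return mask


def classify_inheritance(
    zygote: PeakSet,
    oocyte: PeakSet,
    sperm: PeakSet,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Label each zygote peak by its gametic origin: overlapping only oocyte
    peaks -> oocyte-only; only sperm -> sperm-only; both -> shared; neither
    -> de novo. Returns the zygote table with a ``inheritance`` column."""
    oo = zygote.overlaps_mask(oocyte, min_overlap)
    sp = zygote.overlaps_mask(sperm, min_overlap)
    labels = np.where(
        oo & sp, "shared", np.where(oo, "oocyte-only", np.where(sp, "sperm-only", "de novo"))
    )
    out = zygote.df[["chrom", "start", "end"]].copy()
    out["inheritance"] = labels
    return out


def stage_scale_factor(
    reference: PeakSet,
    other: PeakSet,
    top_fraction: float = 0.25,
    center: str = "median",
) -> float:
    """Cross-stage normalization factor.

    Assumes the most strongly marked regions are fully modified in every
    stage: the median signal_mean of the top-25% peaks should agree between
    stages. factor = median(reference top-25%) / median(other top-25%);
    multiplying the other stage's signal by the factor equalizes the two
    medians exactly.
    """
    for name, ps in (("reference", reference), ("other", other)):
        if len(ps) < 4:
            raise ValueError(f"{name} set has fewer than 4 peaks")
        if not ps.scored:
            raise ValueError(f"{name} set is unscored")
    centerfn = np.median if center == "median" else np.mean
    vals = []
    for ps in (reference, other):
        means = np.sort(ps.df["signal_mean"].to_numpy())[::-1]
        k = math.ceil(top_fraction * means.size)
        vals.append(float(centerfn(means[:k])))
    if vals[1] == 0:
        raise ValueError("other set top-quantile center is zero")
    return vals[0] / vals[1]
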