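"""Transposable-element enrichment and expression statistics.

Enrichment per repeat family is observed/expected: the fraction of total
peak length falling in the family's elements versus the fraction of the
genome the family occupies. Expression profiles count fragments over
non-exonic elements, normalize by library size, and z-score each family
across stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import ChromSizes, IntervalSet, intersect_length
from .io import RepeatElement
from .domains import PeakSet

__all__ = ["EnrichmentRecord", "repeat_enrichment", "repeat_expression_profile"]


@dataclass(frozen=True)
class EnrichmentRecord:
    family: str
    observed: float
    expected: float

    @property
    def ratio(self) -> float:
        return self.observed / self.expected


def _family_sets(repeats: Sequence[RepeatElement]) -> Dict[str, IntervalSet]:
    by_family: Dict[str, list] = {}
    for rep in repeats:
        by_family.setdefault(rep.family, []).append(rep.interval)
    return {fam: IntervalSet.from_intervals(ivs) for fam, ivs in by_family.items()}


def repeat_enrichment(
    peaks: PeakSet,
    repeats: Sequence[RepeatElement],
    genome: ChromSizes,
    families: Optional[Sequence[str]] = None,
) -> Dict[str, EnrichmentRecord]:
    """Observed/expected peak enrichment per repeat family.

    observed = bp of peaks inside the family / total peak bp;
    expected = family bp / genome bp. Under uniform random peak placement
    the expected ratio is 1.
    """
    peak_iv = peaks.intervals().merge()
    total_peak = peak_iv.total_length
    if total_peak == 0:
        raise ValueError("total peak length is zero")
    sets = _family_sets(repeats)
    if families is None:
        families = sorted(sets)
    out = {}
    for fam in families:
        if fam not in sets:
            raise ValueError(f"repeat family {fam!r} absent from annotation")
        fam_iv = sets[fam].merge()
        fam_len = fam_iv.total_length
        if fam_len == 0:
            raise ValueError(f"repeat family {fam!r} has zero total length")
        observed = intersect_length(peak_iv, fam_iv) / total_peak
        expected = fam_len / genome.total_length
        out[fam] = EnrichmentRecord(fam, observed, expected)
    return out


def repeat_expression_profile(
    fragments_per_stage: Dict[str, IntervalSet],
    repeats: Sequence[RepeatElement],
    exons: IntervalSet,
    exon_overlap_max: float = 0.5,
) -> pd.DataFrame:
    """Family x stage expression profile.

    Elements with >= ``exon_overlap_max`` of their length inside exons are
    excluded (protein-coding transcription would confound them). Fragments
    overlapping a remaining element (>= 1 bp) are counted per family, divided
    by library size in millions, then z-scored across stages per family.
    Zero-variance families get a zero vector and are flagged in the
    ``flat`` attribute column.
    """
    if len(fragments_per_stage) < 2:
        raise ValueError("z-scoring requires at least two stages")
    exons_merged = exons.merge()
    kept: Dict[str, IntervalSet] = {}
    for rep in repeats:
        iv = rep.interval
        single = IntervalSet.from_intervals([iv])
        ov = intersect_length(single, exons_merged)
        if ov >= exon_overlap_max * iv.length:
            continue
        kept.setdefault(rep.family, []).append(iv)
    kept_sets = {
        fam: IntervalSet.from_intervals(ivs).merge() for fam, ivs in kept.items()
    }
    stages = list(fragments_per_stage)
    counts = pd.DataFrame(0.0, index=sorted(kept_sets), columns=stages)
    for stage, frags in fragments_per_stage.items():
        lib_millions = len(frags) / 1e6
        for fam, fam_iv in kept_sets.items():
            n = _count_overlapping(frags, fam_iv)
            counts.loc[fam, stage] = n / lib_millions if lib_millions > 0 else 0.0
    means = counts.mean(axis=1)
    sds = counts.std(axis=1, ddof=0)
    flat = sds == 0
    z = counts.sub(means, axis=0).div(sds.where(~flat, 1.0), axis=0)
    z[flat] = 0.0
    z["flat"] = flat
    return z


def _count_overlapping(fragments: IntervalSet, elements: IntervalSet) -> int:
    """Number of fragments overlapping any element by >= 1 bp."""
    total = 0
    for chrom in fragments.chroms():
        fs, fe = fragments.arrays(chrom)
        es, ee = elements.arrays(chrom)
        if not fs.size or not es.size:
            continue
        # fragment overlaps iff some element with start < frag end and end > frag start
        idx = np.searchsorted(es, fe - 1, side="right")  # elements starting before frag end
        # farthest element end up to idx
        run_max_end = np.maximum.accumulate(ee)
        prev = np.where(idx > 0, run_max_end[np.maximum(idx - 1, 0)], -1)
        total += int(np.sum((idx > 0) & (prev > fs)))
    return total
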