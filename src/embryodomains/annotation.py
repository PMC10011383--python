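"""Genomic-element assignment of peaks and peak-to-gene linking.

A peak is assigned to the highest-priority element class it overlaps by at
least 150 bp, with priority promoter > TES > exon > intron > intergenic.
Distal (non-promoter) peaks are linked to genes whose TSS lies within
300 kb of the peak center; the closest-TSS gene is reported separately with
lexicographic tie-breaking.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet
from .io import GeneModel
from .domains import PeakSet
from .tracks import BinnedTrack

__all__ = [
    "ELEMENT_PRIORITY",
    "build_element_sets",
    "assign_elements",
    "promoter_signal",
    "mark_promoters",
    "link_distal_peaks",
]

ELEMENT_PRIORITY = ("promoter", "TES", "exon", "intron", "intergenic")
MIN_ELEMENT_OVERLAP = 150


def build_element_sets(
    genes: Sequence[GeneModel], genome: Optional[ChromSizes] = None
) -> Dict[str, IntervalSet]:
    """Element intervals per class. Introns are gene bodies minus exons minus
    that gene's promoter/TES windows; elements are kept as individual
    intervals (the 150-bp rule applies per element)."""
    promoters, tes, exons, introns = [], [], [], []
    for g in genes:
        promoters.append(g.promoter(genome))
        tes.append(g.tes_region(genome))
        exons.extend(g.exons)
        body = IntervalSet.from_intervals(
            [GenomicInterval(g.chrom, min(g.tx_start, g.tx_end), max(g.tx_start, g.tx_end))]
        )
        cut = IntervalSet.from_intervals(
            list(g.exons) + [g.promoter(genome), g.tes_region(genome)]
        )
        introns.extend(body.subtract(cut))
    return {
        "promoter": IntervalSet.from_intervals(promoters),
        "TES": IntervalSet.from_intervals(tes),
        "exon": IntervalSet.from_intervals(exons),
        "intron": IntervalSet.from_intervals(introns),
    }


def _max_single_overlap(iv: GenomicInterval, elements: IntervalSet) -> int:
    """Largest overlap between the peak and any single element interval."""
    starts, ends = elements.arrays(iv.chrom)
    if not starts.size:
        return 0
    ov = np.minimum(ends, iv.end) - np.maximum(starts, iv.start)
    return int(max(0, ov.max()))


def assign_elements(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    genome: Optional[ChromSizes] = None,
    min_overlap: int = MIN_ELEMENT_OVERLAP,
) -> pd.DataFrame:
    """Assign every peak to exactly one element class (a partition).

    The peak gets the highest-priority class containing an element it
    overlaps by >= min_overlap bp; intergenic otherwise.
    """
    element_sets = build_element_sets(genes, genome)
    labels = []
    for iv in peaks:
        label = "intergenic"
        for cls in ELEMENT_PRIORITY[:-1]:
            if _max_single_overlap(iv, element_sets[cls]) >= min_overlap:
                label = cls
                break
        labels.append(label)
    out = peaks.df[["chrom", "start", "end"]].copy()
    out["element"] = labels
    return out


def promoter_signal(
    gene: GeneModel,
    sample: BinnedTrack,
    input_track: BinnedTrack,
    genome: Optional[ChromSizes] = None,
) -> float:
    """Input-subtracted promoter signal: mean FPKM over the promoter window
    for the sample minus the same for input, floored at 0."""
    if not sample.same_shape(input_track):
        raise ValueError("sample and input tracks have mismatched binning")
    prom = gene.promoter(genome if genome is not None else sample.genome)
    return max(sample.mean_over(prom) - input_track.mean_over(prom), 0.0)


def mark_promoters(
    genes: Sequence[GeneModel],
    peaks: PeakSet,
    genome: Optional[ChromSizes] = None,
    min_overlap: int = 1,
) -> pd.Series:
    """Per-gene boolean: does any peak overlap the promoter by >= min_overlap
    bp (default any overlap; set 150 for the element-assignment rule)."""
    peak_iv = peaks.intervals()
    marked = {}
    for g in genes:
        prom = g.promoter(genome)
        marked[g.gene_id] = _max_single_overlap(prom, peak_iv) >= min_overlap
    return pd.Series(marked, name="promoter_marked")


def link_distal_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    radius: int = 300_000,
) -> pd.DataFrame:
    """Link each distal peak to all genes with |TSS - peak center| <= radius
    and report the closest-TSS gene (ties broken by gene id order).

    Callers are expected to pass peaks already classified as distal
    (non-promoter). Returns one row per peak with the linked gene-id list
    and the closest gene (None if no gene within radius).
    """
    by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    rows = []
    for r in peaks.df.itertuples():
        center = (int(r.start) + int(r.end)) // 2
        cand = by_chrom.get(r.chrom, [])
        linked = [
            (abs(tss - center), gid) for tss, gid in cand if abs(tss - center) <= radius
        ]
        linked.sort()  # distance, then gene id (lexicographic tie-break)
        rows.append(
            {
                "chrom": r.chrom,
                "start": int(r.start),
                "end": int(r.end),
                "linked_genes": ",".join(gid for _, gid in linked),
                "closest_gene": linked[0][1] if linked else None,
                "closest_distance": linked[0][0] if linked else np.nan,
            }
        )
    return pd.DataFrame(rows)
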