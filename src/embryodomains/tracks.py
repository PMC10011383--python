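"""Binned tag-density tracks and the signal operations built on them.

A :class:`BinnedTrack` holds one value array per chromosome at a fixed bin
width. The canonical tag-density unit is FPKM — fragments per kilobase of
bin per million mapped fragments — computed over non-overlapping windows
(5 kb genome-wide density, 100 bp for peak scoring, 10–50 bp for profiles
and heat maps).
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet

__all__ = [
    "BinnedTrack",
    "bin_fragments",
    "fpkm_normalize",
    "subtract_input",
    "subsample_fragments",
    "correlation_matrix",
    "profile_around",
]


class BinnedTrack:
    """Fixed-width per-chromosome bin values.

    ``semantics`` is one of ``counts``, ``fpkm``, ``subtracted`` and is
    carried along so downstream operations can assert what they receive.
    The terminal bin of each chromosome may be partial; its true length is
    used for FPKM normalization.
    """

    def __init__(
        self,
        genome: ChromSizes,
        bin_width: int,
        values: Optional[Dict[str, np.ndarray]] = None,
        semantics: str = "counts",
    ):
        if bin_width <= 0:
            raise ValueError("bin width must be positive")
        self.genome = genome
        self.bin_width = int(bin_width)
        self.semantics = semantics
        self.values: Dict[str, np.ndarray] = {}
        for chrom, length in genome.items():
            n = math.ceil(length / bin_width)
            if values is not None and chrom in values:
                arr = np.asarray(values[chrom], dtype=np.float64)
                if arr.size != n:
                    raise ValueError(
                        f"{chrom}: expected {n} bins, got {arr.size}"
                    )
                self.values[chrom] = arr.copy()
            else:
                self.values[chrom] = np.zeros(n, dtype=np.float64)

    def n_bins(self, chrom: str) -> int:
        return self.values[chrom].size

    def bin_length(self, chrom: str, index: int) -> int:
        """Actual bp length of a bin (terminal bin may be partial)."""
        full = self.bin_width
        length = self.genome[chrom]
        return min(full, length - index * full)

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def same_shape(self, other: "BinnedTrack") -> bool:
        return (
            self.genome == other.genome and self.bin_width == other.bin_width
        )

    def concat(self) -> np.ndarray:
        """All bins as one vector, chromosomes in genome order."""
        return np.concatenate([self.values[c] for c in self.genome])

    def mean_over(self, region: GenomicInterval) -> float:
        """Overlap-weighted mean track value over an arbitrary region."""
        vals = self.values[region.chrom]
        bw = self.bin_width
        lo = region.start // bw
        hi = (region.end - 1) // bw
        idx = np.arange(lo, hi + 1)
        bin_starts = idx * bw
        bin_ends = np.minimum(bin_starts + bw, self.genome[region.chrom])
        weights = np.minimum(bin_ends, region.end) - np.maximum(
            bin_starts, region.start
        )
        weights = np.clip(weights, 0, None).astype(float)
        if weights.sum() == 0:
            return 0.0
        return float(np.average(vals[idx], weights=weights))

    def to_bedgraph(self, path) -> None:
        """One line per non-zero bin: chrom, start, end, value."""
        with open(path, "w") as fh:
            for chrom in self.genome:
                vals = self.values[chrom]
                nz = np.flatnonzero(vals != 0)
                bw = self.bin_width
                length = self.genome[chrom]
                for i in nz:
                    start = int(i) * bw
                    end = min(start + bw, length)
                    fh.write(f"{chrom}\t{start}\t{end}\t{vals[i]:.10g}\n")

    @classmethod
    def from_bedgraph(cls, path, genome: ChromSizes) -> "BinnedTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
        if df.empty:
            raise ValueError(f"{path}: empty bedGraph; bin width undeterminable")
        bin_width = int((df["end"] - df["start"]).max())
        track = cls(genome, bin_width)
        for chrom, sub in df.groupby("chrom"):
            if chrom not in genome:
                raise ValueError(f"{path}: unknown chromosome {chrom!r}")
            if np.any(sub["start"] % bin_width != 0):
                line = int(sub.index[sub["start"] % bin_width != 0][0]) + 1
                raise ValueError(f"{path}: line {line} not on the bin grid")
            idx = sub["start"].to_numpy() // bin_width
            track.values[chrom][idx] = sub["value"].to_numpy()
        return track

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinnedTrack)
            and self.same_shape(other)
            and all(
                np.allclose(self.values[c], other.values[c], rtol=1e-9, atol=0)
                for c in self.genome
            )
        )


def bin_fragments(
    fragments: IntervalSet, genome: ChromSizes, bin_width: int
) -> BinnedTrack:
    """Count fragments per bin, assigning each fragment to the bin holding
    its midpoint (floor convention: a midpoint exactly on a boundary belongs
    to the bin starting there). Conserves fragment count."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    fragments.validate_against(genome)
    track = BinnedTrack(genome, bin_width, semantics="counts")
    for chrom in fragments.chroms():
        starts, ends = fragments.arrays(chrom)
        if not starts.size:
            continue
        mids = (starts + ends) // 2
        idx = mids // bin_width
        np.add.at(track.values[chrom], idx, 1.0)
    return track


def fpkm_normalize(track: BinnedTrack, library_size: int) -> BinnedTrack:
    """FPKM per bin: count / (bin length in kb x library size in millions).

    Terminal partial bins use their actual length, so edge bins are not
    inflated.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    if track.semantics != "counts":
        raise ValueError(f"expected a counts track, got {track.semantics!r}")
    out = BinnedTrack(track.genome, track.bin_width, semantics="fpkm")
    millions = library_size / 1e6
    for chrom, length in track.genome.items():
        n = track.n_bins(chrom)
        lengths_kb = np.full(n, track.bin_width / 1000.0)
        tail = length - (n - 1) * track.bin_width
        lengths_kb[-1] = tail / 1000.0
        out.values[chrom] = track.values[chrom] / (lengths_kb * millions)
    return out


def subtract_input(sample: BinnedTrack, input_track: BinnedTrack) -> BinnedTrack:
    """Per-bin sample minus input, floored at zero."""
    if not sample.same_shape(input_track):
        raise ValueError("sample and input tracks have mismatched binning")
    out = BinnedTrack(sample.genome, sample.bin_width, semantics="subtracted")
    for chrom in sample.genome:
        out.values[chrom] = np.maximum(
            sample.values[chrom] - input_track.values[chrom], 0.0
        )
    return out


def subsample_fragments(fragments: IntervalSet, n: int, seed: int) -> IntervalSet:
    """Uniform sample of ``n`` fragments without replacement (deterministic
    under ``seed``); emulates down-sampling libraries to a common depth
    before peak calling."""
    total = len(fragments)
    if n > total:
        raise ValueError(f"cannot sample {n} of {total} fragments")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(total, size=n, replace=False))
    chroms_list, starts_list, ends_list = [], [], []
    offset = 0
    out_data = {}
    for chrom in fragments.chroms():
        starts, ends = fragments.arrays(chrom)
        lo = np.searchsorted(keep, offset, side="left")
        hi = np.searchsorted(keep, offset + starts.size, side="left")
        local = keep[lo:hi] - offset
        if local.size:
            out_data[chrom] = (starts[local], ends[local])
        offset += starts.size
    return IntervalSet(out_data)


def correlation_matrix(tracks: Sequence[BinnedTrack]) -> np.ndarray:
    """Pearson r between every pair of tracks over all genome bins.

    A constant track has undefined correlation; the corresponding entries
    are NaN and a warning is emitted rather than silently reporting 0.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if not t.same_shape(first):
            raise ValueError("tracks have mismatched binning")
    data = np.vstack([t.concat() for t in tracks])
    constant = data.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant track(s): correlation undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    np.fill_diagonal(r, np.where(constant, np.nan, 1.0))
    return r


def profile_around(
    anchors: Sequence[Tuple[str, int, str]],
    track: BinnedTrack,
    half_window: int = 2000,
    profile_bin: int = 20,
) -> np.ndarray:
    """Average signal profile around anchor positions.

    ``anchors`` are (chrom, position, strand) triples — e.g. peak centers or
    TSSs. The window [-half_window, +half_window) is cut into profile bins
    (200 bins for +/-2 kb at 20 bp); each entry is the mean over anchors of
    the overlap-weighted mean track value in that bin, with minus-strand
    anchors flipped. Bins falling off the chromosome are excluded from the
    anchor average rather than zero-filled.
    """
    if half_window % profile_bin != 0:
        raise ValueError("window must be divisible by the profile bin width")
    n_bins = 2 * half_window // profile_bin
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for chrom, pos, strand in anchors:
        length = track.genome[chrom]
        for j in range(n_bins):
            a = pos - half_window + j * profile_bin
            b = a + profile_bin
            if a < 0 or b > length:
                continue
            v = track.mean_over(GenomicInterval(chrom, a, b))
            k = n_bins - 1 - j if strand == "-" else j
            sums[k] += v
            counts[k] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / counts, np.nan)
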