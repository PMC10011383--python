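"""Genomic interval primitives: chromosome tables, intervals, and interval-set algebra.

All coordinates are 0-based half-open (BED convention). ``IntervalSet`` stores
per-chromosome start/end arrays and is the currency every analysis module
trades in; merge/intersect/coverage are exact (verified against a per-base
boolean-mask oracle in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Mapping, Tuple

import numpy as np

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "IntervalSet",
    "merge_intervals",
    "intersect_length",
    "coverage_fraction",
]


class ChromSizes:
    """Ordered chromosome name -> length (bp) table."""

    def __init__(self, sizes: Mapping[str, int]):
        self._sizes: Dict[str, int] = {}
        for name, length in sizes.items():
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name: {name!r}")
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._sizes[str(name)] = length

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes

    def items(self):
        return self._sizes.items()

    def names(self):
        return list(self._sizes)

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open region [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """Per-chromosome sorted start/end arrays.

    Not necessarily non-overlapping until :meth:`merge` is applied. Strand is
    not tracked here; strand-aware objects (genes, anchors) live elsewhere.
    """

    def __init__(self, data: Mapping[str, Tuple[np.ndarray, np.ndarray]] | None = None):
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (starts, ends) in data.items():
                self._set_chrom(chrom, np.asarray(starts), np.asarray(ends))

    def _set_chrom(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.shape != ends.shape:
            raise ValueError("starts and ends differ in length")
        if starts.size and (np.any(starts < 0) or np.any(starts >= ends)):
            bad = int(np.flatnonzero((starts < 0) | (starts >= ends))[0])
            raise ValueError(
                f"invalid interval {chrom}:{starts[bad]}-{ends[bad]} "
                "(require 0 <= start < end)"
            )
        order = np.lexsort((ends, starts))
        self._data[str(chrom)] = (starts[order], ends[order])

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        by_chrom: Dict[str, list] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        out = cls()
        for chrom, pairs in by_chrom.items():
            arr = np.asarray(pairs, dtype=np.int64)
            out._set_chrom(chrom, arr[:, 0], arr[:, 1])
        return out

    @classmethod
    def from_arrays(cls, chroms, starts, ends) -> "IntervalSet":
        chroms = np.asarray(chroms)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out = cls()
        for chrom in np.unique(chroms):
            mask = chroms == chrom
            out._set_chrom(str(chrom), starts[mask], ends[mask])
        return out

    def chroms(self):
        return sorted(self._data)

    def arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        if chrom not in self._data:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._data[chrom]

    def __len__(self) -> int:
        return sum(s.size for s, _ in self._data.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms():
            starts, ends = self._data[chrom]
            for s, e in zip(starts, ends):
                yield GenomicInterval(chrom, int(s), int(e))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chroms() != other.chroms():
            return False
        for chrom in self.chroms():
            s1, e1 = self.arrays(chrom)
            s2, e2 = other.arrays(chrom)
            if not (np.array_equal(s1, s2) and np.array_equal(e1, e2)):
                return False
        return True

    @property
    def total_length(self) -> int:
        """Total bp covered; exact even when intervals overlap."""
        merged = self.merge()
        return int(
            sum((e - s).sum() for s, e in (merged._data[c] for c in merged._data))
        )

    def validate_against(self, genome: ChromSizes) -> None:
        for chrom, (starts, ends) in self._data.items():
            if chrom not in genome:
                raise ValueError(f"interval on unknown chromosome {chrom!r}")
            if ends.size and ends.max() > genome[chrom]:
                raise ValueError(
                    f"interval end {int(ends.max())} exceeds length of {chrom} "
                    f"({genome[chrom]})"
                )

    def merge(self, gap: int = 0) -> "IntervalSet":
        return merge_intervals(self, gap)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-wise intersection (both sides merged first)."""
        a, b = self.merge(), other.merge()
        out = IntervalSet()
        for chrom in a.chroms():
            s1, e1 = a.arrays(chrom)
            s2, e2 = b.arrays(chrom)
            if not s1.size or not s2.size:
                continue
            starts, ends = _intersect_sorted(s1, e1, s2, e2)
            if starts.size:
                out._set_chrom(chrom, starts, ends)
        return out

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases of self not covered by other (both sides merged first)."""
        a, b = self.merge(), other.merge()
        out = IntervalSet()
        for chrom in a.chroms():
            s1, e1 = a.arrays(chrom)
            s2, e2 = b.arrays(chrom)
            keep_s, keep_e = [], []
            j = 0
            for s, e in zip(s1, e1):
                cur = s
                while j < s2.size and e2[j] <= cur:
                    j += 1
                k = j
                while k < s2.size and s2[k] < e:
                    if s2[k] > cur:
                        keep_s.append(cur)
                        keep_e.append(s2[k])
                    cur = max(cur, e2[k])
                    k += 1
                if cur < e:
                    keep_s.append(cur)
                    keep_e.append(e)
            if keep_s:
                out._set_chrom(chrom, np.asarray(keep_s), np.asarray(keep_e))
        return out

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, chroms={self.chroms()})"


def _intersect_sorted(s1, e1, s2, e2):
    """Intersection of two sorted, non-overlapping interval lists on one chrom."""
    out_s, out_e = [], []
    i = j = 0
    while i < s1.size and j < s2.size:
        lo = max(s1[i], s2[j])
        hi = min(e1[i], e2[j])
        if lo < hi:
            out_s.append(lo)
            out_e.append(hi)
        if e1[i] < e2[j]:
            i += 1
        else:
            j += 1
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge_intervals(s: IntervalSet, gap: int = 0) -> IntervalSet:
    """Union intervals separated by at most ``gap`` bp.

    Two intervals merge when ``next.start - prev.end <= gap`` (inclusive), so a
    5-kb merge joins peaks separated by exactly 5000 bp. Idempotent.
    """
    if gap < 0:
        raise ValueError(f"gap must be non-negative, got {gap}")
    out = IntervalSet()
    for chrom in s.chroms():
        starts, ends = s.arrays(chrom)
        if not starts.size:
            continue
        # running maximum of ends handles contained intervals
        run_end = np.maximum.accumulate(ends)
        new_group = np.ones(starts.size, dtype=bool)
        new_group[1:] = starts[1:] - run_end[:-1] > gap
        group = np.cumsum(new_group) - 1
        n_groups = group[-1] + 1
        m_starts = np.zeros(n_groups, dtype=np.int64)
        m_ends = np.zeros(n_groups, dtype=np.int64)
        m_starts[group[new_group]] = starts[new_group]
        np.maximum.at(m_ends, group, ends)
        out._set_chrom(chrom, m_starts, m_ends)
    return out


def intersect_length(a: IntervalSet, b: IntervalSet) -> int:
    """Total number of bases covered by both sets. Symmetric."""
    inter = a.intersect(b)
    return int(sum((e - s).sum() for s, e in (inter.arrays(c) for c in inter.chroms())))


def coverage_fraction(s: IntervalSet, genome: ChromSizes) -> float:
    """Fraction of the genome covered by the (merged) set, in [0, 1]."""
    s.validate_against(genome)
    return s.total_length / genome.total_length
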