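"""Readers and writers for the plain-text dialects the pipeline consumes.

Dialects: BED3/BED6, bedGraph, chrom.sizes, a refGene-like gene TSV, a
RepeatMasker-like repeat TSV, a per-CpG methylation TSV, and a
feature-by-stage matrix TSV. Coordinates are kept 0-based half-open
throughout; every reader validates and reports the first offending line
number on malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet

__all__ = [
    "GeneModel",
    "RepeatElement",
    "CpGTable",
    "read_table",
    "write_table",
]

PROMOTER_FLANK = 2500  # TSS +/- 2.5 kb
TES_FLANK = 2500  # TTS +/- 2.5 kb


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene collapsed to its longest transcript.

    The TSS of a minus-strand gene is the rightmost transcript coordinate;
    promoter (TSS +/- 2.5 kb) and TES (TTS +/- 2.5 kb) windows are clipped to
    chromosome bounds rather than rejected.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"gene {self.gene_id}: invalid transcript bounds")
        for ex in self.exons:
            if ex.start < self.tx_start or ex.end > self.tx_end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside "
                    f"transcript [{self.tx_start}, {self.tx_end})"
                )

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tts(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start

    def promoter(self, genome: Optional[ChromSizes] = None) -> GenomicInterval:
        return self._window(self.tss, PROMOTER_FLANK, genome)

    def tes_region(self, genome: Optional[ChromSizes] = None) -> GenomicInterval:
        return self._window(self.tts, TES_FLANK, genome)

    def _window(self, center: int, flank: int, genome) -> GenomicInterval:
        start = max(0, center - flank)
        end = center + flank
        if genome is not None:
            end = min(end, genome[self.chrom])
        if start >= end:
            raise ValueError(
                f"gene {self.gene_id}: window around {center} clips to empty"
            )
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass(frozen=True)
class RepeatElement:
    interval: GenomicInterval
    family: str
    repeat_class: str = ""

    def __post_init__(self):
        if not self.family:
            raise ValueError("repeat family must be non-empty")


class CpGTable:
    """Per-CpG methylation level and read coverage, sorted by (chrom, pos)."""

    COLUMNS = ["chrom", "pos", "meth", "cov"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"CpG table missing columns {missing}")
        df = df[self.COLUMNS].copy()
        bad = ~df["meth"].between(0.0, 1.0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"CpG row {i}: methylation {df['meth'].iloc[i]} outside [0, 1]"
            )
        if (df["cov"] < 0).any():
            raise ValueError("CpG coverage must be >= 0")
        self.df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CpGTable) and self.df.equals(other.df)

    def in_region(self, region: GenomicInterval) -> pd.DataFrame:
        sub = self.df[self.df["chrom"] == region.chrom]
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        return sub.iloc[lo:hi]


# ---------------------------------------------------------------------------
# read / write dispatch
# ---------------------------------------------------------------------------

_KINDS = ("bed", "bedgraph", "genes", "repeats", "cpg", "matrix", "chromsizes")


def _read_tsv(path, names, dtypes, kind):
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=names, comment="#", dtype=str
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    if df.isna().any(axis=None):
        line = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: malformed {kind} line {line} (missing field)")
    for col, dt in dtypes.items():
        try:
            df[col] = df[col].astype(dt)
        except ValueError:
            conv = pd.to_numeric(df[col], errors="coerce")
            line = int(conv.isna().idxmax()) + 1
            raise ValueError(
                f"{path}: malformed {kind} line {line} (bad value in column {col!r})"
            ) from None
    return df


def read_table(path, kind: str, genome: Optional[ChromSizes] = None):
    """Read a typed collection from a text file.

    Parameters
    ----------
    path : str or Path
    kind : one of {bed, bedgraph, genes, repeats, cpg, matrix, chromsizes}
    genome : required for ``bedgraph`` (defines the track shape) and used for
        bounds validation elsewhere when given.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {_KINDS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if kind == "chromsizes":
        df = _read_tsv(path, ["name", "length"], {"length": np.int64}, kind)
        return ChromSizes(dict(zip(df["name"], df["length"])))

    if kind == "bed":
        df = _read_tsv(
            path, ["chrom", "start", "end"], {"start": np.int64, "end": np.int64}, kind
        )
        bad = (df["start"] < 0) | (df["start"] >= df["end"])
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path}: malformed bed line {line} "
                f"(start {df['start'].iloc[line - 1]} >= end {df['end'].iloc[line - 1]})"
            )
        s = IntervalSet.from_arrays(
            df["chrom"].to_numpy(), df["start"].to_numpy(), df["end"].to_numpy()
        )
        if genome is not None:
            s.validate_against(genome)
        return s

    if kind == "bedgraph":
        from .tracks import BinnedTrack  # deferred: tracks imports this module

        if genome is None:
            raise ValueError("reading a bedGraph requires genome=ChromSizes")
        return BinnedTrack.from_bedgraph(path, genome)

    if kind == "cpg":
        df = _read_tsv(
            path,
            ["chrom", "pos", "meth", "cov"],
            {"pos": np.int64, "meth": float, "cov": np.int64},
            kind,
        )
        return CpGTable(df)

    if kind == "repeats":
        df = _read_tsv(
            path,
            ["chrom", "start", "end", "family", "repeat_class"],
            {"start": np.int64, "end": np.int64},
            kind,
        )
        return [
            RepeatElement(
                GenomicInterval(r.chrom, r.start, r.end), r.family, r.repeat_class
            )
            for r in df.itertuples()
        ]

    if kind == "genes":
        df = _read_tsv(
            path,
            ["gene_id", "chrom", "strand", "tx_start", "tx_end", "exon_starts", "exon_ends"],
            {"tx_start": np.int64, "tx_end": np.int64},
            kind,
        )
        genes = []
        for r in df.itertuples():
            ex_s = [
                int(x)
                for x in str(r.exon_starts).rstrip(",").split(",")
                if x and x != "."
            ]
            ex_e = [
                int(x) for x in str(r.exon_ends).rstrip(",").split(",") if x and x != "."
            ]
            if len(ex_s) != len(ex_e):
                raise ValueError(
                    f"{path}: gene {r.gene_id}: exonStarts/exonEnds length mismatch"
                )
            exons = tuple(
                GenomicInterval(r.chrom, s, e, r.strand) for s, e in zip(ex_s, ex_e)
            )
            genes.append(
                GeneModel(r.gene_id, r.chrom, r.strand, r.tx_start, r.tx_end, exons)
            )
        return genes

    if kind == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return df
    raise AssertionError("unreachable")


def write_table(collection, path, kind: str, genome: Optional[ChromSizes] = None):
    """Write a typed collection; ``read_table(write_table(x)) == x``."""
    if kind not in _KINDS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {_KINDS}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    if kind == "chromsizes":
        lines = [f"{name}\t{length}\n" for name, length in collection.items()]
        path.write_text("".join(lines))
    elif kind == "bed":
        with open(path, "w") as fh:
            for iv in collection:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    elif kind == "bedgraph":
        collection.to_bedgraph(path)
    elif kind == "cpg":
        collection.df.to_csv(path, sep="\t", header=False, index=False)
    elif kind == "repeats":
        with open(path, "w") as fh:
            for rep in collection:
                iv = rep.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rep.family}\t{rep.repeat_class}\n"
                )
    elif kind == "genes":
        with open(path, "w") as fh:
            for g in collection:
                ex_s = ",".join(str(e.start) for e in g.exons) or "."
                ex_e = ",".join(str(e.end) for e in g.exons) or "."
                fh.write(
                    f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                    f"\t{ex_s}\t{ex_e}\n"
                )
    elif kind == "matrix":
        collection.to_csv(path, sep="\t")
    return path
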