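"""Synthetic multi-stage embryo-like datasets with planted ground truth.

The generator emulates the data structure of a pre-/post-ZGA H3K27ac
stage series on a 10-Mb toy chromosome: pre-ZGA stages carry planted broad
enriched domains (10-60 kb, placed inside planted partially methylated
domains), post-ZGA stages carry narrow peaks (1-3 kb), some of them
stage-specific; a matched input library is uniform. Methylomes plant PMDs
(low methylation, defined CpG density), allelic tables plant biased peaks
over a binomial background, and expression matrices plant ZGA and
stage-specific genes.

Every stochastic draw comes from ``numpy.random.default_rng`` seeded from
``(config.seed, operation tag)`` — one PCG64 stream per operation — so a
fixed config seed reproduces every artifact byte-for-byte, and planted
truth is carried on the config for self-contained recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GenomicInterval, IntervalSet
from .io import CpGTable, GeneModel, RepeatElement

__all__ = [
    "StagePlan",
    "SimulationConfig",
    "default_config",
    "simulate_annotation",
    "simulate_chip",
    "simulate_methylome",
    "simulate_allelic",
    "simulate_expression",
    "simulate_repeat_rna",
]

# per-operation rng stream tags (second word of the seed sequence)
_TAG_ANNOTATION = 1
_TAG_CHIP = 2
_TAG_METHYLOME = 3
_TAG_ALLELIC = 4
_TAG_EXPRESSION = 5
_TAG_REPEAT_RNA = 6
_TAG_LAYOUT = 7


@dataclass(frozen=True)
class StagePlan:
    """One developmental stage: its label, ZGA status, and planted enriched
    regions as (start, end, fold) triples on the single simulated chromosome."""

    name: str
    pre_zga: bool
    domains: Tuple[Tuple[int, int, float], ...] = ()

    def __post_init__(self):
        for s, e, f in self.domains:
            if not 0 <= s < e:
                raise ValueError(f"stage {self.name}: bad planted region {s}-{e}")
            if f < 1:
                raise ValueError(f"stage {self.name}: enrichment fold {f} < 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything the generators need, planted truth included."""

    seed: int
    genome: ChromSizes
    stages: Tuple[StagePlan, ...]
    fragments_per_library: int = 1_000_000
    fragment_length: int = 200
    # methylome
    pmds: Tuple[Tuple[int, int], ...] = ()
    cpg_per_100bp: float = 1.0
    meth_inside: float = 0.35
    meth_outside: float = 0.85
    meth_concentration: float = 20.0
    meth_depth: float = 10.0
    # annotation
    n_genes: int = 200
    gene_length: int = 20_000
    repeat_fractions: Tuple[Tuple[str, float], ...] = (
        ("Alu", 0.05),
        ("ERVK", 0.04),
        ("ERV1", 0.03),
        ("SVA", 0.02),
    )
    dhs_length: int = 300
    n_background_dhs: int = 100
    # allelic
    rho: float = 0.5
    allelic_depth: float = 50.0
    allelic_bias: float = 0.95
    allelic_biased_fraction: float = 0.1
    # expression
    n_zga_genes: int = 40
    n_stage_specific_genes: int = 32
    specific_share: float = 0.95
    baseline_log_fpkm_mean: float = 0.0
    baseline_log_fpkm_sd: float = 0.6
    # repeat expression plants: family -> stage with elevated transcription
    repeat_rna_plants: Tuple[Tuple[str, str], ...] = (("ERVK", "2cell"), ("Alu", "8cell"))
    repeat_rna_fold: float = 10.0
    repeat_rna_fragments: int = 200_000

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise ValueError("allelic background fraction must be in (0, 1)")
        if not 0 < self.allelic_bias < 1:
            raise ValueError("planted allelic bias must be in (0, 1)")
        for m in (self.meth_inside, self.meth_outside):
            if not 0 <= m <= 1:
                raise ValueError("methylation means must lie in [0, 1]")
        total = sum(f for _, f in self.repeat_fractions)
        if total > 1:
            raise ValueError(f"repeat fractions sum to {total} > 1")
        chrom = self.chrom
        L = self.genome[chrom]
        for st in self.stages:
            for s, e, _ in st.domains:
                if e > L:
                    raise ValueError(
                        f"stage {st.name}: planted region {s}-{e} outside genome"
                    )
        for s, e in self.pmds:
            if not (0 <= s < e <= L):
                raise ValueError(f"planted PMD {s}-{e} outside genome")

    @property
    def chrom(self) -> str:
        return next(iter(self.genome))

    def stage(self, name: str) -> StagePlan:
        for st in self.stages:
            if st.name == name:
                return st
        raise KeyError(f"unknown stage {name!r}")

    @property
    def stage_names(self) -> List[str]:
        return [st.name for st in self.stages]

    def pmd_set(self) -> IntervalSet:
        if not self.pmds:
            return IntervalSet()
        arr = np.asarray(self.pmds, dtype=np.int64)
        return IntervalSet({self.chrom: (arr[:, 0], arr[:, 1])})

    def truth_domains(self, stage: str) -> IntervalSet:
        doms = self.stage(stage).domains
        if not doms:
            return IntervalSet()
        arr = np.asarray([(s, e) for s, e, _ in doms], dtype=np.int64)
        return IntervalSet({self.chrom: (arr[:, 0], arr[:, 1])})


def _rng(config: SimulationConfig, tag: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag, extra])


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

def _place_sequential(
    rng: np.random.Generator,
    lengths: np.ndarray,
    region_start: int,
    region_end: int,
    spacing: int,
) -> List[Tuple[int, int]]:
    """Place intervals of the given lengths left-to-right inside a region
    with at least ``spacing`` bp between them, distributing the slack
    randomly. Raises if the lengths cannot fit."""
    n = lengths.size
    need = int(lengths.sum()) + spacing * (n + 1)
    slack = (region_end - region_start) - need
    if slack < 0:
        raise ValueError("planted intervals do not fit in the region")
    cuts = np.sort(rng.integers(0, slack + 1, size=n)) if slack > 0 else np.zeros(n, int)
    out = []
    cursor = region_start
    prev_cut = 0
    for i in range(n):
        cursor += spacing + int(cuts[i] - prev_cut)
        prev_cut = int(cuts[i])
        out.append((cursor, cursor + int(lengths[i])))
        cursor += int(lengths[i])
    return out


def default_config(seed: int = 0) -> SimulationConfig:
    """The standard 4-stage study conditions on a 10-Mb chromosome.

    Pre-ZGA stages (2cell, 4cell) share 20 planted broad domains of
    10-60 kb at 5-fold enrichment, all inside planted PMDs (two sizes are
    pinned above 50 kb so the broad-domain classes are always populated).
    Post-ZGA stages (8cell, morula) share 60 narrow 1-3 kb peaks at 8-fold,
    plus 15 stage-specific peaks each.
    """
    L = 10_000_000
    genome = ChromSizes({"chrS": L})
    last_err = None
    for attempt in range(16):
        rng = np.random.default_rng([seed, _TAG_LAYOUT, attempt])
        try:
            return _build_default_layout(seed, genome, L, rng)
        except ValueError as err:  # a rare layout draw that does not fit
            last_err = err
    raise ValueError(f"could not build a default layout: {last_err}")


def _build_default_layout(
    seed: int, genome: ChromSizes, L: int, rng: np.random.Generator
) -> SimulationConfig:
    # PMDs: eight 10-kb-grid-aligned blocks of 250-400 kb
    pmd_cells = rng.integers(25, 41, size=8)  # in 10-kb units
    pmd_pairs = _place_sequential(
        rng, pmd_cells * 10_000, 0, L, spacing=200_000
    )
    pmds = tuple(
        (10_000 * (s // 10_000), 10_000 * (s // 10_000) + int(e - s))
        for s, e in pmd_pairs
    )

    # broad domains inside PMDs: 18 random 10-60 kb + two pinned > 50 kb
    sizes = np.concatenate(
        [rng.integers(10_000, 60_001, size=18), [55_000, 60_000]]
    )
    rng.shuffle(sizes)
    broad: List[Tuple[int, int, float]] = []
    i = 0
    for pmd_s, pmd_e in pmds:
        if i >= sizes.size:
            break
        take = []
        budget = pmd_e - pmd_s
        while i < sizes.size and sum(take) + int(sizes[i]) + 20_000 * (len(take) + 2) <= budget:
            take.append(int(sizes[i]))
            i += 1
        if take:
            placed = _place_sequential(
                rng, np.asarray(take), pmd_s, pmd_e, spacing=20_000
            )
            broad.extend((s, e, 5.0) for s, e in placed)
    if i < sizes.size:
        raise ValueError("default layout could not place all broad domains")

    # narrow peaks anywhere (spacing keeps them independent after linking)
    narrow_sizes = rng.integers(1_000, 3_001, size=90)
    narrow_all = _place_sequential(rng, narrow_sizes, 0, L, spacing=30_000)
    rng.shuffle(narrow_all)
    shared = [(s, e, 8.0) for s, e in narrow_all[:60]]
    spec_8c = [(s, e, 8.0) for s, e in narrow_all[60:75]]
    spec_mo = [(s, e, 8.0) for s, e in narrow_all[75:90]]

    stages = (
        StagePlan("2cell", True, tuple(broad)),
        StagePlan("4cell", True, tuple(broad)),
        StagePlan("8cell", False, tuple(sorted(shared + spec_8c))),
        StagePlan("morula", False, tuple(sorted(shared + spec_mo))),
    )
    return SimulationConfig(seed=seed, genome=genome, stages=stages, pmds=pmds)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimulationConfig,
) -> Tuple[List[GeneModel], List[RepeatElement], IntervalSet]:
    """Genes (non-overlapping bodies, 3 exons each), repeat elements at the
    configured genome fractions, and DHSs placed next to the planted
    post-ZGA peaks (plus uniform background sites)."""
    rng = _rng(config, _TAG_ANNOTATION)
    chrom = config.chrom
    L = config.genome[chrom]

    gene_lengths = np.full(config.n_genes, config.gene_length)
    bodies = _place_sequential(rng, gene_lengths, 0, L, spacing=10_000)
    genes = []
    for i, (s, e) in enumerate(bodies):
        strand = "+" if rng.random() < 0.5 else "-"
        # three exons: at the ends and middle of the body
        third = (e - s) // 3
        exons = tuple(
            GenomicInterval(chrom, a, b, strand)
            for a, b in (
                (s, s + 1_000),
                (s + third, s + third + 1_500),
                (e - 1_000, e),
            )
        )
        genes.append(GeneModel(f"gene{i:04d}", chrom, strand, s, e, exons))

    repeats: List[RepeatElement] = []
    occupied = IntervalSet()
    for family, fraction in config.repeat_fractions:
        target = fraction * L
        placed = 0.0
        elements = []
        guard = 0
        while placed < target and guard < 200_000:
            guard += 1
            size = int(rng.integers(300, 3_001))
            start = int(rng.integers(0, L - size))
            os_, oe_ = occupied.arrays(chrom)
            j = np.searchsorted(os_, start + size, side="left")
            clash = j > 0 and oe_[:j].max() > start
            if clash:
                continue
            elements.append((start, start + size))
            placed += size
            occupied = IntervalSet(
                {
                    chrom: (
                        np.concatenate([os_, [start]]),
                        np.concatenate([oe_, [start + size]]),
                    )
                }
            )
        for s, e in elements:
            repeats.append(
                RepeatElement(GenomicInterval(chrom, s, e), family, "retro")
            )

    dhs_positions = []
    for st in config.stages:
        if st.pre_zga:
            continue
        for s, e, _ in st.domains:
            if rng.random() < 0.9:
                center = (s + e) // 2 + int(rng.integers(-200, 201))
                dhs_positions.append(center)
    for _ in range(config.n_background_dhs):
        dhs_positions.append(int(rng.integers(0, L)))
    half = config.dhs_length // 2
    starts = np.clip(np.asarray(sorted(set(dhs_positions))) - half, 0, L - config.dhs_length)
    dhs = IntervalSet({chrom: (starts, starts + config.dhs_length)})
    return genes, repeats, dhs


def _weighted_fragment_sample(
    rng: np.random.Generator,
    L: int,
    plants: Sequence[Tuple[int, int, float]],
    n: int,
    frag_len: int,
) -> IntervalSet:
    """Draw fragment start positions from a piecewise-constant weight field
    (weight 1 outside planted regions, the fold inside)."""
    segs: List[Tuple[int, int, float]] = []
    cursor = 0
    for s, e, fold in sorted(plants):
        if s > cursor:
            segs.append((cursor, s, 1.0))
        segs.append((s, e, fold))
        cursor = e
    if cursor < L:
        segs.append((cursor, L, 1.0))
    seg_start = np.array([s for s, _, _ in segs], dtype=np.int64)
    seg_len = np.array([e - s for s, e, _ in segs], dtype=np.float64)
    weights = np.array([f for _, _, f in segs]) * seg_len
    probs = weights / weights.sum()
    seg_idx = rng.choice(len(segs), size=n, p=probs)
    starts = seg_start[seg_idx] + (rng.random(n) * seg_len[seg_idx]).astype(np.int64)
    starts = np.minimum(starts, L - frag_len)
    starts.sort()
    return IntervalSet({"__chrom__": (starts, starts + frag_len)})


def simulate_chip(
    config: SimulationConfig, stage: str
) -> Tuple[IntervalSet, IntervalSet]:
    """ChIP and matched input fragment sets for one stage.

    ChIP start positions follow the stage's planted weight field; input is
    uniform. Deterministic per (config seed, stage index).
    """
    plan = config.stage(stage)
    idx = config.stage_names.index(stage)
    chrom = config.chrom
    L = config.genome[chrom]
    n = config.fragments_per_library
    chip_rng = _rng(config, _TAG_CHIP, 2 * idx)
    input_rng = _rng(config, _TAG_CHIP, 2 * idx + 1)
    chip = _weighted_fragment_sample(
        chip_rng, L, plan.domains, n, config.fragment_length
    )
    inp = _weighted_fragment_sample(input_rng, L, (), n, config.fragment_length)
    rename = lambda s: IntervalSet({chrom: s.arrays("__chrom__")})
    return rename(chip), rename(inp)


def simulate_methylome(config: SimulationConfig) -> CpGTable:
    """CpG table at the configured density: Beta-distributed methylation with
    mean ``meth_inside`` within planted PMDs and ``meth_outside`` elsewhere,
    Poisson coverage around ``meth_depth``."""
    rng = _rng(config, _TAG_METHYLOME)
    chrom = config.chrom
    L = config.genome[chrom]
    n = int(round(config.cpg_per_100bp * L / 100))
    pos = np.unique(rng.integers(0, L, size=int(n * 1.05) + 16))
    if pos.size > n:
        pos = np.sort(rng.choice(pos, size=n, replace=False))

    inside = np.zeros(pos.size, dtype=bool)
    for s, e in config.pmds:
        inside |= (pos >= s) & (pos < e)

    k = config.meth_concentration
    mean = np.where(inside, config.meth_inside, config.meth_outside)
    meth = rng.beta(mean * k, (1 - mean) * k)
    cov = rng.poisson(config.meth_depth, size=pos.size)
    return CpGTable(
        pd.DataFrame({"chrom": chrom, "pos": pos, "meth": meth, "cov": cov})
    )


def simulate_allelic(
    config: SimulationConfig,
    peaks,
    biased_mask: Optional[np.ndarray] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Allelic SNP-informative read counts per peak.

    Total reads per peak are Poisson around ``allelic_depth``; maternal reads
    are binomial with the background fraction rho for null peaks and
    ``allelic_bias`` for planted biased peaks. Returns (table, truth).
    ``peaks`` may be a PeakSet or a DataFrame with chrom/start/end.
    """
    df = peaks.df if hasattr(peaks, "df") else pd.DataFrame(peaks)
    rng = _rng(config, _TAG_ALLELIC)
    n = len(df)
    if biased_mask is None:
        biased_mask = rng.random(n) < config.allelic_biased_fraction
    biased_mask = np.asarray(biased_mask, dtype=bool)
    total = rng.poisson(config.allelic_depth, size=n)
    frac = np.where(biased_mask, config.allelic_bias, config.rho)
    maternal = rng.binomial(total, frac)
    table = pd.DataFrame(
        {
            "peak_id": [f"peak{i:05d}" for i in range(n)],
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].to_numpy(),
            "end": df["end"].to_numpy(),
            "length": (df["end"] - df["start"]).to_numpy(),
            "maternal": maternal,
            "paternal": total - maternal,
        }
    )
    truth = pd.DataFrame(
        {"peak_id": table["peak_id"], "planted_biased": biased_mask}
    )
    return table, truth


def simulate_expression(
    config: SimulationConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x stage FPKM matrix with planted ZGA and stage-specific genes.

    Baseline genes draw i.i.d. log-normal FPKM per stage. Planted ZGA genes
    are near-silent pre-ZGA (< 0.5 FPKM) and activated post-ZGA (> 3x pre,
    > 1 FPKM). Planted stage-specific genes concentrate ``specific_share``
    of their total signal at one stage. Returns (matrix, truth).
    """
    if not config.stages:
        raise ValueError("no stages configured")
    rng = _rng(config, _TAG_EXPRESSION)
    stages = config.stage_names
    n_special = config.n_zga_genes + config.n_stage_specific_genes
    n_total = max(config.n_genes, n_special)
    ids = [f"gene{i:04d}" for i in range(n_total)]
    mat = rng.lognormal(
        config.baseline_log_fpkm_mean,
        config.baseline_log_fpkm_sd,
        size=(n_total, len(stages)),
    )
    order = rng.permutation(n_total)
    zga_idx = order[: config.n_zga_genes]
    spec_idx = order[config.n_zga_genes : n_special]

    pre = [i for i, st in enumerate(config.stages) if st.pre_zga]
    post = [i for i, st in enumerate(config.stages) if not st.pre_zga]
    for gi in zga_idx:
        mat[gi, pre] = rng.uniform(0.0, 0.4, size=len(pre))
        mat[gi, post] = rng.uniform(2.0, 10.0, size=len(post))

    spec_stage = rng.integers(0, len(stages), size=spec_idx.size)
    for gi, si in zip(spec_idx, spec_stage):
        total = rng.uniform(10.0, 30.0)
        rest = (1 - config.specific_share) / (len(stages) - 1)
        shares = np.full(len(stages), rest)
        shares[si] = config.specific_share
        mat[gi] = total * shares

    matrix = pd.DataFrame(mat, index=ids, columns=stages)
    truth = pd.DataFrame(
        {
            "gene_id": ids,
            "planted_zga": np.isin(np.arange(n_total), zga_idx),
            "planted_specific_stage": [
                stages[spec_stage[list(spec_idx).index(i)]] if i in spec_idx else ""
                for i in range(n_total)
            ],
        }
    )
    return matrix, truth


def simulate_repeat_rna(
    config: SimulationConfig,
    stage: str,
    repeats: Sequence[RepeatElement],
) -> IntervalSet:
    """RNA-like fragment set for transposon expression: uniform background
    with ``repeat_rna_fold`` extra weight over the elements of any family
    planted as transcribed at this stage."""
    idx = config.stage_names.index(stage)
    rng = _rng(config, _TAG_REPEAT_RNA, idx)
    chrom = config.chrom
    L = config.genome[chrom]
    plants = []
    active = {fam for fam, st in config.repeat_rna_plants if st == stage}
    if active:
        fam_ivs = [r.interval for r in repeats if r.family in active]
        merged = IntervalSet.from_intervals(fam_ivs).merge()
        s_, e_ = merged.arrays(chrom)
        plants = [(int(a), int(b), config.repeat_rna_fold) for a, b in zip(s_, e_)]
    frags = _weighted_fragment_sample(
        rng, L, plants, config.repeat_rna_fragments, config.fragment_length
    )
    return IntervalSet({chrom: frags.arrays("__chrom__")})


def write_truth(config: SimulationConfig, outdir) -> Dict[str, str]:
    """Emit planted-truth TSVs so downstream recovery tests are
    self-contained. Returns {name: path}."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    rows = []
    for st in config.stages:
        for s, e, f in st.domains:
            rows.append((st.name, config.chrom, s, e, f, st.pre_zga))
    p = outdir / "truth_domains.tsv"
    pd.DataFrame(
        rows, columns=["stage", "chrom", "start", "end", "fold", "pre_zga"]
    ).to_csv(p, sep="\t", index=False)
    paths["domains"] = str(p)
    p = outdir / "truth_pmds.tsv"
    pd.DataFrame(
        [(config.chrom, s, e) for s, e in config.pmds],
        columns=["chrom", "start", "end"],
    ).to_csv(p, sep="\t", index=False)
    paths["pmds"] = str(p)
    return paths
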