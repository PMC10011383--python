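# Methods

This note documents the models and procedures the package implements, the
defaults and why they are what they are, what the synthetic generator does
and does not emulate, and the numerical conventions that matter for
reproducibility.

## Coordinate and interval conventions

All coordinates are 0-based half-open (BED). Interval merging joins two
intervals when `next.start − prev.end ≤ gap` (inclusive), so a "within
5 kb" merge fires at exactly 5000 bp — matching the behavior of the common
genomics toolkits. Promoter (TSS ± 2.5 kb) and transcription-end (TTS ±
2.5 kb) windows are clipped at chromosome edges rather than rejected; the
TSS of a minus-strand gene is its rightmost transcript coordinate. Interval
algebra (merge, intersection length, genome coverage) is exact and is
property-tested against a per-base boolean-mask oracle.

## Tag density and signal

Fragment densities are FPKM over non-overlapping windows. A fragment is
assigned to the bin containing its midpoint (floor convention on
boundaries), which conserves fragment counts; terminal partial bins are
normalized by their actual length so edge bins are not inflated. Input
subtraction is per-bin `max(sample − input, 0)`: negative residuals carry
no information about acetylation and are floored, as is standard for
promoter-level ChIP quantification. Pearson correlation between tracks is
computed over all genome bins including zeros (configurable; the choice
mostly affects sparse marks), and a constant track yields NaN with a
warning rather than a silent zero.

## The enriched-domain caller

The caller is an explicitly simplified, self-contained re-expression of
broad-mode peak calling, not a port of any external tool; its entire
behavior is determined by `CallerParams`:

| parameter | default | meaning |
|---|---|---|
| `p_strong` | 1e-3 | per-bin Poisson tail for seed bins |
| `p_weak` | 0.01 | per-bin tail for extension bins |
| `max_gap` | 500 bp | linking distance between weak runs |
| `bin_width` | 100 bp | analysis resolution |
| `local_windows` | 5 kb, 10 kb | input windows for the local background |

Per bin, the background rate is `λ = max(genome-wide chip rate,
depth-scaled input mean over each local window)`; taking the maximum makes
the test conservative wherever the input fluctuates low, which is why the
null strong-bin rate stays below the nominal tail probability (measured
~6–8 × 10⁻⁴ against the 1e-3 nominal across seeds). The p-value is the
upper-tail Poisson probability `P(X ≥ k)`. Weak runs are linked by merging
their bp extents with gap `max_gap`, and a candidate survives only if it
contains at least one strong bin — seed-and-extend, expressed with interval
algebra. A stringent preset (`p = 1e-5`, no broad extension) serves narrow
putative-enhancer calling.

Downstream order matters and is fixed: score → keep top 75 % by signal sum
(nearest-rank quantile, ties at the threshold kept) → merge within 5 kb →
re-score. Length classes use strict thresholds (> 10 kb broad, > 20 kb,
> 50 kb).

## Cross-stage normalization

Broadly distributed acetylation dilutes per-bin FPKM, so pre-ZGA stages
are not directly comparable with post-ZGA stages. Under the assumption
that the most strongly marked regions are fully modified in every stage,
the median `signal_mean` of the top-25 % peaks should agree across stages;
the scale factor is the ratio of medians (reference / other). "Median" is
the interpretation adopted for the central value (configurable to mean).
Applying the factor equalizes the two medians to machine precision, and a
planted 3× signal scaling is recovered as a factor of 1/3 exactly, since
scaling every peak scales the median.

## PMDs and methylation summaries

PMDs are 10-kb tiling windows (from coordinate 0; the terminal partial
window uses its actual content) with unweighted mean CpG methylation < 0.5
over covered CpGs and strictly more than 20 covered CpGs, merged when
adjacent. "Covered" means coverage ≥ 1 by default (configurable); the mean
is unweighted by coverage — with merged single-cell methylomes, coverage
weighting would let a few deep CpGs dominate a window. Region methylation
is the unweighted mean over CpGs in the region and is NaN (flagged, not
erroring) when a region has no CpG; CpG density is sites per 100 bp.

## Stage specificity

For a feature with signal `E_i` across `N` stages, `R_i = E_i / Σ E` and
`H = −Σ R_i log₂ R_i` (bits), with `0·log₂ 0 ≡ 0`. `H` ranges from 0
(perfectly specific) to `log₂ N` (uniform); features with `H < 0.5` are
stage-specific and assigned to their argmax stage. All-zero features are
flagged undefined and excluded rather than scored. Entropy is applied to
raw (not log-transformed) FPKM-like values. In the pipeline, enhancer
entropy uses input-subtracted FPKM per peak: subtraction zeroes the
off-stage background so a peak enriched at one stage concentrates its
share there.

## Enhancers, eRNAs, ZGA genes, differential calls

Putative enhancers are distal (non-promoter) peaks with a DHS overlapping
the peak or within 500 bp of either edge. eRNAs further require no H3K4me3
overlap, no promoter/exon overlap, and RNA FPKM strictly above 0.5 at a
stage. ZGA genes require post-stage FPKM > 1 and fold > 3 versus the
pre-ZGA stage; fold changes use a 0.1-FPKM pseudocount (configurable, and
stated wherever folds are reported) to guard zero denominators.

Replicated count designs use a simplified two-sample count test: pooled
counts per condition, median-of-ratios size factors (robust to a minority
of strongly changed features distorting library totals), a conditional
binomial test on the pooled total, and Benjamini–Hochberg adjustment; calls
require both fold > 2 and FDR < 0.05 (a fold-only > 3 preset serves
designs without replication). This is a deliberately simple test — it does
not model per-replicate overdispersion — and its null calibration is
verified by simulation in the suite.

## Transposons and allelic peaks

Repeat-family enrichment is observed/expected: the fraction of total peak
bp inside the family versus the family's genome fraction; under uniform
random placement the ratio is 1 in expectation (verified by simulation).
Expression profiles exclude elements with ≥ 50 % of their length in exons
(the exclusion fraction is configurable; element-in-exon membership needs
some convention and half-length is the neutral one), count overlapping
fragments per family, normalize by library millions, and z-score across
stages; zero-variance families are flagged and zeroed.

Allelic testing requires ≥ 10 SNP-informative reads per kb. The expected
split under no bias is the dataset-wide maternal fraction ρ (estimated
from the table's own totals by default, overridable); the statistic is a
1-df χ² without continuity correction (Yates optional), BH-adjusted across
tested peaks. A call needs adjusted p < 0.001 **and** allelic ratio > 5 in
either direction (a zero denominator counts as infinite fold). At depth
~50 the fold filter dominates the null: a balanced peak essentially never
reaches a 5-fold imbalance, which is why 10,000 simulated null peaks yield
zero calls while planted 95:5 peaks with ≥ 30 informative reads are
detected with sensitivity > 0.99.

## The synthetic generator

The generator emulates the *structure* of a pre-/post-ZGA stage series,
not its sequence content: a single 10-Mb chromosome, 10⁶ single-interval
fragments of 200 bp per library (no pairing — the analyses consume
fragment densities only; large enough for stable Poisson statistics at
100-bp bins, small enough for minute-scale tests). Defaults:

- **Stages** 2cell, 4cell (pre-ZGA) and 8cell, morula (post-ZGA). Pre-ZGA
  stages share 20 planted broad domains (10–60 kb, 5-fold enrichment; two
  sizes pinned at 55 and 60 kb so the > 50 kb class is always populated),
  all placed inside planted PMDs — encoding the observed coupling between
  broad acetylation domains and hypomethylated regions. Post-ZGA stages
  share 60 narrow peaks (1–3 kb, 8-fold) plus 15 stage-specific peaks each.
- **Methylome**: CpGs at 1 site/100 bp, Beta-distributed methylation
  (concentration 20) with mean 0.35 inside PMDs and 0.85 outside, Poisson
  coverage at depth 10. Planted PMDs (eight blocks of 250–400 kb) are
  aligned to the 10-kb analysis grid, so boundary recovery is meaningful at
  window resolution.
- **Allelic**: Poisson depth 50, background maternal fraction 0.5, planted
  biased peaks at 95:5 in a 10 % subset.
- **Expression**: i.i.d. log-normal baseline (σ = 0.6 keeps baseline
  entropy far from the 0.5-bit threshold); 40 planted ZGA genes (pre-ZGA
  FPKM < 0.5, post-ZGA 2–10); 32 planted stage-specific genes with 95 % of
  signal at one stage (H ≈ 0.39 < 0.5 by construction).
- **Annotation**: 200 non-overlapping 20-kb genes with three exons; repeat
  families Alu/ERVK/ERV1/SVA at 5/4/3/2 % of the genome; DHSs placed at
  90 % of planted narrow peaks plus 100 background sites. The default
  H3K4me3-like peak set used by the eRNA stage is the promoter windows of
  the simulated genes (H3K4me3 marks active promoters).

Randomness: every draw comes from `numpy.random.default_rng` (PCG64)
seeded with `(config.seed, operation tag[, stream index])` — one stream per
operation — so a fixed seed reproduces every artifact byte-for-byte and
adding a stage does not shift other stages' draws. The rare layout draw
that cannot fit its planted intervals is retried on a derived stream, still
deterministically per seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mappability and GC bias, fragment-length
variation and PCR duplicates, chromosome-scale heterogeneity, SNP phasing
(allelic counts are generated directly, not from reads), biological
replicate structure, and genome-scale multiple testing (10 Mb vs 3 Gb).
Recovery rates measured here are upper bounds for data with those
artifacts.

## Problem sizes

Tests and the acceptance script run the generator at its default scale:
10-Mb genome, 10⁶ fragments per library, 10 null seeds for caller
calibration, 10,000 peaks for allelic calibration, 100 placements for the
enrichment null, 200 instances for the interval oracle. These sizes give
the planted effects comfortable statistical margins (e.g. ~50 vs ~10
expected fragments per 100-bp bin inside a 5-fold domain) while keeping a
full run in minutes.

## Known limitations

- The caller's λ uses truncated windows at chromosome edges; extreme edge
  bins are therefore tested against a slightly noisier background.
- The differential count test assumes Poisson-like variation between
  replicates; overdispersed data would need a negative-binomial model.
- `overlap_table` under the fraction criterion is intentionally
  asymmetric; Venn-style counts from it should state the criterion used.
- Entropy on raw FPKM weights high-signal stages heavily; log-scale
  entropy is a one-line preprocessing step away but is not the default.
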