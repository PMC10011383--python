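# embryodomains

Analysis toolkit for histone-acetylation dynamics across early embryonic
development — the transition from **broad H3K27ac domains** (10–60 kb regions
of contiguous enrichment found before zygotic genome activation, ZGA) to
**typical narrow peaks** after ZGA — together with the surrounding machinery
such a study needs: partially methylated domain (PMD) detection,
entropy-based stage specificity, putative-enhancer and eRNA definitions,
transposon enrichment, and allele-specific peak testing.

Real embryo ChIP-seq is scarce and noisy, so the package is built around a
**synthetic-data generator with planted ground truth**: a 10-Mb toy
chromosome carrying known broad domains, PMDs, biased allelic peaks, and
ZGA/stage-specific genes. Every analytical claim the package makes is
testable as a recovery problem against what was planted.

## What it computes

- **Tag density**: FPKM (fragments per kilobase per million mapped
  fragments) over non-overlapping windows (5 kb genome-wide, 100 bp for peak
  scoring, 10–50 bp for profiles), with input subtraction floored at zero.
- **Enriched domains**: a simplified local-Poisson broad caller. Per 100-bp
  bin, background λ = max(genome-wide chip rate, depth-scaled input mean
  over 5-kb and 10-kb windows); bins with upper-tail Poisson p ≤ 0.01
  ("weak") are linked across gaps ≤ 500 bp and kept when the candidate
  contains a bin with p ≤ 1e-3 ("strong"). Peaks are scored by FPKM sum
  over 100-bp bins, filtered to the top 75 % by signal, merged within 5 kb,
  and classed by length (typical ≤ 10 kb; broad > 10 kb / > 20 kb / > 50 kb).
- **Cross-stage normalization**: assuming the most strongly marked regions
  are fully modified in every stage, the median signal of the top-25 % peaks
  is equalized to a reference stage.
- **PMDs**: 10-kb windows with mean CpG methylation < 0.5 and > 20 covered
  CpGs, merged when adjacent.
- **Stage specificity**: Shannon entropy over stage shares,
  `H = −Σ Rᵢ log₂ Rᵢ` with `Rᵢ = Eᵢ / Σ E`; `H < 0.5` bits defines a
  stage-specific feature, assigned to its argmax stage.
- **Putative enhancers / eRNAs**: distal (non-promoter) peaks with a DNase
  hypersensitive site within 500 bp; eRNAs additionally lack H3K4me3,
  avoid promoters/exons, and have RNA FPKM > 0.5 at a stage.
- **Annotation**: element assignment with ≥ 150 bp overlap and priority
  promoter > TES > exon > intron > intergenic; distal peak-to-gene links
  within TSS ± 300 kb.
- **Transposons**: observed/expected enrichment per repeat family;
  library-normalized, z-scored expression profiles over non-exonic elements.
- **Allelic peaks**: χ² test of maternal:paternal read counts against the
  dataset-wide background ratio at ≥ 10 informative reads/kb,
  Benjamini–Hochberg adjusted; calls need adjusted p < 0.001 and an allelic
  fold > 5.
- **ZGA genes / differential features**: FPKM > 1 and fold > 3 versus the
  pre-ZGA stage; fold > 2 with FDR < 0.05 for replicated count designs.

## Worked example

```python
import embryodomains as ed

res = ed.run_pipeline(seed=1)
print(res.summaries[["n_peaks", "broad", "broad50", "coverage_fraction"]])
print(res.scale_factors)
print("broad domains in PMDs:", res.broad_pmd_overlap_fraction)
```

prints

```
        n_peaks  broad  broad50  coverage_fraction
stage
2cell        16     16        6            0.07133
4cell        15     15        6            0.06921
8cell        72      0        0            0.01591
morula       67      0        0            0.01504
{'2cell': 1.893, '4cell': 1.894, '8cell': 1.0, 'morula': 1.010}
broad domains in PMDs: 1.0
```

Pre-ZGA stages (2cell, 4cell) carry only broad domains — including six
longer than 50 kb — covering ~7 % of the toy genome, all inside PMDs;
post-ZGA stages show only narrow peaks at ~1.5 % coverage. The scale factors
near 1.9 for pre-ZGA stages quantify how spreading the same acetylation
over broad domains dilutes per-bin FPKM, which is exactly what the top-25 %
median normalization corrects.

A CLI wraps the same machinery:

```sh
embryodomains simulate --seed 3 --outdir sim/     # data + truth_*.tsv
embryodomains run --seed 3 --outdir run/          # full pipeline + manifest
embryodomains report run/
```

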