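"""The peak/domain layer: caller behavior, scoring, filtering, merging,
length taxonomy, overlap analyses and cross-stage normalization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from embryodomains import (
    BinnedTrack,
    CallerParams,
    ChromSizes,
    GenomicInterval,
    IntervalSet,
    PeakSet,
    bin_fragments,
    call_enriched_domains,
    classify_inheritance,
    filter_top_signal,
    merge_within_gap,
    overlap_table,
    score_peaks,
    stage_scale_factor,
    summarize_peaks,
)
from embryodomains.domains import length_class
from embryodomains.simulate import StagePlan, default_config, simulate_chip


def peakset(*triples, signal=None):
    df = pd.DataFrame(triples, columns=["chrom", "start", "end"])
    if signal is not None:
        df["signal_sum"] = signal
        df["signal_mean"] = signal
    return PeakSet(df)


class TestCaller:
    def test_linking_rule_joins_across_small_gap(self, toy_genome):
        """Two enriched runs 400 bp apart (<= max_gap 500) become one peak."""
        chip = BinnedTrack(toy_genome, 100)
        inp = BinnedTrack(toy_genome, 100)
        chip.values["chr1"][:] = 5
        inp.values["chr1"][:] = 5
        chip.values["chr1"][100:110] = 60  # run 1: 10000-11000
        chip.values["chr1"][114:124] = 60  # run 2: 11400-12400 (gap 400)
        peaks = call_enriched_domains(chip, inp)
        assert len(peaks) == 1
        iv = next(iter(peaks))
        assert iv.start == 10_000 and iv.end == 12_400

    def test_gap_beyond_max_gap_splits(self, toy_genome):
        chip = BinnedTrack(toy_genome, 100)
        inp = BinnedTrack(toy_genome, 100)
        chip.values["chr1"][:] = 5
        inp.values["chr1"][:] = 5
        chip.values["chr1"][100:110] = 60
        chip.values["chr1"][116:126] = 60  # gap 600 > 500
        assert len(call_enriched_domains(chip, inp)) == 2

    def test_weak_only_candidate_dropped(self, toy_genome):
        """A candidate without any strong bin is discarded."""
        chip = BinnedTrack(toy_genome, 100)
        inp = BinnedTrack(toy_genome, 100)
        chip.values["chr1"][:] = 5
        inp.values["chr1"][:] = 5
        # count 11 at rate 5: p ~ 9.8e-3 (weak, not strong at 1e-3)
        chip.values["chr1"][200:205] = 11
        assert len(call_enriched_domains(chip, inp)) == 0
        # count 15: p ~ 6.9e-5 -> strong; same region now survives
        chip.values["chr1"][202] = 15
        assert len(call_enriched_domains(chip, inp)) == 1

    def test_mismatched_bin_width_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="bin width"):
            call_enriched_domains(
                BinnedTrack(toy_genome, 200), BinnedTrack(toy_genome, 200)
            )

    def test_planted_domain_recovery_single_seed(self):
        """A 20-kb region at 5x enrichment is recovered as one domain with
        >= 80% reciprocal overlap."""
        cfg = default_config(3)
        plant = (4_000_000, 4_020_000, 5.0)
        cfg = dataclasses.replace(
            cfg, stages=(StagePlan("one", True, (plant,)),)
        )
        chip, inp = simulate_chip(cfg, "one")
        peaks = call_enriched_domains(
            bin_fragments(chip, cfg.genome, 100), bin_fragments(inp, cfg.genome, 100)
        )
        hits = [
            iv
            for iv in peaks
            if min(iv.end, plant[1]) - max(iv.start, plant[0])
            >= 0.8 * max(iv.length, 20_000)
        ]
        assert len(hits) == 1


class TestScoring:
    def test_sum_and_mean_over_bins(self, toy_genome):
        fpkm = BinnedTrack(toy_genome, 100, semantics="fpkm")
        fpkm.values["chr1"][10:13] = [1.0, 2.0, 3.0]
        ps = score_peaks(peakset(("chr1", 1000, 1300)), fpkm)
        assert ps.df.loc[0, "signal_sum"] == pytest.approx(6.0)
        assert ps.df.loc[0, "signal_mean"] == pytest.approx(2.0)

    def test_single_bin_peak(self, toy_genome):
        fpkm = BinnedTrack(toy_genome, 100, semantics="fpkm")
        fpkm.values["chr1"][5] = 4.2
        ps = score_peaks(peakset(("chr1", 500, 600)), fpkm)
        assert ps.df.loc[0, "signal_sum"] == ps.df.loc[0, "signal_mean"] == 4.2

    def test_matches_bruteforce_bin_enumeration(self, rng, toy_genome):
        fpkm = BinnedTrack(toy_genome, 100, semantics="fpkm")
        for c in toy_genome.names():
            fpkm.values[c][:] = rng.random(fpkm.n_bins(c))
        starts = np.sort(rng.choice(900, size=20, replace=False)) * 100
        ps = peakset(*[("chr1", int(s), int(s + rng.integers(150, 5000))) for s in starts[::4]])
        scored = score_peaks(ps, fpkm)
        for i, iv in enumerate(scored):
            expected = [
                fpkm.values["chr1"][b]
                for b in range(fpkm.n_bins("chr1"))
                if iv.start <= b * 100 + 50 < iv.end
            ]
            assert scored.df.loc[i, "signal_sum"] == pytest.approx(sum(expected))
            assert scored.df.loc[i, "signal_mean"] == pytest.approx(
                np.mean(expected)
            )


class TestFilterTopSignal:
    def test_nearest_rank_keeps_three_of_four(self):
        ps = peakset(
            ("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500), ("chr1", 600, 700),
            signal=[10.0, 8.0, 5.0, 1.0],
        )
        kept = filter_top_signal(ps, 0.75)
        assert len(kept) == 3
        assert 1.0 not in kept.df["signal_sum"].to_numpy()

    def test_ties_at_threshold_kept(self):
        ps = peakset(
            ("chr1", 0, 100), ("chr1", 200, 300), ("chr1", 400, 500), ("chr1", 600, 700),
            signal=[2.0, 2.0, 2.0, 2.0],
        )
        assert len(filter_top_signal(ps, 0.75)) == 4

    def test_full_fraction_is_identity_and_empty_ok(self):
        ps = peakset(("chr1", 0, 100), signal=[1.0])
        assert len(filter_top_signal(ps, 1.0)) == 1
        assert len(filter_top_signal(PeakSet.empty(), 0.75)) == 0


class TestMergeAndSummary:
    def test_merge_within_5kb_and_rescore(self, toy_genome):
        fpkm = BinnedTrack(toy_genome, 100, semantics="fpkm")
        fpkm.values["chr1"][:] = 1.0
        ps = peakset(("chr1", 0, 1000), ("chr1", 6000, 7000), signal=[1.0, 1.0])
        merged = merge_within_gap(ps, gap=5000, fpkm100=fpkm)
        assert len(merged) == 1 and next(iter(merged)).end == 7000
        assert merged.df.loc[0, "signal_sum"] == pytest.approx(70.0)

    def test_length_classes_strict_thresholds(self):
        assert length_class(9_999) == "typical"
        assert length_class(10_000) == "typical"
        assert length_class(10_001) == "broad"
        assert length_class(60_000) == "broad50"

    def test_summary_counts_nested(self, toy_genome):
        ps = peakset(("chr1", 0, 9_999), ("chr1", 20_000, 30_001), ("chr2", 0, 60_000) )
        hundredkb = ChromSizes({"chr1": 100_000, "chr2": 100_000})
        s = summarize_peaks(ps, hundredkb)
        assert s["typical"] == 1 and s["broad"] == 2 and s["broad50"] == 1
        assert s["coverage_fraction"] == pytest.approx((9_999 + 10_001 + 60_000) / 200_000)

    def test_empty_summary(self, toy_genome):
        s = summarize_peaks(PeakSet.empty(), toy_genome)
        assert s["n_peaks"] == 0 and s["coverage_fraction"] == 0.0


class TestPeakBed:
    def test_empty_set_writes_header_only(self, tmp_path):
        p = PeakSet.empty().to_bed(tmp_path / "empty.bed")
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    def test_scored_peaks_roundtrip_fields(self, tmp_path, toy_genome):
        fpkm = BinnedTrack(toy_genome, 100, semantics="fpkm")
        fpkm.values["chr1"][:] = 1.5
        ps = score_peaks(peakset(("chr1", 0, 12_000), ("chr1", 20_000, 21_000)), fpkm)
        p = ps.to_bed(tmp_path / "peaks.bed")
        lines = [l.split("\t") for l in p.read_text().splitlines()[1:]]
        assert [l[3] for l in lines] == ["broad", "typical"]
        assert float(lines[0][4]) == pytest.approx(180.0)


class TestOverlapAndInheritance:
    def test_identical_sets_full_overlap(self):
        a = peakset(("chr1", 0, 100), ("chr1", 500, 700))
        t = overlap_table(a, a, "any")
        assert t["a_overlap"] == t["b_overlap"] == 2 and t["a_only"] == 0

    def test_disjoint_sets(self):
        a = peakset(("chr1", 0, 100))
        b = peakset(("chr1", 500, 700))
        t = overlap_table(a, b, "any")
        assert t["a_overlap"] == 0 and t["b_only"] == 1

    def test_fraction_criterion_asymmetric(self):
        a = peakset(("chr1", 0, 1000))
        b = peakset(("chr1", 900, 950))
        t = overlap_table(a, b, "fraction", fraction=0.5)
        assert t["a_overlap"] == 0  # only 5% of a covered
        assert t["b_overlap"] == 1  # b fully covered

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            overlap_table(peakset(("chr1", 0, 10)), peakset(("chr1", 0, 10)), "xx")

    def test_matches_bruteforce_pairwise(self, rng, toy_genome):
        for _ in range(10):
            mk = lambda: peakset(
                *[
                    ("chr1", int(s), int(s + rng.integers(50, 3000)))
                    for s in np.sort(rng.choice(20_000, 15, replace=False) * 4)[::3]
                ]
            )
            a, b = mk(), mk()
            expected = sum(
                any(
                    min(x.end, y.end) - max(x.start, y.start) >= 1
                    for y in b
                )
                for x in a
            )
            assert overlap_table(a, b, "any")["a_overlap"] == expected

    def test_inheritance_labels(self):
        zygote = peakset(
            ("chr1", 0, 100), ("chr1", 1000, 1100), ("chr1", 2000, 2100), ("chr1", 3000, 3100)
        )
        oocyte = peakset(("chr1", 50, 150), ("chr1", 2050, 2150))
        sperm = peakset(("chr1", 1050, 1150), ("chr1", 2000, 2100))
        labels = classify_inheritance(zygote, oocyte, sperm)["inheritance"].tolist()
        assert labels == ["oocyte-only", "sperm-only", "shared", "de novo"]


class TestStageScaling:
    def test_simple_ratio(self):
        ref = peakset(*[("chr1", i * 1000, i * 1000 + 100) for i in range(8)],
                      signal=[2.0] * 8)
        other = peakset(*[("chr1", i * 1000, i * 1000 + 100) for i in range(8)],
                        signal=[4.0] * 8)
        assert stage_scale_factor(ref, other) == pytest.approx(0.5)

    def test_identity(self):
        ps = peakset(*[("chr1", i * 1000, i * 1000 + 100) for i in range(8)],
                     signal=list(range(1, 9)))
        assert stage_scale_factor(ps, ps) == pytest.approx(1.0)

    def test_recovers_planted_scaling(self, rng):
        n = 200
        signal = rng.lognormal(0, 1, n)
        ref = peakset(*[("chr1", i * 1000, i * 1000 + 100) for i in range(n)],
                      signal=list(signal))
        other = peakset(*[("chr1", i * 1000, i * 1000 + 100) for i in range(n)],
                        signal=list(signal * 3))
        f = stage_scale_factor(ref, other)
        assert f == pytest.approx(1 / 3, rel=1e-9)

    def test_too_few_peaks_rejected(self):
        small = peakset(("chr1", 0, 100), signal=[1.0])
        with pytest.raises(ValueError, match="fewer than 4"):
            stage_scale_factor(small, small)
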