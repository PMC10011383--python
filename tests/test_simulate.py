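"""The synthetic-data generator: determinism and planted-truth statistics."""

import dataclasses

import numpy as np
import pytest

from embryodomains import GenomicInterval, bin_fragments
from embryodomains.intervals import intersect_length
from embryodomains.simulate import (
    SimulationConfig,
    StagePlan,
    default_config,
    simulate_allelic,
    simulate_annotation,
    simulate_chip,
    simulate_expression,
    simulate_methylome,
)


class TestConfigValidation:
    def test_fold_below_one_rejected(self):
        with pytest.raises(ValueError, match="fold"):
            StagePlan("s", True, ((0, 100, 0.5),))

    def test_planted_region_outside_genome_rejected(self, config):
        bad = (StagePlan("s", True, ((0, 99_000_000, 5.0),)),)
        with pytest.raises(ValueError, match="outside genome"):
            dataclasses.replace(config, stages=bad)

    def test_repeat_fractions_over_one_rejected(self, config):
        with pytest.raises(ValueError, match="> 1"):
            dataclasses.replace(
                config, repeat_fractions=(("Alu", 0.6), ("ERVK", 0.6))
            )

    def test_bad_rho_rejected(self, config):
        with pytest.raises(ValueError):
            dataclasses.replace(config, rho=1.0)


class TestDeterminism:
    def test_same_seed_identical_everything(self):
        a, b = default_config(5), default_config(5)
        assert a == b
        ca, _ = simulate_chip(a, "2cell")
        cb, _ = simulate_chip(b, "2cell")
        assert ca == cb
        assert simulate_methylome(a) == simulate_methylome(b)
        ea, _ = simulate_expression(a)
        eb, _ = simulate_expression(b)
        assert ea.equals(eb)
        ga, ra, da = simulate_annotation(a)
        gb, rb, db = simulate_annotation(b)
        assert ga == gb and ra == rb and da == db

    def test_different_seeds_differ(self):
        ca, _ = simulate_chip(default_config(5), "2cell")
        cb, _ = simulate_chip(default_config(6), "2cell")
        assert ca != cb

    def test_chip_and_input_independent_streams(self, config):
        chip, inp = simulate_chip(config, "8cell")
        assert chip != inp


class TestChip:
    def test_planted_enrichment_matches_expectation(self):
        """Fragments inside one 20-kb 5x region follow the closed-form
        weight-field expectation within 3 binomial sigma."""
        cfg = default_config(7)
        plant = (4_000_000, 4_020_000, 5.0)
        cfg = dataclasses.replace(cfg, stages=(StagePlan("one", True, (plant,)),))
        chip, _ = simulate_chip(cfg, "one")
        starts, _ = chip.arrays("chrS")
        n = cfg.fragments_per_library
        in_region = int(np.sum((starts >= plant[0]) & (starts < plant[1])))
        p = (20_000 * 5) / (10_000_000 - 20_000 + 20_000 * 5)
        expected = n * p
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(in_region - expected) <= 3 * sigma

    def test_null_chip_resembles_input(self, config):
        cfg = dataclasses.replace(config, stages=(StagePlan("null", True, ()),))
        chip, inp = simulate_chip(cfg, "null")
        tc = bin_fragments(chip, cfg.genome, 100_000).concat()
        ti = bin_fragments(inp, cfg.genome, 100_000).concat()
        # same uniform intensity: per-bin difference within Poisson noise
        z = (tc - ti) / np.sqrt(tc + ti)
        assert np.abs(z).max() < 5

    def test_library_size_as_configured(self, config):
        chip, inp = simulate_chip(config, "2cell")
        assert len(chip) == len(inp) == config.fragments_per_library


class TestMethylome:
    def test_pmd_windows_hypomethylated(self, config):
        t = simulate_methylome(config)
        s, e = config.pmds[0]
        sub = t.in_region(GenomicInterval(config.chrom, s, min(e, s + 10_000)))
        assert len(sub) >= 50
        assert sub["meth"].mean() == pytest.approx(config.meth_inside, abs=0.05)

    def test_cpg_density_as_configured(self, config):
        t = simulate_methylome(config)
        L = config.genome[config.chrom]
        expected = config.cpg_per_100bp * L / 100
        assert len(t) == pytest.approx(expected, rel=0.01)

    def test_no_pmds_gives_uniform_high_methylation(self, config):
        cfg = dataclasses.replace(config, pmds=())
        t = simulate_methylome(cfg)
        assert t.df["meth"].mean() == pytest.approx(config.meth_outside, abs=0.02)


class TestAllelicAndExpression:
    def test_null_peaks_binomial_background(self, config):
        import pandas as pd

        df = pd.DataFrame(
            {"chrom": "chrS", "start": np.arange(2000) * 100, "end": np.arange(2000) * 100 + 100}
        )
        table, truth = simulate_allelic(config, df, biased_mask=np.zeros(2000, bool))
        frac = table["maternal"].sum() / (table["maternal"] + table["paternal"]).sum()
        assert frac == pytest.approx(config.rho, abs=0.01)

    def test_planted_bias_ratio(self, config):
        import pandas as pd

        df = pd.DataFrame({"chrom": "chrS", "start": [0], "end": [1000]})
        cfg = dataclasses.replace(config, allelic_depth=5_000.0)
        table, _ = simulate_allelic(cfg, df, biased_mask=np.ones(1, bool))
        ratio = table["maternal"].iloc[0] / table["paternal"].iloc[0]
        assert ratio == pytest.approx(19.0, rel=0.25)  # 0.95 : 0.05

    def test_planted_zga_genes_satisfy_rule_by_construction(self, config):
        matrix, truth = simulate_expression(config)
        zga = truth.loc[truth["planted_zga"], "gene_id"]
        pre = [s.name for s in config.stages if s.pre_zga]
        post = [s.name for s in config.stages if not s.pre_zga]
        sub = matrix.loc[zga]
        assert (sub[pre].to_numpy() < 0.5).all()
        assert (sub[post].to_numpy() > 1.0).all()
        assert (sub[post].min(axis=1) > 3 * sub[pre].max(axis=1)).all()

    def test_housekeeping_uniform_entropy_high(self, config):
        from embryodomains import entropy_score

        matrix, truth = simulate_expression(config)
        base = truth[
            (~truth["planted_zga"]) & (truth["planted_specific_stage"] == "")
        ]["gene_id"]
        hs = [entropy_score(matrix.loc[g].to_numpy())[1] for g in base[:100]]
        assert np.median(hs) > 1.5  # near log2(4) for balanced genes


class TestAnnotation:
    def test_promoter_width(self, config):
        genes, _, _ = simulate_annotation(config)
        prom = genes[0].promoter(config.genome)
        assert prom.length == 5_000

    def test_gene_bodies_non_overlapping(self, config):
        genes, _, _ = simulate_annotation(config)
        spans = sorted((g.tx_start, g.tx_end) for g in genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 >= e1

    def test_repeat_family_fractions(self, config):
        _, repeats, _ = simulate_annotation(config)
        L = config.genome[config.chrom]
        for family, fraction in config.repeat_fractions:
            total = sum(
                r.interval.length for r in repeats if r.family == family
            )
            assert total == pytest.approx(fraction * L, rel=0.05)

    def test_dhs_near_planted_narrow_peaks(self, config):
        _, _, dhs = simulate_annotation(config)
        post = next(s for s in config.stages if not s.pre_zga)
        truth = config.truth_domains(post.name)
        hits = sum(
            1
            for s, e, _ in post.domains
            if intersect_length(
                truth.__class__({config.chrom: (np.array([s - 500]), np.array([e + 500]))}),
                dhs,
            )
            > 0
        )
        assert hits / len(post.domains) >= 0.7
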