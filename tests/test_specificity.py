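"""Entropy-based stage specificity, enhancers, eRNAs, ZGA genes, and
fold-change differential calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryodomains import (
    GeneModel,
    GenomicInterval,
    IntervalSet,
    PeakSet,
    call_ernas,
    define_putative_enhancers,
    define_zga_genes,
    entropy_score,
    entropy_table,
    fold_change_differential,
    select_stage_specific,
)
from embryodomains.simulate import default_config, simulate_expression


def entropy_oracle(values):
    """Independent direct evaluation of H = -sum r_i log2 r_i."""
    total = sum(values)
    h = 0.0
    for v in values:
        if v > 0:
            r = v / total
            h -= r * math.log2(r)
    return h


def peaks(*triples):
    return PeakSet(pd.DataFrame(triples, columns=["chrom", "start", "end"]))


class TestEntropy:
    def test_uniform_is_log2_n(self):
        _, h = entropy_score([1, 1, 1, 1])
        assert h == 2.0

    def test_point_mass_is_zero(self):
        _, h = entropy_score([5, 0, 0, 0])
        assert h == 0.0

    def test_mixed_example(self):
        _, h = entropy_score([8, 1, 1, 0])
        assert h == pytest.approx(entropy_oracle([8, 1, 1, 0]), abs=1e-12)
        assert h == pytest.approx(0.9219, abs=1e-4)

    def test_all_zero_flagged_undefined(self):
        r, h = entropy_score([0, 0, 0])
        assert np.isnan(h) and np.isnan(r).all()

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            v = rng.random(int(rng.integers(2, 8))) * 10
            _, h = entropy_score(v)
            assert h == pytest.approx(entropy_oracle(v), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=8).filter(
            lambda v: sum(v) > 0
        )
    )
    def test_bounds_invariant(self, values):
        """0 <= H <= log2 N for every non-degenerate feature."""
        _, h = entropy_score(values)
        assert -1e-12 <= h <= math.log2(len(values)) + 1e-9

    def test_permutation_invariance(self, rng):
        v = rng.random(5)
        _, h1 = entropy_score(v)
        _, h2 = entropy_score(v[::-1])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_table_matches_scalar_path(self, rng):
        m = pd.DataFrame(rng.random((50, 4)), columns=list("abcd"))
        tab = entropy_table(m)
        for i in range(50):
            _, h = entropy_score(m.iloc[i].to_numpy())
            assert tab["H"].iloc[i] == pytest.approx(h, abs=1e-12)


class TestStageSpecific:
    def test_high_share_selected_with_argmax_stage(self):
        m = pd.DataFrame(
            [[0.97, 0.01, 0.01, 0.01], [1, 1, 1, 1]],
            columns=["s1", "s2", "s3", "s4"],
            index=["spec", "flat"],
        )
        sel = select_stage_specific(m)
        assert list(sel.index) == ["spec"]
        assert sel.loc["spec", "peak_stage"] == "s1"
        assert sel.loc["spec", "H"] == pytest.approx(
            entropy_oracle([0.97, 0.01, 0.01, 0.01]), abs=1e-12
        )

    def test_zero_threshold_selects_nothing(self):
        m = pd.DataFrame([[5, 0, 0, 0]], columns=list("abcd"))
        assert len(select_stage_specific(m, threshold=0.0)) == 0

    def test_planted_genes_recovered_with_low_false_positives(self, config):
        """Planted stage-specific genes (share 0.95 -> H ~ 0.39 bits) are
        found with >= 0.95 sensitivity; baseline genes rarely pass."""
        matrix, truth = simulate_expression(config)
        sel = select_stage_specific(matrix)
        planted = truth[truth["planted_specific_stage"] != ""]
        sens = planted["gene_id"].isin(sel.index).mean()
        assert sens >= 0.95
        baseline = truth[
            (truth["planted_specific_stage"] == "") & (~truth["planted_zga"])
        ]
        fpr = baseline["gene_id"].isin(sel.index).mean()
        assert fpr <= 0.01
        # assigned stage matches the planted stage for every recovered gene
        rec = planted[planted["gene_id"].isin(sel.index)]
        assert (
            sel.loc[rec["gene_id"], "peak_stage"].to_numpy()
            == rec["planted_specific_stage"].to_numpy()
        ).all()


class TestPutativeEnhancers:
    dhs = IntervalSet.from_intervals([GenomicInterval("chr1", 10_000, 10_300)])

    def test_dhs_within_500bp_downstream(self):
        # peak ends 300 bp before the DHS
        out = define_putative_enhancers(peaks(("chr1", 9_000, 9_700)), self.dhs)
        assert len(out) == 1

    def test_dhs_too_far(self):
        out = define_putative_enhancers(peaks(("chr1", 8_000, 9_200)), self.dhs)
        assert len(out) == 0

    def test_dhs_inside_peak(self):
        out = define_putative_enhancers(peaks(("chr1", 9_900, 10_600)), self.dhs)
        assert len(out) == 1


class TestErnas:
    genes = [
        GeneModel(
            "geneA",
            "chr1",
            "+",
            100_000,
            120_000,
            (GenomicInterval("chr1", 100_000, 101_000, "+"),),
        )
    ]

    def make(self, fpkm, k4=None, peak=("chr1", 500_000, 502_000)):
        k27 = peaks(peak)
        k4 = k4 if k4 is not None else PeakSet.empty()
        rna = pd.DataFrame({"8cell": [fpkm]}, index=["p0"])
        return call_ernas(k27, k4, self.genes, rna)

    def test_clean_distal_peak_with_rna(self):
        assert list(self.make(0.7)["8cell"]) == ["p0"]

    def test_fpkm_threshold_strict(self):
        assert len(self.make(0.5)["8cell"]) == 0

    def test_k4_overlap_excludes(self):
        k4 = peaks(("chr1", 501_000, 503_000))
        assert len(self.make(0.9, k4=k4)["8cell"]) == 0

    def test_promoter_overlap_excludes(self):
        # promoter window is 97.5k-102.5k
        assert len(self.make(0.9, peak=("chr1", 98_000, 99_000))["8cell"]) == 0


class TestZgaGenes:
    def test_rule_arithmetic(self):
        expr = pd.DataFrame(
            {"2cell": [0.5, 0.2, 2.0], "8cell": [3.0, 0.9, 5.0]},
            index=["zga", "silent", "constitutive"],
        )
        got = define_zga_genes(expr, "2cell", "8cell")
        assert list(got) == ["zga"]


class TestFoldChangeDifferential:
    def test_fold_only_mode(self):
        a = pd.Series([10.0, 5.0, 2.0], index=list("xyz"))
        b = pd.Series([2.0, 5.0, 9.0], index=list("xyz"))
        out = fold_change_differential(a, b, fold_min=3.0)
        assert out.loc["x", "call"] == "down"
        assert out.loc["y", "call"] == "ns"
        assert out.loc["z", "call"] == "up"

    def test_statistical_mode_requires_replicates(self):
        a = pd.DataFrame({"r1": [10]})
        b = pd.DataFrame({"r1": [10]})
        with pytest.raises(ValueError, match="replicates"):
            fold_change_differential(a, b, fdr_max=0.05)

    def test_statistical_mode_null_calibration(self):
        """No planted differences: flagged features stay far below the
        nominal FDR budget."""
        rng = np.random.default_rng(9)
        n = 5_000
        base = rng.lognormal(3, 1, n)
        a = pd.DataFrame(
            {f"a{r}": rng.poisson(base) for r in range(2)}
        )
        b = pd.DataFrame(
            {f"b{r}": rng.poisson(base) for r in range(2)}
        )
        out = fold_change_differential(a, b, fold_min=2.0, fdr_max=0.05)
        n_called = (out["call"] != "ns").sum()
        assert n_called <= 0.1 * 0.05 * n

    def test_statistical_mode_finds_planted_changes(self):
        rng = np.random.default_rng(10)
        n = 500
        base = rng.lognormal(4, 0.5, n)
        fold = np.ones(n)
        fold[:50] = 8.0
        a = pd.DataFrame({f"a{r}": rng.poisson(base) for r in range(2)})
        b = pd.DataFrame({f"b{r}": rng.poisson(base * fold) for r in range(2)})
        out = fold_change_differential(a, b, fold_min=2.0, fdr_max=0.05)
        assert (out["call"].iloc[:50] == "up").mean() >= 0.9
        assert (out["call"].iloc[50:] == "ns").mean() >= 0.99
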