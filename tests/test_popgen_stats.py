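"""Unit and property tests for Fst, pi and gene-level aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sweepscan import popgen_stats as ps
from sweepscan.core_io import GeneModel

from conftest import make_table, two_pop_assignment


def wc_oracle(n1, n2, p1, p2, h1, h2):
    """Independent Weir-Cockerham (1984) r-population formulas at r=2."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1))
        * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    return (a, b, c, a / denom if denom != 0 else float("nan"))


def genotype_config(rng, n1, n2):
    """Random two-population genotype table for one site."""
    gt = np.zeros((1, n1 + n2, 2), dtype=np.int8)
    for j in range(n1 + n2):
        dos = rng.integers(0, 3)
        gt[0, j] = [(0, 0), (0, 1), (1, 1)][dos]
    return gt


class TestWcComponents:
    def test_fixed_difference_theta_one(self):
        gt = np.zeros((1, 20, 2), dtype=np.int8)
        gt[0, :10] = 1  # population 1 fixed alt
        t = make_table([100], gt)
        pops = two_pop_assignment(t.samples, 10)
        comp = ps.site_fst_wc(t.site(0), t.samples, pops)
        assert comp.a == pytest.approx(0.5)
        assert comp.b == 0.0 and comp.c == 0.0
        assert comp.theta == 1.0

    def test_monomorphic_theta_nan_never_zero(self):
        gt = np.zeros((1, 20, 2), dtype=np.int8)
        t = make_table([100], gt)
        pops = two_pop_assignment(t.samples, 10)
        comp = ps.site_fst_wc(t.site(0), t.samples, pops)
        assert math.isnan(comp.theta)

    def test_requires_biallelic(self):
        gt = np.zeros((1, 4, 2), dtype=np.int8)
        t = make_table([100], gt, alts=[("G", "T")])
        pops = two_pop_assignment(t.samples, 2)
        with pytest.raises(ValueError, match="biallelic"):
            ps.site_fst_wc(t.site(0), t.samples, pops)

    def test_uncalled_population_raises(self):
        gt = np.zeros((1, 4, 2), dtype=np.int8)
        gt[0, 2:] = -1
        t = make_table([100], gt)
        pops = two_pop_assignment(t.samples, 2)
        with pytest.raises(ValueError, match="at least one called"):
            ps.site_fst_wc(t.site(0), t.samples, pops)

    def test_matches_oracle_from_genotypes(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n1, n2 = int(rng.integers(2, 20)), int(rng.integers(2, 20))
            gt = genotype_config(rng, n1, n2)
            t = make_table([100], gt)
            pops = two_pop_assignment(t.samples, n1)
            comp = ps.site_fst_wc(t.site(0), t.samples, pops)
            a, b, c, theta = wc_oracle(
                comp.n1, comp.n2, comp.p1, comp.p2, comp.h1, comp.h2
            )
            assert comp.a == pytest.approx(a, abs=1e-12)
            assert comp.b == pytest.approx(b, abs=1e-12)
            assert comp.c == pytest.approx(c, abs=1e-12)
            if math.isnan(theta):
                assert math.isnan(comp.theta)
            else:
                assert comp.theta == pytest.approx(theta, abs=1e-12)

    @given(
        n1=st.integers(2, 100),
        n2=st.integers(2, 100),
        k1=st.integers(0, 200),
        k2=st.integers(0, 200),
        het1=st.integers(0, 100),
        het2=st.integers(0, 100),
    )
    def test_symmetry_properties(self, n1, n2, k1, k2, het1, het2):
        k1, k2 = min(k1, 2 * n1), min(k2, 2 * n2)
        p1, p2 = k1 / (2 * n1), k2 / (2 * n2)
        h1 = min(het1, n1) / n1
        h2 = min(het2, n2) / n2
        a, b, c, theta = ps._wc_components(n1, n2, p1, p2, h1, h2)
        # swap populations: estimator invariant
        a2, b2, c2, theta2 = ps._wc_components(n2, n1, p2, p1, h2, h1)
        assert np.isclose(a, a2, atol=1e-12)
        # relabel alleles p -> 1-p: estimator invariant
        a3, b3, c3, theta3 = ps._wc_components(n1, n2, 1 - p1, 1 - p2, h1, h2)
        assert np.isclose(a, a3, atol=1e-12)
        if not (np.isnan(theta) or np.isnan(theta3)):
            assert np.isclose(float(theta), float(theta3), atol=1e-12)


class TestFstTable:
    def test_skips_uncalled_and_counts(self):
        gt = np.zeros((2, 6, 2), dtype=np.int8)
        gt[0, 0] = [0, 1]
        gt[1, 3:] = -1  # reference population fully missing at site 2
        t = make_table([100, 200], gt)
        pops = two_pop_assignment(t.samples, 3)
        df = ps.fst_table(t, pops)
        assert len(df) == 1
        assert df.attrs["n_skipped"] == 1

    def test_genomewide_weighted_vs_per_site(self):
        df = pd.DataFrame(
            {"a": [1.0, 0.0], "b": [0.0, 1.0], "c": [0.0, 0.0],
             "theta": [1.0, 0.0]}
        )
        assert ps.genomewide_fst(df, "weighted") == pytest.approx(0.5)
        assert ps.genomewide_fst(df, "per-site") == pytest.approx(0.5)
        with pytest.raises(ValueError):
            ps.genomewide_fst(df, "nope")


class TestZTransform:
    def test_fisher_clips_and_monotone(self):
        vals = np.array([-0.5, 0.0, 0.5, 0.9])
        z = ps.z_transform_fst(vals)
        assert z[0] == 0.0 and z[1] == 0.0
        assert z[2] == pytest.approx(math.atanh(0.5))
        assert np.all(np.diff(z) >= 0)

    def test_fisher_handles_theta_one(self):
        z = ps.z_transform_fst(np.array([1.0]))
        assert np.isfinite(z[0])

    def test_zscore(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        z = ps.z_transform_fst(vals, "zscore")
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_empty(self):
        assert ps.z_transform_fst([]).size == 0


class TestGeneFst:
    FST = pd.DataFrame(
        {
            "contig": ["chr1"] * 4,
            "pos": [100, 150, 300, 1000],
            "theta": [0.2, 0.8, 0.5, np.nan],
        }
    )
    GENES = [
        GeneModel("gA", "chr1", 50, 200),
        GeneModel("gB", "chr1", 140, 350),  # overlaps gA
        GeneModel("gC", "chr1", 900, 1100),  # only a NaN site
        GeneModel("gD", "chr1", 5000, 6000),  # no SNPs
    ]

    def test_max_aggregator_and_overlap(self):
        out = ps.gene_fst(self.FST, self.GENES)
        assert list(out["gene_id"]) == ["gA", "gB"]
        assert out.loc[out["gene_id"] == "gA", "score"].iloc[0] == 0.8
        assert out.loc[out["gene_id"] == "gB", "score"].iloc[0] == 0.8

    def test_mean_aggregator(self):
        out = ps.gene_fst(self.FST, self.GENES, aggregator="mean")
        assert out.loc[out["gene_id"] == "gA", "score"].iloc[0] == pytest.approx(0.5)
        assert out.loc[out["gene_id"] == "gB", "score"].iloc[0] == pytest.approx(0.65)

    def test_bad_aggregator(self):
        with pytest.raises(ValueError):
            ps.gene_fst(self.FST, self.GENES, aggregator="median")

    def test_gene_interval_boundaries_inclusive(self):
        genes = [GeneModel("g", "chr1", 100, 150)]
        out = ps.gene_fst(self.FST, genes)
        assert out["n_snps"].iloc[0] == 2


class TestTopFraction:
    def test_ceil_and_tiebreak(self):
        scores = pd.DataFrame(
            {
                "gene_id": ["g3", "g1", "g2", "g4", "g5"],
                "contig": ["chr1"] * 5,
                "start": [300, 100, 200, 400, 500],
                "score": [0.5, 0.9, 0.5, 0.5, 0.1],
            }
        )
        top = ps.top_fraction(scores, 0.5)  # ceil(2.5) = 3
        assert len(top) == 3
        assert list(top["gene_id"]) == ["g1", "g2", "g3"]  # ties by position

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            ps.top_fraction(pd.DataFrame({"contig": [], "score": []}), 1.0)

    def test_empty_frame(self):
        empty = pd.DataFrame({"gene_id": [], "contig": [], "start": [], "score": []})
        assert len(ps.top_fraction(empty, 0.1)) == 0


class TestPi:
    def test_site_pi_hand_values(self):
        assert ps.site_pi(2, 2) == pytest.approx(2 / 3)
        assert ps.site_pi(199, 1) == pytest.approx(0.01)
        assert ps.site_pi(4, 0) == 0.0
        with pytest.raises(ValueError):
            ps.site_pi(1, 0)

    def test_windowed_pi_hand_case(self):
        # 4 diploids; one het site -> c0=7, c1=1 -> pi_site = 2*7/(8*7) = 0.25
        gt = np.zeros((2, 4, 2), dtype=np.int8)
        gt[0, 0] = [0, 1]
        t = make_table([5, 150], gt, contig_length=250)
        wins = ps.windowed_pi(t, window_bp=100)
        assert len(wins) == 3
        assert wins[0].pi == pytest.approx(0.25 / 100)
        assert wins[1].pi == 0.0  # monomorphic site contributes 0
        assert wins[1].n_variant_sites == 1
        assert wins[2].end == 250  # partial window reported

    def test_partial_window_length(self):
        gt = np.zeros((1, 4, 2), dtype=np.int8)
        gt[0, 0] = [0, 1]
        t = make_table([230], gt, contig_length=250)
        wins = ps.windowed_pi(t, window_bp=100)
        assert wins[2].pi == pytest.approx(0.25 / 50)

    def test_population_subsetting(self):
        gt = np.zeros((1, 6, 2), dtype=np.int8)
        gt[0, 3:] = 1  # population 2 fixed alt
        t = make_table([10], gt, contig_length=100)
        pops = two_pop_assignment(t.samples, 3)
        w1 = ps.windowed_pi(t, pops, "P1", 100)
        w2 = ps.windowed_pi(t, pops, "P2", 100)
        assert w1[0].pi == 0.0 and w2[0].pi == 0.0
        wall = ps.windowed_pi(t, window_bp=100)
        assert wall[0].pi > 0

    def test_sites_with_fewer_than_two_alleles_skipped(self):
        gt = np.full((1, 3, 2), -1, dtype=np.int8)
        gt[0, 0] = [0, 1]
        t = make_table([10], gt, contig_length=100)
        wins = ps.windowed_pi(t, window_bp=100)
        assert wins[0].pi == pytest.approx(1.0 / 100)  # (c0,c1)=(1,1): pi=1

    def test_unknown_contig_length(self):
        gt = np.zeros((1, 2, 2), dtype=np.int8)
        t = make_table([10], gt)
        t.contig_lengths = {}
        with pytest.raises(ValueError, match="unknown length"):
            ps.windowed_pi(t)


class TestComparePi:
    def test_keys_and_shift(self):
        a = [ps.WindowPi("c", 1, 100, 1, 0.01 * i) for i in range(1, 30)]
        b = [ps.WindowPi("c", 1, 100, 1, 0.01 * i + 0.5) for i in range(1, 30)]
        res = ps.compare_pi(a, b)
        assert res["mean_b"] > res["mean_a"]
        assert res["median_b"] > res["median_a"]
        assert res["p_value"] < 1e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ps.compare_pi([], [ps.WindowPi("c", 1, 2, 0, 0.0)])

    def test_tiny_groups_nan_p(self):
        a = [ps.WindowPi("c", 1, 2, 0, 0.1)]
        res = ps.compare_pi(a, a)
        assert math.isnan(res["p_value"])
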