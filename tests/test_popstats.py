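"""Heterozygosity, Weir-Cockerham F_ST, LD pruning and kinship."""

import numpy as np
import pytest

from whalepop.popstats import (
    genome_wide_heterozygosity,
    kinship_mom,
    ld_prune,
    substructure_inflation,
    wc_fst,
    windowed_heterozygosity,
)
from conftest import make_dataset


def wc_single_locus_oracle(counts1, n1, counts2, n2, het1, het2):
    """Textbook Weir & Cockerham (1984) single-locus estimator written
    independently from the implementation (r=2 populations)."""
    r = 2
    n_i = np.array([n1, n2], dtype=float)
    p_i = np.array([counts1 / (2 * n1), counts2 / (2 * n2)])
    h_i = np.array([het1 / n1, het2 / n2])
    n_bar = n_i.mean()
    nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
    p_bar = (n_i * p_i).sum() / n_i.sum()
    s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum() / n_i.sum()
    a = n_bar / nc * (s2 - 1 / (n_bar - 1) * (p_bar * (1 - p_bar)
        - (r - 1) / r * s2 - h_bar / 4))
    b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    return a / (a + b + c)


class TestHeterozygosity:
    def test_per_kb(self):
        g = np.zeros((1, 100), dtype=np.int8)
        g[0, :5] = 1
        ds = make_dataset(g)
        ds.n_monomorphic = 4900
        assert genome_wide_heterozygosity(ds, 0) == pytest.approx(1.0)

    def test_denominator_is_called_sites(self):
        g = np.zeros((1, 1000), dtype=np.int8)
        g[0, :2] = 1
        ds = make_dataset(g)
        ds.n_monomorphic = 2000
        ds.mono_called_ind = np.array([0])  # all monomorphic missing
        assert genome_wide_heterozygosity(ds, 0) == pytest.approx(2.0)

    def test_zero_called_raises(self):
        ds = make_dataset(np.full((1, 3), -1))
        ds.n_monomorphic = 0
        with pytest.raises(ValueError):
            genome_wide_heterozygosity(ds, 0)

    def test_matches_coalescent_expectation(self, onepop_ds):
        # constant N=500, mu=1e-7: expected het/site = 4 N mu
        hets = [genome_wide_heterozygosity(onepop_ds, i) / 1000
                for i in range(onepop_ds.n_individuals)]
        expected = 4 * 500 * 1e-7
        assert np.mean(hets) == pytest.approx(expected, rel=0.35)


class TestWindowedHeterozygosity:
    def test_window_masked_above_missing_bound(self):
        g = np.full((1, 10), -1, dtype=np.int8)
        ds = make_dataset(g, positions=np.arange(10) * 1000)
        ds.seq_len = 10_000
        ds.n_monomorphic = 0
        out = windowed_heterozygosity(ds, 0, window=10_000, max_missing=0.80)
        assert np.isnan(out[0])

    def test_homozygous_window_zero(self):
        g = np.zeros((1, 10), dtype=np.int8)
        ds = make_dataset(g, positions=np.arange(10) * 100)
        ds.seq_len = 1000
        ds.n_monomorphic = 0
        out = windowed_heterozygosity(ds, 0, window=1000, max_missing=0.99)
        assert out[0] == 0.0

    def test_additivity_with_genome_wide(self):
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, size=(1, 400)).astype(np.int8)
        ds = make_dataset(g, positions=np.sort(rng.choice(4000, 400, replace=False)))
        ds.seq_len = 4000
        ds.n_monomorphic = 0
        wins = windowed_heterozygosity(ds, 0, window=1000, max_missing=1.0)
        total_het = (g == 1).sum()
        # numerators add up across windows
        called = (g != -1).sum()
        gw = genome_wide_heterozygosity(ds, 0)
        assert gw == pytest.approx(1000 * total_het / called)


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        g = np.array([[2, 2, 2]] * 4 + [[0, 0, 0]] * 4, dtype=np.int8)
        ds = make_dataset(g, pops=["A"] * 4 + ["B"] * 4)
        res = wc_fst(ds, n_perm=0)
        assert res.fst == pytest.approx(1.0)

    def test_single_locus_matches_independent_oracle(self):
        # pop1: 8 derived of 20 haploids, pop2: 2 of 20
        g1 = np.array([2, 2, 2, 1, 1, 0, 0, 0, 0, 0], dtype=np.int8)
        g2 = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], dtype=np.int8)
        g = np.concatenate([g1, g2])[:, None]
        ds = make_dataset(g, pops=["A"] * 10 + ["B"] * 10)
        res = wc_fst(ds, n_perm=0)
        oracle = wc_single_locus_oracle(8, 10, 2, 10, het1=2, het2=2)
        assert res.fst == pytest.approx(oracle, abs=1e-12)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        labels = np.array(["A"] * 6 + ["B"] * 6)
        f1 = wc_fst(g, labels, n_perm=0).fst
        f2 = wc_fst(g, np.where(labels == "A", "B", "A"), n_perm=0).fst
        assert f1 == pytest.approx(f2)

    def test_permutation_p_reproducible(self, twopop_ds):
        r1 = wc_fst(twopop_ds, n_perm=49, seed=11)
        r2 = wc_fst(twopop_ds, n_perm=49, seed=11)
        assert r1.p_value == r2.p_value
        assert r1.fst > 0
        assert r1.p_value <= 0.05  # structured demes are detectable

    def test_monomorphic_only_rejected(self):
        g = np.zeros((8, 5), dtype=np.int8)
        ds = make_dataset(g, pops=["A"] * 4 + ["B"] * 4)
        with pytest.raises(ValueError):
            wc_fst(ds, n_perm=0)


class TestInflation:
    def test_printed_value(self):
        assert substructure_inflation(0.008) == pytest.approx(0.8, abs=0.05)

    def test_zero(self):
        assert substructure_inflation(0.0) == 0.0

    def test_half(self):
        assert substructure_inflation(0.5) == pytest.approx(100.0)

    def test_at_one_rejected(self):
        with pytest.raises(ValueError):
            substructure_inflation(1.0)


class TestLdPrune:
    def test_duplicated_site_keeps_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=20).astype(np.int8)
        g = np.stack([col, col], axis=1)
        ds = make_dataset(g, positions=[100, 200])
        ds.seq_len = 1000
        kept = ld_prune(ds, maf_min=0.0)
        assert len(kept) == 1

    def test_low_maf_removed(self):
        g = np.zeros((10, 1), dtype=np.int8)
        g[0, 0] = 1  # MAF 0.05
        ds = make_dataset(g)
        ds.seq_len = 1000
        assert len(ld_prune(ds, maf_min=0.10)) == 0

    def test_independent_sites_mostly_retained(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.2, 0.8, 80)
        g = rng.binomial(2, p, size=(60, 80)).astype(np.int8)
        ds = make_dataset(g, positions=np.arange(80) * 500)
        ds.seq_len = 40_000
        kept = ld_prune(ds, r2_max=0.2, maf_min=0.1,
                        window=20_000, step=10_000)
        freq = g.mean(axis=0) / 2
        maf_ok = np.minimum(freq, 1 - freq) >= 0.1
        assert len(kept) > 0.85 * maf_ok.sum()


class TestKinship:
    def test_self_kinship_half(self, twopop_ds):
        assert kinship_mom(twopop_ds, (0, 0)) == 0.5

    def test_parent_offspring_quarter(self):
        rng = np.random.default_rng(8)
        n_sites = 4000
        p = rng.uniform(0.2, 0.8, n_sites)
        pop = rng.binomial(1, p, size=(40, 2, n_sites))  # 40 diploids
        parent = pop[0]
        other_parent = pop[1]
        # child inherits one allele from each parent
        child = np.stack([
            np.where(rng.random(n_sites) < 0.5, parent[0], parent[1]),
            np.where(rng.random(n_sites) < 0.5, other_parent[0], other_parent[1]),
        ])
        g = np.vstack([pop.sum(axis=1), (parent.sum(axis=0) * 0 + child.sum(axis=0))[None, :]])
        ds = make_dataset(g.astype(np.int8), positions=np.arange(n_sites),
                          pops=["A"] * 41)
        k = kinship_mom(ds, (0, 40))
        assert k == pytest.approx(0.25, abs=0.05)

    def test_unrelated_near_zero(self):
        rng = np.random.default_rng(2)
        n_sites = 3000
        p = rng.uniform(0.2, 0.8, n_sites)
        g = rng.binomial(2, p, size=(30, n_sites)).astype(np.int8)
        ds = make_dataset(g, positions=np.arange(n_sites), pops=["A"] * 30)
        ks = [kinship_mom(ds, (i, i + 1)) for i in range(0, 10, 2)]
        assert abs(np.mean(ks)) < 0.03

    def test_insufficient_overlap_raises(self):
        g = np.full((2, 30), -1, dtype=np.int8)
        ds = make_dataset(g, pops=["A", "A"])
        with pytest.raises(ValueError):
            kinship_mom(ds, (0, 1))
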