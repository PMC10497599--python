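"""Forward Wright-Fisher simulator: layout, DFE/dominance, rescaling and
population-genetic sanity checks."""

import numpy as np
import pytest

from whalepop.demography.models import EpochModel, TwoPopModel
from whalepop.forward_sim import (
    DFE,
    SimConfig,
    build_genome_layout,
    compute_sim_stats,
    dominance_of,
    draw_mutation,
    lethal_truncation_mass,
    rescale_config,
    run_simulation,
)


class TestLayout:
    def test_exonic_fraction_realized(self):
        layout = build_genome_layout(1e7, exon_fraction=0.013, seed=1)
        assert layout.exonic_bp == pytest.approx(0.013 * 1e7, rel=0.10)

    def test_deterministic_given_seed(self):
        a = build_genome_layout(1e6, 0.05, seed=9)
        b = build_genome_layout(1e6, 0.05, seed=9)
        np.testing.assert_array_equal(a.exon_starts, b.exon_starts)

    def test_is_exonic_lookup(self):
        layout = build_genome_layout(1e6, 0.05, seed=2)
        mid = (layout.exon_starts[0] + layout.exon_ends[0]) / 2
        assert layout.is_exonic(np.array([mid]))[0]
        assert not layout.is_exonic(np.array([layout.exon_ends[0] + 1.0]))[0]

    def test_zero_exon_fraction_no_deleterious(self):
        cfg = SimConfig(demography=EpochModel.one_epoch(50), seq_len=2e5,
                        mu=1e-7, exon_fraction=0.0, seed=3, burnin_mult=2)
        res = run_simulation(cfg)["present"]["pop"]
        assert res.load == 0.0


class TestDominance:
    @pytest.mark.parametrize("s,h", [(-0.02, 0.0), (-0.005, 0.1), (-0.0005, 0.4)])
    def test_dominance_map(self, s, h):
        assert dominance_of(s) == h

    def test_neutral_draw_outside_exon(self):
        rng = np.random.default_rng(0)
        s, h = draw_mutation(False, DFE(), rng)
        assert s == 0.0


class TestRescaling:
    def _cfg(self):
        return SimConfig(demography=EpochModel.two_epoch(1000, 200, 500),
                         seq_len=1e6, mu=1e-8, rec=1e-8)

    def test_identity_at_lambda_one(self):
        cfg = self._cfg()
        out = rescale_config(cfg, 1.0)
        assert out.mu == cfg.mu and out.demography.sizes == cfg.demography.sizes

    def test_theta_preserved(self):
        cfg = self._cfg()
        out = rescale_config(cfg, 10.0)
        assert out.demography.sizes[0] * out.mu == pytest.approx(
            cfg.demography.sizes[0] * cfg.mu
        )
        assert out.demography.sizes[0] * out.rec == pytest.approx(
            cfg.demography.sizes[0] * cfg.rec
        )

    def test_shrink_genome_preserves_genomic_mutation_rate(self):
        cfg = self._cfg()
        out = rescale_config(cfg, 10.0, shrink_genome=True)
        assert out.mu * out.seq_len == pytest.approx(cfg.mu * cfg.seq_len)

    def test_migrant_fraction_bound(self):
        cfg = SimConfig(demography=TwoPopModel(n_anc=100, n1=100, n2=50,
                                               t_split=10, m_1_to_2=0.2))
        with pytest.raises(ValueError):
            rescale_config(cfg, 10.0)

    def test_lethal_truncation_mass_grows(self):
        cfg = rescale_config(self._cfg(), 10.0)
        cfg2 = rescale_config(self._cfg(), 40.0)
        assert lethal_truncation_mass(cfg2) > lethal_truncation_mass(cfg)

    def test_neutral_het_agrees_across_lambda(self):
        # equilibrium heterozygosity invariant under rescaling
        hets = {}
        for lam in (1.0, 5.0):
            vals = []
            for seed in range(3):
                cfg = SimConfig(demography=EpochModel.one_epoch(150),
                                seq_len=3e5, mu=2e-7, rec=1e-8,
                                exon_fraction=0.0, seed=40 + seed,
                                burnin_mult=10)
                cfg = rescale_config(cfg, lam)
                st = run_simulation(cfg)["present"]["pop"]
                vals.append(st.heterozygosity)
            hets[lam] = (np.mean(vals), np.std(vals) / np.sqrt(3))
        diff = abs(hets[1.0][0] - hets[5.0][0])
        se = np.hypot(hets[1.0][1], hets[5.0][1])
        assert diff < 3.5 * se


class TestStats:
    def _stats_for(self, H, s, h, pos=None, seq_len=1000.0, sample_n=10):
        from whalepop.forward_sim import _Deme, _Registry

        reg = _Registry()
        n = H.shape[1]
        reg.append(pos if pos is not None else np.arange(n, dtype=float),
                   np.asarray(s, dtype=float), np.asarray(s, dtype=float),
                   np.asarray(h, dtype=float))
        cfg = SimConfig(demography=EpochModel.one_epoch(10), seq_len=seq_len,
                        sample_n=sample_n, roh_min_bp=seq_len * 2)
        return compute_sim_stats(np.asarray(H, dtype=np.int8), reg, cfg,
                                 _Deme(np.asarray(H, dtype=np.int8)),
                                 np.random.default_rng(0))

    def test_mutation_free_zero_load(self):
        H = np.zeros((20, 1), dtype=np.int8)
        st = self._stats_for(H, [-0.1], [0.0])
        assert st.load == 0.0

    def test_single_homozygote_hand_value(self):
        # one of ten diploids homozygous for s=-0.1: load = 1 - (9 + 0.9)/10
        H = np.zeros((20, 1), dtype=np.int8)
        H[0] = 1
        H[1] = 1
        st = self._stats_for(H, [-0.1], [0.0])
        assert st.load == pytest.approx(0.01)

    def test_recessive_heterozygotes_no_load(self):
        H = np.zeros((20, 1), dtype=np.int8)
        H[0::2] = 1  # every individual heterozygous
        st = self._stats_for(H, [-0.1], [0.0])
        assert st.load == 0.0


class TestEquilibrium:
    def test_neutral_heterozygosity_matches_diffusion(self):
        vals = []
        for seed in range(4):
            cfg = SimConfig(demography=EpochModel.one_epoch(100), seq_len=1e6,
                            mu=1e-7, rec=1e-8, exon_fraction=0.0,
                            seed=7 + seed, burnin_mult=10)
            st = run_simulation(cfg)["present"]["pop"]
            vals.append(st.heterozygosity)
        theta = 4 * 100 * 1e-7
        expected = theta / (1 + theta)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3.5 * se

    def test_segregating_sites_match_coalescent_with_no_selection(self):
        # cross-module oracle: forward WF equilibrium vs the coalescent's
        # Watterson expectation for the whole population sample
        n_rep = 6
        S_vals = []
        for seed in range(n_rep):
            cfg = SimConfig(demography=EpochModel.one_epoch(80), seq_len=2e5,
                            mu=2e-7, rec=1e-8, exon_fraction=0.0,
                            seed=70 + seed, burnin_mult=12)
            res = run_simulation(cfg)["present"]["pop"]
            S_vals.append(res.n_segregating)
        theta_tot = 4 * 80 * 2e-7 * 2e5
        a_n = sum(1 / i for i in range(1, 160))
        expected = theta_tot * a_n
        se = np.std(S_vals) / np.sqrt(n_rep)
        assert abs(np.mean(S_vals) - expected) < 4 * se


class TestNamedScenarios:
    def test_catalogue_names(self):
        from whalepop.forward_sim import named_scenario

        for name in ("enp_3epoch", "twopop_mig", "twopop_nomig",
                     "recovery_n1000"):
            cfg = named_scenario(name, seed=1)
            cfg.validate()
        import pytest as _pt
        with _pt.raises(KeyError):
            named_scenario("nope")

    def test_two_generations_at_bottleneck_change_nothing(self):
        # a generations-old crash cannot move load or heterozygosity yet
        dem = EpochModel.three_epoch(150, 220, 10, 300, 2)
        pre, post = [], []
        for seed in (1, 2, 3, 4):
            cfg = SimConfig(demography=dem, seq_len=3e5, mu=3e-7, rec=1e-8,
                            exon_fraction=0.2, s_scale=5.0, seed=seed,
                            burnin_mult=8)
            res = run_simulation(cfg, checkpoints={"pre_bott": 2.0,
                                                   "present": 0.0})
            pre.append(res["pre_bott"]["pop"])
            post.append(res["present"]["pop"])
        h_pre = np.mean([s.heterozygosity for s in pre])
        h_post = np.mean([s.heterozygosity for s in post])
        sd = np.std([s.heterozygosity for s in pre], ddof=1)
        assert abs(h_post - h_pre) < 3 * sd
        l_pre = np.mean([s.load for s in pre])
        l_post = np.mean([s.load for s in post])
        l_sd = np.std([s.load for s in pre], ddof=1) + 1e-4
        assert abs(l_post - l_pre) < 4 * l_sd


class TestScenario:
    def test_migration_reduces_load_in_small_deme(self):
        # matched seeds, tiny model: isolated small deme accumulates load
        model_kw = dict(n_anc=120, n1=120, n2=6, t_split=60)
        loads = {}
        for mig in (True, False):
            vals = []
            for seed in (3, 4, 5):
                dem = TwoPopModel(**model_kw,
                                  m_1_to_2=0.05 if mig else 0.0)
                cfg = SimConfig(demography=dem, seq_len=4e5, mu=5e-7,
                                rec=5e-8, exon_fraction=0.2, seed=seed,
                                burnin_mult=8, s_scale=8.0,
                                track_neutral=False)
                st = run_simulation(cfg)["present"]
                vals.append(st["GOC"].load if "GOC" in st else st["pop2"].load)
            loads[mig] = np.mean(vals)
        assert loads[False] > loads[True]
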