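import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hybridcline.simulate import (ConfigurationError, SimState,
                                  SimulationConfig, ancestry_proxy,
                                  assign_phenotypes, fitness, genetic_value,
                                  initialize, interspecific_het_proxy,
                                  make_fixture_dataset, migrate, reproduce,
                                  run)


def neutral_config(**kwargs):
    defaults = dict(n_trait_loci=0, n_neutral_loci=40,
                    trait_optima=tuple([0.0] * 9), n_generations=50, seed=0)
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def make_state(dosage, deme, W=None):
    n = dosage.shape[0]
    return SimState(generation=0, deme=np.asarray(deme, dtype=np.int16),
                    dosage=np.asarray(dosage, dtype=np.int8),
                    G=np.zeros(n), P=np.zeros(n),
                    W=np.ones(n) if W is None else np.asarray(W, float))


class TestFitness:
    @pytest.mark.parametrize("P,zopt,omega,expected", [
        (5.0, 5.0, 10.0, 1.0),
        (15.0, 5.0, 10.0, np.exp(-0.5)),
        (0.0, 5.0, 10.0, np.exp(-0.125)),
    ])
    def test_gaussian_closed_form(self, P, zopt, omega, expected):
        assert fitness(P, zopt, omega) == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_deviation(self):
        devs = np.linspace(0, 50, 200)
        w = fitness(5.0 + devs, 5.0, 10.0)
        assert np.all(np.diff(w) < 0)
        assert np.all((w > 0) & (w <= 1))

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ConfigurationError):
            fitness(1.0, 0.0, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(P=st.floats(-100, 100), zopt=st.floats(-5, 5),
           omega=st.floats(0.1, 50))
    def test_bounded_and_maximal_at_optimum(self, P, zopt, omega):
        w = fitness(P, zopt, omega)
        assert 0.0 <= w <= 1.0  # positive in exact arithmetic; may underflow
        if (P - zopt) ** 2 / (2 * omega ** 2) < 700:
            assert w > 0.0
        assert w <= fitness(zopt, zopt, omega)


class TestGeneticValue:
    def test_all_plus_alleles(self):
        g = np.ones((40, 2), dtype=int)
        assert genetic_value(g) == 80.0

    def test_heterozygous_cancels(self):
        g = np.tile([0, 1], (40, 1))
        assert genetic_value(g) == 0.0

    def test_mostly_homozygous_minus(self):
        g = np.zeros((40, 2), dtype=int)
        g[0] = [0, 1]
        assert genetic_value(g) == -78.0

    def test_missing_allele_rejected(self):
        g = np.zeros((40, 2), dtype=int)
        g[3] = [-9, -9]
        with pytest.raises(ValueError):
            genetic_value(g)


class TestPhenotypes:
    def test_degenerate_variance(self, rng):
        G = np.full(50, 3.0)
        assert np.array_equal(assign_phenotypes(G, 0.5, rng), G)

    def test_realized_heritability(self, rng):
        G = rng.normal(0, 2, 100_000)
        P = assign_phenotypes(G, 0.5, rng)
        assert G.var() / P.var() == pytest.approx(0.5, abs=0.02)

    def test_h2_one_means_no_noise(self, rng):
        G = rng.normal(0, 2, 100)
        assert np.array_equal(assign_phenotypes(G, 1.0, rng), G)


class TestMigrate:
    def test_zero_rate_is_identity(self, rng):
        st = make_state(np.zeros((30, 4)), np.repeat([0, 1, 2], 10))
        out = migrate(st, 0.0, "stepping_stone", rng, 3)
        assert np.array_equal(out.deme, st.deme)

    @pytest.mark.parametrize("model", ["stepping_stone", "island"])
    def test_individual_count_conserved(self, rng, model):
        st = make_state(np.zeros((900, 2)), rng.integers(0, 9, 900))
        out = migrate(st, 0.3, model, rng, 9)
        assert out.n_individuals == 900
        assert out.deme.min() >= 0 and out.deme.max() < 9

    def test_stepping_stone_binomial_expectation(self, rng):
        # interior deme of 1000, m=0.1: ~100 emigrants, split 50/50
        emigrants, to_left = [], []
        st = make_state(np.zeros((1000, 1)), np.full(1000, 1))
        for _ in range(10_000):
            out = migrate(st, 0.1, "stepping_stone", rng, 3)
            moved = out.deme != 1
            emigrants.append(moved.sum())
            to_left.append((out.deme == 0).sum())
        emigrants = np.array(emigrants, float)
        to_left = np.array(to_left, float)
        se = emigrants.std() / 100.0
        assert emigrants.mean() == pytest.approx(100.0, abs=3 * se + 1e-9)
        frac_left = to_left.sum() / emigrants.sum()
        assert frac_left == pytest.approx(0.5, abs=0.01)

    def test_edge_demes_have_single_neighbor(self, rng):
        st = make_state(np.zeros((2000, 1)), np.repeat([0, 8], 1000))
        out = migrate(st, 0.5, "stepping_stone", rng, 9)
        moved = out.deme != st.deme
        assert set(np.unique(out.deme[moved & (st.deme == 0)])) == {1}
        assert set(np.unique(out.deme[moved & (st.deme == 8)])) == {7}


class TestReproduce:
    def test_fixed_deme_stays_fixed(self, rng):
        cfg = neutral_config(carrying_capacity=50)
        st = make_state(np.full((20, 40), 2), np.zeros(20))
        out = reproduce(st, 50, rng, cfg)
        assert np.all(out.dosage == 2)
        assert out.n_individuals == 50

    def test_selfing_heterozygote_mendelian_ratio(self, rng):
        # single 0/1 parent selfing at one locus: offspring 1:2:1
        cfg = SimulationConfig(n_trait_loci=0, n_neutral_loci=1,
                               trait_optima=tuple([0.0] * 9),
                               carrying_capacity=40_000)
        st = make_state(np.array([[1]]), np.array([0]))
        out = reproduce(st, 40_000, rng, cfg)
        counts = np.bincount(out.dosage[:, 0], minlength=3)
        chi2 = stats.chisquare(counts, f_exp=40_000 * np.array([.25, .5, .25]))
        assert chi2.pvalue > 0.01

    def test_uniform_fitness_gives_uniform_parentage(self, rng):
        # tag parents by private alleles at distinct loci; with equal W the
        # per-parent transmission counts should be multinomially uniform
        cfg = SimulationConfig(n_trait_loci=0, n_neutral_loci=40,
                               trait_optima=tuple([0.0] * 9),
                               carrying_capacity=4000)
        n_parents = 40
        dosage = np.zeros((n_parents, 40), dtype=np.int8)
        dosage[np.arange(n_parents), np.arange(n_parents)] = 2  # marker allele
        st = make_state(dosage, np.zeros(n_parents))
        out = reproduce(st, 4000, rng, cfg)
        # each offspring inherits exactly one marker per parent slot drawn;
        # column sums count parental gametes
        gametes = out.dosage.sum(axis=0)
        chi2 = stats.chisquare(gametes)
        assert chi2.pvalue > 0.01

    def test_empty_demes_stay_empty(self, rng):
        cfg = neutral_config(carrying_capacity=10)
        st = make_state(np.zeros((5, 40)), np.zeros(5))
        out = reproduce(st, 10, rng, cfg)
        assert np.all(out.deme == 0)


class TestInitialize:
    def test_founding_layout(self):
        cfg = SimulationConfig()
        st = initialize(cfg, np.random.default_rng(0))
        assert st.deme_sizes(9).tolist() == [1000, 1000, 1000, 0, 0, 0,
                                             1000, 1000, 1000]
        assert np.all(st.dosage[st.deme < 3] == 0)
        assert np.all(st.dosage[st.deme > 5] == 2)

    def test_founder_genetic_values(self):
        cfg = SimulationConfig()
        st = initialize(cfg, np.random.default_rng(0))
        assert np.all(st.G[st.deme == 0] == -80.0)
        assert np.all(st.G[st.deme == 8] == 80.0)

    def test_founders_have_zero_interspecific_het(self):
        st = initialize(SimulationConfig(), np.random.default_rng(0))
        assert np.all(interspecific_het_proxy(st) == 0.0)

    def test_wrong_deme_count_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_demes=7)
        cfg = SimulationConfig(n_demes=7, trait_optima=tuple([0.0] * 7))
        with pytest.raises(ConfigurationError):
            initialize(cfg, np.random.default_rng(0))


class TestRun:
    def test_deterministic_given_seed(self):
        cfg = neutral_config(n_generations=20, seed=7,
                             snapshot_generations=(20,))
        a, b = run(cfg), run(cfg)
        assert np.array_equal(a.snapshots[0][1].geno, b.snapshots[0][1].geno)
        assert a.summary.equals(b.summary)

    def test_generation_zero_is_two_parental_clusters(self):
        cfg = neutral_config(n_generations=0, snapshot_generations=(0,))
        res = run(cfg)
        st = initialize(cfg, np.random.default_rng(cfg.seed))
        anc, het = ancestry_proxy(st), interspecific_het_proxy(st)
        assert set(np.unique(anc)) == {0.0, 1.0}
        assert np.all(het == 0.0)

    def test_central_demes_get_colonized(self):
        cfg = neutral_config(n_generations=50, seed=3)
        res = run(cfg)
        sizes = res.final_state.deme_sizes(9)
        assert np.all(sizes[3:6] > 0)
        # migration follows reproduction, so end-of-generation sizes
        # fluctuate around K while the total is conserved
        assert sizes.sum() == 9 * 1000

    def test_deme_sizes_equal_capacity_after_reproduction(self, rng):
        cfg = neutral_config(carrying_capacity=200)
        st = make_state(rng.integers(0, 3, (500, 40)),
                        rng.integers(0, 9, 500))
        out = reproduce(st, 200, rng, cfg)
        occupied_before = np.unique(st.deme)
        sizes = out.deme_sizes(9)
        assert np.all(sizes[occupied_before] == 200)

    def test_neutral_allele_frequency_is_martingale(self):
        # single isolated deme: mean frequency over replicate runs stays at p0
        p0 = 0.3
        K = 100
        cfg = SimulationConfig(n_trait_loci=0, n_neutral_loci=40,
                               trait_optima=tuple([0.0] * 9),
                               carrying_capacity=K)
        rng = np.random.default_rng(99)
        finals = []
        for _ in range(25):  # 25 runs x 40 loci = 1000 locus replicates
            dosage = (rng.random((K, 40, 2)) < p0).sum(axis=2).astype(np.int8)
            st = make_state(dosage, np.zeros(K))
            for _ in range(50):
                st = reproduce(st, K, rng, cfg)
            finals.append(st.dosage.mean(axis=0) / 2.0)
        finals = np.concatenate(finals)
        se = finals.std(ddof=1) / np.sqrt(finals.size)
        assert abs(finals.mean() - p0) < 3 * se

    def test_clusters_persist_under_stepping_stone_selection(self):
        # <=30% selected loci: parental + hybrid clusters remain distinct
        # when individuals are scored against the current parental demes
        from hybridcline.ancestry import (biallelic_ml_hybrid_index,
                                          classify_modality)
        from hybridcline.simulate import parental_panel_freqs
        cfg = SimulationConfig(n_trait_loci=10, n_neutral_loci=30,
                               n_generations=3000, seed=5)
        st = run(cfg).final_state
        p_w, p_e = parental_panel_freqs(st)
        h = biallelic_ml_hybrid_index(st.dosage, p_w, p_e, grid_step=0.002)
        assert classify_modality(h) in ("bimodal", "trimodal")


class TestFixtureDataset:
    def test_deterministic(self):
        a_ssr, a_snp, a_meta = make_fixture_dataset(seed=11)
        b_ssr, b_snp, b_meta = make_fixture_dataset(seed=11)
        assert np.array_equal(a_ssr.geno, b_ssr.geno)
        assert np.array_equal(a_snp.geno, b_snp.geno)
        assert a_meta.equals(b_meta)

    def test_metadata_rows(self, fixture_dataset):
        _, _, meta = fixture_dataset
        assert len(meta) == 13
        assert meta["distance_km"].min() == 0.0

    def test_parental_pairs_more_differentiated_than_admixed(self, fixture_dataset):
        gm_snp, = (fixture_dataset[1],)

        def sharing_distance(p1, p2):
            d = 0.0
            for j in range(gm_snp.n_loci):
                f1 = gm_snp.allele_freqs(j, gm_snp.pop_rows(p1))
                f2 = gm_snp.allele_freqs(j, gm_snp.pop_rows(p2))
                alleles = set(f1) | set(f2)
                d += sum(abs(f1.get(a, 0) - f2.get(a, 0)) for a in alleles)
            return d / gm_snp.n_loci

        cross_parental = sharing_distance("FN", "E3")
        admixed = sharing_distance("PG", "MG")
        assert cross_parental > admixed
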