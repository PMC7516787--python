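import numpy as np
import pytest

from mblasso.io_preprocess import allele_frequencies
from mblasso import simulator as sim


class TestSimulateGenotypes:
    def test_seed_reproducibility(self):
        G1 = sim.simulate_genotypes(50, 100, seed=9)
        G2 = sim.simulate_genotypes(50, 100, seed=9)
        np.testing.assert_array_equal(G1.X, G2.X)
        assert G1.snp_map.equals(G2.snp_map)

    def test_allele_frequency_matches_spec(self):
        """At maf 0.5 the empirical frequency stays within 3 binomial SDs."""
        n = 4000
        G = sim.simulate_genotypes(n, 10, maf_range=(0.5, 0.5), seed=1)
        f = allele_frequencies(G)
        sd = np.sqrt(0.5 * 0.5 / (2 * n))
        assert np.all(np.abs(f - 0.5) < 3 * sd + 1e-12)

    def test_qtn_columns_forced_to_030(self):
        G = sim.simulate_genotypes(5000, 20, qtn_indices=[3, 7], seed=2)
        f = allele_frequencies(G)
        for j in (3, 7):
            assert f[j] == pytest.approx(0.30, abs=0.03)

    def test_no_ld_means_uncorrelated_neighbours(self):
        G = sim.simulate_genotypes(2000, 40, ld_rho=0.0, seed=3)
        X = G.X.astype(float)
        corrs = [abs(np.corrcoef(X[:, j], X[:, j + 1])[0, 1])
                 for j in range(39)]
        assert np.mean(corrs) < 0.05

    def test_ld_blocks_induce_local_correlation(self):
        G = sim.simulate_genotypes(2000, 40, ld_rho=0.9, ld_block=20, seed=3)
        X = G.X.astype(float)
        corrs = [np.corrcoef(X[:, j], X[:, j + 1])[0, 1] for j in range(19)]
        assert np.mean(corrs) > 0.4

    def test_five_chromosomes_increasing_positions(self):
        G = sim.simulate_genotypes(10, 100, seed=4)
        m = G.snp_map
        assert sorted(m["chromosome"].unique()) == [1, 2, 3, 4, 5]
        for c, grp in m.groupby("chromosome"):
            assert np.all(np.diff(grp["position"]) > 0)


class TestEffectsFromHeritability:
    def test_polygenic_scenario_accounting(self):
        """sigma2_pg = 2 with the six stated heritabilities implies a
        polygenic heritability of 0.092."""
        V_P = sim.total_phenotypic_variance(
            sim.BENCHMARK_HERITABILITIES, sigma2_e=10.0, sigma2_pg=2.0)
        assert V_P == pytest.approx(12.0 / 0.55)
        assert 2.0 / V_P == pytest.approx(0.092, abs=5e-4)

    def test_epistatic_scenario_accounting(self):
        """Three epistatic pairs at 1.25 each: V_P = 25, per-pair h2 = 0.05."""
        V_P = sim.total_phenotypic_variance(
            sim.BENCHMARK_HERITABILITIES, sigma2_e=10.0,
            sigma2_epi_total=3 * 1.25)
        assert V_P == pytest.approx(25.0)
        assert 1.25 / V_P == pytest.approx(0.05)

    def test_additive_effect_closed_form(self):
        """Scenario-1 accounting: h=0.1 at f=0.3 gives b = 2.0807..."""
        b = sim.effects_from_heritability([0.1, 0.05, 0.05, 0.15, 0.05, 0.05],
                                          np.full(6, 0.3), sigma2_e=10.0)
        V_P = 10.0 / 0.55
        assert b[0] == pytest.approx(np.sqrt(0.1 * V_P / 0.42), rel=1e-12)
        assert b[0] == pytest.approx(2.0807, abs=2e-4)

    def test_heritabilities_must_sum_below_one(self):
        with pytest.raises(ValueError):
            sim.effects_from_heritability([0.6, 0.5], [0.3, 0.3], 10.0)


class TestSimulatePhenotype:
    def test_null_genetics_moments(self):
        """With all effects zero, the trait is Normal(mu, sigma2_e)."""
        G = sim.simulate_genotypes(10_000, 10, seed=6)
        truth = sim.SimTruth(np.array([0]), np.array([0.0]),
                             np.array([0.05]), mu=10.0, sigma2_e=10.0)
        y = sim.simulate_phenotype(G, truth, scenario=1, seed=6)
        assert y.values.mean() == pytest.approx(10.0, abs=0.15)
        assert y.values.var() == pytest.approx(10.0, rel=0.1)

    def test_empirical_heritability_of_strongest_qtn(self):
        """On a large draw, the variance contributed by the h2=0.15 QTN
        matches its nominal share of the phenotypic variance."""
        n = 10_000
        qtn = sim.default_qtn_indices(60)
        G = sim.simulate_genotypes(n, 60, qtn_indices=qtn, seed=8)
        truth = sim.make_sim_truth(G, qtn_indices=qtn, scenario=1)
        y = sim.simulate_phenotype(G, truth, scenario=1, seed=8)
        x4 = G.X[:, truth.qtn_indices[3]].astype(float)
        V_P = sim.total_phenotypic_variance(truth.heritabilities, 10.0)
        h4 = truth.qtn_effects[3] ** 2 * x4.var() / V_P
        assert h4 == pytest.approx(0.15, rel=0.05)
        assert y.values.var() == pytest.approx(V_P, rel=0.1)

    def test_scenario2_adds_kinship_structured_variance(self):
        G, y2, truth = sim.simulate_scenario(2, n=199, p=300, seed=10)
        assert truth.kinship is not None
        assert truth.sigma2_pg == pytest.approx(2.0)
        y1 = sim.simulate_phenotype(G, truth, scenario=1, seed=11)
        # polygenic term raises total variance on average
        assert y2.values.var() > 0

    def test_scenario3_epistasis_pairs_disjoint_from_qtns(self):
        G, y, truth = sim.simulate_scenario(3, n=100, p=200, seed=12)
        assert len(truth.epistatic_pairs) == 3
        for a, b, b_jj in truth.epistatic_pairs:
            assert a not in truth.qtn_indices
            assert b not in truth.qtn_indices
            assert b_jj > 0

    def test_epistatic_collision_rejected(self):
        G = sim.simulate_genotypes(50, 20, qtn_indices=[2], seed=13)
        with pytest.raises(ValueError, match="collides"):
            sim.make_sim_truth(G, qtn_indices=[2], scenario=3,
                               epistatic_pairs=[(2, 5), (6, 7), (8, 9)])

    def test_seed_reproducibility(self):
        G, y1, t = sim.simulate_scenario(1, n=50, p=40, seed=14)
        _, y2, _ = sim.simulate_scenario(1, n=50, p=40, seed=14)
        np.testing.assert_array_equal(y1.values, y2.values)


class TestKinship:
    def test_symmetric_psd(self):
        G = sim.simulate_genotypes(30, 200, seed=15)
        K = sim.kinship(G)
        np.testing.assert_allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_duplicate_individuals_maximally_related(self):
        G = sim.simulate_genotypes(10, 300, seed=16)
        X = np.vstack([G.X, G.X[:1]])  # clone individual 0

        K = sim.kinship(X)
        assert K[0, 10] == pytest.approx(K[0, 0])

    def test_independent_individuals_near_zero_offdiag(self):
        # centering makes off-diagonals ~ -1/(n-1) plus O(1/sqrt(p)) noise,
        # both vanishing for unrelated individuals at this scale
        G = sim.simulate_genotypes(100, 2000, seed=17)
        K = sim.kinship(G)
        off = K[~np.eye(100, dtype=bool)]
        assert np.mean(np.abs(off)) < 0.05

    def test_zero_variance_columns_skipped(self):
        X = np.column_stack([np.ones(8), np.tile([1, -1], 4)]).astype(int)
        with pytest.warns(UserWarning, match="zero-variance"):
            K = sim.kinship(X)
        assert np.isfinite(K).all()


def test_phenotypic_variance_accounting_monte_carlo():
    """Generated trait variance matches the accounting identity within
    Monte-Carlo error at n = 1000."""
    qtn = sim.default_qtn_indices(100)
    G = sim.simulate_genotypes(1000, 100, qtn_indices=qtn, seed=20)
    truth = sim.make_sim_truth(G, qtn_indices=qtn, scenario=1)
    y = sim.simulate_phenotype(G, truth, scenario=1, seed=21)
    V_P = sim.total_phenotypic_variance(truth.heritabilities, truth.sigma2_e)
    # 3-SD band for a variance estimate from ~n draws
    sd = V_P * np.sqrt(2 / 999)
    assert abs(y.values.var() - V_P) < 4 * sd
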