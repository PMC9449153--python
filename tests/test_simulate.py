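import numpy as np
import pandas as pd
import pytest

from hatchtraj.legendre import legendre_matrix
from hatchtraj.relationships import Pedigree
from hatchtraj.simulate import (
    SimulationConfig,
    TrueParameters,
    _gene_drop_coefficients,
    _transmit,
    default_parameters,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)
from hatchtraj.trajectories import variance_at_age


def quiet_parameters(**overrides) -> TrueParameters:
    """Parameters with every effect switched off unless overridden."""
    base = dict(
        K_aF=np.zeros((1, 1)),
        K_aM=np.zeros((1, 1)),
        K_peF=np.zeros((1, 1)),
        K_peM=np.zeros((1, 1)),
        sigma2_e=np.zeros(13),
        beta_age=np.array([-3.5, -1.0, 0.8]),
        hatch_week_effects=np.zeros(6),
        egg_hatch_week_effects=np.zeros(10),
    )
    base.update(overrides)
    return TrueParameters(**base)


class TestPedigreeSimulation:
    def test_single_generation_founders_only(self):
        cfg = SimulationConfig(n_generations=1, n_females_per_gen=4, n_males_per_gen=2)
        ped = simulate_pedigree(cfg)
        assert ped.n == 6
        assert np.all(ped.sire == -1) and np.all(ped.dam == -1)

    def test_parents_come_from_previous_generation(self):
        cfg = SimulationConfig(n_generations=2, n_females_per_gen=20, n_males_per_gen=4)
        ped = simulate_pedigree(cfg)
        young = ped.generation == 1
        assert np.all(ped.generation[ped.sire[young]] == 0)
        assert np.all(ped.generation[ped.dam[young]] == 0)

    def test_mating_ratio_about_five_to_one(self):
        cfg = SimulationConfig(n_generations=2, n_females_per_gen=100, n_males_per_gen=20)
        ped = simulate_pedigree(cfg)
        per_tom = ped.matings.groupby("tom").size()
        assert per_tom.max() == 5 and per_tom.min() == 5

    def test_determinism_under_seed(self):
        cfg = SimulationConfig(n_generations=3, n_females_per_gen=15, n_males_per_gen=3)
        a, b = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert np.array_equal(a.sire, b.sire) and np.array_equal(a.dam, b.dam)
        assert a.matings.equals(b.matings)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_females_per_gen=0)


class TestGenotypeSimulation:
    def test_homozygous_parents_fix_offspring(self):
        rng = np.random.default_rng(0)
        assert np.array_equal(_transmit(np.array([2, 0, 2]), rng), [1, 0, 1])

    def test_offspring_within_mendelian_bounds(self):
        cfg = SimulationConfig(
            n_generations=2, n_females_per_gen=30, n_males_per_gen=6,
            n_snps=100, genotyped_fraction=1.0, seed=9,
        )
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        dos = g.dosages
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s < 0:
                continue
            # parent dosage 0 contributes no alt allele; dosage 2 contributes one
            low = (dos[s] == 2).astype(int) + (dos[d] == 2).astype(int)
            high = 2 - (dos[s] == 0).astype(int) - (dos[d] == 0).astype(int)
            assert np.all(dos[i] >= low) and np.all(dos[i] <= high)

    def test_allele_frequencies_drift_bounded(self):
        cfg = SimulationConfig(
            n_generations=2, n_females_per_gen=200, n_males_per_gen=40,
            n_snps=300, genotyped_fraction=1.0, seed=2,
        )
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        founders = ped.generation[ped.positions(g.animal_ids)] == 0
        pf = g.dosages[founders].mean(axis=0) / 2
        po = g.dosages[~founders].mean(axis=0) / 2
        # binomial-sampling bound on the generation-to-generation change
        se = np.sqrt(pf * (1 - pf) / (2 * (~founders).sum()) * 5)
        assert np.mean(np.abs(po - pf) < 5 * se + 0.05) > 0.95

    def test_last_chromosome_is_non_autosomal(self):
        cfg = SimulationConfig(
            n_generations=1, n_females_per_gen=10, n_males_per_gen=2,
            n_snps=50, n_chromosomes=5, genotyped_fraction=1.0,
        )
        ped = simulate_pedigree(cfg)
        g = simulate_genotypes(ped, cfg)
        chroms = g.marker_meta["chromosome"]
        assert (chroms == "Z").sum() == 10
        assert chroms.iloc[-1] == "Z"

    def test_determinism_under_seed(self):
        cfg = SimulationConfig(
            n_generations=2, n_females_per_gen=10, n_males_per_gen=2, n_snps=40
        )
        ped = simulate_pedigree(cfg)
        assert np.array_equal(
            simulate_genotypes(ped, cfg).dosages, simulate_genotypes(ped, cfg).dosages
        )


class TestPhenotypeSimulation:
    def test_noise_free_limit_equals_fixed_trend(self):
        cfg = SimulationConfig(
            n_generations=2, n_females_per_gen=10, n_males_per_gen=2, dropout=0.0
        )
        params = quiet_parameters()
        ped = simulate_pedigree(cfg)
        data = simulate_phenotypes(ped, params, cfg)
        grid = cfg.grid
        basis = legendre_matrix(grid, 3).values[:, 1:]
        trend = {a: 81.1 + basis[i] @ params.beta_age for i, a in enumerate(grid.ages)}
        expect = data["age_weeks"].map(trend)
        assert np.allclose(data["value"], expect, atol=1e-4)

    def test_intercept_only_additive_variance(self):
        v = 100.0
        cfg = SimulationConfig(
            n_generations=2, n_females_per_gen=600, n_males_per_gen=120, dropout=0.0,
            seed=5,
        )
        params = quiet_parameters(K_aF=np.array([[v]]))
        ped = simulate_pedigree(cfg)
        data, eff = simulate_phenotypes(ped, params, cfg, return_effects=True)
        one_age = data[data["age_weeks"] == 38]["value"]
        # contribution is phi_0 * aF with phi_0^2 = 1/2
        assert one_age.var() == pytest.approx(v / 2, rel=0.2)

    def test_full_sib_coefficient_correlation(self):
        ped = Pedigree(
            ids=np.arange(1, 5),
            sire=np.array([-1, -1, 0, 0]),
            dam=np.array([-1, -1, 1, 1]),
        )
        rng = np.random.default_rng(12)
        sibs = np.array(
            [_gene_drop_coefficients(ped, np.eye(1), rng)[2:, 0] for _ in range(4000)]
        )
        r = np.corrcoef(sibs[:, 0], sibs[:, 1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.05)

    def test_per_age_phenotypic_variance_matches_closed_form(self):
        cfg = SimulationConfig(
            n_generations=2, n_females_per_gen=800, n_males_per_gen=160, dropout=0.0,
            seed=3,
        )
        params = default_parameters()
        ped = simulate_pedigree(cfg)
        data = simulate_phenotypes(ped, params, cfg)
        grid = cfg.grid
        expected = params.sigma2_e.copy()
        for K in (params.K_aF, params.K_aM, params.K_peF, params.K_peM):
            expected += variance_at_age(K, legendre_matrix(grid, K.shape[0] - 1))
        observed = data.groupby("age_weeks")["value"].var().to_numpy()
        rel = np.abs(observed - expected) / expected
        assert rel.mean() < 0.10

    def test_non_psd_covariance_rejected_by_name(self):
        with pytest.raises(ValueError, match="K_peM"):
            quiet_parameters(K_peM=np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_dropout_thins_records(self):
        cfg = SimulationConfig(
            n_generations=2, n_females_per_gen=200, n_males_per_gen=40, dropout=0.3,
            seed=8,
        )
        ped = simulate_pedigree(cfg)
        data = simulate_phenotypes(ped, quiet_parameters(), cfg)
        frac = len(data) / (200 * 13)
        assert frac == pytest.approx(0.7, abs=0.05)

    def test_determinism_and_clamping(self):
        cfg = SimulationConfig(
            n_generations=2, n_females_per_gen=20, n_males_per_gen=4,
            clamp_percentages=True, seed=4,
        )
        ped = simulate_pedigree(cfg)
        params = default_parameters()
        a = simulate_phenotypes(ped, params, cfg)
        b = simulate_phenotypes(ped, params, cfg)
        assert a.equals(b)
        assert a["value"].between(0, 100).all()
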