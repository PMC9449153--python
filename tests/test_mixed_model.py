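import numpy as np
import pandas as pd
import pytest

from hatchtraj.legendre import AgeGrid, legendre_matrix, legendre_row
from hatchtraj.mixed_model import (
    ModelSpec,
    RandomTerm,
    REMLOptions,
    VarianceComponents,
    aggregate_cumulative,
    assemble_mme,
    build_design,
    default_start,
    ebv_per_age,
    log_likelihood,
    reml_estimate,
    solve_mme,
)
from hatchtraj.relationships import (
    Pedigree,
    build_A,
    build_H_inverse,
    pedigree_relationship_inverse,
)
from hatchtraj.simulate import SimulationConfig, simulate_pedigree, simulate_phenotypes

from conftest import random_pedigree
from test_simulate import quiet_parameters


def one_founder():
    return Pedigree(ids=np.array([1]), sire=np.array([-1]), dam=np.array([-1]))


def cum_records(values, hens=None, hw=None):
    n = len(values)
    return pd.DataFrame(
        {
            "hen": hens if hens is not None else np.arange(1, n + 1),
            "hatch_week": hw if hw is not None else np.ones(n, dtype=int),
            "value": values,
        }
    )


def tiny_rr_dataset(seed=3, dropout=0.3, nf=6, nm=2):
    cfg = SimulationConfig(
        n_generations=2, n_females_per_gen=nf, n_males_per_gen=nm,
        genotyped_fraction=0.0, seed=seed, dropout=dropout,
    )
    ped = simulate_pedigree(cfg)
    from hatchtraj.simulate import default_parameters

    data = simulate_phenotypes(ped, default_parameters(), cfg)
    return cfg, ped, data


def dense_gls(design, vc, A):
    """Brute-force GLS/BLUP oracle from the observation covariance."""
    X = design.X.toarray()
    y = design.y
    R = np.diag(vc.sigma2_e[design.age_class])
    V = R.copy()
    covs = {}
    for term in design.spec.terms:
        Z = design.Z[term.name].toarray()
        nlev = design.term_levels[term.name].size
        rel = A if term.covariance == "additive" else np.eye(nlev)
        G = np.kron(rel, vc.K[term.name])
        covs[term.name] = (Z, G)
        V += Z @ G @ Z.T
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = y - X @ beta
    u = {t: G @ Z.T @ Vi @ resid for t, (Z, G) in covs.items()}
    n, p = y.size, X.shape[1]
    P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi)
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(X.T @ Vi @ X)[1]
        + y @ P @ y
    )
    return beta, u, ll


class TestDesign:
    def test_cumulative_random_design_is_indicator(self, trio):
        data = cum_records([70.0, 80.0, 90.0], hens=[1, 2, 3])
        des = build_design(ModelSpec.cumulative(), data, ped=trio)
        Z = des.Z["animal"].toarray()
        assert np.array_equal(Z, np.eye(3))

    def test_rr_record_carries_basis_row_of_its_hen(self):
        ped = Pedigree(
            ids=np.array([1, 2]), sire=np.array([-1, -1]), dam=np.array([-1, -1]),
        )
        data = pd.DataFrame(
            {
                "hen": [1, 1],
                "tom": [2, 2],
                "age_weeks": [50, 38],
                "hatch_week": [1, 1],
                "egg_hatch_week": [1, 2],
                "value": [80.0, 82.0],
            }
        )
        des = build_design(ModelSpec.random_regression(), data, ped=ped)
        grid = AgeGrid()
        Z = des.Z["hen_additive"].toarray()
        assert np.allclose(Z[0, 0:4], legendre_row(50.0, grid, 3))
        assert np.allclose(Z[1, 0:4], legendre_row(38.0, grid, 3))
        # same hen: identical column block, different covariate rows
        assert np.all(Z[:, 4:] == 0)

    def test_unknown_animal_reported(self, trio):
        data = cum_records([70.0], hens=[99])
        with pytest.raises(ValueError, match="99"):
            build_design(ModelSpec.cumulative(), data, ped=trio)


class TestSolve:
    def test_single_record_founder(self):
        ped = one_founder()
        des = build_design(ModelSpec.cumulative(), cum_records([10.0]), ped=ped)
        vc = VarianceComponents({"animal": [[1.0]]}, [1.0])
        res = solve_mme(assemble_mme(des, vc, pedigree_relationship_inverse(ped)))
        assert res.fixed.sum() == pytest.approx(10.0)
        assert res.coefficients["animal"].iloc[0, 0] == pytest.approx(0.0)

    def test_infinite_variance_ridge_limit(self):
        ped = random_pedigree(30, seed=0)
        rng = np.random.default_rng(1)
        data = cum_records(rng.normal(80, 5, 30), hens=ped.ids)
        des = build_design(ModelSpec.cumulative(), data, ped=ped)
        relinv = pedigree_relationship_inverse(ped)
        big = solve_mme(assemble_mme(des, VarianceComponents({"animal": [[1e12]]}, [1.0]), relinv))
        X = des.X.toarray()
        ols = np.linalg.lstsq(X, des.y, rcond=None)[0]
        fit_big = X @ big.fixed.to_numpy() + big.coefficients["animal"].to_numpy()[:, 0][
            des.data["hen"].to_numpy() - 1
        ]
        assert np.allclose(fit_big, des.y, atol=1e-3)

    def test_duplicate_records_leave_solutions_unchanged(self, trio):
        data = cum_records([70.0, 80.0, 90.0], hens=[1, 2, 3])
        doubled = pd.concat([data, data], ignore_index=True)
        vc = VarianceComponents({"animal": [[5.0]]}, [10.0])
        relinv = pedigree_relationship_inverse(trio)
        r1 = solve_mme(assemble_mme(build_design(ModelSpec.cumulative(), data, ped=trio), vc, relinv))
        # two half-weight copies of each record carry the same information
        vc2 = VarianceComponents({"animal": [[5.0]]}, [20.0])
        r2 = solve_mme(
            assemble_mme(build_design(ModelSpec.cumulative(), doubled, ped=trio), vc2, relinv)
        )
        assert np.allclose(
            r1.coefficients["animal"].to_numpy(), r2.coefficients["animal"].to_numpy(),
            atol=1e-10,
        )

    def test_matches_gls_oracle_cumulative(self):
        ped = random_pedigree(100, seed=5)
        rng = np.random.default_rng(2)
        data = cum_records(
            rng.normal(80, 8, 100), hens=ped.ids, hw=rng.integers(1, 4, 100)
        )
        des = build_design(ModelSpec.cumulative(), data, ped=ped)
        vc = VarianceComponents({"animal": [[30.0]]}, [70.0])
        res = solve_mme(assemble_mme(des, vc, pedigree_relationship_inverse(ped)))
        beta, u, _ = dense_gls(des, vc, build_A(ped))
        assert np.abs(beta - res.fixed.to_numpy()).max() < 1e-8
        assert np.abs(u["animal"] - res.coefficients["animal"].to_numpy()[:, 0]).max() < 1e-8

    def test_matches_gls_oracle_random_regression(self):
        _, ped, data = tiny_rr_dataset()
        spec = ModelSpec.random_regression()
        des = build_design(spec, data, ped=ped)
        vc = default_start(des)
        res = solve_mme(assemble_mme(des, vc, pedigree_relationship_inverse(ped)))
        beta, u, _ = dense_gls(des, vc, build_A(ped))
        assert np.abs(beta - res.fixed.to_numpy()).max() < 1e-7
        got = res.coefficients["hen_additive"].to_numpy().ravel()
        assert np.abs(u["hen_additive"] - got).max() < 1e-7

    def test_fixed_effect_normal_equation_orthogonality(self):
        _, ped, data = tiny_rr_dataset(seed=8)
        des = build_design(ModelSpec.random_regression(), data, ped=ped)
        vc = default_start(des)
        system = assemble_mme(des, vc, pedigree_relationship_inverse(ped))
        sol = system.solution()
        resid = system.rinv * (des.y - system.W @ sol)
        assert np.abs(des.X.T @ resid).max() < 1e-8

    def test_pedigree_and_single_step_agree_without_genotypes(self):
        _, ped, data = tiny_rr_dataset(seed=4)
        des = build_design(ModelSpec.random_regression(), data, ped=ped)
        vc = default_start(des)
        r_a = solve_mme(assemble_mme(des, vc, pedigree_relationship_inverse(ped)))
        r_h = solve_mme(assemble_mme(des, vc, build_H_inverse(ped, None)))
        assert np.allclose(
            r_a.coefficients["hen_additive"].to_numpy(),
            r_h.coefficients["hen_additive"].to_numpy(),
        )


class TestRestrictedLikelihood:
    def test_matches_multivariate_normal_oracle(self):
        _, ped, data = tiny_rr_dataset(seed=7, nf=4, nm=2, dropout=0.6)
        assert len(data) <= 60
        des = build_design(ModelSpec.random_regression(), data, ped=ped)
        vc = default_start(des)
        relinv = pedigree_relationship_inverse(ped)
        _, _, oracle = dense_gls(des, vc, build_A(ped))
        assert log_likelihood(des, vc, relinv) == pytest.approx(oracle, abs=1e-6)

    def test_dense_and_sparse_paths_agree(self):
        _, ped, data = tiny_rr_dataset(seed=5)
        des = build_design(ModelSpec.random_regression(), data, ped=ped)
        vc = default_start(des)
        relinv = pedigree_relationship_inverse(ped)
        ll_dense = log_likelihood(des, vc, relinv, dense_threshold=10**6)
        ll_sparse = log_likelihood(des, vc, relinv, dense_threshold=0)
        assert ll_dense == pytest.approx(ll_sparse, abs=1e-8)

    def test_reml_optimum_beats_perturbations(self):
        ped = random_pedigree(60, seed=9)
        rng = np.random.default_rng(3)
        u = rng.multivariate_normal(np.zeros(60), 25 * build_A(ped))
        data = cum_records(80 + u + rng.normal(0, np.sqrt(50), 60), hens=ped.ids)
        relinv = pedigree_relationship_inverse(ped)
        fit = reml_estimate(ModelSpec.cumulative(), data, ped=ped, relinv=relinv)
        des = build_design(ModelSpec.cumulative(), data, ped=ped)
        assert log_likelihood(des, fit.vc, relinv) == pytest.approx(fit.logL, abs=1e-6)
        for _ in range(20):
            pert = VarianceComponents(
                {"animal": fit.vc.K["animal"] * rng.uniform(0.5, 2.0)},
                fit.vc.sigma2_e * rng.uniform(0.5, 2.0),
            )
            assert log_likelihood(des, pert, relinv) <= fit.logL + 1e-8


class TestREML:
    def test_balanced_one_way_matches_anova(self):
        rng = np.random.default_rng(0)
        k, m = 80, 4
        u = rng.normal(0, np.sqrt(3.0), k)
        y = 10 + np.repeat(u, m) + rng.normal(0, np.sqrt(2.0), k * m)
        data = pd.DataFrame(
            {"hen": np.repeat(np.arange(1, k + 1), m), "hatch_week": 1, "value": y}
        )
        ybar_i = data.groupby("hen")["value"].mean().to_numpy()
        msb = m * np.sum((ybar_i - y.mean()) ** 2) / (k - 1)
        msw = np.sum((y - np.repeat(ybar_i, m)) ** 2) / (k * (m - 1))
        spec = ModelSpec(
            kind="cumulative",
            fixed_factors=(),
            fixed_regression_order=0,
            terms=(RandomTerm("animal", "hen", 0, "iid", "indicator"),),
            residual="homogeneous",
        )
        fit = reml_estimate(spec, data)
        assert fit.converged
        assert fit.vc.K["animal"][0, 0] == pytest.approx((msb - msw) / m, rel=1e-5)
        assert fit.vc.sigma2_e[0] == pytest.approx(msw, rel=1e-5)

    def test_profile_path_agrees_with_generic_likelihood(self):
        ped = random_pedigree(80, seed=2)
        rng = np.random.default_rng(1)
        u = rng.multivariate_normal(np.zeros(80), 30 * build_A(ped))
        data = cum_records(80 + u + rng.normal(0, np.sqrt(70), 80), hens=ped.ids)
        relinv = pedigree_relationship_inverse(ped)
        fit = reml_estimate(ModelSpec.cumulative(), data, ped=ped, relinv=relinv)
        des = build_design(ModelSpec.cumulative(), data, ped=ped)
        assert log_likelihood(des, fit.vc, relinv) == pytest.approx(fit.logL, abs=1e-7)

    def test_zero_residual_boundary_floored(self):
        ped = random_pedigree(50, seed=6)
        rng = np.random.default_rng(4)
        u = rng.multivariate_normal(np.zeros(50), 25 * build_A(ped))
        data = cum_records(80 + u, hens=ped.ids)  # no residual noise at all
        fit = reml_estimate(ModelSpec.cumulative(), data, ped=ped)
        assert fit.vc.sigma2_e[0] > 0
        h2 = fit.vc.K["animal"][0, 0] / (fit.vc.K["animal"][0, 0] + fit.vc.sigma2_e[0])
        assert h2 > 0.95

    def test_monotone_accepted_loglik_trace(self):
        _, ped, data = tiny_rr_dataset(seed=2, nf=20, nm=4, dropout=0.1)
        fit = reml_estimate(
            ModelSpec.random_regression(),
            data,
            ped=ped,
            options=REMLOptions(max_iter=8, dense_threshold=0),
        )
        lls = [t[1] for t in fit.trace]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


class TestBreedingValues:
    def test_intercept_only_coefficient_gives_constant_ebv(self):
        coefs = pd.DataFrame({"c0": [2.0], "c1": [0.0], "c2": [0.0], "c3": [0.0]})
        from hatchtraj.mixed_model import EvaluationResult

        res = EvaluationResult(
            fixed=pd.Series(dtype=float),
            coefficients={"hen_additive": coefs},
            spec=ModelSpec.random_regression(),
            vc=VarianceComponents({"hen_additive": np.eye(4)}, np.ones(13)),
        )
        basis = legendre_matrix(AgeGrid(), 3)
        ebv = ebv_per_age(res, basis)
        assert np.allclose(ebv.to_numpy(), 2.0 * np.sqrt(0.5))

    def test_zero_coefficients_give_zero_ebv(self, trio):
        data = cum_records([80.0, 80.0, 80.0], hens=[1, 2, 3])
        des = build_design(ModelSpec.cumulative(), data, ped=trio)
        vc = VarianceComponents({"animal": [[5.0]]}, [10.0])
        res = solve_mme(assemble_mme(des, vc, pedigree_relationship_inverse(trio)))
        assert np.allclose(ebv_per_age(res)["ebv"], 0.0, atol=1e-12)

    def test_cumulative_ebv_equals_coefficient(self, trio):
        data = cum_records([70.0, 90.0, 80.0], hens=[1, 2, 3])
        des = build_design(ModelSpec.cumulative(), data, ped=trio)
        vc = VarianceComponents({"animal": [[20.0]]}, [50.0])
        res = solve_mme(assemble_mme(des, vc, pedigree_relationship_inverse(trio)))
        assert np.array_equal(
            ebv_per_age(res)["ebv"].to_numpy(),
            res.coefficients["animal"]["c0"].to_numpy(),
        )

    def test_basis_order_mismatch_rejected(self):
        coefs = pd.DataFrame(np.zeros((1, 4)), columns=[f"c{i}" for i in range(4)])
        from hatchtraj.mixed_model import EvaluationResult

        res = EvaluationResult(
            fixed=pd.Series(dtype=float),
            coefficients={"hen_additive": coefs},
            spec=ModelSpec.random_regression(),
            vc=VarianceComponents({"hen_additive": np.eye(4)}, np.ones(13)),
        )
        with pytest.raises(ValueError, match="basis"):
            ebv_per_age(res, legendre_matrix(AgeGrid(), 2))


def test_aggregate_cumulative_means_per_hen():
    data = pd.DataFrame(
        {
            "trait": ["HOF"] * 4,
            "hen": [1, 1, 2, 2],
            "tom": [5, 5, 6, 6],
            "age_weeks": [38, 40, 38, 40],
            "hatch_week": [1, 1, 2, 2],
            "egg_hatch_week": [1, 2, 1, 2],
            "value": [80.0, 90.0, 60.0, 70.0],
        }
    )
    cum = aggregate_cumulative(data)
    assert cum.set_index("hen")["value"].to_dict() == {1: 85.0, 2: 65.0}
    assert cum.set_index("hen")["tom"].to_dict() == {1: 5, 2: 6}
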