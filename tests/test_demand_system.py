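import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vatfood.demand_system import (
    ElasticityMatrix,
    calibrate_elasticities,
    check_aggregation,
    demand_response,
    energy_and_mass_changes,
)
from vatfood.synthetic_data import generate_elasticity_prior


def random_prior(n, rng):
    eps, eta = generate_elasticity_prior(n, rng)
    w = rng.dirichlet(np.ones(n) * 5.0)
    return ElasticityMatrix(eps=eps, eta=eta, w=w)


class TestCheckAggregation:
    def test_single_good_forced_solution(self):
        E = ElasticityMatrix(eps=[[-1.0]], eta=[1.0], w=[1.0])
        engel, cournot = check_aggregation(E)
        assert engel == 0.0 and cournot[0] == 0.0

    def test_two_good_zero_prior(self):
        E = ElasticityMatrix(eps=np.zeros((2, 2)), eta=[0.0, 0.0], w=[0.5, 0.5])
        engel, cournot = check_aggregation(E)
        assert engel == pytest.approx(-1.0)
        assert cournot == pytest.approx([0.5, 0.5])

    def test_matches_loop_oracle(self, rng):
        E = random_prior(4, rng)
        engel, cournot = check_aggregation(E)
        engel_loop = sum(E.w[i] * E.eta[i] for i in range(4)) - 1.0
        assert engel == pytest.approx(engel_loop, abs=1e-12)
        for j in range(4):
            cj = sum(E.w[i] * E.eps[i, j] for i in range(4)) + E.w[j]
            assert cournot[j] == pytest.approx(cj, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimensions"):
            ElasticityMatrix(eps=np.zeros((2, 3)), eta=[0.0, 0.0], w=[0.5, 0.5])


class TestCalibration:
    def test_consistent_prior_is_a_fixed_point(self, rng):
        prior = random_prior(3, rng)
        first = calibrate_elasticities(prior, method="projection")
        second = calibrate_elasticities(first, method="projection")
        assert np.allclose(first.eps, second.eps, atol=1e-10)
        assert np.allclose(first.eta, second.eta, atol=1e-10)

    def test_single_good_fully_determined(self):
        prior = ElasticityMatrix(eps=[[-0.3]], eta=[0.5], w=[1.0])
        for method in ("projection", "gme"):
            out = calibrate_elasticities(prior, method=method)
            assert out.eta[0] == pytest.approx(1.0, abs=1e-8)
            assert out.eps[0, 0] == pytest.approx(-1.0, abs=1e-8)

    def test_projection_matches_hand_assembled_kkt(self):
        # 2 goods: 3 restrictions (Engel + 2 Cournot) on 6 unknowns
        w = np.array([0.6, 0.4])
        eps_hat = np.array([[-0.5, 0.1], [0.1, -0.5]])
        eta_hat = np.array([0.8, 0.9])
        prior = ElasticityMatrix(eps=eps_hat, eta=eta_hat, w=w)
        out = calibrate_elasticities(prior, method="projection")

        # independent oracle: explicit KKT assembly with loops
        x_hat = np.array([-0.5, 0.1, 0.1, -0.5, 0.8, 0.9])
        A = np.zeros((3, 6))
        A[0, 4], A[0, 5] = w
        for j in range(2):
            for i in range(2):
                A[1 + j, i * 2 + j] = w[i]
        b = np.array([1.0, -w[0], -w[1]])
        K = np.block([[2 * np.eye(6), A.T], [A, np.zeros((3, 3))]])
        sol = np.linalg.solve(K, np.concatenate([2 * x_hat, b]))
        assert np.allclose(np.concatenate([out.eps.ravel(), out.eta]), sol[:6], atol=1e-10)

    @pytest.mark.parametrize("method", ["projection", "gme"])
    def test_residuals_below_tolerance(self, method, rng):
        for n in (2, 5, 9):
            out = calibrate_elasticities(random_prior(n, rng), method=method)
            engel, cournot = check_aggregation(out)
            assert abs(engel) <= 1e-8
            assert np.abs(cournot).max() <= 1e-8

    def test_projection_minimality_among_feasible_points(self, rng):
        prior = random_prior(5, rng)
        out = calibrate_elasticities(prior, method="projection")
        x_hat = np.concatenate([prior.eps.ravel(), prior.eta])
        x_star = np.concatenate([out.eps.ravel(), out.eta])
        n = 5
        A = np.zeros((n + 1, n * n + n))
        A[0, n * n :] = prior.w
        for j in range(n):
            A[1 + j, j : n * n : n] = prior.w
        # random feasible perturbations stay in the constraint null space
        _, _, vt = np.linalg.svd(A)
        null = vt[n + 1 :].T
        obj = lambda x: ((x - x_hat) ** 2).sum()
        for _ in range(25):
            d = null @ rng.normal(size=null.shape[1])
            assert obj(x_star + 0.1 * d) >= obj(x_star) - 1e-10

    def test_gme_infeasible_support_reports_helpfully(self):
        prior = ElasticityMatrix(
            eps=np.zeros((2, 2)), eta=[0.0, 0.0], w=[0.5, 0.5]
        )
        with pytest.raises(ValueError, match="support"):
            calibrate_elasticities(prior, method="gme", support_width=1e-6)

    def test_homogeneity_flag_adds_row_restrictions(self, rng):
        out = calibrate_elasticities(
            random_prior(4, rng), method="projection", homogeneity=True
        )
        assert np.allclose(out.eps.sum(axis=1) + out.eta, 0.0, atol=1e-8)


class TestDemandResponse:
    def test_zero_price_change_is_identity(self, rng):
        E = calibrate_elasticities(random_prior(4, rng))
        q = np.array([10.0, 20.0, 30.0, 40.0])
        assert np.array_equal(demand_response(q, np.zeros(4), E), q)

    def test_unit_elastic_single_good(self):
        E = ElasticityMatrix(eps=[[-1.0]], eta=[1.0], w=[1.0])
        q1 = demand_response(np.array([100.0]), np.array([np.log(1.1)]), E)
        assert q1[0] == pytest.approx(100.0 / 1.1, rel=1e-12)

    def test_matches_elementwise_loop_oracle(self, rng):
        E = calibrate_elasticities(random_prior(5, rng))
        q = rng.uniform(10, 500, size=5)
        dlnp = rng.uniform(-0.2, 0.2, size=5)
        got = demand_response(q, dlnp, E)
        for i in range(5):
            expect = q[i] * np.exp(sum(E.eps[i, j] * dlnp[j] for j in range(5)))
            assert got[i] == pytest.approx(expect, rel=1e-12)

    def test_linear_form_first_order(self, rng):
        E = calibrate_elasticities(random_prior(3, rng))
        q = np.array([1.0, 2.0, 3.0])
        dlnp = np.array([0.01, 0.0, -0.01])
        lin = demand_response(q, dlnp, E, form="linear")
        assert np.allclose(lin, q * (1 + E.eps @ dlnp))

    @given(st.floats(0.001, 0.3))
    @settings(max_examples=20)
    def test_monotone_decreasing_in_own_price(self, dp):
        E = ElasticityMatrix(
            eps=[[-0.8, 0.0], [0.0, -0.5]], eta=[1.0, 1.0], w=[0.5, 0.5]
        )
        q = np.array([100.0, 100.0])
        up = demand_response(q, np.array([np.log1p(dp), 0.0]), E)
        assert up[0] < q[0] and up[1] == q[1]

    def test_first_order_expenditure_neutrality_after_calibration(self, rng):
        # Cournot aggregation makes spending invariant to first order
        for _ in range(5):
            n = int(rng.integers(2, 10))
            E = calibrate_elasticities(random_prior(n, rng))
            dlnp = rng.uniform(-1e-4, 1e-4, size=n)
            dlnq = E.eps @ dlnp
            residual = E.w @ (dlnq + dlnp)
            assert abs(residual) <= 10 * (np.linalg.norm(dlnp) ** 2 + 1e-14)

    def test_nonfinite_price_change_rejected(self, rng):
        E = calibrate_elasticities(random_prior(2, rng))
        with pytest.raises(ValueError, match="finite"):
            demand_response(np.ones(2), np.array([np.nan, 0.0]), E)


class TestEnergyAndMassChanges:
    def test_no_change(self):
        q = np.array([10.0, 20.0])
        dm, de = energy_and_mass_changes(q, q, np.array([1.0, 2.0]))
        assert np.all(dm == 0) and de == 0.0

    def test_single_group_arithmetic(self):
        dm, de = energy_and_mass_changes(
            np.array([100.0]), np.array([51.0]), np.array([0.6])
        )
        assert dm[0] == pytest.approx(-49.0)
        assert de == pytest.approx(-29.4)

    def test_matches_loop_summation(self, rng):
        q0 = rng.uniform(0, 500, 24)
        q1 = rng.uniform(0, 500, 24)
        kcal = rng.uniform(0.2, 9.0, 24)
        dm, de = energy_and_mass_changes(q0, q1, kcal)
        assert de == pytest.approx(
            sum(kcal[i] * (q1[i] - q0[i]) for i in range(24)), rel=1e-12
        )
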