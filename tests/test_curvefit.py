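import numpy as np
import pytest

from ecfctox import build_basis, penalty_matrix, evaluate_curve, fit_curve, FittedCurve
from ecfctox.normalize import NormalizedProfile
from ecfctox.design import t_from_um
from conftest import hill_profile


def _cox_de_boor(knots, i, k, x):
    """Brute-force B-spline recursion (degree k), independent of scipy."""
    if k == 0:
        # right-closed last interval so the basis covers the domain end
        last = knots[i + 1] == knots[-1]
        if knots[i] <= x < knots[i + 1] or (last and x == knots[i + 1] and knots[i] < knots[i + 1]):
            return 1.0
        return 0.0
    out = 0.0
    d1 = knots[i + k] - knots[i]
    if d1 > 0:
        out += (x - knots[i]) / d1 * _cox_de_boor(knots, i, k - 1, x)
    d2 = knots[i + k + 1] - knots[i + 1]
    if d2 > 0:
        out += (knots[i + k + 1] - x) / d2 * _cox_de_boor(knots, i + 1, k - 1, x)
    return out


def _zero_curve(T=10.0, K=20):
    basis = build_basis(K, 4, (0.0, T))
    return FittedCurve(basis=basis, c=np.zeros(K), lam=0.01, sse=0.0, pen=0.0,
                       pensse=0.0, converged=True, n_points=9)


class TestBasis:
    def test_partition_of_unity(self):
        basis = build_basis(20, 4, (0.0, 10.0))
        s = np.linspace(0.0, 10.0, 101)
        np.testing.assert_allclose(basis.design_matrix(s).sum(axis=1), 1.0, atol=1e-12)

    def test_constant_basis(self):
        basis = build_basis(1, 1, (0.0, 5.0))
        s = np.linspace(0.0, 4.999, 20)
        np.testing.assert_allclose(basis.design_matrix(s), 1.0)
        np.testing.assert_allclose(basis.second_deriv_matrix(s), 0.0)

    def test_k_below_order_rejected(self):
        with pytest.raises(ValueError):
            build_basis(3, 4, (0.0, 1.0))

    def test_matches_cox_de_boor_recursion(self):
        basis = build_basis(20, 4, (0.0, 10.0))
        probes = np.linspace(0.0, 10.0, 50)
        B = basis.design_matrix(probes)
        expected = np.array([[_cox_de_boor(basis.knots, i, 3, x)
                              for i in range(basis.K)] for x in probes])
        np.testing.assert_allclose(B, expected, atol=1e-12)

    def test_interior_knot_count(self):
        basis = build_basis(20, 4, (0.0, 10.0))
        interior = basis.knots[(basis.knots > 0) & (basis.knots < 10)]
        assert len(interior) == 20 - 4  # 16 interior knots → 17 subintervals
        np.testing.assert_allclose(np.diff(interior), interior[0], rtol=1e-9)


class TestPenalty:
    def test_zero_coefficients_zero_penalty(self):
        basis = build_basis(12, 4, (0.0, 5.0))
        R = penalty_matrix(basis)
        assert np.zeros(12) @ R @ np.zeros(12) == 0.0

    def test_linear_log_integrand_unpenalized(self):
        basis = build_basis(12, 4, (0.0, 5.0))
        # Greville abscissae reproduce affine functions exactly in a B-spline basis
        grev = np.array([basis.knots[i + 1:i + basis.order].mean() for i in range(basis.K)])
        c = 0.7 - 1.3 * grev
        s = np.linspace(0, 5, 50)
        np.testing.assert_allclose(basis.design_matrix(s) @ c, 0.7 - 1.3 * s, atol=1e-10)
        R = penalty_matrix(basis)
        assert abs(c @ R @ c) < 1e-9 * np.abs(R).max()

    def test_gram_matrix_matches_brute_force_quadrature(self):
        basis = build_basis(6, 4, (0.0, 3.0))
        R = penalty_matrix(basis)
        rng = np.random.default_rng(5)
        c = rng.normal(size=6)
        s = np.linspace(0.0, 3.0, 10001)
        w2 = basis.second_deriv_matrix(s) @ c
        brute = np.trapezoid(w2 ** 2, s)
        assert c @ R @ c == pytest.approx(brute, rel=1e-6)

    def test_positive_semidefinite(self):
        R = penalty_matrix(build_basis(15, 4, (0.0, 8.0)))
        eig = np.linalg.eigvalsh(R)
        assert eig.min() > -1e-9


class TestEvaluateCurve:
    def test_zero_coefficients_closed_form(self):
        curve = _zero_curve()
        assert evaluate_curve(curve, 0.0) == 100.0
        assert evaluate_curve(curve, 1.0) == pytest.approx(50.0, abs=1e-9)
        assert evaluate_curve(curve, 3.0) == pytest.approx(25.0, abs=1e-9)

    def test_beyond_domain_flat_extrapolation_warns(self):
        curve = _zero_curve(T=2.0)
        with pytest.warns(UserWarning, match="beyond fitted domain"):
            y = evaluate_curve(curve, 3.0)
        assert y == pytest.approx(100.0 / 4.0, abs=1e-9)

    def test_negative_t_rejected(self):
        with pytest.raises(ValueError):
            evaluate_curve(_zero_curve(), -0.5)


class TestFitCurve:
    def test_noise_free_reciprocal_curve_recovered(self):
        # data from y = 100/(1+t): the c = 0 member of the model family
        conc = 50.0 / np.exp2(np.arange(8, -1, -1))
        t = t_from_um(conc)
        prof = NormalizedProfile("c", "x", 1, conc, t, 100.0 / (1.0 + t), 32, 0, "d")
        fc = fit_curve(prof)
        assert fc.converged
        grid = np.linspace(0, t[-1], 100)
        np.testing.assert_allclose(evaluate_curve(fc, grid), 100.0 / (1.0 + grid), atol=0.5)

    def test_flat_profile_stays_near_hundred(self):
        conc = 50.0 / np.exp2(np.arange(8, -1, -1))
        t = t_from_um(conc)
        with pytest.warns(UserWarning, match="degenerate"):
            fc = fit_curve(NormalizedProfile("c", "x", 1, conc, t,
                                             np.full(9, 100.0), 32, 0, "d"))
        assert fc.degenerate
        grid = np.linspace(0, t[-1], 100)
        assert evaluate_curve(fc, grid).min() >= 99.0

    def test_monotone_by_construction(self):
        prof = hill_profile(m=3.0, h=2.0, sd_well=0.05, seed=2)
        fc = fit_curve(prof)
        y = evaluate_curve(fc, np.linspace(0, fc.domain_T, 300))
        assert np.all(np.diff(y) <= 1e-9)

    def test_pensse_identity_and_objective(self):
        prof = hill_profile(m=3.0, h=2.0, sd_well=0.02, seed=3)
        fc = fit_curve(prof)
        assert fc.pensse == pytest.approx(fc.sse + fc.lam * fc.pen, rel=1e-9)

    def test_fit_invariant_to_point_order(self):
        prof = hill_profile(m=3.0, h=2.0, sd_well=0.03, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(prof.conc_um))
        # profile container requires sorted concentrations, so shuffle then re-sort
        order = np.argsort(prof.conc_um[perm])
        shuffled = NormalizedProfile(
            prof.clone_id, prof.chemical, prof.day,
            prof.conc_um[perm][order], prof.t[perm][order],
            prof.viability[perm][order], 32, 0, prof.donor_id)
        f1, f2 = fit_curve(prof), fit_curve(shuffled)
        np.testing.assert_allclose(f1.c, f2.c, atol=1e-10)

    def test_refit_is_deterministic(self):
        prof = hill_profile(m=3.0, h=2.0, sd_well=0.03, seed=5)
        np.testing.assert_array_equal(fit_curve(prof).c, fit_curve(prof).c)

    def test_lambda_limit_drives_penalty_to_zero(self):
        prof = hill_profile(m=3.0, h=2.0, sd_well=0.02, seed=6)
        pens, sses = [], []
        for lam in [0.01, 1.0, 100.0, 1e4]:
            fc = fit_curve(prof, lam=lam)
            pens.append(fc.pen)
            sses.append(fc.sse)
        assert pens[-1] < 1e-3 * max(pens[0], 1e-12) or pens[-1] < 1e-8
        assert all(b >= a - 1e-7 for a, b in zip(sses, sses[1:]))

    def test_too_few_points_rejected(self):
        prof = NormalizedProfile("c", "x", 1, np.array([1.0, 2.0]),
                                 t_from_um(np.array([1.0, 2.0])),
                                 np.array([90.0, 60.0]), 32, 0, "d")
        with pytest.raises(ValueError, match="3 distinct"):
            fit_curve(prof)

    def test_json_round_trip(self):
        fc = fit_curve(hill_profile(m=3.0, h=2.0, sd_well=0.02, seed=8))
        fc2 = FittedCurve.from_json(fc.to_json())
        grid = np.linspace(0, fc.domain_T, 50)
        np.testing.assert_allclose(evaluate_curve(fc, grid), evaluate_curve(fc2, grid),
                                   atol=1e-12)
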