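import numpy as np
import pytest

from ecfctox import CurveCollection, fit_fanova, permutation_test


def _collection(Y, grid=None):
    I, J, G = Y.shape
    if grid is None:
        grid = np.linspace(0.0, 1.0, G)
    return CurveCollection(grid=grid, curves=Y,
                           toxicant_labels=tuple(f"tox{i}" for i in range(I)),
                           day_labels=tuple(range(1, J + 1)))


def _smooth_noise(rng, G, sd=1.0):
    """Smooth random curve: few random Fourier modes, mean zero."""
    t = np.linspace(0, 1, G)
    out = np.zeros(G)
    for k in range(1, 4):
        out += rng.normal(0, sd) * np.sin(np.pi * k * t) + rng.normal(0, sd) * np.cos(np.pi * k * t)
    return out / np.sqrt(6)


class TestFitFanova:
    def test_no_day_effect_gives_zero_beta(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(3, 1, 20))
        Y = np.repeat(base, 4, axis=1)            # identical across days
        fit = fit_fanova(_collection(Y))
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-12)

    def test_no_toxicant_effect_gives_zero_alpha(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(1, 4, 20))
        Y = np.repeat(base, 3, axis=0)            # identical across toxicants
        fit = fit_fanova(_collection(Y))
        np.testing.assert_allclose(fit.alpha, 0.0, atol=1e-12)

    def test_two_by_two_saturated_solution(self):
        # hand-solved additive system: {(i1,j1):10, (i1,j2):12, (i2,j1):20, (i2,j2):22}
        Y = np.array([[[10.0], [12.0]], [[20.0], [22.0]]])
        fit = fit_fanova(_collection(Y, grid=np.array([0.5])))
        assert fit.mu[0] == pytest.approx(10.0)
        assert fit.alpha[0, 0] == pytest.approx(10.0)
        assert fit.beta[0, 0] == pytest.approx(2.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_exact_reconstruction(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(4, 3, 30))
        coll = _collection(Y)
        fit = fit_fanova(coll)
        alpha = np.vstack([np.zeros(30), fit.alpha])
        beta = np.vstack([np.zeros(30), fit.beta])
        rebuilt = (fit.mu[None, None, :] + alpha[:, None, :] + beta[None, :, :]
                   + fit.residuals)
        np.testing.assert_allclose(rebuilt, Y, atol=1e-10)

    def test_incomplete_crossing_rejected(self):
        Y = np.random.default_rng(3).normal(size=(2, 2, 5))
        Y[1, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            _collection(Y)

    def test_needs_two_levels_each(self):
        Y = np.zeros((1, 3, 5))
        with pytest.raises(ValueError):
            fit_fanova(_collection(Y))


class TestPermutationTest:
    def test_identical_days_give_stat_zero_p_one(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(3, 1, 15))
        Y = np.repeat(base, 3, axis=1)
        res = permutation_test(_collection(Y), B=99, seed=0)
        np.testing.assert_allclose(res.observed_stat, 0.0)
        np.testing.assert_allclose(res.p_value, 1.0)

    def test_p_value_bounds_and_shapes(self):
        rng = np.random.default_rng(5)
        Y = 50.0 + rng.normal(size=(4, 3, 20))
        res = permutation_test(_collection(Y), B=200, seed=1)
        assert res.null_stats.shape == (200, 2)
        assert np.all(res.p_value >= 1.0 / 201) and np.all(res.p_value <= 1.0)
        assert res.pointwise_lower.shape == (2, 20)
        assert np.all(res.pointwise_lower <= res.pointwise_upper + 1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(size=(3, 3, 10))
        r1 = permutation_test(_collection(Y), B=50, seed=9)
        r2 = permutation_test(_collection(Y), B=50, seed=9)
        np.testing.assert_array_equal(r1.null_stats, r2.null_stats)
        np.testing.assert_array_equal(r1.p_value, r2.p_value)

    def test_observed_stat_invariant_to_day_swap_with_two_days(self):
        # swapping the two day columns flips β's sign; |β|/SE is unchanged
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(3, 2, 12))
        r1 = permutation_test(_collection(Y), B=50, seed=3)
        r2 = permutation_test(_collection(Y[:, ::-1, :]), B=50, seed=3)
        np.testing.assert_allclose(r1.observed_stat, r2.observed_stat, atol=1e-10)

    def test_strong_day_shift_detected(self):
        rng = np.random.default_rng(8)
        I, J, G = 4, 3, 25
        Y = np.empty((I, J, G))
        for i in range(I):
            base = 50.0 + 10.0 * _smooth_noise(rng, G)
            for j in range(J):
                Y[i, j] = base + _smooth_noise(rng, G, sd=1.0)
        Y[:, 1, :] += 8.0                        # day-2 shift of many residual SDs
        res = permutation_test(_collection(Y), B=500, seed=2)
        assert res.p_value[0] <= 0.01

    def test_b_zero_rejected(self):
        Y = np.zeros((2, 2, 5))
        with pytest.raises(ValueError):
            permutation_test(_collection(Y), B=0, seed=0)
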