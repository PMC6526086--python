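import numpy as np
import pytest
from scipy.optimize import approx_fprime

from fdagof import (
    Domain,
    FunctionalSample,
    NullCovarianceFit,
    SimulationDesign,
    SubjectRecord,
    eval_null_cov,
    fit_null,
    simulate_dataset,
    simulate_null_subject,
)
from fdagof.null_model import QuadraticLikelihood

TRUE_V0 = np.array([[1.0, -0.5], [-0.5, 1.0]])


def quad_fit(v0=TRUE_V0, noise=1.0):
    return NullCovarianceFit(family="quadratic_polynomial", V0=v0, noise_var=noise)


def test_eval_quadratic_cov_arithmetic():
    f = quad_fit()
    assert eval_null_cov(f, 1.0, 1.0) == pytest.approx(1.0 + (-0.5) * 2 + 1.0)
    assert eval_null_cov(f, 0.0, 0.0) == pytest.approx(1.0)  # sigma0^2
    # symmetry in (t, t')
    assert eval_null_cov(f, 0.3, -0.7) == pytest.approx(eval_null_cov(f, -0.7, 0.3))


def test_eval_sqexp_cov():
    f = NullCovarianceFit(family="squared_exponential", theta=2.0, delta=0.5, noise_var=0.1)
    assert eval_null_cov(f, 0.4, 0.4) == pytest.approx(2.0)  # h = 0 -> theta
    assert eval_null_cov(f, 0.0, 0.5) == pytest.approx(2.0 * np.exp(-1.0))
    assert eval_null_cov(f, 0.5, 0.0) == pytest.approx(eval_null_cov(f, 0.0, 0.5))


def test_marginal_cov_structure():
    f = quad_fit()
    t = np.array([-1.0, 0.0, 1.0])
    Z = np.column_stack([np.ones(3), t])
    expected = Z @ TRUE_V0 @ Z.T + np.eye(3)
    np.testing.assert_allclose(f.marginal_cov(t), expected, atol=1e-12)


def test_analytic_gradient_matches_finite_differences():
    s = simulate_dataset(SimulationDesign(n=25, m=6, seed=9))
    ll = QuadraticLikelihood(s.times_list(), s.values_list())
    rng = np.random.default_rng(1)
    for _ in range(4):
        x = rng.normal(0, 0.5, 4)
        f, g = ll.negloglik_grad_x(x)
        assert f == pytest.approx(ll.negloglik_x(x))
        gn = approx_fprime(x, ll.negloglik_x, 1e-6)
        np.testing.assert_allclose(g, gn, rtol=5e-4, atol=5e-4)


def test_ml_recovers_generating_parameters():
    """Large-sample ML fit lands within 10% of the generating values
    (estimates averaged over a few datasets to damp Monte-Carlo noise in
    the realized random effects)."""
    fits = []
    for seed in range(3):
        s = simulate_dataset(SimulationDesign(n=2000, m=20, seed=seed))
        f = fit_null(s)  # mu = 0 in the generator, no demeaning needed
        assert f.converged
        fits.append([f.V0[0, 0], f.V0[0, 1], f.V0[1, 1], f.noise_var])
    avg = np.mean(fits, axis=0)
    np.testing.assert_allclose(avg, [1.0, -0.5, 1.0, 1.0], rtol=0.10)


def test_loglik_at_optimum_dominates_truth_and_is_locally_maximal():
    s = simulate_dataset(SimulationDesign(n=200, m=10, seed=8))
    fit = fit_null(s)
    ll = QuadraticLikelihood(s.times_list(), s.values_list())
    L_true = np.linalg.cholesky(TRUE_V0)
    assert -fit.loglik <= ll.negloglik(L_true, 1.0) + 1e-6
    # profile probe: +-10% single-parameter perturbations reduce the loglik
    Lhat = np.linalg.cholesky(fit.V0 + 1e-12 * np.eye(2))
    base = ll.negloglik(Lhat, fit.noise_var)
    for i, j in [(0, 0), (1, 0), (1, 1)]:
        for fac in (0.9, 1.1):
            Lp = Lhat.copy()
            Lp[i, j] *= fac
            assert ll.negloglik(Lp, fit.noise_var) >= base - 1e-8
    for fac in (0.9, 1.1):
        assert ll.negloglik(Lhat, fit.noise_var * fac) >= base - 1e-8


def test_loglik_invariant_to_subject_order():
    s = simulate_dataset(SimulationDesign(n=40, m=8, seed=17))
    f1 = fit_null(s)
    f2 = fit_null(FunctionalSample(list(reversed(s.subjects)), s.domain))
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
    np.testing.assert_allclose(f1.V0, f2.V0, atol=1e-5)


def test_all_singletons_unidentifiable():
    subs = [SubjectRecord(i, [0.1 * i - 0.5], [1.0]) for i in range(10)]
    s = FunctionalSample(subs, Domain(-1, 1))
    with pytest.raises(ValueError, match="identifiab"):
        fit_null(s)


def test_sqexp_family_fit_recovers_scale():
    """Generate from a squared-exponential process and refit."""
    rng = np.random.default_rng(4)
    t = np.linspace(-1, 1, 15)
    truth = NullCovarianceFit(family="squared_exponential", theta=2.0, delta=0.8, noise_var=0.25)
    V = truth.marginal_cov(t)
    L = np.linalg.cholesky(V)
    subs = [SubjectRecord(i, t, L @ rng.standard_normal(15)) for i in range(400)]
    s = FunctionalSample(subs, Domain(-1, 1))
    fit = fit_null(s, family="squared_exponential")
    assert fit.theta == pytest.approx(2.0, rel=0.25)
    assert fit.delta == pytest.approx(0.8, rel=0.25)
    assert fit.noise_var == pytest.approx(0.25, rel=0.25)


def test_simulate_null_subject_linear_and_degenerate():
    f = quad_fit()
    t = np.linspace(-1, 1, 9)
    x = simulate_null_subject(f, t, seed=0)
    # exactly linear: second differences vanish on the equispaced grid
    assert np.allclose(np.diff(x, 2), 0.0, atol=1e-10)
    zero = quad_fit(v0=np.zeros((2, 2)))
    np.testing.assert_array_equal(simulate_null_subject(zero, t, seed=1), np.zeros(9))


def test_simulate_null_subject_covariance_monte_carlo():
    f = quad_fit()
    t = np.array([-0.5, 0.25])
    rng = np.random.default_rng(11)
    draws = np.stack([simulate_null_subject(f, t, rng) for _ in range(40_000)])
    emp = np.cov(draws.T)
    expected = f.cov_matrix(t)
    np.testing.assert_allclose(emp, expected, atol=0.03)
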