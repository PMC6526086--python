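import numpy as np
import pytest

from fdagof import (
    Domain,
    FunctionalSample,
    SimulationDesign,
    build_basis,
    hs_distance,
    run_gof_test,
    simulate_dataset,
)
from fdagof.covariance import SmoothedCovariance
from fdagof.gof import GofEngine

DOMAIN = Domain(-1.0, 1.0)


def _random_surface(basis, rng):
    T = rng.normal(size=(basis.H, basis.H))
    return SmoothedCovariance(basis, (T + T.T) / 2)


class TestHsDistance:
    def test_identical_surfaces_give_zero(self):
        b = build_basis(DOMAIN, H=7)
        A = _random_surface(b, np.random.default_rng(0))
        assert hs_distance(A, A) == 0.0

    def test_constant_difference_integrates_to_area_times_c_squared(self):
        b = build_basis(DOMAIN, H=6)
        c = 1.7
        # partition of unity: theta = c * ones gives the constant surface c
        A = SmoothedCovariance(b, np.full((6, 6), c))
        B = SmoothedCovariance(b, np.zeros((6, 6)))
        assert hs_distance(A, B) == pytest.approx(4 * c**2, rel=1e-12)

    def test_squared_pseudometric_properties(self):
        b = build_basis(DOMAIN, H=6)
        rng = np.random.default_rng(3)
        A, B = _random_surface(b, rng), _random_surface(b, rng)
        assert hs_distance(A, B) == pytest.approx(hs_distance(B, A))
        assert hs_distance(A, B) > 0

    def test_basis_mismatch_rejected(self):
        A = _random_surface(build_basis(DOMAIN, H=6), np.random.default_rng(0))
        B = _random_surface(build_basis(DOMAIN, H=7), np.random.default_rng(0))
        with pytest.raises(ValueError, match="basis"):
            hs_distance(A, B)

    def test_trapezoid_quadrature_converges_to_closed_form_at_h_squared(self):
        """Independent grid quadrature approaches the Gram-matrix value at
        the trapezoid rate: halving h divides the error by ~4."""
        b = build_basis(DOMAIN, H=10)
        rng = np.random.default_rng(1)
        A, B = _random_surface(b, rng), _random_surface(b, rng)
        exact = hs_distance(A, B)
        errs = []
        for ng in (200, 400, 800):
            t = np.linspace(-1, 1, ng)
            d = A.evaluate(t, t) - B.evaluate(t, t)
            errs.append(abs(np.trapezoid(np.trapezoid(d**2, t, axis=1), t) - exact))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.1)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.1)


class TestBootstrapTest:
    def test_pvalue_formula_with_single_replicate(self):
        s = simulate_dataset(SimulationDesign(n=40, m=10, seed=1))
        res = run_gof_test(s, L=1, seed=0)
        assert res.p_value in (0.0, 1.0)
        assert res.p_value == float(res.bootstrap_stats[0] > res.statistic)

    def test_seed_reproducibility(self):
        s = simulate_dataset(SimulationDesign(n=40, m=10, seed=2))
        r1 = run_gof_test(s, L=5, seed=42)
        r2 = run_gof_test(s, L=5, seed=42)
        assert r1.statistic == r2.statistic
        np.testing.assert_array_equal(r1.bootstrap_stats, r2.bootstrap_stats)
        assert r1.p_value == r2.p_value

    def test_statistics_nonnegative_and_pvalue_consistent(self):
        s = simulate_dataset(SimulationDesign(n=50, m=15, seed=3))
        res = run_gof_test(s, L=20, seed=7)
        assert res.statistic >= 0
        assert np.all(res.bootstrap_stats >= 0)
        assert res.p_value == pytest.approx(
            np.mean(res.bootstrap_stats > res.statistic)
        )
        assert res.L == 20 and res.n_failed == 0

    def test_degenerate_null_gives_near_zero_replicates(self):
        """With V0hat = 0 and no noise, bootstrap data equal the fitted mean,
        so both smoothers agree and the replicate statistic vanishes."""
        s = simulate_dataset(SimulationDesign(n=40, m=12, seed=4))
        engine = GofEngine(s)
        from fdagof import NullCovarianceFit

        zero = NullCovarianceFit(
            family="quadratic_polynomial", V0=np.zeros((2, 2)), noise_var=0.0
        )
        mu = np.zeros(s.n_obs)
        tn = engine.replicate(zero, mu, 0.0, np.random.default_rng(0))
        assert tn == pytest.approx(0.0, abs=1e-12)

    def test_replicates_identical_under_same_substream(self):
        s = simulate_dataset(SimulationDesign(n=30, m=10, seed=5))
        engine = GofEngine(s)
        obs = engine.analyze(s.pooled()[1])
        t1 = engine.replicate(obs["null_fit"], obs["muhat_pooled"], 1.0,
                              np.random.default_rng(99))
        t2 = engine.replicate(obs["null_fit"], obs["muhat_pooled"], 1.0,
                              np.random.default_rng(99))
        assert t1 == t2

    def test_observed_statistic_invariant_to_subject_relabeling(self):
        s = simulate_dataset(SimulationDesign(n=30, m=10, seed=6))
        rev = FunctionalSample(list(reversed(s.subjects)), s.domain)
        e1, e2 = GofEngine(s), GofEngine(rev)
        t1 = e1.analyze(s.pooled()[1])["Tn"]
        t2 = e2.analyze(rev.pooled()[1])["Tn"]
        assert t1 == pytest.approx(t2, rel=1e-6)

    def test_alternative_data_yield_larger_statistic_than_null(self):
        """A strong trigonometric deviation inflates Tn well past the null
        bootstrap spread (small-scale power sanity check)."""
        null_s = simulate_dataset(SimulationDesign(n=100, m=20, seed=7))
        dev_s = simulate_dataset(
            SimulationDesign(n=100, m=20, delta=2.0, deviation="trigonometric", seed=7)
        )
        r_null = run_gof_test(null_s, L=30, seed=1)
        r_dev = run_gof_test(dev_s, L=30, seed=1)
        assert r_dev.statistic > r_null.statistic
        assert r_dev.p_value <= 0.05
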