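"""Ensemble sampler correctness and the Geweke diagnostic."""

import math

import numpy as np
import pytest
from scipy import stats

from cvcalib.mcmc import (ChainSet, McmcConfig, geweke, geweke_chains,
                          init_walkers, make_log_posterior, run_ensemble)


def _std_normal_2d(th):
    return -0.5 * float(th @ th)


@pytest.fixture(scope="module")
def gaussian_chains():
    cfg = McmcConfig(n_walkers=32, n_steps=2000, burn_in=500, seed=10)
    init = np.random.default_rng(0).normal(size=(32, 2)) * 0.5
    return run_ensemble(_std_normal_2d, init, cfg,
                        parameter_names=["x", "y"])


class TestLogPosterior:
    def test_outside_box_is_minus_inf(self):
        lp = make_log_posterior(lambda th: 0.0, np.array([[0.0, 1.0]]))
        assert lp(np.array([2.0])) == -math.inf
        assert lp(np.array([0.5])) == 0.0

    def test_difference_equals_loglike_difference(self):
        """With a uniform prior the log-posterior difference of two in-box
        points is exactly -0.5 x the cost difference."""
        costs = {0.2: 3.0, 0.8: 7.0}
        lp = make_log_posterior(lambda th: -0.5 * costs[float(th[0])],
                                np.array([[0.0, 1.0]]))
        d = lp(np.array([0.2])) - lp(np.array([0.8]))
        assert d == pytest.approx(-0.5 * (3.0 - 7.0))

    def test_solver_failure_maps_to_minus_inf(self):
        lp = make_log_posterior(lambda th: math.nan, np.array([[0.0, 1.0]]))
        assert lp(np.array([0.5])) == -math.inf


class TestInitWalkers:
    def test_rows_inside_support(self):
        cfg = McmcConfig(n_walkers=32, n_steps=10, burn_in=0, seed=0)
        lp = make_log_posterior(lambda th: 0.0,
                                np.array([[0.0, 2.0], [0.0, 2.0]]))
        w = init_walkers(np.array([1.0, 1.0]), cfg, lp)
        assert w.shape == (32, 2)
        assert np.all((w >= 0.0) & (w <= 2.0))

    def test_moments_match_declared_law(self):
        """Monte-Carlo check of the initialization law: mean theta*,
        per-coordinate SD 0.01 theta*."""
        theta = np.array([2.0, 0.5])
        cfg = McmcConfig(n_walkers=10000, n_steps=10, burn_in=0, seed=1)
        draws = init_walkers(theta, cfg, lambda th: 0.0)
        sd_expect = 0.01 * theta
        se_mean = sd_expect / math.sqrt(1e4)
        assert np.all(np.abs(draws.mean(0) - theta) < 3 * se_mean)
        assert np.all(np.abs(draws.std(0) / sd_expect - 1.0) < 0.1)

    def test_impossible_support_raises(self):
        cfg = McmcConfig(n_walkers=4, n_steps=10, burn_in=0, seed=0)
        with pytest.raises(RuntimeError, match="initialize walker"):
            init_walkers(np.array([1.0]), cfg, lambda th: -math.inf,
                         max_tries=5)


class TestRunEnsemble:
    def test_gaussian_moments(self, gaussian_chains):
        """2-D standard normal target: posterior mean within +-0.05 and
        marginal SDs within 5% of 1."""
        flat = gaussian_chains.flat()
        assert flat.shape[0] == 32 * 1500
        assert np.all(np.abs(flat.mean(0)) < 0.05)
        assert np.all(np.abs(flat.std(0) - 1.0) < 0.05)

    def test_1d_normal_ks_distance(self):
        """Empirical CDF of post-burn-in samples vs the analytic normal
        CDF: Kolmogorov-Smirnov distance < 0.02 at 3e4 samples."""
        cfg = McmcConfig(n_walkers=20, n_steps=2000, burn_in=500, seed=3)
        init = np.random.default_rng(1).normal(size=(20, 1)) * 0.3
        ch = run_ensemble(lambda th: -0.5 * float(th[0] ** 2), init, cfg)
        x = ch.flat()[:, 0]
        d = stats.kstest(x, "norm").statistic
        assert x.size == 3e4
        assert d < 0.02

    def test_uniform_box_support_confinement(self):
        lp = make_log_posterior(lambda th: 0.0,
                                np.array([[0.0, 1.0], [2.0, 3.0]]))
        cfg = McmcConfig(n_walkers=16, n_steps=500, burn_in=100, seed=4)
        init = np.column_stack([np.random.default_rng(2).uniform(0.4, 0.6, 16),
                                np.random.default_rng(3).uniform(2.4, 2.6, 16)])
        ch = run_ensemble(lp, init, cfg)
        flat = ch.samples.reshape(-1, 2)
        assert np.all((flat[:, 0] >= 0) & (flat[:, 0] <= 1))
        assert np.all((flat[:, 1] >= 2) & (flat[:, 1] <= 3))
        assert 0.1 < ch.acceptance_fraction.mean() < 1.0

    def test_same_seed_bit_identical(self):
        cfg = McmcConfig(n_walkers=8, n_steps=200, burn_in=50, seed=9)
        init = np.random.default_rng(5).normal(size=(8, 2)) * 0.1
        c1 = run_ensemble(_std_normal_2d, init, cfg)
        c2 = run_ensemble(_std_normal_2d, init, cfg)
        np.testing.assert_array_equal(c1.samples, c2.samples)
        np.testing.assert_array_equal(c1.log_post, c2.log_post)

    def test_matches_reference_sampler_moments(self):
        """Independent cross-check: the reimplemented stretch move and the
        reference ensemble-sampler library agree on the target moments of
        a correlated 2-D Gaussian."""
        emcee = pytest.importorskip("emcee")
        cov = np.array([[1.0, 0.6], [0.6, 0.5]])
        icov = np.linalg.inv(cov)

        def lp(th):
            return -0.5 * float(th @ icov @ th)

        init = np.random.default_rng(7).normal(size=(32, 2)) * 0.2
        cfg = McmcConfig(n_walkers=32, n_steps=3000, burn_in=1000, seed=8)
        ours = run_ensemble(lp, init, cfg).flat()

        np.random.seed(9)
        ref = emcee.EnsembleSampler(32, 2, lp)
        ref.run_mcmc(init, 3000)
        theirs = ref.get_chain(discard=1000, flat=True)

        np.testing.assert_allclose(np.cov(ours.T), np.cov(theirs.T),
                                   atol=0.12)
        np.testing.assert_allclose(ours.mean(0), theirs.mean(0), atol=0.08)

    def test_all_minus_inf_raises(self):
        cfg = McmcConfig(n_walkers=8, n_steps=10, burn_in=0, seed=0)
        init = np.zeros((8, 2))
        with pytest.raises(RuntimeError, match="-inf"):
            run_ensemble(lambda th: -math.inf, init, cfg)

    def test_hdf5_roundtrip(self, gaussian_chains, tmp_path):
        path = tmp_path / "chains.h5"
        gaussian_chains.save(path)
        back = ChainSet.load(path)
        np.testing.assert_array_equal(back.samples, gaussian_chains.samples)
        np.testing.assert_array_equal(back.log_post, gaussian_chains.log_post)
        assert back.parameter_names == gaussian_chains.parameter_names
        assert back.burn_in == gaussian_chains.burn_in


class TestGeweke:
    def test_null_calibration_iid(self):
        """|Z| < 3 in at least 99% of iid-normal replicates."""
        rng = np.random.default_rng(0)
        ok = 0
        n_rep = 200
        for _ in range(n_rep):
            z, _ = geweke(rng.standard_normal(10000))
            ok += abs(z) < 3
        assert ok / n_rep >= 0.99

    def test_power_against_linear_trend(self):
        """A linear drift spanning 5 SDs is detected (p < 0.05)."""
        rng = np.random.default_rng(1)
        n = 10000
        series = rng.standard_normal(n) + np.linspace(0.0, 5.0, n)
        _, p = geweke(series)
        assert p < 0.05

    def test_equal_segment_means_give_small_z(self):
        """A symmetric series has identical first/last segment means up to
        noise; Z stays small."""
        rng = np.random.default_rng(2)
        half = rng.standard_normal(5000)
        series = np.concatenate([half, half[::-1]])
        z, p = geweke(series, first=0.1, last=0.5)
        assert abs(z) < 3

    def test_degenerate_series_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            geweke(np.ones(1000))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            geweke(np.arange(50.0))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            geweke(np.random.default_rng(0).normal(size=1000),
                   first=0.6, last=0.6)

    def test_converged_ensemble_passes(self, gaussian_chains):
        gw = geweke_chains(gaussian_chains)
        assert gw.passed
        assert set(gw.p) == {"x", "y"}
        assert all(0.0 <= p <= 1.0 for p in gw.p.values())

    def test_cold_start_fails(self):
        """An unconverged ensemble (started far off with a token burn-in)
        is flagged."""
        cfg = McmcConfig(n_walkers=32, n_steps=300, burn_in=10, seed=0)
        init = np.random.default_rng(7).normal(size=(32, 2)) * 0.05 + 5.0
        ch = run_ensemble(_std_normal_2d, init, cfg)
        gw = geweke_chains(ch)
        assert not gw.passed


def test_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(n_walkers=7)
    with pytest.raises(ValueError):
        McmcConfig(n_steps=100, burn_in=100)
    with pytest.raises(ValueError):
        McmcConfig(a=0.5)
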