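"""Gibbs samplers: oracle equivalence, invariances, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from saltgp.bayes import (
    GibbsConfig,
    KernelMixedModel,
    MultiEnvKernelMixedModel,
    gelman_rubin,
)
from saltgp.kernels import CenteredMatrix, gaussian_kernel, linear_kernel, \
    squared_distance_matrix


def sim_kernel_data(rng, n=50, p=80, noise=1.0, kind="linear"):
    x = rng.normal(size=(n, p))
    x -= x.mean(axis=0)
    if kind == "linear":
        k = linear_kernel(CenteredMatrix(x, [f"g{i}" for i in range(n)]))
    else:
        d2 = squared_distance_matrix(x)
        k = gaussian_kernel(d2, 1.0 / np.median(d2[d2 > 0]),
                            samples=[f"g{i}" for i in range(n)])
    g = rng.multivariate_normal(np.zeros(n), k.values + 1e-10 * np.eye(n))
    y = 2.0 + g + rng.normal(0, noise, n)
    return k, y


def blup(kv, y, lam, train=None):
    """Closed-form K (K + lam I)^-1 (y - ybar) with optional training subset."""
    if train is None:
        return kv @ np.linalg.solve(kv + lam * np.eye(len(y)), y - y.mean())
    ktt = kv[np.ix_(train, train)]
    kat = kv[:, train]
    yt = y[train]
    return kat @ np.linalg.solve(ktt + lam * np.eye(len(train)), yt - yt.mean())


FIXED = {"sigma2_u": 1.0, "sigma2_e": 1.0}


class TestSingleEnv:
    @pytest.mark.parametrize("kind", ["linear", "gaussian"])
    def test_posterior_mean_matches_blup_oracle(self, kind):
        rng = np.random.default_rng(42)
        k, y = sim_kernel_data(rng, kind=kind)
        cfg = GibbsConfig(n_iter=8000, burn_in=1000, thin=2, seed=3,
                          fixed_variances=FIXED)
        res = KernelMixedModel(y, k).fit(cfg)
        u_hat = res.gebv()["gebv"].to_numpy()
        oracle = blup(k.values, y, lam=1.0)
        draws = res.samples.vectors["u0"][0]
        mcse = draws.std(axis=0) / np.sqrt(draws.shape[0] / 10)  # crude ESS/10
        assert np.all(np.abs(u_hat - oracle) < 3 * np.maximum(mcse, 0.02))

    def test_constant_phenotype_no_signal(self):
        rng = np.random.default_rng(0)
        k, _ = sim_kernel_data(rng)
        y = np.full(k.n, 5.0)
        cfg = GibbsConfig(n_iter=3000, burn_in=500, thin=5, seed=1)
        res = KernelMixedModel(y, k).fit(cfg)
        u = res.gebv()["gebv"].to_numpy()
        assert np.abs(u).max() < 0.2
        assert res.samples.posterior_mean("mu[env]") == pytest.approx(5.0, abs=0.1)

    def test_two_chains_converge(self):
        rng = np.random.default_rng(7)
        k, y = sim_kernel_data(rng)
        cfg = GibbsConfig(n_iter=6000, burn_in=1000, thin=5, n_chains=2, seed=5)
        res = KernelMixedModel(y, k).fit(cfg)
        psrf = res.gelman_rubin()
        for p in ("mu[env]", "sigma2_u0", "sigma2_e[env]"):
            assert psrf[p] < 1.1

    def test_location_invariance(self):
        rng = np.random.default_rng(12)
        k, y = sim_kernel_data(rng)
        cfg = GibbsConfig(n_iter=2000, burn_in=500, thin=3, seed=9)
        r0 = KernelMixedModel(y, k).fit(cfg)
        r1 = KernelMixedModel(y + 100.0, k).fit(cfg)
        # same seed -> identical noise stream; GEBVs unchanged, mu shifted
        np.testing.assert_allclose(
            r0.samples.vectors["u0"], r1.samples.vectors["u0"], atol=1e-8
        )
        assert r1.samples.posterior_mean("mu[env]") - r0.samples.posterior_mean(
            "mu[env]"
        ) == pytest.approx(100.0, abs=1e-8)

    def test_masked_lines_match_blup_extension(self):
        """Predictions for unphenotyped lines equal the closed-form BLUP
        extension at fixed variances."""
        rng = np.random.default_rng(21)
        k, y = sim_kernel_data(rng, n=40)
        train = np.arange(30)
        y_masked = y.copy()
        y_masked[30:] = np.nan
        cfg = GibbsConfig(n_iter=12_000, burn_in=2000, thin=2, seed=13,
                          fixed_variances=FIXED)
        res = KernelMixedModel(y_masked, k).fit(cfg)
        u_hat = res.gebv()["gebv"].to_numpy()
        oracle = blup(k.values, y, lam=1.0, train=train)
        assert np.abs(u_hat[30:] - oracle[30:]).max() < 0.12

    def test_duplicated_rows_get_equal_gebvs(self):
        rng = np.random.default_rng(3)
        k, y = sim_kernel_data(rng, n=30)
        kv = k.values.copy()
        kv[1, :] = kv[0, :]
        kv[:, 1] = kv[:, 0]
        kv[1, 1] = kv[0, 0]
        from saltgp.kernels import KernelMatrix

        k2 = KernelMatrix(kv, k.samples)
        y2 = y.copy()
        y2[1] = y[0]
        cfg = GibbsConfig(n_iter=6000, burn_in=1000, thin=2, seed=2)
        res = KernelMixedModel(y2, k2).fit(cfg)
        u = res.gebv()["gebv"].to_numpy()
        assert abs(u[0] - u[1]) < 0.05

    def test_variance_recovery(self):
        """Posterior medians bracket the generating variances."""
        rng = np.random.default_rng(31)
        n = 200
        x = rng.normal(size=(n, 300))
        x -= x.mean(axis=0)
        k = linear_kernel(CenteredMatrix(x, list(range(n))))
        g = rng.multivariate_normal(np.zeros(n), k.values + 1e-10 * np.eye(n))
        y = g + rng.normal(0, 1, n)
        cfg = GibbsConfig(n_iter=6000, burn_in=1000, thin=5, seed=17)
        res = KernelMixedModel(y, k).fit(cfg)
        med_u = np.median(res.samples.scalars["sigma2_u0"])
        med_e = np.median(res.samples.scalars["sigma2_e[env]"])
        assert 0.5 < med_u < 2.0
        assert 0.5 < med_e < 2.0


class TestMultiEnv:
    def test_single_env_is_exact_reduction(self, small_kernel):
        rng = np.random.default_rng(4)
        y = rng.normal(size=small_kernel.n)
        cfg = GibbsConfig(n_iter=1000, burn_in=200, thin=2, seed=8)
        r1 = KernelMixedModel(y, small_kernel).fit(cfg)
        r2 = MultiEnvKernelMixedModel(
            y[:, None], small_kernel, env_names=["env"], include_env_specific=False
        ).fit(cfg)
        np.testing.assert_array_equal(
            r1.samples.vectors["u0"], r2.samples.vectors["u0"]
        )
        np.testing.assert_array_equal(
            r1.samples.scalars["sigma2_u0"], r2.samples.scalars["sigma2_u0"]
        )

    def test_pinned_env_variance_matches_single_env(self):
        """With environment-specific variances pinned near zero the
        multi-environment predictions collapse to per-environment
        single-env fits sharing the kernel."""
        rng = np.random.default_rng(44)
        k, y1 = sim_kernel_data(rng, n=45)
        y2 = y1 + rng.normal(0, 0.3, k.n)
        fixed = {"sigma2_u": 1.0, "sigma2_e": 1.0, "sigma2_u_env": 1e-8}
        cfg = GibbsConfig(n_iter=8000, burn_in=1500, thin=2, seed=6,
                          fixed_variances=fixed)
        multi = MultiEnvKernelMixedModel(
            np.column_stack([y1, y2]), k, env_names=["a", "b"]
        ).fit(cfg)
        g = multi.gebv()
        # oracle: joint likelihood with shared u and both envs observed is
        # ridge on the stacked residuals with lam = 1/2
        oracle = k.values @ np.linalg.solve(
            k.values + 0.5 * np.eye(k.n),
            ((y1 - y1.mean()) + (y2 - y2.mean())) / 2.0,
        )
        for env in ("a", "b"):
            u = g.query("environment == @env")["gebv"].to_numpy()
            assert np.abs(u - oracle).max() < 0.12

    def test_shared_effects_dominate_when_correlation_one(self):
        """Data generated with cross-environment genetic correlation 1
        allocate most genetic variance to the main component."""
        rng = np.random.default_rng(55)
        k, y = sim_kernel_data(rng, n=60, noise=0.5)
        y2 = y + rng.normal(0, 0.5, k.n)  # same genetic values
        cfg = GibbsConfig(n_iter=4000, burn_in=1000, thin=3, seed=5)
        res = MultiEnvKernelMixedModel(
            np.column_stack([y, y2]), k, env_names=["a", "b"]
        ).fit(cfg)
        s_env = (
            res.samples.scalars["sigma2_u[a]"] + res.samples.scalars["sigma2_u[b]"]
        )
        s_main = res.samples.scalars["sigma2_u0"]
        frac = float(np.mean(s_env / (s_main + s_env)))
        assert frac < 0.25

    def test_environment_label_equivariance(self):
        rng = np.random.default_rng(66)
        k, y1 = sim_kernel_data(rng, n=30)
        y2 = y1 + rng.normal(0, 1, k.n)
        cfg = GibbsConfig(n_iter=1500, burn_in=300, thin=2, seed=10)
        r_ab = MultiEnvKernelMixedModel(
            np.column_stack([y1, y2]), k, env_names=["a", "b"]
        ).fit(cfg)
        r_ba = MultiEnvKernelMixedModel(
            np.column_stack([y2, y1]), k, env_names=["b", "a"]
        ).fit(cfg)
        ga = r_ab.gebv().set_index(["genotype", "environment"])["predicted"]
        gb = r_ba.gebv().set_index(["genotype", "environment"])["predicted"]
        # same environments, swapped storage order: posterior means agree
        # within MC error (the RNG stream differs between layouts)
        diffs = (ga - gb).abs()
        assert diffs.max() < 0.35
        assert diffs.mean() < 0.1


class TestGelmanRubin:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 3000))
        psrf = gelman_rubin(chains)["parameter"]
        assert 0.99 <= psrf <= 1.05

    def test_shifted_chain_flagged(self):
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(2, 3000))
        chains[1] += 5.0
        assert gelman_rubin(chains)["parameter"] > 1.5

    def test_zero_variance_is_nan(self):
        chains = np.ones((2, 100))
        assert np.isnan(gelman_rubin(chains)["parameter"])

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 500)) + rng.normal(0, 0.1, size=(4, 1))
        mine = gelman_rubin(chains)["parameter"]
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"])
        assert mine == pytest.approx(theirs, abs=0.02)


def test_retained_draw_count():
    cfg = GibbsConfig(n_iter=35_000, burn_in=5_000, thin=10)
    assert cfg.n_retained == 3000
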