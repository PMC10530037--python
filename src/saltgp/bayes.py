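"""Gibbs samplers for kernel-based genomic prediction.

Two mixed models are implemented, in the statsmodels Model/Results style:

* :class:`KernelMixedModel` — single environment,
  ``y = 1 mu + u + e`` with ``u ~ N(0, s2_u K)`` and ``e ~ N(0, s2_e I)``;
* :class:`MultiEnvKernelMixedModel` — stacked environments,
  ``y_j = 1 mu_j + u0 + u_j + e_j`` where the main genetic effect ``u0``
  (covariance ``s2_u0 K0``) is shared across environments and each
  environment adds a specific effect ``u_j`` (covariance ``s2_uj K_j``)
  and its own residual variance.

Sampling operates in the eigenbasis of each kernel, where the genetic
coordinates are conditionally independent given the variances, so every
update is a vectorized draw.  Unphenotyped lines (``NaN`` in ``y``) are
handled by data augmentation: their records are sampled from the current
predictive distribution each sweep, which keeps the eigen-coordinate
updates exact while yielding genuine predictions for masked lines —
exactly the masking used for cross-validation and across-population
prediction.

Variance components carry scaled-inverse-chi-square priors (df0 = 5 by
default, scale set so the prior mode splits a fraction R2 = 0.5 of the
phenotypic variance across the genetic components and the rest to the
residual); intercepts are flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelMatrix

__all__ = [
    "GibbsConfig",
    "PosteriorSamples",
    "KernelMixedModel",
    "MultiEnvKernelMixedModel",
    "KernelMixedModelResults",
    "MultiEnvResults",
    "gelman_rubin",
]


@dataclass
class GibbsConfig:
    """MCMC settings.

    Defaults follow common practice for Bayesian kernel regression in
    genomic selection: 35,000 iterations, the first 5,000 discarded as
    burn-in, every 10th draw retained (3,000 retained draws).
    """

    n_iter: int = 35_000
    burn_in: int = 5_000
    thin: int = 10
    n_chains: int = 1
    seed: int | None = None
    df0: float = 5.0
    r2: float = 0.5
    pooled_residual: bool = False
    # {"sigma2_u": v, "sigma2_e": v} (and "sigma2_u_env" for multi-env)
    # freezes variance components instead of sampling them.
    fixed_variances: dict | None = None
    # pin every intercept at this value (oracle tests against closed-form
    # BLUP, which conditions on a known mean)
    fixed_intercept: float | None = None

    def __post_init__(self):
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorSamples:
    """Retained Gibbs draws, one array per parameter block.

    ``scalars`` maps parameter name -> array (n_chains, n_retained);
    ``vectors`` maps name -> array (n_chains, n_retained, n).
    """

    scalars: dict
    vectors: dict
    config: GibbsConfig
    sample_ids: list

    def posterior_mean(self, name: str) -> np.ndarray | float:
        if name in self.scalars:
            return float(np.mean(self.scalars[name]))
        return np.asarray(self.vectors[name]).mean(axis=(0, 1))

    def to_frame(self) -> pd.DataFrame:
        """Scalar draws in long format (chain, draw, parameter, value)."""
        frames = []
        for name, arr in self.scalars.items():
            c, r = arr.shape
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), r),
                        "draw": np.tile(np.arange(r), c),
                        "parameter": name,
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _sample_scaled_inv_chi2(rng, df: float, scale: float) -> float:
    return df * scale / rng.chisquare(df)


def _prior_scale(mode: float, df0: float) -> float:
    # mode of scaled-inv-chi2(df, S) is df*S/(df+2)
    return max(mode, 1e-12) * (df0 + 2.0) / df0


class _EigenKernel:
    """Kernel eigendecomposition reused across sweeps."""

    def __init__(self, kernel: KernelMatrix, tol: float = 1e-10):
        self.sample_ids = list(kernel.samples)
        w, v = kernel.eigendecompose(tol=tol)
        self.d = w  # (m_eig,)
        self.u = v  # (n, m_eig)
        self.n = kernel.n


class _GibbsCore:
    """Shared sampler for 1..m environments with optional env-specific term.

    ``KernelMixedModel`` runs it with one environment and the specific
    term switched off, so the single-environment model is literally the
    m = 1 special case (identical code path, identical draws for a given
    seed).
    """

    def __init__(self, y: np.ndarray, k0: KernelMatrix,
                 env_kernels: list[KernelMatrix] | None,
                 include_env_specific: bool, env_names: list[str]):
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        self.y = y  # (n, m) with NaN = masked
        self.n, self.m = y.shape
        if k0.n != self.n:
            raise ValueError("kernel dimension does not match phenotype length")
        self.ek0 = _EigenKernel(k0)
        self.include_env = include_env_specific
        if include_env_specific:
            kl = env_kernels if env_kernels is not None else [k0] * self.m
            if len(kl) != self.m:
                raise ValueError("need one environment kernel per environment")
            self.ek_env = [_EigenKernel(k) for k in kl]
        else:
            self.ek_env = []
        self.env_names = env_names
        self.obs = ~np.isnan(y)
        if not self.obs.any():
            raise ValueError("no observed phenotypes")
        fully_missing = ~self.obs.any(axis=1)
        self.n_unobserved_lines = int(fully_missing.sum())

    def run(self, cfg: GibbsConfig) -> PosteriorSamples:
        if cfg.n_retained < 100:
            import warnings

            warnings.warn(
                f"only {cfg.n_retained} retained draws; inferences will be noisy"
            )
        ss = np.random.SeedSequence(cfg.seed)
        child = ss.spawn(cfg.n_chains)
        scalars: dict[str, list] = {}
        vectors: dict[str, list] = {}
        for c in range(cfg.n_chains):
            sc, vec = self._run_chain(np.random.default_rng(child[c]), cfg)
            for k, v in sc.items():
                scalars.setdefault(k, []).append(v)
            for k, v in vec.items():
                vectors.setdefault(k, []).append(v)
        return PosteriorSamples(
            scalars={k: np.stack(v) for k, v in scalars.items()},
            vectors={k: np.stack(v) for k, v in vectors.items()},
            config=cfg,
            sample_ids=self.ek0.sample_ids,
        )

    def _run_chain(self, rng, cfg: GibbsConfig):
        n, m = self.n, self.m
        obs = self.obs
        y_obs_var = float(np.nanvar(self.y))
        if y_obs_var == 0.0:
            y_obs_var = 1.0
        n_gen = 1 + (m if self.include_env else 0)
        mode_gen = cfg.r2 * y_obs_var / n_gen
        mode_res = (1.0 - cfg.r2) * y_obs_var
        s_u = _prior_scale(mode_gen, cfg.df0)
        s_e = _prior_scale(mode_res, cfg.df0)
        fv = cfg.fixed_variances or {}

        d0, u0mat = self.ek0.d, self.ek0.u
        m0 = d0.size

        # state
        y = self.y.copy()
        col_means = np.nanmean(self.y, axis=0)
        for j in range(m):
            y[~obs[:, j], j] = col_means[j]
        mu = col_means.copy()
        a0 = np.zeros(m0)
        g0 = np.zeros(n)
        s2_u0 = float(fv.get("sigma2_u", mode_gen if mode_gen > 0 else 1.0))
        u_env = np.zeros((n, m))
        a_env = [np.zeros(ek.d.size) for ek in self.ek_env]
        s2_uj = np.full(m, float(fv.get("sigma2_u_env", mode_gen)))
        s2_ej = np.full(m, float(fv.get("sigma2_e", mode_res if mode_res > 0 else 1.0)))

        sample_u0 = "sigma2_u" not in fv
        sample_uj = "sigma2_u_env" not in fv
        sample_e = "sigma2_e" not in fv

        keep = cfg.n_retained
        out_mu = np.empty((keep, m))
        out_s2u0 = np.empty(keep)
        out_s2uj = np.empty((keep, m))
        out_s2ej = np.empty((keep, m))
        out_g0 = np.empty((keep, n))
        out_uenv = np.empty((keep, n, m)) if self.include_env else None
        kept = 0

        for it in range(cfg.n_iter):
            # intercepts
            if cfg.fixed_intercept is not None:
                mu[:] = cfg.fixed_intercept
            else:
                for j in range(m):
                    r = y[:, j] - g0 - u_env[:, j]
                    mu[j] = rng.normal(r.mean(), np.sqrt(s2_ej[j] / n))

            # main genetic effect in the eigenbasis of K0
            resid = y - mu[None, :] - u_env  # (n, m)
            rt = u0mat.T @ resid  # (m0, m)
            prec = (1.0 / s2_ej).sum() + 1.0 / (s2_u0 * d0)
            mean = (rt / s2_ej[None, :]).sum(axis=1) / prec
            a0 = mean + rng.standard_normal(m0) / np.sqrt(prec)
            g0 = u0mat @ a0

            # environment-specific effects
            if self.include_env:
                for j in range(m):
                    ek = self.ek_env[j]
                    r = y[:, j] - mu[j] - g0
                    rt = ek.u.T @ r
                    var = 1.0 / (1.0 / s2_ej[j] + 1.0 / (s2_uj[j] * ek.d))
                    a_env[j] = var * rt / s2_ej[j] + rng.standard_normal(
                        ek.d.size
                    ) * np.sqrt(var)
                    u_env[:, j] = ek.u @ a_env[j]

            # variance components
            if sample_u0:
                ss0 = float(np.sum(a0**2 / d0))
                df = cfg.df0 + m0
                s2_u0 = _sample_scaled_inv_chi2(rng, df, (cfg.df0 * s_u + ss0) / df)
            if self.include_env and sample_uj:
                for j in range(m):
                    ek = self.ek_env[j]
                    ssj = float(np.sum(a_env[j] ** 2 / ek.d))
                    df = cfg.df0 + ek.d.size
                    s2_uj[j] = _sample_scaled_inv_chi2(
                        rng, df, (cfg.df0 * s_u + ssj) / df
                    )
            resid = y - mu[None, :] - g0[:, None] - u_env
            if sample_e:
                if cfg.pooled_residual:
                    sse = float(np.sum(resid**2))
                    df = cfg.df0 + n * m
                    s2 = _sample_scaled_inv_chi2(rng, df, (cfg.df0 * s_e + sse) / df)
                    s2_ej[:] = s2
                else:
                    for j in range(m):
                        sse = float(np.sum(resid[:, j] ** 2))
                        df = cfg.df0 + n
                        s2_ej[j] = _sample_scaled_inv_chi2(
                            rng, df, (cfg.df0 * s_e + sse) / df
                        )

            # data augmentation for masked records
            for j in range(m):
                miss = ~obs[:, j]
                if miss.any():
                    pred = mu[j] + g0[miss] + u_env[miss, j]
                    y[miss, j] = pred + rng.standard_normal(miss.sum()) * np.sqrt(
                        s2_ej[j]
                    )

            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and kept < keep:
                out_mu[kept] = mu
                out_s2u0[kept] = s2_u0
                out_s2uj[kept] = s2_uj
                out_s2ej[kept] = s2_ej
                out_g0[kept] = g0
                if out_uenv is not None:
                    out_uenv[kept] = u_env
                kept += 1

        scalars = {"sigma2_u0": out_s2u0}
        for j, name in enumerate(self.env_names):
            scalars[f"mu[{name}]"] = out_mu[:, j]
            scalars[f"sigma2_e[{name}]"] = out_s2ej[:, j]
            if self.include_env:
                scalars[f"sigma2_u[{name}]"] = out_s2uj[:, j]
        vectors = {"u0": out_g0}
        if out_uenv is not None:
            for j, name in enumerate(self.env_names):
                vectors[f"u[{name}]"] = out_uenv[:, :, j]
        return scalars, vectors


# ----------------------------------------------------------------------
# Public model classes
# ----------------------------------------------------------------------

class KernelMixedModel:
    """Single-environment Bayesian kernel regression (GBLUP / RKHS).

    Parameters
    ----------
    y : array-like, length n
        Phenotypes aligned with the kernel's samples; ``NaN`` marks lines
        to predict (masked from training).
    kernel : KernelMatrix
        Linear kernel for GBLUP, Gaussian kernel for RKHS.
    """

    def __init__(self, y, kernel: KernelMatrix):
        self.kernel = kernel
        self.y = np.asarray(y, dtype=float).ravel()
        self._core = _GibbsCore(
            self.y, kernel, None, include_env_specific=False, env_names=["env"]
        )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, kernel: KernelMatrix):
        """Build from a genotype-indexed DataFrame; kernel samples absent
        from ``data`` get ``NaN`` (predicted, not trained on)."""
        y = data[trait].reindex(kernel.samples).to_numpy(float)
        return cls(y, kernel)

    def fit(self, config: GibbsConfig | None = None) -> "KernelMixedModelResults":
        cfg = config or GibbsConfig()
        samples = self._core.run(cfg)
        return KernelMixedModelResults(self, samples)


class MultiEnvKernelMixedModel:
    """Multi-environment kernel regression with a shared main genetic
    effect and environment-specific deviations.

    Parameters
    ----------
    y : DataFrame or (n, m) array
        One column per environment, rows aligned with the kernel samples;
        ``NaN`` marks masked records.
    kernel_main : KernelMatrix
        Kernel of the across-environment (main) genetic effect.
    env_kernels : list of KernelMatrix, optional
        Per-environment kernels; defaults to ``kernel_main`` for each.
    """

    def __init__(self, y, kernel_main: KernelMatrix, env_kernels=None,
                 env_names=None, include_env_specific: bool = True):
        if isinstance(y, pd.DataFrame):
            env_names = env_names or [str(c) for c in y.columns]
            y = y.to_numpy(float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if env_names is None:
            env_names = [f"env{j}" for j in range(y.shape[1])]
        self.kernel = kernel_main
        self.env_names = list(env_names)
        self.y = y
        self._core = _GibbsCore(
            y, kernel_main, env_kernels, include_env_specific, self.env_names
        )

    def fit(self, config: GibbsConfig | None = None) -> "MultiEnvResults":
        cfg = config or GibbsConfig()
        samples = self._core.run(cfg)
        return MultiEnvResults(self, samples)


class _ResultsBase:
    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% interval per scalar parameter."""
        rows = []
        for name, arr in self.samples.scalars.items():
            flat = arr.ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            rows.append(
                {
                    "parameter": name,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "hdi_2.5%": lo,
                    "hdi_97.5%": hi,
                    "n_draws": flat.size,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def gelman_rubin(self) -> pd.Series:
        return gelman_rubin(self.samples.scalars)

    def plot_trace(self, parameters=None, ax=None):
        """Trace plots of scalar parameters (one panel per parameter)."""
        import matplotlib.pyplot as plt

        names = parameters or list(self.samples.scalars)
        fig, axes = plt.subplots(len(names), 1, figsize=(7, 1.8 * len(names)),
                                 squeeze=False)
        for axi, name in zip(axes[:, 0], names):
            for c, chain in enumerate(self.samples.scalars[name]):
                axi.plot(chain, lw=0.6, label=f"chain {c}")
            axi.set_ylabel(name)
        axes[-1, 0].set_xlabel("retained draw")
        return fig


class KernelMixedModelResults(_ResultsBase):
    """Posterior summaries and GEBVs for the single-environment model."""

    def gebv(self, genotypes=None) -> pd.DataFrame:
        """Posterior-mean genetic values and predicted performances."""
        ids = self.samples.sample_ids
        u = self.samples.posterior_mean("u0")
        mu = self.samples.posterior_mean("mu[env]")
        df = pd.DataFrame({"genotype": ids, "gebv": u, "predicted": mu + u})
        if genotypes is not None:
            missing = set(genotypes) - set(ids)
            if missing:
                raise KeyError(f"genotypes absent from kernel: {sorted(missing)[:5]}")
            df = df.set_index("genotype").loc[list(genotypes)].reset_index()
        return df


class MultiEnvResults(_ResultsBase):
    """Posterior summaries and per-environment GEBVs."""

    def gebv(self, genotypes=None) -> pd.DataFrame:
        ids = self.samples.sample_ids
        u0 = self.samples.posterior_mean("u0")
        frames = []
        for name in self.model.env_names:
            mu = self.samples.posterior_mean(f"mu[{name}]")
            ue = (
                self.samples.posterior_mean(f"u[{name}]")
                if f"u[{name}]" in self.samples.vectors
                else np.zeros_like(u0)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "genotype": ids,
                        "environment": name,
                        "gebv": u0 + ue,
                        "predicted": mu + u0 + ue,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        if genotypes is not None:
            missing = set(genotypes) - set(ids)
            if missing:
                raise KeyError(f"genotypes absent from kernel: {sorted(missing)[:5]}")
            df = df[df["genotype"].isin(set(genotypes))].reset_index(drop=True)
        return df


# ----------------------------------------------------------------------
# Convergence diagnostics
# ----------------------------------------------------------------------

def gelman_rubin(chains) -> pd.Series:
    """Split-chain potential scale reduction factor (PSRF) per parameter.

    ``chains`` is either a dict name -> (n_chains, n_draws) array or a
    single such array.  Each chain is split in half, so at least two
    half-chains always enter the between/within comparison; parameters
    with zero within-chain variance get ``NaN``.
    """
    if not isinstance(chains, dict):
        chains = {"parameter": np.asarray(chains)}
    out = {}
    for name, arr in chains.items():
        arr = np.atleast_2d(np.asarray(arr, dtype=float))
        if arr.shape[0] < 2 and arr.shape[1] < 4:
            raise ValueError("need at least 2 chains or 4 draws to split")
        half = arr.shape[1] // 2
        splits = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
        m, nn = splits.shape
        chain_means = splits.mean(axis=1)
        chain_vars = splits.var(axis=1, ddof=1)
        w = chain_vars.mean()
        b = nn * chain_means.var(ddof=1)
        if w <= 0:
            out[name] = np.nan
            continue
        var_plus = (nn - 1) / nn * w + b / nn
        out[name] = float(np.sqrt(var_plus / w))
    return pd.Series(out, name="psrf")
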