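"""Cross-validation of predictive ability.

Implements the CV1 scheme: validation genotypes have their phenotypes
masked in every environment, models are refitted per partition, and
predictive ability (PA) is the Pearson correlation between predicted and
observed values in the validation set.  The same partitions are reused
across traits, methods and models so comparisons are paired.  PA values
are compared on the Fisher Z scale, Z = 0.5 {ln[1+r] - ln[1-r]}, via a
fixed-effects analysis of variance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .bayes import GibbsConfig, KernelMixedModel, MultiEnvKernelMixedModel
from .kernels import (
    KernelMatrix,
    center_genotypes,
    estimate_bandwidth,
    gaussian_kernel,
    linear_kernel,
    squared_distance_matrix,
)

__all__ = [
    "CVPartitions",
    "make_partitions",
    "build_kernel",
    "run_cv",
    "summarize_cv",
    "fisher_z",
    "inverse_fisher_z",
    "anova_pa",
    "method_agreement",
]


@dataclass
class CVPartitions:
    """Reusable random train/validation splits (CV1)."""

    n: int
    fraction: float
    seed: int | None
    splits: list  # list of (train_idx, val_idx) int arrays

    @property
    def n_reps(self) -> int:
        return len(self.splits)

    def to_json(self, path, sample_ids=None) -> None:
        ids = list(sample_ids) if sample_ids is not None else list(range(self.n))
        payload = {
            "n": self.n,
            "fraction": self.fraction,
            "seed": self.seed,
            "reps": [
                {"train": [ids[i] for i in tr], "validation": [ids[i] for i in va]}
                for tr, va in self.splits
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def make_partitions(
    n: int, fraction: float = 0.8, n_reps: int = 100, seed: int | None = None
) -> CVPartitions:
    """Uniformly random 80/20-style splits, reproducible under ``seed``.

    The training set holds ``floor(fraction * n)`` samples; the remainder
    forms the validation set.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if n < 10:
        raise ValueError("need at least 10 samples for cross-validation")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(fraction * n))
    splits = []
    for _ in range(n_reps):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return CVPartitions(n=n, fraction=fraction, seed=seed, splits=splits)


def build_kernel(genotypes, method: str, y: np.ndarray | None = None,
                 bandwidth: float | None = None,
                 normalize_distances: bool = True) -> KernelMatrix:
    """Kernel for a prediction method: ``GBLUP`` -> linear K = XX'/p,
    ``RKHS`` -> Gaussian with ``bandwidth`` (estimated from ``y`` when not
    given).

    For RKHS the squared distances are scaled to mean 1 by default
    (``normalize_distances``): genomic-scale raw distances are in the
    thousands, where any O(1) bandwidth collapses the kernel to the
    identity; on the normalized scale the Gamma(3.0, 1.5) bandwidth prior
    is informative.
    """
    if method == "GBLUP":
        return linear_kernel(center_genotypes(genotypes))
    if method == "RKHS":
        d2 = squared_distance_matrix(genotypes)
        if normalize_distances:
            off = d2[np.triu_indices(d2.shape[0], k=1)]
            scale = off.mean() if off.size and off.mean() > 0 else 1.0
            d2 = d2 / scale
        if bandwidth is None:
            if y is None:
                raise ValueError("RKHS needs a bandwidth or phenotypes to estimate it")
            yy = np.asarray(y, float)
            mask = np.isfinite(yy)
            if mask.all():
                bandwidth = estimate_bandwidth(d2, yy).h
            else:
                sub = d2[np.ix_(mask, mask)]
                bandwidth = estimate_bandwidth(sub, yy[mask]).h
        samples = getattr(genotypes, "samples", None)
        return gaussian_kernel(d2, bandwidth, samples=samples)
    raise ValueError(f"unknown method {method!r} (use 'GBLUP' or 'RKHS')")


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero-variance vector in a validation set; PA undefined")
        return np.nan
    return float(pearsonr(a, b).statistic)


def run_cv(
    genotypes,
    phenotypes: pd.DataFrame,
    partitions: CVPartitions,
    method: str = "GBLUP",
    model: str = "single",
    cfg: GibbsConfig | None = None,
    trait: str = "trait",
    bandwidth: float | None = None,
) -> pd.DataFrame:
    """CV1 predictive ability for one trait.

    Parameters
    ----------
    genotypes : MarkerMatrix or array
        Imputed dosages for all samples; the kernel is built once.
    phenotypes : DataFrame
        One column per condition (adjusted means), rows aligned with the
        genotype samples.
    model : {"single", "multi"}
        ``single`` fits each condition separately on the same partitions;
        ``multi`` fits the stacked two-condition model, masking validation
        lines in both conditions.

    Returns a tidy frame (rep, trait, condition, method, model, r).
    """
    cfg = cfg or GibbsConfig()
    y_all = phenotypes.to_numpy(float)
    conditions = [str(c) for c in phenotypes.columns]
    n = y_all.shape[0]
    if partitions.n != n:
        raise ValueError("partitions built for a different sample count")
    ref_y = np.nanmean(y_all, axis=1)
    kernel = build_kernel(genotypes, method, y=ref_y, bandwidth=bandwidth)

    rows = []
    base_seed = cfg.seed if cfg.seed is not None else 0
    for rep, (train, val) in enumerate(partitions.splits):
        rep_cfg = GibbsConfig(
            n_iter=cfg.n_iter, burn_in=cfg.burn_in, thin=cfg.thin,
            n_chains=1, seed=(base_seed * 100_003 + rep) % (2**31),
            df0=cfg.df0, r2=cfg.r2, pooled_residual=cfg.pooled_residual,
        )
        if model == "single":
            for j, cond in enumerate(conditions):
                y = y_all[:, j].copy()
                y[val] = np.nan
                res = KernelMixedModel(y, kernel).fit(rep_cfg)
                pred = res.gebv()["predicted"].to_numpy()
                ok = val[np.isfinite(y_all[val, j])]
                rows.append(
                    dict(rep=rep, trait=trait, condition=cond, method=method,
                         model=model, r=_safe_pearson(pred[ok], y_all[ok, j]))
                )
        elif model == "multi":
            y = y_all.copy()
            y[val, :] = np.nan
            res = MultiEnvKernelMixedModel(
                y, kernel, env_names=conditions
            ).fit(rep_cfg)
            g = res.gebv()
            for j, cond in enumerate(conditions):
                pred = g.query("environment == @cond")["predicted"].to_numpy()
                ok = val[np.isfinite(y_all[val, j])]
                rows.append(
                    dict(rep=rep, trait=trait, condition=cond, method=method,
                         model=model, r=_safe_pearson(pred[ok], y_all[ok, j]))
                )
        else:
            raise ValueError(f"unknown model {model!r} (use 'single' or 'multi')")
    return pd.DataFrame(rows)


def summarize_cv(cv: pd.DataFrame) -> pd.DataFrame:
    """Mean PA and its standard error per trait/condition/method/model
    cell; undefined reps are excluded and counted."""
    def agg(g):
        r = g["r"].dropna()
        return pd.Series(
            {
                "mean_pa": r.mean(),
                "se_pa": r.sem(),
                "n_reps": len(r),
                "n_undefined": int(g["r"].isna().sum()),
            }
        )

    return (
        cv.groupby(["trait", "condition", "method", "model"])
        .apply(agg, include_groups=False)
        .reset_index()
    )


def fisher_z(r, clamp: bool = False):
    """Fisher transformation Z = 0.5 ln((1+r)/(1-r)) = artanh(r)."""
    r = np.asarray(r, dtype=float)
    if clamp:
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| >= 1; pass clamp=True to clip at 1 - 1e-12")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def anova_pa(cv: pd.DataFrame, factors=("trait", "condition", "method", "model"),
             block_on_rep: bool = True) -> pd.DataFrame:
    """Fixed-effects ANOVA of Fisher-Z-transformed predictive abilities.

    Type-II sums of squares on the main effects of the requested factors,
    with partition id as a blocking factor (the same partitions are reused
    across cells, so reps are paired).  Factors with fewer than two levels
    are dropped with a warning.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    d = cv.dropna(subset=["r"]).copy()
    d["z"] = fisher_z(d["r"].to_numpy(), clamp=True)
    terms = []
    for f in factors:
        if f in d.columns and d[f].nunique() >= 2:
            terms.append(f"C({f})")
        else:
            warnings.warn(f"factor {f!r} has < 2 levels; dropped from the ANOVA")
    if block_on_rep and d["rep"].nunique() >= 2:
        terms.append("C(rep)")
    if not terms:
        raise ValueError("no factor with >= 2 levels")
    if np.ptp(d["z"].to_numpy()) == 0.0:
        # degenerate: identical Z everywhere -> every F statistic is 0
        return pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": 0.0, "PR(>F)": 1.0},
            index=terms + ["Residual"],
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols("z ~ " + " + ".join(terms), d).fit()
        table = anova_lm(fit, typ=2)
    return table


def method_agreement(g1: pd.DataFrame, g2: pd.DataFrame,
                     value: str = "predicted") -> pd.Series:
    """Spearman rank correlation between two GEBV tables, per trait (or
    globally when no trait column is present)."""
    keys = ["genotype"] + [c for c in ("trait", "environment") if
                           c in g1.columns and c in g2.columns]
    merged = g1.merge(g2, on=keys, suffixes=("_1", "_2"))
    if merged.empty:
        raise ValueError("no common genotypes between the two GEBV tables")
    group_keys = [k for k in keys if k != "genotype"]
    if group_keys:
        out = merged.groupby(group_keys).apply(
            lambda g: spearmanr(g[f"{value}_1"], g[f"{value}_2"]).statistic,
            include_groups=False,
        )
        return out.rename("spearman_rho")
    if len(merged) < 3:
        raise ValueError("need at least 3 common genotypes")
    rho = spearmanr(merged[f"{value}_1"], merged[f"{value}_2"]).statistic
    return pd.Series({"all": float(rho)}, name="spearman_rho")
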