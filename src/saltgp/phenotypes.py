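"""Phenotype handling for the two-condition (control vs salt) hydroponic
screen: derived traits, the split-plot mixed model for adjusted genotype
means, stress-response indices, repeatability and genotype-by-condition
rank correlations.

Phenotypes live in a tidy table with columns ``genotype``, ``condition``
(control/salt), ``replicate``, ``tank``, ``trait``, ``value`` — one row
per observation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, spearmanr

log = logging.getLogger(__name__)

CONDITIONS = ("control", "salt")

PHENO_COLUMNS = ["genotype", "condition", "replicate", "tank", "trait", "value"]

__all__ = [
    "CONDITIONS",
    "PHENO_COLUMNS",
    "LMMFit",
    "validate_phenotypes",
    "derived_traits",
    "fit_split_plot",
    "adjusted_means",
    "stress_index",
    "gxc_rank_correlation",
    "repeatability",
]


def validate_phenotypes(tab: pd.DataFrame) -> pd.DataFrame:
    missing = set(PHENO_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    bad = set(tab["condition"].unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels {sorted(bad)}; use {CONDITIONS}")
    if not np.isfinite(tab["value"].to_numpy(float)).all():
        raise ValueError("non-finite phenotype values")
    return tab


@dataclass
class LMMFit:
    """A fitted per-trait model of the split-plot screen."""

    trait: str
    fixed_effects: pd.Series
    varcomp: dict  # {"replicate": v, "tank": v, "residual": v}
    loglike: float
    converged: bool
    method: str  # "mixedlm" | "ols" | "cellmeans"
    anova: pd.DataFrame  # F tests for condition, genotype, interaction
    _cellmeans: pd.DataFrame = None  # genotype x condition predicted means + se


def derived_traits(raw: pd.DataFrame) -> pd.DataFrame:
    """Append derived traits computed per observation.

    LA = LGTH * WDTH * 0.75; SLA = LA / LEAF; R_S = ROOT / SHOOT;
    Na_K = Na / K.  Observations with a zero denominator are skipped with
    a logged warning.
    """
    validate_phenotypes(raw)
    keys = ["genotype", "condition", "replicate", "tank"]
    wide = raw.pivot_table(index=keys, columns="trait", values="value", aggfunc="mean")
    new_rows = []
    n_skipped = 0

    def emit(idx, trait, value):
        rec = dict(zip(keys, idx))
        rec.update(trait=trait, value=value)
        new_rows.append(rec)

    for idx, row in wide.iterrows():
        if {"LGTH", "WDTH"}.issubset(row.dropna().index):
            la = row["LGTH"] * row["WDTH"] * 0.75
            emit(idx, "LA", la)
            if "LEAF" in row.dropna().index:
                if row["LEAF"] == 0:
                    n_skipped += 1
                else:
                    emit(idx, "SLA", la / row["LEAF"])
        if {"ROOT", "SHOOT"}.issubset(row.dropna().index):
            if row["SHOOT"] == 0:
                n_skipped += 1
            else:
                emit(idx, "R_S", row["ROOT"] / row["SHOOT"])
        if {"Na", "K"}.issubset(row.dropna().index):
            if row["K"] == 0:
                n_skipped += 1
            else:
                emit(idx, "Na_K", row["Na"] / row["K"])
    if n_skipped:
        log.warning("derived_traits: skipped %d observations with zero denominator",
                    n_skipped)
    if not new_rows:
        return raw.copy()
    return pd.concat([raw, pd.DataFrame(new_rows)[PHENO_COLUMNS]], ignore_index=True)


def fit_split_plot(
    tab: pd.DataFrame, trait: str, combine_tank_replicate: bool = False
) -> LMMFit:
    """REML fit of the split-plot model for one trait.

    Fixed: condition + genotype + genotype:condition (sum-to-zero
    contrasts).  Random: replicate and tank within replicate (or a single
    combined term for small designs).  Falls back to ordinary least
    squares when the mixed fit does not converge, and to raw cell means as
    a last resort; the path taken is recorded on ``method``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    d = validate_phenotypes(tab).query("trait == @trait").copy()
    if d.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    if d["condition"].nunique() < 2:
        raise ValueError(f"trait {trait!r} observed in a single condition")
    if d["replicate"].nunique() < 2:
        raise ValueError("need at least two replicates")
    d["unit"] = d["replicate"].astype(str) + ":" + d["tank"].astype(str)

    fixed = "value ~ C(condition, Sum) * C(genotype, Sum)"
    fit = None
    converged = False
    varcomp = {"replicate": 0.0, "tank": 0.0, "residual": float("nan")}
    method = "mixedlm"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if combine_tank_replicate:
                md = smf.mixedlm(fixed, d, groups="unit")
            else:
                md = smf.mixedlm(fixed, d, groups="replicate",
                                 vc_formula={"tank": "0 + C(unit)"})
            fit = md.fit(reml=True, method="lbfgs", maxiter=200)
        converged = bool(fit.converged)
        if combine_tank_replicate:
            varcomp["tank"] = float(fit.cov_re.iloc[0, 0])
        else:
            varcomp["replicate"] = float(fit.cov_re.iloc[0, 0])
            varcomp["tank"] = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
        varcomp["residual"] = float(fit.scale)
    except Exception:
        converged = False

    if fit is None or not converged:
        method = "ols"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols(fixed, d).fit()
        varcomp = {"replicate": 0.0, "tank": 0.0, "residual": float(fit.scale)}

    # term-wise tests
    try:
        if method == "ols":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                an = anova_lm(fit, typ=2)
            an = an.rename(
                columns={"F": "F_value", "PR(>F)": "p_value", "df": "df_num"}
            )[["df_num", "F_value", "p_value"]]
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                wt = fit.wald_test_terms(scalar=True)
            an = wt.table.rename(
                columns={"statistic": "F_value", "pvalue": "p_value", "df_constraint": "df_num"}
            )
    except Exception:
        an = pd.DataFrame(columns=["df_num", "F_value", "p_value"])

    cellmeans = _predict_cell_means(fit, d, method)
    return LMMFit(
        trait=trait,
        fixed_effects=fit.params if hasattr(fit, "params") else pd.Series(dtype=float),
        varcomp=varcomp,
        loglike=float(fit.llf) if hasattr(fit, "llf") else float("nan"),
        converged=converged,
        method=method,
        anova=an,
        _cellmeans=cellmeans,
    )


def _predict_cell_means(fit, d: pd.DataFrame, method: str) -> pd.DataFrame:
    """Fixed-effect predicted mean per observed genotype x condition cell."""
    cells = d[["genotype", "condition"]].drop_duplicates().reset_index(drop=True)
    try:
        pred = np.asarray(fit.predict(exog=cells)).ravel()
        # standard errors from the fixed-effect covariance where available
        se = np.full(len(cells), np.nan)
        try:
            design_info = fit.model.data.design_info
            from patsy import dmatrix

            xm = np.asarray(dmatrix(design_info, cells))
            cov = np.asarray(fit.cov_params())[: xm.shape[1], : xm.shape[1]]
            se = np.sqrt(np.einsum("ij,jk,ik->i", xm, cov, xm))
        except Exception:
            pass
        out = cells.copy()
        out["value"] = pred
        out["se"] = se
        return out
    except Exception:
        g = (
            d.groupby(["genotype", "condition"])["value"]
            .agg(["mean", "sem"])
            .reset_index()
            .rename(columns={"mean": "value", "sem": "se"})
        )
        return g


def adjusted_means(fit: LMMFit) -> pd.DataFrame:
    """Per genotype x condition adjusted (least-squares-type) means.

    Predicted cell means under sum-to-zero contrasts with random effects
    set to zero; genotypes observed in a single condition are reported for
    that condition only.
    """
    out = fit._cellmeans.copy()
    out["trait"] = fit.trait
    return out[["genotype", "condition", "trait", "value", "se"]].sort_values(
        ["genotype", "condition"]
    ).reset_index(drop=True)


def stress_index(am: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Percent response to salt: i_trait = (salt - control) * 100 / control.

    Genotypes without both condition means, or with a zero control mean,
    are dropped with a logged warning.
    """
    d = am.query("trait == @trait")
    wide = d.pivot_table(index="genotype", columns="condition", values="value")
    if not {"control", "salt"}.issubset(wide.columns):
        raise ValueError(f"trait {trait!r} needs adjusted means in both conditions")
    wide = wide.dropna(subset=["control", "salt"])
    zero = wide["control"] == 0
    if zero.any():
        log.warning("stress_index(%s): %d genotypes with zero control mean dropped",
                    trait, int(zero.sum()))
        wide = wide[~zero]
    idx = (wide["salt"] - wide["control"]) * 100.0 / wide["control"]
    return pd.DataFrame(
        {"genotype": wide.index, "trait": f"i{trait}", "value": idx.to_numpy()}
    ).reset_index(drop=True)


def gxc_rank_correlation(am: pd.DataFrame, trait: str, method: str = "spearman") -> float:
    """Rank correlation of a trait's adjusted means across conditions."""
    wide = (
        am.query("trait == @trait")
        .pivot_table(index="genotype", columns="condition", values="value")
        .dropna(subset=["control", "salt"])
    )
    if len(wide) < 3:
        raise ValueError("need at least 3 genotypes observed in both conditions")
    if method == "spearman":
        rho = spearmanr(wide["control"], wide["salt"]).statistic
    elif method == "kendall":
        rho = kendalltau(wide["control"], wide["salt"]).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho)


def repeatability(tab: pd.DataFrame, trait: str, condition: str) -> float:
    """Repeatability H2 = s2_g / (s2_g + s2_e / r) within one condition.

    ``s2_g`` and ``s2_e`` come from a random-genotype fit (REML via a
    one-way variance decomposition) and ``r`` is the harmonic mean number
    of replicates per genotype.
    """
    import statsmodels.formula.api as smf

    d = validate_phenotypes(tab).query("trait == @trait and condition == @condition")
    counts = d.groupby("genotype")["value"].count()
    if (counts < 2).all():
        raise ValueError("need >= 2 replicates per genotype for repeatability")
    r_bar = len(counts) / (1.0 / counts).sum()  # harmonic mean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm("value ~ 1", d, groups="genotype").fit(reml=True)
    s2_g = max(float(fit.cov_re.iloc[0, 0]), 0.0)
    s2_e = float(fit.scale)
    if s2_g == 0.0:
        return 0.0
    return s2_g / (s2_g + s2_e / r_bar)
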