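"""Across-population prediction and validation-subset selection.

A model trained on a phenotyped reference panel (RP) predicts a breeding
population (BP) through a kernel built on the union of the two sample
sets with BP phenotypes masked.  A representative validation subset is
then drawn from the BP by composition over predicted-performance strata:
20% of the subset from the bottom decile, 20% from the top decile and 60%
from the middle of a consensus ranking across traits and methods.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bayes import GibbsConfig, KernelMixedModel, MultiEnvKernelMixedModel
from .evaluation import build_kernel
from .genotypes import MarkerMatrix

log = logging.getLogger(__name__)

__all__ = ["SelectionSpec", "SelectionResult", "predict_population",
           "select_validation_set"]

DEFAULT_TRAITS = ("Na", "K", "Na_K", "iSHOOT", "iROOT")


@dataclass(frozen=True)
class SelectionSpec:
    """Composition rule for the validation subset."""

    traits: tuple = DEFAULT_TRAITS
    methods: tuple = ("GBLUP", "RKHS")
    n_sel: int = 41
    tail_q: float = 0.10
    proportions: tuple = (0.20, 0.20, 0.60)  # bottom, top, middle

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("composition proportions must sum to 1")
        if not 0.0 < self.tail_q < 0.5:
            raise ValueError("tail decile q must be in (0, 0.5)")

    def quotas(self) -> tuple[int, int, int]:
        n_bottom = int(np.floor(self.proportions[0] * self.n_sel))
        n_top = int(np.floor(self.proportions[1] * self.n_sel))
        return n_bottom, n_top, self.n_sel - n_bottom - n_top


@dataclass
class SelectionResult:
    selected: pd.DataFrame  # line, stratum, consensus
    composition: dict  # stratum -> count

    @property
    def lines(self) -> list:
        return list(self.selected["line"])

    def to_csv(self, path) -> None:
        self.selected.to_csv(path, index=False)


def predict_population(
    rp_genotypes: MarkerMatrix,
    rp_phenotypes: pd.DataFrame,
    bp_genotypes: MarkerMatrix,
    method: str = "GBLUP",
    model: str = "single",
    cfg: GibbsConfig | None = None,
    bandwidth: float | None = None,
) -> pd.DataFrame:
    """Predict every BP line from a model trained on the RP.

    ``rp_phenotypes`` is indexed by RP genotype id with one column per
    trait (single-condition adjusted means or indices).  The marker sets
    are intersected (an error is raised when the overlap falls below 50%
    of either panel); the kernel is built on the stacked samples and each
    trait is fitted with the BP phenotypes masked.

    Returns a tidy frame (line, trait, method, model, gebv, predicted).
    """
    cfg = cfg or GibbsConfig()
    common = [mk for mk in rp_genotypes.markers if mk in set(bp_genotypes.markers)]
    frac_rp = len(common) / rp_genotypes.n_markers
    frac_bp = len(common) / bp_genotypes.n_markers
    if frac_rp < 0.5 or frac_bp < 0.5:
        raise ValueError(
            f"marker intersection covers only {frac_rp:.0%} of RP / "
            f"{frac_bp:.0%} of BP"
        )
    log.info("predict_population: %d common markers (%.0f%% RP, %.0f%% BP)",
             len(common), 100 * frac_rp, 100 * frac_bp)
    rp_idx = {mk: j for j, mk in enumerate(rp_genotypes.markers)}
    bp_idx = {mk: j for j, mk in enumerate(bp_genotypes.markers)}
    rp = rp_genotypes.subset_markers([rp_idx[mk] for mk in common])
    bp = bp_genotypes.subset_markers([bp_idx[mk] for mk in common])

    stacked = np.vstack([rp.dosage, bp.dosage])
    samples = list(rp.samples) + list(bp.samples)
    stack = MarkerMatrix(
        samples=samples,
        markers=common,
        chrom=rp.chrom,
        pos=rp.pos,
        dosage=stacked,
    )
    frames = []
    for trait in rp_phenotypes.columns:
        y_rp = rp_phenotypes[trait].reindex(rp.samples).to_numpy(float)
        y = np.concatenate([y_rp, np.full(bp.n_samples, np.nan)])
        kernel = build_kernel(stack, method, y=y, bandwidth=bandwidth)
        if model == "single":
            res = KernelMixedModel(y, kernel).fit(cfg)
            g = res.gebv(genotypes=bp.samples)
        elif model == "multi":
            raise ValueError(
                "multi-environment prediction needs per-condition phenotypes; "
                "pass each condition through model='single' or use "
                "MultiEnvKernelMixedModel directly"
            )
        else:
            raise ValueError(f"unknown model {model!r}")
        g = g.rename(columns={"genotype": "line"})
        g["trait"] = trait
        g["method"] = method
        g["model"] = model
        frames.append(g[["line", "trait", "method", "model", "gebv", "predicted"]])
    return pd.concat(frames, ignore_index=True)


def select_validation_set(
    gebv: pd.DataFrame, spec: SelectionSpec = SelectionSpec(), seed: int | None = None,
    randomize_within_strata: bool = False,
) -> SelectionResult:
    """Pick a representative subset of lines from predicted performances.

    Each trait x method column is converted to percentile ranks (midrank
    convention, so scores lie strictly inside (0, 1)); the consensus score
    of a line is its mean percentile across columns.  Lines with consensus
    below ``tail_q`` form the bottom stratum, above ``1 - tail_q`` the top
    stratum, the rest the middle.  Quotas follow the composition rule
    (floors for the tails, remainder to the middle); within each stratum
    lines sit at evenly spaced quantiles of the consensus score
    (maximum-spread rule, deterministic ties by line id), or are sampled
    uniformly when ``randomize_within_strata`` is set.
    """
    required = {"line", "trait", "method", "predicted"}
    if not required.issubset(gebv.columns):
        raise ValueError(f"GEBV table must have columns {sorted(required)}")
    if not spec.traits or not spec.methods:
        raise ValueError("selection spec needs at least one trait and method")
    wide = gebv.pivot_table(index="line", columns=["trait", "method"],
                            values="predicted")
    missing = [
        (t, m) for t in spec.traits for m in spec.methods
        if (t, m) not in wide.columns
    ]
    if missing:
        raise ValueError(f"GEBV table missing trait x method cells: {missing}")
    wide = wide[[(t, m) for t in spec.traits for m in spec.methods]].dropna()
    n = len(wide)
    if spec.n_sel > n:
        raise ValueError(f"n_sel={spec.n_sel} exceeds population size {n}")

    pct = wide.apply(lambda col: (rankdata(col) - 0.5) / n, axis=0)
    consensus = pct.mean(axis=1).rename("consensus")

    # strata are deciles of the consensus *ranking*: the lowest-ranked
    # tail_q of lines form the bottom stratum, the highest the top
    consensus_pct = pd.Series((rankdata(consensus) - 0.5) / n, index=consensus.index)
    strata = pd.Series("middle", index=consensus.index, dtype=object)
    strata[consensus_pct < spec.tail_q] = "bottom"
    strata[consensus_pct > 1.0 - spec.tail_q] = "top"

    n_bottom, n_top, n_middle = spec.quotas()
    quotas = {"bottom": n_bottom, "top": n_top, "middle": n_middle}
    # reallocate deficits from undersized tail strata to the middle
    for s in ("bottom", "top"):
        avail = int((strata == s).sum())
        if avail < quotas[s]:
            warnings.warn(
                f"stratum {s!r} has {avail} lines for a quota of {quotas[s]}; "
                "deficit moved to the middle stratum"
            )
            quotas["middle"] += quotas[s] - avail
            quotas[s] = avail

    rng = np.random.default_rng(seed)
    chosen = []
    for s in ("bottom", "top", "middle"):
        # stable sort: ties fall back to line-id order from the pivot index
        members = consensus[strata == s].sort_values(kind="mergesort")
        k = quotas[s]
        if k == 0 or members.empty:
            continue
        if randomize_within_strata:
            pick = rng.choice(len(members), size=k, replace=False)
            pick = np.sort(pick)
        elif k == 1:
            pick = np.array([len(members) // 2])
        else:
            pick = np.unique(np.round(np.linspace(0, len(members) - 1, k)).astype(int))
            # rounding collisions: fill with nearest unused positions
            while pick.size < k:
                extra = next(i for i in range(len(members)) if i not in set(pick))
                pick = np.sort(np.append(pick, extra))
        for i in pick:
            chosen.append({"line": members.index[i], "stratum": s,
                           "consensus": float(members.iloc[i])})

    selected = pd.DataFrame(chosen).sort_values(
        ["stratum", "consensus", "line"]
    ).reset_index(drop=True)
    composition = selected["stratum"].value_counts().to_dict()
    return SelectionResult(selected=selected, composition=composition)
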