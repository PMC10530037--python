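"""Synthetic data generator with known truth.

Emulates the structure of a japonica rice diversity panel screened for
salinity tolerance: ~600 individuals genotyped at ~17k SNPs on 12
chromosomes, two genetic subgroups plus admixed individuals
(Balding-Nichols allele-frequency model), and two-condition (control /
salt) phenotypes from a split-plot design with replicate and tank
effects.  Genetic effects decompose into a shared (main) component and
condition-specific components, so the cross-condition genetic correlation
rho_G and per-condition heritabilities are controlled directly; ion-like
traits (Na, K) are produced in the salt condition only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotypes import MarkerMatrix
from .phenotypes import PHENO_COLUMNS

__all__ = [
    "SimulationConfig",
    "TraitSpec",
    "SimulationTruth",
    "simulate_genotypes",
    "simulate_effects_and_phenotypes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class TraitSpec:
    """Generative settings for one trait.

    ``h2`` is the per-condition plot-level heritability (fraction of
    phenotypic variance that is genetic), ``rho_g`` the cross-condition
    genetic correlation; ``salt_only`` mimics ion mass fractions measured
    only under stress.
    """

    name: str
    h2: tuple = (0.5, 0.5)  # (control, salt)
    rho_g: float = 0.6
    mu: tuple = (10.0, 8.0)
    salt_only: bool = False


def default_traits() -> tuple:
    """Trait panel spanning the weak-to-strong interaction range observed
    in two-condition salinity screens (rank correlations ~0.25-0.83,
    repeatabilities ~0.44-0.93)."""
    return (
        TraitSpec("SHOOT", h2=(0.7, 0.6), rho_g=0.85, mu=(12.0, 9.0)),
        TraitSpec("ROOT", h2=(0.6, 0.5), rho_g=0.75, mu=(4.0, 3.2)),
        TraitSpec("LL", h2=(0.8, 0.7), rho_g=0.85, mu=(60.0, 52.0)),
        TraitSpec("SLA", h2=(0.45, 0.5), rho_g=0.30, mu=(250.0, 260.0)),
        TraitSpec("Na", h2=(0.5, 0.5), rho_g=1.0, mu=(0.4, 0.4), salt_only=True),
        TraitSpec("K", h2=(0.5, 0.5), rho_g=1.0, mu=(3.0, 3.0), salt_only=True),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 600 individuals, 17,000 SNPs on 12
    chromosomes, two subpopulations (F_ST = 0.1) with 37% admixture."""

    n_individuals: int = 600
    n_markers: int = 17_000
    n_chromosomes: int = 12
    chrom_length_bp: int = 25_000_000
    fst: float = 0.1
    admixture_fraction: float = 0.37
    inbreeding: float = 1.0  # rice accessions are selfing: hets only by error
    n_causal: int = 300
    traits: tuple = field(default_factory=default_traits)
    replicate_var_frac: float = 0.05
    tank_var_frac: float = 0.05
    n_replicates: int = 3
    n_tanks_per_condition: int = 6
    missing_rate: float = 0.0
    het_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_causal > self.n_markers:
            raise ValueError("n_causal cannot exceed n_markers")
        for t in self.traits:
            if not all(0.0 < h < 1.0 for h in t.h2):
                raise ValueError(f"trait {t.name}: h2 must be in (0, 1)")
            if not 0.0 <= t.rho_g <= 1.0:
                raise ValueError(f"trait {t.name}: rho_g must be in [0, 1]")
            if t.h2[0] > 0 and self.n_causal == 0:
                raise ValueError("n_causal = 0 is incompatible with h2 > 0")


@dataclass
class SimulationTruth:
    """Generative ground truth for recovery tests."""

    subpopulation: pd.Series  # sample -> "pop1" | "pop2" | "admixed"
    admixture_coef: pd.Series
    causal_markers: list = None
    beta_main: dict = None  # trait -> (n_causal,) shared effects
    beta_env: dict = None  # trait -> {condition: effects}
    genetic_values: dict = None  # trait -> DataFrame (genotype x condition)
    realized_h2: dict = None
    realized_rho_g: dict = None


def simulate_genotypes(cfg: SimulationConfig) -> tuple[MarkerMatrix, SimulationTruth]:
    """Balding-Nichols genotypes with two subpopulations plus admixture.

    Ancestral allele frequencies are uniform on [0.1, 0.9]; each
    subpopulation draws marker frequencies from
    Beta(p(1-F)/F, (1-p)(1-F)/F).  Admixed individuals draw each of their
    two alleles from a subpopulation chosen with an individual admixture
    coefficient uniform on (0, 1); the rest are binomial(2, freq) within
    their subpopulation.  Markers are placed uniformly along each
    chromosome.  Optional missing-call and heterozygote injection supports
    QC testing.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_individuals, cfg.n_markers
    f = cfg.fst
    p_anc = rng.uniform(0.1, 0.9, size=p)
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    freqs = np.stack([rng.beta(a, b), rng.beta(a, b)])  # (2, p)

    n_adm = int(round(cfg.admixture_fraction * n))
    subpop = np.array(["pop1"] * ((n - n_adm + 1) // 2)
                      + ["pop2"] * ((n - n_adm) // 2)
                      + ["admixed"] * n_adm, dtype=object)
    rng.shuffle(subpop)
    alpha = np.where(subpop == "pop1", 1.0, np.where(subpop == "pop2", 0.0, np.nan))
    alpha[subpop == "admixed"] = rng.uniform(0, 1, size=n_adm)

    # per-entry inbreeding: with probability `inbreeding` the two allele
    # draws are identical by descent (selfing lineages), else independent
    ibd = rng.random((n, p)) < cfg.inbreeding
    dosage = np.empty((n, p))
    pure = subpop != "admixed"
    for popidx, name in enumerate(("pop1", "pop2")):
        rows = subpop == name
        if rows.any():
            pr = np.broadcast_to(freqs[popidx], (rows.sum(), p))
            a1 = rng.random((rows.sum(), p)) < pr
            a2 = rng.random((rows.sum(), p)) < pr
            dosage[rows] = np.where(ibd[rows], 2.0 * a1, a1.astype(float) + a2)
    adm = ~pure
    if adm.any():
        # each allele independently picks a source population by the
        # individual's admixture coefficient
        al = alpha[adm][:, None]
        acc = None
        for allele in range(2):
            src = rng.random((adm.sum(), p)) < al  # True -> pop1
            pr = np.where(src, freqs[0], freqs[1])
            draw = rng.random((adm.sum(), p)) < pr
            acc = draw.astype(float) if acc is None else acc + draw
            if allele == 0:
                first = draw
        dosage[adm] = np.where(ibd[adm], 2.0 * first, acc)

    per_chrom = np.array_split(np.arange(p), cfg.n_chromosomes)
    chrom = np.empty(p, dtype=object)
    pos = np.empty(p, dtype=np.int64)
    for ci, idx in enumerate(per_chrom, start=1):
        chrom[idx] = str(ci)
        pos[idx] = np.sort(
            rng.choice(np.arange(1, cfg.chrom_length_bp), size=idx.size, replace=False)
        )

    if cfg.het_rate > 0:
        inject = rng.random(dosage.shape) < cfg.het_rate
        dosage[inject] = 1.0
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = np.nan

    samples = [f"G{i:04d}" for i in range(n)]
    markers = [f"M{j:05d}" for j in range(p)]
    m = MarkerMatrix(samples, markers, chrom, pos, dosage)
    sidx = pd.Index(samples, name="sample")
    truth = SimulationTruth(
        subpopulation=pd.Series(subpop, index=sidx),
        admixture_coef=pd.Series(alpha, index=sidx),
    )
    return m, truth


def simulate_effects_and_phenotypes(
    m: MarkerMatrix, cfg: SimulationConfig, truth: SimulationTruth | None = None
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Two-condition phenotypes from additive causal effects.

    For each trait, shared effects beta0 ~ N(0, s2_0) and
    condition-specific effects beta_j ~ N(0, s2_E) are drawn with
    s2_0 / (s2_0 + s2_E) = rho_g; genetic values g_j = X beta0 + X beta_j
    (centered causal columns) are rescaled so the genetic share of the
    phenotypic variance matches the trait's h2 per condition.  Records are
    laid out on the split-plot design (replicates x tanks within
    condition) with the configured replicate and tank variance fractions;
    the residual takes the remainder.
    """
    if np.isnan(m.dosage).any():
        raise ValueError("genotypes must be imputed before phenotype simulation")
    rng = np.random.default_rng(
        None if cfg.seed is None else np.random.SeedSequence([cfg.seed, 7919])
    )
    n = m.n_samples
    conditions = ("control", "salt")
    causal = np.sort(rng.choice(m.n_markers, size=cfg.n_causal, replace=False))
    xc = m.dosage[:, causal] - m.dosage[:, causal].mean(axis=0, keepdims=True)

    if truth is None:
        truth = SimulationTruth(
            subpopulation=pd.Series("pop1", index=pd.Index(m.samples, name="sample")),
            admixture_coef=pd.Series(np.nan, index=pd.Index(m.samples, name="sample")),
        )
    truth.causal_markers = [m.markers[j] for j in causal]
    truth.beta_main, truth.beta_env = {}, {}
    truth.genetic_values, truth.realized_h2, truth.realized_rho_g = {}, {}, {}

    rows = []
    for trait in cfg.traits:
        s2_0 = trait.rho_g
        s2_e = 1.0 - trait.rho_g
        beta0 = rng.normal(0.0, np.sqrt(max(s2_0, 1e-12)), size=cfg.n_causal)
        g = {}
        beta_env = {}
        for j, cond in enumerate(conditions):
            bj = rng.normal(0.0, np.sqrt(max(s2_e, 1e-12)), size=cfg.n_causal)
            beta_env[cond] = bj
            raw = xc @ (beta0 + bj)
            sd = raw.std()
            target_sd = np.sqrt(trait.h2[j])  # phenotypic variance normalized to 1
            g[cond] = raw * (target_sd / sd) if sd > 0 else raw
        truth.beta_main[trait.name] = beta0
        truth.beta_env[trait.name] = beta_env
        gdf = pd.DataFrame(g, index=pd.Index(m.samples, name="genotype"))
        truth.genetic_values[trait.name] = gdf
        truth.realized_rho_g[trait.name] = float(
            np.corrcoef(gdf["control"], gdf["salt"])[0, 1]
        )

        rep_sd = np.sqrt(cfg.replicate_var_frac)
        tank_sd = np.sqrt(cfg.tank_var_frac)
        h2_realized = {}
        for j, cond in enumerate(conditions):
            if trait.salt_only and cond != "salt":
                continue
            resid_var = 1.0 - trait.h2[j] - cfg.replicate_var_frac - cfg.tank_var_frac
            if resid_var <= 0:
                raise ValueError(
                    f"trait {trait.name}: h2 + design variance fractions exceed 1"
                )
            for rep in range(1, cfg.n_replicates + 1):
                rep_eff = rng.normal(0.0, rep_sd)
                tank_ids = [f"{cond[:1]}{t}" for t in range(1, cfg.n_tanks_per_condition + 1)]
                tank_eff = {t: rng.normal(0.0, tank_sd) for t in tank_ids}
                tanks = np.array(tank_ids)[np.arange(n) % len(tank_ids)]
                eps = rng.normal(0.0, np.sqrt(resid_var), size=n)
                values = trait.mu[j] + gdf[cond].to_numpy() + rep_eff + eps
                values = values + np.array([tank_eff[t] for t in tanks])
                for i, sample in enumerate(m.samples):
                    rows.append(
                        (sample, cond, f"R{rep}", f"R{rep}:{tanks[i]}", trait.name,
                         values[i])
                    )
            h2_realized[cond] = trait.h2[j]
        truth.realized_h2[trait.name] = h2_realized

    tab = pd.DataFrame(rows, columns=PHENO_COLUMNS)
    return tab, truth


def simulate_dataset(cfg: SimulationConfig) -> tuple[MarkerMatrix, pd.DataFrame, SimulationTruth]:
    """Genotypes plus phenotypes in one call (shared truth object)."""
    m, truth = simulate_genotypes(cfg)
    if cfg.missing_rate > 0 or cfg.het_rate > 0:
        from .genotypes import impute_naive

        m_clean = impute_naive(m, method="mode")
    else:
        m_clean = m
    tab, truth = simulate_effects_and_phenotypes(m_clean, cfg, truth)
    return m, tab, truth
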