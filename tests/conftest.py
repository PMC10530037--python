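import numpy as np
import pandas as pd
import pytest

from saltgp.genotypes import MarkerMatrix
from saltgp.kernels import CenteredMatrix, linear_kernel
from saltgp.simulate import SimulationConfig, TraitSpec, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def small_markers():
    """60 samples x 200 inbred markers with map, no missingness."""
    from saltgp.simulate import simulate_genotypes

    cfg = SimulationConfig(
        n_individuals=60, n_markers=200, n_chromosomes=4, n_causal=50, seed=101
    )
    m, truth = simulate_genotypes(cfg)
    return m


@pytest.fixture(scope="session")
def small_kernel(small_markers):
    from saltgp.kernels import center_genotypes

    return linear_kernel(center_genotypes(small_markers))


@pytest.fixture(scope="session")
def sim_dataset():
    """Genotypes + two-condition phenotypes + truth for one trait."""
    cfg = SimulationConfig(
        n_individuals=60,
        n_markers=300,
        n_chromosomes=6,
        n_causal=60,
        seed=202,
        traits=(TraitSpec("SHOOT", h2=(0.6, 0.5), rho_g=0.8, mu=(10.0, 8.0)),),
    )
    return simulate_dataset(cfg)


def toy_marker_matrix(dosage, chrom=None, pos=None, samples=None, markers=None,
                      **kw):
    dosage = np.asarray(dosage, dtype=float)
    n, p = dosage.shape
    return MarkerMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        markers=markers or [f"m{j}" for j in range(p)],
        chrom=chrom if chrom is not None else np.array(["1"] * p, dtype=object),
        pos=pos if pos is not None else np.arange(1, p + 1) * 100,
        dosage=dosage,
        **kw,
    )
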