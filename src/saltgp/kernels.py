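"""Genomic kernels.

Two kernels drive the prediction models:

* the linear (genomic-relationship) kernel ``K = X X' / p`` built from the
  column-centered dosage matrix ``X`` with ``p`` markers (GBLUP), and
* the Gaussian kernel ``K(x_i, x_j) = exp(-h * ||x_i - x_j||^2)`` on raw
  dosage vectors (RKHS regression), with bandwidth ``h``.

The bandwidth is estimated as the mode of the joint posterior of ``h`` and
the noise-to-signal ratio ``phi`` under the working model
``y = 1 mu + u + e``, ``u ~ N(0, s2 K_h)``, ``e ~ N(0, phi s2 I)``, with
``mu`` and ``s2`` integrated out analytically and a Gamma(shape 3.0,
scale 1.5) prior on ``h``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform, pdist
from scipy.stats import gamma as gamma_dist

from .genotypes import MarkerMatrix

__all__ = [
    "CenteredMatrix",
    "KernelMatrix",
    "BandwidthEstimate",
    "center_genotypes",
    "linear_kernel",
    "squared_distance_matrix",
    "gaussian_kernel",
    "estimate_bandwidth",
]


@dataclass
class CenteredMatrix:
    """Column-centered genotype matrix X (samples x markers)."""

    values: np.ndarray
    samples: list
    markers: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        colsum = np.abs(self.values.sum(axis=0))
        if colsum.size and colsum.max() > 1e-8 * max(n, 1):
            raise ValueError("columns are not centered")

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class KernelMatrix:
    """Symmetric PSD genotype-similarity matrix."""

    values: np.ndarray
    samples: list
    kind: str = "linear"  # "linear" | "gaussian"
    bandwidth: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = self.values
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("kernel must be symmetric")
        w = np.linalg.eigvalsh(k)
        tol = 1e-8 * max(np.trace(k) / k.shape[0], 1e-12)
        if w.min() < -tol:
            raise ValueError(f"kernel not PSD: min eigenvalue {w.min():.3e}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def eigendecompose(self, tol: float = 1e-10):
        """Eigenpairs with eigenvalues below ``tol`` dropped."""
        w, v = np.linalg.eigh(self.values)
        keep = w > tol
        return w[keep], v[:, keep]

    def to_file(self, path) -> None:
        pd.DataFrame(self.values, index=self.samples, columns=self.samples).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_file(cls, path, kind="linear", bandwidth=None) -> "KernelMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(s) for s in df.index], kind, bandwidth)


@dataclass
class BandwidthEstimate:
    h: float
    phi: float
    log_posterior_at_mode: float
    trace: pd.DataFrame  # grid evaluations: h, phi, log_posterior
    grid_h: float  # argmax over the coarse grid, before refinement
    grid_phi: float


def center_genotypes(m: MarkerMatrix | np.ndarray, samples=None) -> CenteredMatrix:
    """Subtract each marker's mean dosage, yielding the X of K = XX'/p."""
    if isinstance(m, MarkerMatrix):
        values, samples, markers = m.dosage, m.samples, m.markers
    else:
        values = np.asarray(m, dtype=float)
        markers = None
        if samples is None:
            samples = list(range(values.shape[0]))
    if np.isnan(values).any():
        raise ValueError("missing dosages: impute first (impute_naive)")
    x = values - values.mean(axis=0, keepdims=True)
    return CenteredMatrix(x, list(samples), markers)


def linear_kernel(x: CenteredMatrix) -> KernelMatrix:
    """Genomic relationship matrix K = X X' / p."""
    if x.p < 1:
        raise ValueError("need at least one marker")
    k = x.values @ x.values.T / x.p
    return KernelMatrix(k, x.samples, kind="linear")


def squared_distance_matrix(m: MarkerMatrix | CenteredMatrix | np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances between genotype rows.

    Invariant to column centering, so raw dosages and centered matrices
    give identical results.
    """
    if isinstance(m, MarkerMatrix):
        values = m.dosage
    elif isinstance(m, CenteredMatrix):
        values = m.values
    else:
        values = np.asarray(m, dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing dosages: impute first")
    d2 = squareform(pdist(values, metric="sqeuclidean"))
    return d2


def gaussian_kernel(d2: np.ndarray, h: float, samples=None) -> KernelMatrix:
    """Gaussian kernel exp(-h * d^2) from a squared-distance matrix."""
    if h <= 0:
        raise ValueError(f"bandwidth h must be > 0, got {h}")
    d2 = np.asarray(d2, dtype=float)
    k = np.exp(-h * d2)
    np.fill_diagonal(k, 1.0)
    if samples is None:
        samples = list(range(k.shape[0]))
    return KernelMatrix(k, list(samples), kind="gaussian", bandwidth=float(h))


# ----------------------------------------------------------------------
# Bandwidth estimation
# ----------------------------------------------------------------------

def _profile_log_marginal(y_rot: np.ndarray, lam: np.ndarray, phi: float) -> float:
    """Log marginal density of the mean-free rotated data given (h, phi).

    ``y_rot`` and ``lam`` are the data and kernel eigenvalues after
    projecting out the grand mean (Helmert rotation), so the flat prior on
    mu is already integrated.  The common scale s2 carries a Jeffreys
    prior and integrates to a multivariate-t-type kernel.
    """
    v = lam + phi
    q = float(np.sum(y_rot**2 / v))
    nm1 = y_rot.size
    return -0.5 * float(np.sum(np.log(v))) - 0.5 * nm1 * np.log(q)


def estimate_bandwidth(
    x: MarkerMatrix | CenteredMatrix | np.ndarray,
    y: np.ndarray,
    prior_shape: float = 3.0,
    prior_scale: float = 1.5,
    n_grid_h: int = 50,
    phi_grid: np.ndarray | None = None,
    h_bounds: tuple[float, float] | None = None,
    refine: bool = True,
) -> BandwidthEstimate:
    """Posterior-mode bandwidth for the Gaussian kernel.

    Maximizes ``log p(y | h, phi) + log Gamma(h; shape, scale)`` over a 2-D
    grid: 50 log-spaced h values spanning [1e-4, 1e2] x (1 / median squared
    distance) and a flat-on-log grid for phi in [1e-3, 1e3]; optionally
    refined by bounded 1-D optimization in h around the grid argmax.
    """
    y = np.asarray(y, dtype=float).ravel()
    d2 = squared_distance_matrix(x) if not (isinstance(x, np.ndarray) and x.ndim == 2 and x.shape[0] == x.shape[1] and np.allclose(np.diag(x), 0)) else np.asarray(x, float)
    n = d2.shape[0]
    if y.size != n:
        raise ValueError(f"y has length {y.size}, expected {n}")

    off = d2[np.triu_indices(n, k=1)]
    med = np.median(off[off > 0]) if np.any(off > 0) else 1.0
    h_ref = 1.0 / med
    if h_bounds is None:
        # span the data-driven scale and the prior's effective support
        prior_lo, prior_hi = gamma_dist.ppf([0.001, 0.999], prior_shape,
                                            scale=prior_scale)
        h_bounds = (min(1e-4 * h_ref, prior_lo), max(1e2 * h_ref, prior_hi))
    h_grid = np.geomspace(h_bounds[0], h_bounds[1], n_grid_h)
    if phi_grid is None:
        phi_grid = np.geomspace(1e-3, 1e3, 25)

    a = helmert(n)  # (n-1) x n, rows orthonormal, orthogonal to 1
    z = a @ y

    rows = []

    def log_post(h: float) -> tuple[float, float]:
        """Best log-posterior over the phi grid at this h."""
        kh = np.exp(-h * d2)
        lam, v = np.linalg.eigh(a @ kh @ a.T)
        lam = np.clip(lam, 0.0, None)
        zr = v.T @ z  # data in the eigenbasis of the projected kernel
        best, best_phi = -np.inf, phi_grid[0]
        for phi in phi_grid:
            lp = _profile_log_marginal(zr, lam, phi) + gamma_dist.logpdf(
                h, prior_shape, scale=prior_scale
            )
            rows.append((h, phi, lp))
            if lp > best:
                best, best_phi = lp, phi
        return best, best_phi

    evals = []
    for h in h_grid:
        lp, phi = log_post(h)
        evals.append((h, phi, lp))
    evals = np.array(evals)
    if not np.isfinite(evals[:, 2]).any():
        raise RuntimeError(
            f"log-posterior non-finite over the whole grid h in "
            f"[{h_bounds[0]:.3g}, {h_bounds[1]:.3g}]"
        )
    i = int(np.nanargmax(evals[:, 2]))
    grid_h, grid_phi, grid_lp = evals[i]

    h_hat, phi_hat, lp_hat = grid_h, grid_phi, grid_lp
    if refine:
        lo = h_grid[max(i - 1, 0)]
        hi = h_grid[min(i + 1, len(h_grid) - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda h: -log_post(h)[0], bounds=(lo, hi), method="bounded"
            )
            if res.success and -res.fun >= lp_hat:
                h_hat = float(res.x)
                lp_hat, phi_hat = log_post(h_hat)

    trace = pd.DataFrame(rows, columns=["h", "phi", "log_posterior"])
    return BandwidthEstimate(
        h=float(h_hat),
        phi=float(phi_hat),
        log_posterior_at_mode=float(lp_hat),
        trace=trace,
        grid_h=float(grid_h),
        grid_phi=float(grid_phi),
    )
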