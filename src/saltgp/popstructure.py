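"""Population structure: simple-matching dissimilarity, neighbor-joining
tree, and PCA + k-means group assignment.

The workflow mirrors standard diversity analyses of rice panels: a
simple-matching index between genotype call vectors feeds an unweighted
neighbor-joining tree, and genetic groups (e.g. temperate japonica,
tropical japonica, admixed) are assigned by k-means on the leading
principal components of the centered dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .genotypes import MarkerMatrix

__all__ = ["simple_matching", "nj_tree", "assign_groups", "GroupAssignment"]


@dataclass
class GroupAssignment:
    labels: pd.Series  # sample -> group in {0..k-1}
    k: int
    n_components: int
    var_explained: float


def simple_matching(m: MarkerMatrix) -> _SkbioDM:
    """Simple-matching dissimilarity: the fraction of markers at which two
    individuals carry different dosage calls (a heterozygote mismatches
    both homozygotes)."""
    if np.isnan(m.dosage).any():
        raise ValueError("missing dosages: impute first")
    x = m.dosage
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i + 1:] = (x[i + 1:, :] != x[i, :]).mean(axis=1)
    d = d + d.T
    return _SkbioDM(d, ids=[str(s) for s in m.samples])


def nj_tree(d, clamp_negative: bool = True) -> str:
    """Unweighted neighbor-joining (Saitou-Nei) tree in newick form.

    Accepts a scikit-bio DistanceMatrix or a square symmetric array with
    ``ids``-less integer labels.  Negative branch lengths produced by the
    NJ formulas are clamped to zero.
    """
    if not isinstance(d, _SkbioDM):
        arr = np.asarray(d, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        d = _SkbioDM(arr, ids=[str(i) for i in range(arr.shape[0])])
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(d)
    if clamp_negative:
        for node in tree.traverse():
            if node.length is not None and node.length < 0:
                node.length = 0.0
    return str(tree).strip()


def assign_groups(
    m: MarkerMatrix,
    k: int = 3,
    var_explained: float = 0.90,
    n_restarts: int = 10,
    seed: int | None = None,
) -> GroupAssignment:
    """Cluster individuals on leading principal components.

    PCA retains the fewest components explaining at least
    ``var_explained`` of the dosage variance; k-means (``n_restarts``
    seeded restarts, best within-cluster sum of squares kept) labels the
    individuals.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples {m.n_samples}")
    if np.isnan(m.dosage).any():
        raise ValueError("missing dosages: impute first")
    x = m.dosage - m.dosage.mean(axis=0, keepdims=True)
    max_comp = min(x.shape) - 1 if min(x.shape) > 1 else 1
    pca = PCA(n_components=max_comp, random_state=seed)
    scores = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, var_explained) + 1)
    n_comp = min(n_comp, scores.shape[1])
    scores = scores[:, :n_comp]
    if k == 1:
        labels = np.zeros(m.n_samples, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(scores)
    return GroupAssignment(
        labels=pd.Series(labels, index=pd.Index(m.samples, name="sample")),
        k=k,
        n_components=n_comp,
        var_explained=float(cum[n_comp - 1]),
    )
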