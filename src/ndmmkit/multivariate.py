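"""Compositional dissimilarity, Mantel correlation and NMDS ordination.

Profile-level phylogenetic signal is assessed by comparing Bray-Curtis
dissimilarities between closed compositional profiles against patristic
distances from the tree: a Mantel test on Spearman-correlated lower
triangles with a joint row/column permutation null, and a non-metric
multidimensional scaling (NMDS) ordination minimising Kruskal stress-1
for visual structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from sklearn.manifold import MDS

from .profiles import CompositionProfile

__all__ = [
    "MantelResult",
    "NMDSResult",
    "bray_curtis_matrix",
    "mantel_test",
    "nmds_ordination",
]


@dataclass
class MantelResult:
    rho: float
    p_value: float
    n_perm: int


@dataclass
class NMDSResult:
    coordinates: np.ndarray  # (n, k)
    stress: float  # Kruskal stress-1
    n_restarts: int
    converged: bool


def bray_curtis_matrix(profiles: CompositionProfile) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarities between species profiles.

    ``BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``; requires closed
    (rows-sum-to-100) profiles so absolute production scale cannot leak in.
    """
    if profiles.mode != "closed_all":
        raise ValueError(
            "Bray-Curtis expects closed_all profiles "
            f"(got mode {profiles.mode!r})"
        )
    x = profiles.values.to_numpy(dtype=float)
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("all-zero profile row")
    return squareform(pdist(x, metric="braycurtis"))


def _check_square(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(m, m.T):
        raise ValueError("matrix is not symmetric")
    return m


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test of matrix association with a Spearman statistic.

    The observed statistic is Spearman's rho over the lower triangles
    (midranks for ties). The null jointly permutes the rows and columns of
    the second matrix; the one-sided p-value is
    ``(1 + #{rho_perm >= rho_obs}) / (n_perm + 1)``.
    """
    m1, m2 = _check_square(m1), _check_square(m2)
    if m1.shape != m2.shape:
        raise ValueError("matrix size mismatch")
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    tri = np.tril_indices(n, k=-1)
    v1 = m1[tri]
    rho_obs = spearmanr(v1, m2[tri]).statistic
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mp = m2[np.ix_(perm, perm)]
        if spearmanr(v1, mp[tri]).statistic >= rho_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(float(rho_obs), float(p), n_perm)


def nmds_ordination(
    dissim: np.ndarray,
    k: int = 2,
    n_restarts: int = 8,
    seed: int | None = None,
    max_iter: int = 300,
) -> NMDSResult:
    """Non-metric MDS of a dissimilarity matrix.

    Minimises Kruskal stress-1 (monotone regression of configuration
    distances on the input dissimilarities) via SMACOF, keeping the best
    of ``n_restarts`` random starts. Deterministic for a given seed.
    """
    d = _check_square(dissim)
    n = d.shape[0]
    if n <= k:
        raise ValueError("need more objects than ordination dimensions")
    off = d[np.tril_indices(n, k=-1)]
    if np.allclose(off, off[0]):
        raise ValueError("degenerate dissimilarities: all pairs equal")
    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        random_state=seed,
        normalized_stress=True,
    )
    coords = mds.fit_transform(d)
    return NMDSResult(
        coordinates=coords,
        stress=float(mds.stress_),
        n_restarts=n_restarts,
        converged=bool(mds.n_iter_ < max_iter),
    )
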