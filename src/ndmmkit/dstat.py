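"""Phylogenetic signal for binary traits: the D statistic.

D scales the observed sum of sister-clade differences of a 0/1 trait
between two simulated baselines: traits shuffled at random across tips
(no phylogenetic structure; E[D] = 1) and traits produced by thresholding
a Brownian motion evolved on the tree at the observed prevalence
(clumped, heritable variation; E[D] = 0). Values below 0 indicate
conservation stronger than Brownian expectation; values above 1 indicate
phylogenetic overdispersion.

The sister-clade difference sum uses nodal trait values estimated
tips-to-root by averaging daughter values; each internal node contributes
the absolute difference of its two daughters' values. The whole pass is
vectorised over trait columns, so the permutation and Brownian null sets
are computed in a handful of array sweeps.

D is undefined for constant traits and for singletons (one tip differing
from all others), for which neither null distribution has usable spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .mk import BinaryTrait
from .trees import Phylogeny

__all__ = ["DResult", "sister_difference_sum", "estimate_D", "bh_fdr"]


@dataclass
class DResult:
    """Observed statistic, null means, scaled D, and permutation p-values."""

    trait: str
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_d0: float  # two-sided test of H0: D = 0 (Brownian null)
    p_d1: float  # two-sided test of H0: D = 1 (random null)
    n_perm: int
    n_brownian: int


def sister_difference_sum(phy: Phylogeny, states: np.ndarray) -> np.ndarray:
    """Sum over internal nodes of |difference of daughter nodal values|.

    ``states`` is (n_tips,) or (n_tips, m); nodal values are daughter
    averages computed tips-to-root. Returns a scalar array of shape () or
    (m,). Requires a binary (fully bifurcating) tree.
    """
    if not phy.is_binary():
        raise ValueError("sister-clade differences require a binary tree")
    single = states.ndim == 1
    vals = np.zeros(
        (phy.n_nodes,) + ((states.shape[1],) if not single else ())
    )
    vals[: phy.n_tips] = states
    d = np.zeros(states.shape[1] if not single else ())
    for node in phy.postorder:
        c1, c2 = phy.children[node]
        d = d + np.abs(vals[c1] - vals[c2])
        vals[node] = 0.5 * (vals[c1] + vals[c2])
    return d


def brownian_tip_covariance(phy: Phylogeny) -> np.ndarray:
    """Tip covariance of unit-rate Brownian motion: shared path length."""
    depths = phy.node_depths()
    n = phy.n_tips
    cov = np.diag(depths[:n])
    under: dict[int, np.ndarray] = {i: np.array([i]) for i in range(n)}
    for node in phy.postorder:
        groups = [under.pop(c) for c in phy.children[node]]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                cov[np.ix_(groups[a], groups[b])] = depths[node]
                cov[np.ix_(groups[b], groups[a])] = depths[node]
        under[node] = np.concatenate(groups)
    return cov


def threshold_at_prevalence(values: np.ndarray, k: int) -> np.ndarray:
    """Binary matrix marking the ``k`` largest entries per column as 1.

    Rank-thresholding guarantees every simulated trait has exactly the
    observed prevalence.
    """
    order = np.argsort(values, axis=0)
    out = np.zeros_like(values, dtype=int)
    n = values.shape[0]
    rows = order[n - k:, ...]
    np.put_along_axis(out, rows, 1, axis=0)
    return out


def _tail_p(null: np.ndarray, obs: float) -> tuple[float, float]:
    n = null.size
    p_low = (1 + np.sum(null <= obs)) / (n + 1)
    p_high = (1 + np.sum(null >= obs)) / (n + 1)
    return p_low, p_high


def estimate_D(
    phy: Phylogeny,
    trait: BinaryTrait,
    n_perm: int = 10_000,
    n_brownian: int = 10_000,
    seed: int | None = None,
) -> DResult:
    """Estimate D with permutation and Brownian-threshold nulls.

    ``D = (d_obs - mean_d_brownian) / (mean_d_random - mean_d_brownian)``.
    The random null shuffles tip labels; the Brownian null simulates
    continuous values from the tree's Brownian covariance and thresholds
    them at the observed prevalence. One-sided permutation p-values are
    converted to two-sided as ``min(1, 2 * min(p_low, p_high))``.
    """
    pattern = trait.pattern_class(phy)
    if pattern != "variable":
        raise ValueError(
            "D cannot be estimated and tested for constant traits or for "
            f"traits where a single species differs (trait {trait.name!r} "
            f"is {pattern})"
        )
    rng = np.random.default_rng(seed)
    states = trait.vector(phy)
    n = phy.n_tips
    k = int(states.sum())

    d_obs = float(sister_difference_sum(phy, states))

    # random null: tip-label shuffles
    perms = rng.permuted(
        np.tile(states[:, None], (1, n_perm)), axis=0
    )
    d_rand = sister_difference_sum(phy, perms)

    # Brownian null: threshold simulated values at observed prevalence
    cov = brownian_tip_covariance(phy)
    # tiny jitter keeps the Cholesky stable for near-duplicate tips
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    sims = L @ rng.standard_normal((n, n_brownian))
    d_brown = sister_difference_sum(phy, threshold_at_prevalence(sims, k))

    mean_rand = float(d_rand.mean())
    mean_brown = float(d_brown.mean())
    denom = mean_rand - mean_brown
    if denom == 0:
        raise ValueError("degenerate null distributions (equal means)")
    D = (d_obs - mean_brown) / denom

    p0 = min(1.0, 2 * min(*_tail_p(d_brown, d_obs)))
    p1 = min(1.0, 2 * min(*_tail_p(d_rand, d_obs)))
    return DResult(
        trait=trait.name,
        d_obs=d_obs,
        mean_d_random=mean_rand,
        mean_d_brownian=mean_brown,
        D=float(D),
        p_d0=float(p0),
        p_d1=float(p1),
        n_perm=n_perm,
        n_brownian=n_brownian,
    )


def bh_fdr(pvalues, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
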