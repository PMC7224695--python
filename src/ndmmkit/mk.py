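"""Two-state Mk models: likelihood, fitting, model choice, stochastic maps.

The Mk model is a continuous-time Markov chain on {0, 1} with gain rate
``q01`` and loss rate ``q10`` per unit branch length. The "equal rates"
(ER) model constrains ``q01 = q10``; "all rates differ" (ARD) frees both.
The likelihood of tip states is computed by Felsenstein's pruning algorithm
with an equal (1/2, 1/2) root prior; the closed-form 2-state transition
matrix avoids any matrix exponential.

Stochastic character mapping samples complete character histories
conditional on the tip data: node states are drawn root-down from the
conditional likelihoods, then each branch history is simulated conditional
on its endpoint states (modified rejection sampling with a uniformization
fallback). Summaries over many maps give posterior node-state
probabilities and the expected number of state changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .trees import Phylogeny

__all__ = [
    "BinaryTrait",
    "MkModel",
    "StochasticMapSet",
    "transition_matrix",
    "mk_loglik",
    "fit_mk",
    "select_model_lrt",
    "marginal_ancestral_probs",
    "sample_stochastic_maps",
    "summarize_maps",
]

#: Sentinel for an impossible configuration (likelihood exactly zero).
LOG_ZERO = -np.inf

#: Rates are per unit branch length; with trees scaled to root depth ~1,
#: rates beyond ~100 are unresolvable saturation and the likelihood is
#: flat, so the optimizer is kept inside these bounds.
_RATE_BOUNDS = (1e-9, 1e2)


@dataclass(frozen=True)
class BinaryTrait:
    """Per-tip 0/1 states for a named trait."""

    name: str
    states: dict[str, int]

    def __post_init__(self) -> None:
        bad = {v for v in self.states.values() if v not in (0, 1)}
        if bad:
            raise ValueError(f"non-binary states: {bad}")

    def vector(self, phy: Phylogeny) -> np.ndarray:
        missing = set(phy.tip_labels) - set(self.states)
        if missing:
            raise ValueError(f"trait {self.name!r} missing tips {missing}")
        return np.array(
            [self.states[t] for t in phy.tip_labels], dtype=int
        )

    def pattern_class(self, phy: Phylogeny) -> str:
        """``constant``, ``singleton`` (one tip differs) or ``variable``."""
        v = self.vector(phy)
        k = int(v.sum())
        if k in (0, len(v)):
            return "constant"
        if k in (1, len(v) - 1):
            return "singleton"
        return "variable"


@dataclass
class MkModel:
    """A fitted (or fixed) 2-state Mk rate matrix."""

    model: str  # "ER" | "ARD"
    q01: float
    q10: float
    logL: float
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be >= 0")
        if self.model == "ER" and self.q01 != self.q10:
            raise ValueError("ER model requires q01 == q10")


def transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form 2-state transition probabilities P(t) = exp(Qt)."""
    s = q01 + q10
    if s == 0 or t == 0:
        return np.eye(2)
    e = np.exp(-s * t)
    return np.array(
        [
            [(q10 + q01 * e) / s, q01 * (1 - e) / s],
            [q10 * (1 - e) / s, (q01 + q10 * e) / s],
        ]
    )


def _tip_partials(phy: Phylogeny, states: np.ndarray) -> np.ndarray:
    part = np.zeros((phy.n_nodes, 2))
    part[np.arange(phy.n_tips), states] = 1.0
    return part


def _prune(
    phy: Phylogeny, states: np.ndarray, q01: float, q10: float
) -> tuple[np.ndarray, float]:
    """Up-pass partial likelihoods with log-scaling.

    Returns (partials, log-scale) where the true partial at node i is
    ``partials[i] * exp(scale contributions above)`` — only the total
    log-likelihood and the *relative* partials per node are used
    downstream.
    """
    part = _tip_partials(phy, states)
    logscale = 0.0
    for node in phy.postorder:
        acc = np.ones(2)
        for c in phy.children[node]:
            P = transition_matrix(q01, q10, phy.edge_length[c])
            acc = acc * (P @ part[c])
        m = acc.max()
        if m == 0.0:
            return part, LOG_ZERO
        part[node] = acc / m
        logscale += np.log(m)
    return part, logscale


def mk_loglik(
    phy: Phylogeny, trait: BinaryTrait, q01: float, q10: float
) -> float:
    """Pruning log-likelihood with an equal (1/2, 1/2) root prior.

    Returns ``-inf`` when the tip configuration has probability zero
    (e.g. both rates zero but the trait varies).
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be >= 0")
    states = trait.vector(phy)
    part, logscale = _prune(phy, states, q01, q10)
    if logscale == LOG_ZERO:
        return LOG_ZERO
    root_l = 0.5 * part[phy.root].sum()
    if root_l == 0.0:
        return LOG_ZERO
    return float(np.log(root_l) + logscale)


def fit_mk(
    phy: Phylogeny,
    trait: BinaryTrait,
    model: str = "ER",
    n_starts: int = 4,
) -> MkModel:
    """Maximum-likelihood Mk rates via bounded multi-start optimization.

    Optimization runs on log-rates with L-BFGS-B from several starting
    values spread around a parsimony-informed initial rate. Constant or
    singleton traits are fit anyway but flagged ``at_bound`` when the
    optimizer runs into the rate bounds.
    """
    if model not in ("ER", "ARD"):
        raise ValueError(f"unknown model {model!r}")
    states = trait.vector(phy)
    tree_len = float(phy.edge_length.sum())
    k = phy.fitch_score(states) if trait.pattern_class(phy) != "constant" else 0
    base = max(k, 0.5) / max(tree_len, 1e-9)
    lo, hi = np.log(_RATE_BOUNDS[0]), np.log(_RATE_BOUNDS[1])
    dim = 1 if model == "ER" else 2

    def negll(logq: np.ndarray) -> float:
        q = np.exp(logq)
        q01, q10 = (q[0], q[0]) if model == "ER" else (q[0], q[1])
        ll = mk_loglik(phy, trait, q01, q10)
        return 1e12 if ll == LOG_ZERO else -ll

    starts = [np.full(dim, np.log(base * f)) for f in (1.0, 0.2, 5.0)]
    rng = np.random.default_rng(abs(hash(trait.name)) % 2**31)
    while len(starts) < n_starts:
        starts.append(np.clip(np.log(base) + rng.normal(0, 2, dim), lo, hi))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negll,
            np.clip(x0, lo, hi),
            method="L-BFGS-B",
            bounds=[(lo, hi)] * dim,
        )
        if best is None or res.fun < best.fun:
            best = res
    q = np.exp(best.x)
    q01, q10 = (q[0], q[0]) if model == "ER" else (q[0], q[1])
    # flat likelihoods park the optimizer near (not on) a bound; flag
    # rates that are effectively zero or saturated on a depth-~1 tree
    at_bound = bool(np.any(q < 1e-6) or np.any(q > 0.5 * _RATE_BOUNDS[1]))
    return MkModel(model, float(q01), float(q10), -float(best.fun), at_bound)


def select_model_lrt(
    er: MkModel, ard: MkModel, alpha: float = 0.05, tol: float = 1e-6
) -> str:
    """Likelihood-ratio test of ER (null) against ARD (1 extra rate).

    Rejects ER when ``2 * (logL_ARD - logL_ER)`` exceeds the chi-square
    critical value with one degree of freedom.
    """
    delta = ard.logL - er.logL
    if delta < -tol:
        raise ValueError(
            f"ARD log-likelihood below ER ({ard.logL} < {er.logL}); "
            "optimizer failure"
        )
    lr = 2.0 * max(delta, 0.0)
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    return "ARD" if lr > crit else "ER"


def marginal_ancestral_probs(
    phy: Phylogeny, trait: BinaryTrait, q01: float, q10: float
) -> np.ndarray:
    """Analytic marginal P(state=1) at every node, equal root prior.

    Standard up-pass/down-pass marginals: the down-pass propagates the
    likelihood of everything outside each node's subtree; multiplying by
    the node's own partials and normalising gives the marginal posterior.
    """
    states = trait.vector(phy)
    part, logscale = _prune(phy, states, q01, q10)
    if logscale == LOG_ZERO:
        raise ValueError("zero-likelihood configuration")
    down = np.zeros((phy.n_nodes, 2))
    down[phy.root] = 0.5  # root prior
    for node in phy.postorder[::-1]:  # preorder over internal nodes
        for c in phy.children[node]:
            # sibling contributions at `node`, seen from child c
            other = down[node].copy()
            for sib in phy.children[node]:
                if sib == c:
                    continue
                P = transition_matrix(q01, q10, phy.edge_length[sib])
                other = other * (P @ part[sib])
            Pc = transition_matrix(q01, q10, phy.edge_length[c])
            down[c] = other @ Pc
            m = down[c].max()
            if m > 0:
                down[c] /= m
    post = part * down
    totals = post.sum(axis=1, keepdims=True)
    return (post / totals)[:, 1]


# ---------------------------------------------------------------------------
# Stochastic character mapping
# ---------------------------------------------------------------------------


@dataclass
class StochasticMapSet:
    """Sampled character histories conditional on tip data.

    ``node_states``: (n_sim, n_nodes) sampled states; ``change_counts``:
    state changes per map; ``histories``: per map and branch, the ordered
    (state, duration) segments from the parent end of the branch.
    """

    node_states: np.ndarray
    change_counts: np.ndarray
    histories: list[dict[int, list[tuple[int, float]]]]
    rates: np.ndarray  # (n_sim, 2) q01, q10 used per map

    @property
    def n_sim(self) -> int:
        return self.node_states.shape[0]

    def node_state_frequencies(self) -> np.ndarray:
        """(n_nodes, 2) relative frequency of states 0/1 across maps."""
        freq1 = self.node_states.mean(axis=0)
        return np.column_stack([1.0 - freq1, freq1])


def _sample_branch_path(
    a: int,
    b: int,
    t: float,
    q: np.ndarray,
    rng: np.random.Generator,
    max_rejects: int = 200,
) -> list[tuple[int, float]]:
    """Endpoint-conditioned 2-state CTMC path on a branch of length ``t``.

    ``q[i]`` is the rate of leaving state ``i``. Modified rejection
    sampling: when the endpoints differ, the first jump time is drawn from
    the exponential truncated to (0, t). Falls back to uniformization if
    rejection keeps failing (very unequal rates).
    """
    if t == 0:
        if a != b:
            raise ValueError("state change on a zero-length branch")
        return [(a, 0.0)]
    if a != b and q[a] == 0:
        raise ValueError("impossible endpoint pair: leaving rate is zero")

    def forward(start: int, first_forced: bool) -> tuple[int, list]:
        segs = []
        state, now = start, 0.0
        if first_forced:
            u = rng.random()
            w = -np.log(1 - u * (1 - np.exp(-q[state] * t))) / q[state]
            segs.append((state, w))
            state, now = 1 - state, w
        while True:
            rate = q[state]
            w = rng.exponential(1 / rate) if rate > 0 else np.inf
            if now + w >= t:
                segs.append((state, t - now))
                return state, segs
            segs.append((state, w))
            state, now = 1 - state, now + w

    for _ in range(max_rejects):
        end, segs = forward(a, first_forced=(a != b))
        if end == b:
            return segs
    return _uniformization_path(a, b, t, q, rng)


def _uniformization_path(
    a: int, b: int, t: float, q: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, float]]:
    mu = max(q.max(), 1e-12) * 1.05
    Q = np.array([[-q[0], q[0]], [q[1], -q[1]]])
    R = np.eye(2) + Q / mu
    p_ab = transition_matrix(q[0], q[1], t)[a, b]
    if p_ab <= 0:
        raise ValueError("impossible endpoint pair")
    # sample number of virtual jumps n | a, b, t
    weights = []
    Rn = np.eye(2)
    pois = np.exp(-mu * t)
    total, n = 0.0, 0
    probs = []
    while total < 0.999999 and n < 1000:
        w = pois * Rn[a, b] / p_ab
        probs.append(w)
        total += w
        n += 1
        Rn = Rn @ R
        pois *= mu * t / n
    probs = np.array(probs) / sum(probs)
    n_jumps = int(rng.choice(len(probs), p=probs))
    if n_jumps == 0:
        return [(a, t)]
    times = np.sort(rng.uniform(0, t, n_jumps))
    # sample the embedded chain states by forward filtering
    Rpow = [np.eye(2)]
    for _ in range(n_jumps):
        Rpow.append(Rpow[-1] @ R)
    chain = [a]
    for j in range(1, n_jumps + 1):
        pvec = np.array(
            [
                R[chain[-1], s] * Rpow[n_jumps - j][s, b]
                for s in (0, 1)
            ]
        )
        pvec = pvec / pvec.sum()
        chain.append(int(rng.choice(2, p=pvec)))
    # collapse virtual (self) jumps into segments
    segs: list[tuple[int, float]] = []
    bounds = [0.0, *times, t]
    for state, dur in zip(
        chain, np.diff(bounds)
    ):
        if segs and segs[-1][0] == state:
            segs[-1] = (state, segs[-1][1] + dur)
        else:
            segs.append((state, float(dur)))
    return segs


def _mcmc_rate_sample(
    phy: Phylogeny,
    trait: BinaryTrait,
    model: MkModel,
    n_sim: int,
    rng: np.random.Generator,
    burn_in: int = 1000,
    thin: int = 10,
    proposal_sd: float = 0.5,
) -> np.ndarray:
    """Metropolis sample of rates to propagate rate uncertainty into maps.

    Random-walk Metropolis on log-rates with a gamma(2, scale=q_ml) prior
    centred on the ML prefit; returns ``n_sim`` thinned draws of
    (q01, q10). Under ER the two rates move jointly.
    """
    dim = 1 if model.model == "ER" else 2
    ml = np.array([model.q01, model.q10][:dim])
    ml = np.maximum(ml, 1e-6)

    def logpost(logq: np.ndarray) -> float:
        q = np.exp(logq)
        q01, q10 = (q[0], q[0]) if dim == 1 else (q[0], q[1])
        ll = mk_loglik(phy, trait, q01, q10)
        if ll == LOG_ZERO:
            return -np.inf
        # gamma(2, scale=ml) prior on rates, log-scale Jacobian included
        prior = np.sum(2 * logq - q / ml)
        return ll + prior

    x = np.log(ml)
    lp = logpost(x)
    draws = np.empty((n_sim, 2))
    kept = 0
    total = burn_in + n_sim * thin
    for it in range(total):
        prop = x + rng.normal(0, proposal_sd, dim)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_sim:
            q = np.exp(x)
            draws[kept] = (q[0], q[0]) if dim == 1 else (q[0], q[1])
            kept += 1
    return draws


def sample_stochastic_maps(
    phy: Phylogeny,
    trait: BinaryTrait,
    model: MkModel,
    n_sim: int = 100,
    rate_uncertainty: bool = False,
    seed: Optional[int] = None,
    keep_histories: bool = True,
) -> StochasticMapSet:
    """Draw stochastic character maps conditional on the tip states.

    Each map samples node states root-down from the conditional
    likelihoods (equal root prior) and then an endpoint-conditioned CTMC
    path on every branch. With ``rate_uncertainty`` the rate matrix is
    redrawn for each map from a Metropolis posterior sample centred on the
    ML fit; otherwise the fitted rates are used throughout.
    """
    if trait.pattern_class(phy) == "constant":
        raise ValueError(
            "stochastic mapping is undefined for constant traits"
        )
    rng = np.random.default_rng(seed)
    states = trait.vector(phy)
    if rate_uncertainty:
        rates = _mcmc_rate_sample(phy, trait, model, n_sim, rng)
    else:
        rates = np.tile([model.q01, model.q10], (n_sim, 1))

    n_nodes = phy.n_nodes
    node_states = np.empty((n_sim, n_nodes), dtype=int)
    change_counts = np.empty(n_sim, dtype=int)
    histories: list[dict[int, list[tuple[int, float]]]] = []
    preorder = list(phy.postorder[::-1])
    for m in range(n_sim):
        q01, q10 = rates[m]
        part, logscale = _prune(phy, states, q01, q10)
        if logscale == LOG_ZERO:
            raise ValueError("zero-likelihood rates in stochastic mapping")
        ns = np.empty(n_nodes, dtype=int)
        ns[: phy.n_tips] = states
        root = phy.root
        p = 0.5 * part[root]
        p /= p.sum()
        ns[root] = rng.choice(2, p=p)
        for node in preorder:
            for c in phy.children[node]:
                if c < phy.n_tips:
                    continue
                P = transition_matrix(q01, q10, phy.edge_length[c])
                w = P[ns[node]] * part[c]
                w /= w.sum()
                ns[c] = rng.choice(2, p=w)
        # branch histories conditional on endpoint states
        qvec = np.array([q01, q10])
        n_changes = 0
        hist: dict[int, list[tuple[int, float]]] = {}
        for node in range(n_nodes):
            par = phy.parent[node]
            if par == -1:
                continue
            segs = _sample_branch_path(
                int(ns[par]), int(ns[node]), float(phy.edge_length[node]),
                qvec, rng,
            )
            n_changes += len(segs) - 1
            if keep_histories:
                hist[node] = segs
        node_states[m] = ns
        change_counts[m] = n_changes
        if keep_histories:
            histories.append(hist)
    return StochasticMapSet(node_states, change_counts, histories, rates)


def summarize_maps(
    maps: StochasticMapSet,
    phy: Phylogeny,
    clades: Optional[Sequence[str]] = None,
) -> dict:
    """Expected change count and per-clade MRCA presence probabilities."""
    if maps.n_sim < 1:
        raise ValueError("empty map set")
    freqs = maps.node_state_frequencies()
    out = {
        "expected_changes": float(maps.change_counts.mean()),
        "node_presence_prob": freqs[:, 1],
    }
    if clades is not None:
        mrcas = {}
        for name in clades:
            if name not in phy.clades:
                raise ValueError(f"unknown clade {name!r}")
            node = phy.mrca(phy.clades[name])
            mrcas[name] = float(freqs[node, 1])
        out["clade_mrca_presence"] = mrcas
    return out
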