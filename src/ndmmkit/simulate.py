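"""Synthetic inputs: trees, binary traits, profiles, abundances, spectra.

The generators reproduce the shape of the study this package is built
around: an ultrametric phylogeny of 32 species with root depth 1,
partitioned into four named ingroup clades (10 pacificus, 7 maupasi,
6 entomophagus, 5 triformis) plus a 4-species outgroup; roughly 46
compounds measured in three biological replicates per species; tandem-MS
spectra with planted precursors and class-diagnostic fragments perturbed
by Gaussian ppm error among uniform decoy peaks.

Binary traits evolve under the 2-state Mk model or under a
Brownian-threshold model (continuous Brownian values on the tree cut at
the rank matching a target prevalence); compositional profiles mix a
Brownian component with independent noise under a tunable signal
strength, then close via softmax so every composition is strictly
positive. All generators are driven by an explicit seed and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dstat import brownian_tip_covariance, threshold_at_prevalence
from .mk import BinaryTrait, transition_matrix
from .profiles import AbundanceTable, CompositionProfile
from .screen import Spectrum
from .structures import NDMMStructure
from .trees import Phylogeny

__all__ = [
    "SimConfig",
    "DEFAULT_CLADE_SIZES",
    "simulate_tree",
    "simulate_mk_trait",
    "simulate_threshold_trait",
    "simulate_profiles",
    "simulate_abundance_table",
    "simulate_spectra",
]

#: Clade structure of the emulated 32-species ingroup + outgroup sampling.
DEFAULT_CLADE_SIZES: dict[str, int] = {
    "pacificus": 10,
    "maupasi": 7,
    "entomophagus": 6,
    "triformis": 5,
    "outgroup": 4,
}


@dataclass(frozen=True)
class SimConfig:
    """Bundle of generator settings (YAML/JSON-friendly)."""

    n_tips: int = 32
    clade_sizes: dict = field(
        default_factory=lambda: dict(DEFAULT_CLADE_SIZES)
    )
    root_depth: float = 1.0
    q01: float = 1.0
    q10: float = 1.0
    prevalence: float = 0.5
    signal_strength: float = 1.0
    ppm_sd: float = 0.0
    n_decoys: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must lie in [0, 1]")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class _Node:
    __slots__ = ("height", "children", "label")

    def __init__(self, height: float = 0.0, label: str | None = None):
        self.height = height
        self.children: list[_Node] = []
        self.label = label


def _newick(node: _Node, parent_height: float | None = None) -> str:
    if node.children:
        body = "(" + ",".join(
            _newick(c, node.height) for c in node.children
        ) + ")"
    else:
        body = node.label
    if parent_height is None:
        return body + ";"
    return f"{body}:{node.height - parent_height:.10f}"


def _yule(labels: list[str], rng: np.random.Generator) -> _Node:
    """Pure-birth tree; tips at equal depth (heights later rescaled)."""
    n = len(labels)
    root = _Node(0.0)
    if n == 1:
        root.label = labels[0]
        root.height = 1.0
        return root
    a, b = _Node(), _Node()
    root.children = [a, b]
    active = [a, b]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / len(active))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        node.height = t
        c1, c2 = _Node(), _Node()
        node.children = [c1, c2]
        active.extend([c1, c2])
    present = t + rng.exponential(1.0 / n)
    order = rng.permutation(n)
    for node, lab in zip(active, (labels[i] for i in order)):
        node.height = present
        node.label = lab
    _rescale(root, present or 1.0)
    return root


def _rescale(node: _Node, total: float, offset: float = 0.0,
             span: float = 1.0) -> None:
    """Map heights [0, total] onto [offset, offset + span]."""
    node.height = offset + span * node.height / total
    for c in node.children:
        _rescale(c, total, offset, span)


def simulate_tree(
    n_tips: int = 32,
    clade_sizes: dict[str, int] | None = None,
    root_depth: float = 1.0,
    seed: int | None = None,
    clade_depth_fraction: float = 0.5,
) -> Phylogeny:
    """Simulate an ultrametric pure-birth tree with root depth ``root_depth``.

    With ``clade_sizes``, tips are partitioned into named monophyletic
    clades: each clade is an independent pure-birth subtree whose root sits
    at ``clade_depth_fraction * root_depth``, and the clade stems hang off
    a backbone ladder whose split heights are drawn above the clade roots.
    Identical seeds give identical Newick strings.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    if clade_sizes is None:
        labels = [f"sp{i + 1:02d}" for i in range(n_tips)]
        root = _yule(labels, rng)
        _rescale(root, 1.0, 0.0, root_depth)
        phy = Phylogeny.from_newick(_newick(root))
        return phy
    if sum(clade_sizes.values()) != n_tips:
        raise ValueError(
            f"clade sizes sum to {sum(clade_sizes.values())}, "
            f"expected n_tips={n_tips}"
        )
    names = list(clade_sizes)
    sub_h = clade_depth_fraction * root_depth
    subtrees: dict[str, _Node] = {}
    clades: dict[str, tuple[str, ...]] = {}
    for name in names:
        k = clade_sizes[name]
        labels = [f"{name}_{i + 1:02d}" for i in range(k)]
        clades[name] = tuple(labels)
        sub = _yule(labels, rng)
        _rescale(sub, 1.0, sub_h, root_depth - sub_h)
        subtrees[name] = sub
    # ladder backbone: the last-listed clade (outgroup) splits at the root
    inner = names[:-1]
    heights = np.sort(
        rng.uniform(0.05 * root_depth, 0.9 * sub_h, len(inner) - 1)
    )[::-1]
    node = subtrees[inner[0]]
    for name, h in zip(inner[1:], heights):
        join = _Node(float(h))
        join.children = [node, subtrees[name]]
        node = join
    root = _Node(0.0)
    root.children = [node, subtrees[names[-1]]]
    return Phylogeny.from_newick(_newick(root), clades)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def simulate_mk_trait(
    phy: Phylogeny,
    q01: float,
    q10: float,
    seed: int | None = None,
    name: str = "mk_trait",
) -> BinaryTrait:
    """Evolve a 0/1 trait under the Mk model, root drawn from (1/2, 1/2)."""
    if q01 < 0 or q10 < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    states = np.empty(phy.n_nodes, dtype=int)
    states[phy.root] = rng.integers(2)
    for node in phy.postorder[::-1]:
        for c in phy.children[node]:
            P = transition_matrix(q01, q10, phy.edge_length[c])
            states[c] = rng.random() < P[states[node], 1]
    return BinaryTrait(
        name, dict(zip(phy.tip_labels, states[: phy.n_tips].tolist()))
    )


def simulate_threshold_trait(
    phy: Phylogeny,
    prevalence: float,
    seed: int | None = None,
    name: str = "threshold_trait",
) -> BinaryTrait:
    """Brownian values on the tree, cut at the rank matching ``prevalence``.

    Exactly ``round(prevalence * n_tips)`` tips receive state 1; the
    result is the clumped, heritable trait pattern expected when a
    continuous liability evolves by Brownian motion.
    """
    n = phy.n_tips
    k = int(round(prevalence * n))
    if k <= 0 or k >= n:
        raise ValueError(
            f"prevalence {prevalence} yields a constant trait on {n} tips"
        )
    rng = np.random.default_rng(seed)
    values = np.empty(phy.n_nodes)
    values[phy.root] = 0.0
    for node in phy.postorder[::-1]:
        for c in phy.children[node]:
            values[c] = values[node] + rng.normal(
                0.0, np.sqrt(phy.edge_length[c])
            )
    tips = values[:n][:, None]
    states = threshold_at_prevalence(tips, k)[:, 0]
    return BinaryTrait(name, dict(zip(phy.tip_labels, states.tolist())))


# ---------------------------------------------------------------------------
# Profiles and abundance tables
# ---------------------------------------------------------------------------


def simulate_profiles(
    phy: Phylogeny,
    signal_strength: float,
    n_compounds: int = 46,
    seed: int | None = None,
    contrast: float = 3.0,
) -> CompositionProfile:
    """Closed compositional profiles with tunable phylogenetic signal.

    Per compound, latent values are
    ``signal * Brownian-on-tree + (1 - signal) * iid noise``; a softmax
    over compounds (scaled by ``contrast``) closes each species row to
    100% while keeping all entries strictly positive.
    """
    if not 0 <= signal_strength <= 1:
        raise ValueError("signal_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = phy.n_tips
    cov = brownian_tip_covariance(phy)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    brown = L @ rng.standard_normal((n, n_compounds))
    noise = rng.standard_normal((n, n_compounds))
    latent = signal_strength * brown + (1 - signal_strength) * noise
    z = contrast * latent
    z -= z.max(axis=1, keepdims=True)
    w = np.exp(z)
    pct = 100.0 * w / w.sum(axis=1, keepdims=True)
    values = pd.DataFrame(
        pct,
        index=list(phy.tip_labels),
        columns=[f"cmp{i + 1:02d}" for i in range(n_compounds)],
    )
    return CompositionProfile(values, "closed_all")


def simulate_abundance_table(
    phy: Phylogeny,
    compound_classes: dict[str, str],
    n_replicates: int = 3,
    q: float = 1.0,
    seed: int | None = None,
    mean_log10_area: float = 4.0,
    replicate_cv: float = 0.3,
    trace_fraction: float = 0.05,
) -> AbundanceTable:
    """Replicate peak-area table with Mk-evolved presence patterns.

    Each compound's presence/absence evolves on the tree under an
    equal-rates Mk model; present species get log-normal peak areas
    centred at ``10 ** mean_log10_area`` ion counts with replicate-level
    noise, and a small fraction of present species are down-scaled to
    trace intensities below the 1.0e3 quantifiability threshold.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for j, (compound, _cls) in enumerate(sorted(compound_classes.items())):
        trait = simulate_mk_trait(
            phy, q, q, seed=int(rng.integers(2**31)), name=compound
        )
        for sp in phy.tip_labels:
            if not trait.states[sp]:
                continue
            level = 10.0 ** rng.normal(mean_log10_area, 0.5)
            if rng.random() < trace_fraction:
                level = rng.uniform(50.0, 900.0)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "species": sp,
                        "compound": compound,
                        "replicate": rep,
                        "area": level
                        * rng.lognormal(0.0, replicate_cv),
                    }
                )
        # every species keeps a replicate record even if compound absent
    # guarantee all species appear (zero-area anchor rows for replicates)
    for sp in phy.tip_labels:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "species": sp,
                    "compound": sorted(compound_classes)[0],
                    "replicate": rep,
                    "area": 0.0,
                }
            )
    data = pd.DataFrame(rows)
    return AbundanceTable(data, dict(compound_classes))


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

_CLASS_ADDUCT = {
    "simple": "M+Na",
    "DASC": "M+Na",
    "UBAS": "M+H",
    "UPAS": "M-H",
    "registry": "M-H",
}


def simulate_spectra(
    compounds: list[NDMMStructure],
    ppm_sd: float = 0.0,
    n_decoys: int = 0,
    seed: int | None = None,
    precursor_intensity: float = 1.0e4,
    avoid_mz: list[float] | None = None,
    decoy_margin_ppm: float = 50.0,
) -> list[Spectrum]:
    """One spectrum per planted compound, with decoy peaks.

    The precursor sits at the theoretical adduct m/z perturbed by
    Gaussian ppm error; modular compounds also carry their diagnostic
    fragment peak. Decoy peaks are uniform on m/z 50-1300 (the emulated
    acquisition window) but are resampled until at least
    ``decoy_margin_ppm`` away from every m/z in ``avoid_mz`` (default:
    all planted precursor and fragment ions), so specificity failures
    cannot arise from the generator itself.
    """
    from .formula import ion_mz
    from .structures import diagnostic_fragments

    rng = np.random.default_rng(seed)
    planted: list[tuple[NDMMStructure, str, float, list[float]]] = []
    for s in compounds:
        adduct = _CLASS_ADDUCT[s.ndmm_class]
        mz = ion_mz(s.formula, adduct)
        frags = []
        if s.ndmm_class in ("DASC", "UBAS", "UPAS"):
            for _, ion in diagnostic_fragments(s):
                pol = "positive" if adduct != "M-H" else "negative"
                if ion.polarity == pol:
                    frags.append(ion.theoretical_mz)
        planted.append((s, adduct, mz, frags))
    if avoid_mz is None:
        avoid_mz = [mz for _, _, mz, fr in planted for mz in (mz, *fr)]
    avoid = np.array(sorted(avoid_mz)) if avoid_mz else np.array([])

    def decoy() -> float:
        while True:
            x = rng.uniform(50.0, 1300.0)
            if avoid.size == 0:
                return x
            if np.min(np.abs(avoid - x) / avoid) * 1e6 > decoy_margin_ppm:
                return x

    spectra = []
    for i, (s, adduct, mz, frags) in enumerate(planted):
        polarity = "negative" if adduct == "M-H" else "positive"
        obs_mz = mz * (1 + rng.normal(0, ppm_sd) * 1e-6)
        peaks = [
            (
                f * (1 + rng.normal(0, ppm_sd) * 1e-6),
                precursor_intensity * rng.uniform(0.1, 0.5),
            )
            for f in frags
        ]
        peaks += [
            (decoy(), 10.0 ** rng.uniform(2, 4)) for _ in range(n_decoys)
        ]
        spectra.append(
            Spectrum(
                id=f"scan{i + 1:04d}_{s.name}",
                precursor_mz=obs_mz,
                polarity=polarity,
                peaks=peaks,
                precursor_intensity=precursor_intensity,
            )
        )
    return spectra
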