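"""Combinatorial candidate library and targeted diagnostic-ion screening.

The screen enumerates every modular metabolite expressible from a set of
building blocks (side-chain lengths, saturation, attachment, head groups,
dimerisation), attaches theoretical adduct m/z values, and matches tandem-MS
spectra by precursor mass within a ppm tolerance. For modular classes the
class-diagnostic fragment ion must additionally be present within a (wider)
fragment tolerance. Detections at precursor intensity at or above
1.0e3 ion counts are called quantifiable; weaker detections are trace.

Mass-identical candidates (ascarylose vs paratose sugars, 2'- vs 4'-linked
dimers) are reported as one isomer set: high-resolution MS cannot separate
them, and resolving them requires NMR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .formula import MolecularFormula, ion_mz, ppm_error
from .structures import (
    IonSpec,
    NDMMStructure,
    assemble_ndmm,
    diagnostic_fragments,
)

__all__ = [
    "Spectrum",
    "ScreenConfig",
    "LibraryConfig",
    "Candidate",
    "MatchResult",
    "build_library",
    "match_spectrum",
    "targeted_fragment_screen",
    "classify_abundance",
]

POSITIVE_ADDUCTS = ("M+H", "M+Na")
NEGATIVE_ADDUCTS = ("M-H",)


@dataclass
class Spectrum:
    """A tandem-MS spectrum: precursor and fragment peak list."""

    id: str
    precursor_mz: float
    polarity: str  # "positive" | "negative"
    peaks: Sequence[tuple[float, float]] = field(default_factory=list)
    precursor_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"bad polarity {self.polarity!r}")
        pk = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i < 0 for _, i in pk):
            raise ValueError("negative peak intensity")
        self.peaks = pk
        self._mz = np.array([m for m, _ in pk], dtype=float)

    def has_peak_within_ppm(self, mz: float, tol_ppm: float) -> bool:
        if self._mz.size == 0:
            return False
        lo = mz * (1 - tol_ppm * 1e-6)
        hi = mz * (1 + tol_ppm * 1e-6)
        i = np.searchsorted(self._mz, lo)
        return i < self._mz.size and self._mz[i] <= hi


@dataclass(frozen=True)
class ScreenConfig:
    """Matching tolerances and the quantifiability threshold."""

    precursor_tol_ppm: float = 5.0
    fragment_tol_ppm: float = 10.0
    positive_adducts: tuple[str, ...] = POSITIVE_ADDUCTS
    negative_adducts: tuple[str, ...] = NEGATIVE_ADDUCTS
    intensity_threshold: float = 1.0e3

    def __post_init__(self) -> None:
        if self.precursor_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if self.intensity_threshold < 0:
            raise ValueError("intensity threshold must be >= 0")

    def adducts_for(self, polarity: str) -> tuple[str, ...]:
        return (
            self.positive_adducts
            if polarity == "positive"
            else self.negative_adducts
        )


@dataclass(frozen=True)
class LibraryConfig:
    """Building blocks for exhaustive candidate enumeration."""

    chain_lengths: tuple[int, ...]
    unsaturated_lengths: tuple[int, ...] = ()
    omega_lengths: tuple[int, ...] = ()
    heads: tuple[str, ...] = ()
    dimers: bool = False
    dimer_linkages: tuple[str, ...] = ("2'", "4'")
    heads_on_dimers: bool = False


@dataclass(frozen=True)
class Candidate:
    """A library entry: structure, neutral formula and adduct ions."""

    structure: NDMMStructure
    name: str
    ndmm_class: str
    neutral: MolecularFormula
    ions: tuple[tuple[str, float], ...]  # (adduct, theoretical m/z)
    fragments: tuple[tuple[MolecularFormula, IonSpec], ...] = ()


@dataclass
class MatchResult:
    """Outcome of matching one spectrum against one isomer set."""

    spectrum_id: str
    isomers: tuple[str, ...]
    ndmm_class: str
    adduct: str
    theoretical_mz: float
    ppm: float
    fragments_confirmed: Optional[bool]
    call: str  # quantifiable | trace | absent


def _candidate(s: NDMMStructure, adducts: Iterable[str]) -> Candidate:
    neutral = s.formula
    frags: tuple = ()
    if s.ndmm_class in ("DASC", "UBAS", "UPAS"):
        frags = tuple(diagnostic_fragments(s))
    return Candidate(
        structure=s,
        name=s.name,
        ndmm_class=s.ndmm_class,
        neutral=neutral,
        ions=tuple((a, ion_mz(neutral, a)) for a in adducts),
        fragments=frags,
    )


def build_library(
    blocks: LibraryConfig,
    registry: Sequence[NDMMStructure] = (),
    adducts: Sequence[str] = POSITIVE_ADDUCTS + NEGATIVE_ADDUCTS,
) -> list[Candidate]:
    """Exhaustively enumerate candidate structures from building blocks.

    Simple units come from all (length, saturation, attachment)
    combinations; heads attach at 4' to single units (and, optionally, to
    2'-linked dimers); dimers are ordered (first, second) pairs of simple
    units over the configured linkages. Registry compounds are appended
    as-is. The result is duplicate-free.
    """
    if not blocks.chain_lengths:
        raise ValueError("empty chain-length set")
    simples: list[NDMMStructure] = []
    for n in sorted(set(blocks.chain_lengths)):
        variants = [(False, "omega_minus_1")]
        if n in blocks.unsaturated_lengths:
            variants.append((True, "omega_minus_1"))
        if n in blocks.omega_lengths:
            variants.append((False, "omega"))
        for unsat, attach in variants:
            simples.append(
                assemble_ndmm(n, unsaturated=unsat, attachment=attach)
            )

    out: list[NDMMStructure] = list(simples)
    for head in blocks.heads:
        out.extend(
            assemble_ndmm(
                u.side_chain.n_carbons,
                unsaturated=u.side_chain.unsaturated,
                attachment=u.side_chain.attachment,
                head=head,
            )
            for u in simples
        )
    if blocks.dimers:
        dimers = [
            assemble_ndmm(
                second.side_chain.n_carbons,
                unsaturated=second.side_chain.unsaturated,
                attachment=second.side_chain.attachment,
                first_unit=first,
                linkage=link,
            )
            for first in simples
            for second in simples
            for link in blocks.dimer_linkages
        ]
        out.extend(dimers)
        if blocks.heads_on_dimers:
            out.extend(
                assemble_ndmm(
                    d.side_chain.n_carbons,
                    unsaturated=d.side_chain.unsaturated,
                    attachment=d.side_chain.attachment,
                    first_unit=d.first_unit,
                    linkage=d.linkage,
                    head=head,
                )
                for d in dimers
                if d.linkage == "2'"  # head occupies the 4'-position
                for head in blocks.heads
            )

    seen: set[str] = set()
    cands: list[Candidate] = []
    for s in out:
        if s.name in seen:
            continue
        seen.add(s.name)
        cands.append(_candidate(s, adducts))
    for s in registry:
        if s.name in seen:
            continue
        seen.add(s.name)
        cands.append(_candidate(s, adducts))
    return cands


def _isomer_groups(lib: Sequence[Candidate]) -> list[list[Candidate]]:
    groups: dict[MolecularFormula, list[Candidate]] = {}
    for c in lib:
        groups.setdefault(c.neutral, []).append(c)
    return list(groups.values())


def classify_abundance(intensity: float, cfg: ScreenConfig) -> str:
    """Quantifiable at/above the ion-intensity threshold, trace below,
    absent at zero."""
    if intensity < 0:
        raise ValueError("negative intensity")
    if intensity == 0:
        return "absent"
    return "quantifiable" if intensity >= cfg.intensity_threshold else "trace"


def match_spectrum(
    s: Spectrum, lib: Sequence[Candidate], cfg: ScreenConfig
) -> list[MatchResult]:
    """Match a spectrum's precursor against the candidate library.

    Each mass-identical isomer set yields at most one result per adduct;
    for modular classes the diagnostic fragment is looked up among the
    spectrum's peaks within the fragment tolerance (``None`` when the
    diagnostic ion's polarity differs from the spectrum's). Results are
    sorted by absolute ppm deviation, then by first isomer name.
    """
    adducts = cfg.adducts_for(s.polarity)
    if not adducts:
        raise ValueError(f"no adducts configured for {s.polarity} mode")
    results: list[MatchResult] = []
    for group in _isomer_groups(lib):
        rep = group[0]
        for adduct, theo in rep.ions:
            if adduct not in adducts:
                continue
            err = ppm_error(s.precursor_mz, theo)
            if abs(err) > cfg.precursor_tol_ppm:
                continue
            confirmed: Optional[bool] = None
            frag_rules = [
                ion
                for c in group
                for _, ion in c.fragments
                if ion.polarity == s.polarity
            ]
            if frag_rules:
                confirmed = any(
                    s.has_peak_within_ppm(
                        ion.theoretical_mz, cfg.fragment_tol_ppm
                    )
                    for ion in frag_rules
                )
            results.append(
                MatchResult(
                    spectrum_id=s.id,
                    isomers=tuple(sorted(c.name for c in group)),
                    ndmm_class=rep.ndmm_class,
                    adduct=adduct,
                    theoretical_mz=theo,
                    ppm=err,
                    fragments_confirmed=confirmed,
                    call=classify_abundance(s.precursor_intensity, cfg),
                )
            )
    results.sort(key=lambda r: (abs(r.ppm), r.isomers[0]))
    return results


def targeted_fragment_screen(
    spectra: Iterable[Spectrum], diagnostic: IonSpec, cfg: ScreenConfig
) -> list[str]:
    """Ids of spectra containing a peak at the diagnostic ion m/z.

    This is the targeted MS/MS screen used to sweep whole runs for the
    head-group reporter ions (the UBAS cation and the UPAS anion).
    """
    return [
        s.id
        for s in spectra
        if s.polarity == diagnostic.polarity
        and s.has_peak_within_ppm(
            diagnostic.theoretical_mz, cfg.fragment_tol_ppm
        )
    ]
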