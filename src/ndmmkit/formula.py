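"""Molecular-formula arithmetic and monoisotopic ion m/z computation.

High-resolution annotation of modular metabolites rests on exact-mass
bookkeeping: neutral molecular formulas are assembled by element-wise
addition/subtraction (one H2O lost per condensation bond), singly charged
adduct ions are derived from the neutral formula, and agreement between
observed and theoretical m/z is expressed in parts per million (ppm).

Monoisotopic atomic masses are hard-coded to seven decimals and ion masses
carry an explicit electron-mass correction; the sub-ppm accuracy of printed
Q-TOF mass deviations is only reproducible with the electron term included.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "MolecularFormula",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "parse_formula",
    "ion_mz",
    "ppm_error",
    "ADDUCTS",
]

#: Monoisotopic masses (Da), 7-decimal precision.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0000000,
    "H": 1.0078250,
    "N": 14.0030740,
    "O": 15.9949146,
    "Na": 22.9897693,
    "P": 30.9737615,
    "S": 31.9720707,
}

ELECTRON_MASS = 0.0005486
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

#: Hill convention: carbon, hydrogen, then remaining elements alphabetically.
_HILL_HEAD = ("C", "H")

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition with an integer charge.

    Counts are non-negative; addition and subtraction are element-wise and
    subtraction raises ``ValueError`` if any count would go negative.
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for el, n in self.element_counts.items():
            if el not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise ValueError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = int(n)
        object.__setattr__(self, "element_counts", clean)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            counts[el] = counts.get(el, 0) + n
        return MolecularFormula(counts, self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self.element_counts)
        for el, n in other.element_counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count "
                    f"({self} - {other})"
                )
            counts[el] = new
        return MolecularFormula(counts, self.charge - other.charge)

    def __mul__(self, k: int) -> "MolecularFormula":
        if not isinstance(k, int) or k < 0:
            raise ValueError("formula multiplier must be a non-negative int")
        return MolecularFormula(
            {el: n * k for el, n in self.element_counts.items()},
            self.charge * k,
        )

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return (
            dict(self.element_counts) == dict(other.element_counts)
            and self.charge == other.charge
        )

    def __hash__(self) -> int:
        return hash((tuple(sorted(self.element_counts.items())), self.charge))

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.element_counts.items()))

    # -- rendering --------------------------------------------------------
    def render(self) -> str:
        """Canonical Hill-order string, e.g. ``C17H28NaO8+``."""
        parts = []
        rest = sorted(set(self.element_counts) - set(_HILL_HEAD))
        for el in (*_HILL_HEAD, *rest):
            n = self.element_counts.get(el, 0)
            if n == 0:
                continue
            parts.append(el if n == 1 else f"{el}{n}")
        body = "".join(parts)
        if self.charge == 0:
            return body
        sign = "+" if self.charge > 0 else "-"
        return body + sign * abs(self.charge)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @property
    def monoisotopic_mass(self) -> float:
        """Monoisotopic mass in Da (sum of atoms; charge carries the
        electron correction: mass decreases by one electron per positive
        charge)."""
        m = sum(
            MONOISOTOPIC_MASS[el] * n for el, n in self.element_counts.items()
        )
        return m - self.charge * ELECTRON_MASS


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-order-ish formula string with optional trailing charge.

    Examples: ``"C17H28NaO8+"``, ``"H2O"``, ``"C4H7N2O3-"``.
    """
    s = text.strip()
    if not s:
        raise ValueError("empty formula string")
    charge = 0
    m = re.search(r"([+]+|[-−]+)$", s)
    if m:
        mag = len(m.group(1))
        charge = mag if m.group(1)[0] == "+" else -mag
        s = s[: m.start()]
    counts: dict[str, int] = {}
    pos = 0
    for tok in _TOKEN_RE.finditer(s):
        if tok.start() != pos:
            raise ValueError(f"malformed formula near {s[pos:]!r} in {text!r}")
        el, digits = tok.groups()
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = tok.end()
    if pos != len(s):
        raise ValueError(f"malformed formula near {s[pos:]!r} in {text!r}")
    if not counts:
        raise ValueError(f"no elements parsed from {text!r}")
    return MolecularFormula(counts, charge)


#: Supported singly charged adducts: (element added, charge).
ADDUCTS: dict[str, tuple[str | None, int]] = {
    "M+H": ("H", +1),
    "M+Na": ("Na", +1),
    "M-H": ("H", -1),
}

_ADDUCT_ALIASES = {"M−H": "M-H", "[M+H]+": "M+H", "[M+Na]+": "M+Na",
                   "[M-H]-": "M-H"}


def adduct_polarity(adduct: str) -> str:
    """``"positive"`` or ``"negative"`` for a supported adduct."""
    adduct = _ADDUCT_ALIASES.get(adduct, adduct)
    if adduct not in ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}")
    return "positive" if ADDUCTS[adduct][1] > 0 else "negative"


def ion_mz(neutral: MolecularFormula, adduct: str) -> float:
    """Theoretical monoisotopic m/z of a singly charged adduct ion.

    The input must be a neutral formula. Cation masses subtract one
    electron mass; anion masses add it. ``ion_mz`` of an empty formula with
    ``M+H`` returns the bare proton mass.
    """
    adduct = _ADDUCT_ALIASES.get(adduct, adduct)
    if adduct not in ADDUCTS:
        raise ValueError(f"unsupported adduct {adduct!r}")
    if neutral.charge != 0:
        raise ValueError("ion_mz expects a neutral formula")
    element, charge = ADDUCTS[adduct]
    mass = neutral.monoisotopic_mass
    if charge > 0:
        mass += MONOISOTOPIC_MASS[element] - ELECTRON_MASS
    else:
        if neutral.element_counts.get(element, 0) < 1:
            raise ValueError(f"cannot deprotonate {neutral}: no {element}")
        mass -= MONOISOTOPIC_MASS[element] - ELECTRON_MASS
    if mass <= 0:
        raise ValueError("non-positive ion mass")
    return mass


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass deviation in ppm: ``1e6 * (obs - theo) / theo``.

    Reports conventionally quote the absolute value rounded to one decimal.
    """
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed - theoretical) / theoretical
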