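"""Modular-metabolite structures, assembly, fragments and nomenclature.

Nematode-derived modular metabolites (NDMMs) are built from a small set of
components: a 3,6-dideoxy sugar (ascarylose or its isomer paratose,
both C6H12O4), a fatty-acid-derived side chain attached glycosidically at
the (omega-1) or omega carbon, an optional ureido head group esterified at
the sugar 4'-position (ureidoisobutyric acid, UB, C5H10N2O3; or
ureidopropionic acid, UP, C4H8N2O3), and optionally a second ascaroside
unit esterified at the 2'- or 4'-position (a dimeric ascaroside, DASC).

Every condensation bond (glycoside or ester) removes one H2O, so the
neutral formula of any assembled structure is the element-wise sum of its
components minus one water per bond. Structures that differ only in the
sugar isomer or in the 2'- vs 4'-linkage are mass-identical; downstream
annotation therefore reports isomer sets rather than inventing a unique
assignment.

Structure-based names follow the grammar
``(head group-)asc-(omega)(Delta)C#`` with a parenthesised first unit for
dimers, e.g. ``4'-UB-2'-(asc-C5)-asc-C4``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Optional

from .formula import MolecularFormula, adduct_polarity, ion_mz, parse_formula

__all__ = [
    "SideChain",
    "NDMMStructure",
    "IonSpec",
    "ASCARYLOSE",
    "WATER",
    "HEAD_GROUPS",
    "assemble_ndmm",
    "diagnostic_fragments",
    "charged_formula",
    "parse_name",
    "render_name",
    "load_registry",
]

ASCARYLOSE = parse_formula("C6H12O4")
#: Paratose is a mass-identical isomer of ascarylose.
PARATOSE = ASCARYLOSE
WATER = parse_formula("H2O")
HEAD_GROUPS = {
    "UB": parse_formula("C5H10N2O3"),  # ureidoisobutyric acid
    "UP": parse_formula("C4H8N2O3"),  # ureidopropionic acid
}

MIN_CHAIN, MAX_CHAIN = 3, 11

Sugar = Literal["ascarylose", "paratose"]
Attachment = Literal["omega_minus_1", "omega"]
Linkage = Literal["2'", "4'", "unresolved"]
NDMMClass = Literal["simple", "DASC", "UBAS", "UPAS", "registry"]


@dataclass(frozen=True)
class SideChain:
    """Fatty-acid side chain of an ascaroside.

    The free hydroxy-acid precursor has formula CnH2nO3 when saturated and
    CnH(2n-2)O3 with one C=C double bond (the "Delta" chains).
    """

    n_carbons: int
    unsaturated: bool = False
    attachment: Attachment = "omega_minus_1"

    def __post_init__(self) -> None:
        if not MIN_CHAIN <= self.n_carbons <= MAX_CHAIN:
            raise ValueError(
                f"side-chain length {self.n_carbons} outside supported "
                f"range {MIN_CHAIN}-{MAX_CHAIN}"
            )
        if self.attachment not in ("omega_minus_1", "omega"):
            raise ValueError(f"bad attachment {self.attachment!r}")

    @property
    def formula(self) -> MolecularFormula:
        n = self.n_carbons
        h = 2 * n - 2 if self.unsaturated else 2 * n
        return MolecularFormula({"C": n, "H": h, "O": 3})


@dataclass(frozen=True)
class IonSpec:
    """A singly charged adduct ion of a neutral formula."""

    adduct: str
    polarity: str
    theoretical_mz: float

    @classmethod
    def for_neutral(cls, neutral: MolecularFormula, adduct: str) -> "IonSpec":
        return cls(adduct, adduct_polarity(adduct), ion_mz(neutral, adduct))


@dataclass(frozen=True)
class NDMMStructure:
    """A modular metabolite: sugar + side chain + optional head/dimer unit.

    ``first_unit`` holds the 2'- or 4'-attached ascaroside of a dimer (the
    unit written in parentheses in structure-based names). Registry
    compounds (highly modular PASC/NPAR chemicals whose side-chain
    chemistry is catalogued rather than assembled) carry a user-supplied
    formula and a registry id.
    """

    sugar: Sugar = "ascarylose"
    side_chain: Optional[SideChain] = None
    head: Optional[Literal["UB", "UP"]] = None
    head_position: str = "4'"
    first_unit: Optional["NDMMStructure"] = None
    linkage: Optional[Linkage] = None
    registry_id: Optional[str] = None
    registry_formula: Optional[MolecularFormula] = None

    def __post_init__(self) -> None:
        if self.registry_formula is not None:
            return
        if self.side_chain is None:
            raise ValueError("non-registry structure requires a side chain")
        if self.head is not None:
            if self.head not in HEAD_GROUPS:
                raise ValueError(f"unknown head group {self.head!r}")
            if self.head_position != "4'":
                raise ValueError(
                    f"head group only supported at 4' "
                    f"(got {self.head_position!r})"
                )
        if self.first_unit is not None:
            if self.linkage not in ("2'", "4'", "unresolved"):
                raise ValueError("dimer requires a linkage (2', 4' or "
                                 "unresolved)")
            if self.first_unit.ndmm_class != "simple":
                raise ValueError("first unit of a dimer must be a simple "
                                 "ascaroside")
        elif self.linkage is not None:
            raise ValueError("linkage given without a first unit")

    @property
    def ndmm_class(self) -> NDMMClass:
        if self.registry_formula is not None:
            return "registry"
        if self.head == "UB":
            return "UBAS"
        if self.head == "UP":
            return "UPAS"
        if self.first_unit is not None:
            return "DASC"
        return "simple"

    @property
    def n_condensation_bonds(self) -> int:
        if self.registry_formula is not None:
            return 0
        n = 1  # sugar-side-chain glycoside
        if self.head is not None:
            n += 1
        if self.first_unit is not None:
            n += 1
        return n

    @property
    def formula(self) -> MolecularFormula:
        """Neutral formula: sum of components minus one H2O per bond."""
        if self.registry_formula is not None:
            return self.registry_formula
        f = ASCARYLOSE + self.side_chain.formula - WATER
        if self.head is not None:
            f = f + HEAD_GROUPS[self.head] - WATER
        if self.first_unit is not None:
            f = f + self.first_unit.formula - WATER
        return f

    @property
    def name(self) -> str:
        if self.registry_id is not None and self.registry_formula is not None:
            return self.registry_id
        return render_name(self)

    def with_unresolved_linkage(self) -> "NDMMStructure":
        if self.first_unit is None:
            return self
        return replace(self, linkage="unresolved")


def assemble_ndmm(
    chain_length: int | None = None,
    *,
    unsaturated: bool = False,
    attachment: Attachment = "omega_minus_1",
    sugar: Sugar = "ascarylose",
    head: Optional[str] = None,
    head_position: str = "4'",
    first_unit: Optional[NDMMStructure] = None,
    linkage: Optional[Linkage] = None,
) -> NDMMStructure:
    """Build an :class:`NDMMStructure` from building blocks.

    The derived neutral formula is the element-wise component sum minus one
    water per condensation bond; the class label follows from the
    components (UB head -> UBAS, UP head -> UPAS, dimer without head ->
    DASC, otherwise simple).
    """
    return NDMMStructure(
        sugar=sugar,
        side_chain=SideChain(chain_length, unsaturated, attachment),
        head=head,
        head_position=head_position,
        first_unit=first_unit,
        linkage=linkage,
    )


#: The UBAS diagnostic cation contains the head group plus the sugar
#: (UB + ascarylose - 2 H2O = C11H18N2O5, observed as [M+H]+).
UBAS_DIAGNOSTIC_NEUTRAL = HEAD_GROUPS["UB"] + ASCARYLOSE - 2 * WATER
#: The UPAS diagnostic anion is deprotonated ureidopropionic acid.
UPAS_DIAGNOSTIC_NEUTRAL = HEAD_GROUPS["UP"]


def diagnostic_fragments(
    s: NDMMStructure,
) -> list[tuple[MolecularFormula, IonSpec]]:
    """Class-diagnostic MS/MS fragment ions of a modular structure.

    DASC compounds lose the terminal side chain, leaving the first
    ascaroside plus the second sugar (first unit + ascarylose - 2 H2O),
    observed as [M+Na]+. UBAS compounds yield the head-plus-sugar cation
    C11H19N2O5+ ([M+H]+ of C11H18N2O5); UPAS compounds yield the
    ureidopropionate anion C4H7N2O3- ([M-H]- of ureidopropionic acid).
    """
    cls = s.ndmm_class
    if cls == "DASC":
        frag = s.first_unit.formula + ASCARYLOSE - 2 * WATER
        return [(frag, IonSpec.for_neutral(frag, "M+Na"))]
    if cls == "UBAS":
        frag = UBAS_DIAGNOSTIC_NEUTRAL
        return [(frag, IonSpec.for_neutral(frag, "M+H"))]
    if cls == "UPAS":
        frag = UPAS_DIAGNOSTIC_NEUTRAL
        return [(frag, IonSpec.for_neutral(frag, "M-H"))]
    raise ValueError(f"no diagnostic-fragment rule for class {cls!r}")


def charged_formula(neutral: MolecularFormula, adduct: str) -> MolecularFormula:
    """The ion's own formula, e.g. C17H28O8 + M+Na -> C17H28NaO8+."""
    pol = adduct_polarity(adduct)
    if pol == "positive":
        el = "Na" if "Na" in adduct else "H"
        return neutral + MolecularFormula({el: 1}, charge=+1)
    depro = neutral - MolecularFormula({"H": 1})
    return MolecularFormula(depro.element_counts, charge=-1)


# ---------------------------------------------------------------------------
# Nomenclature grammar
# ---------------------------------------------------------------------------

_SIMPLE_RE = re.compile(r"^asc-(ω?)(Δ?)C(\d+)$")
_NAME_RE = re.compile(
    r"^(?:4'-(UB|UP)-)?"          # optional head group at 4'
    r"(?:(2'|4'|2'/4')-\((asc-[^)]+)\)-)?"  # optional linked first unit
    r"(asc-.+)$"                  # the (second) ascaroside unit
)


def _parse_simple(text: str) -> NDMMStructure:
    m = _SIMPLE_RE.match(text)
    if not m:
        raise ValueError(f"malformed ascaroside unit {text!r}")
    omega, delta, digits = m.groups()
    return assemble_ndmm(
        int(digits),
        unsaturated=bool(delta),
        attachment="omega" if omega else "omega_minus_1",
    )


def parse_name(name: str) -> NDMMStructure:
    """Parse a structure-based name into an :class:`NDMMStructure`.

    Grammar: optional ``4'-UB-``/``4'-UP-`` head, optional ``2'-``/``4'-``
    plus parenthesised first unit, then ``asc-`` + optional ``ω`` +
    optional ``Δ`` + ``C`` + chain length. Head groups at positions other
    than 4' are rejected.
    """
    s = name.strip()
    if re.match(r"^(\d')-(UB|UP)-", s) and not s.startswith("4'-"):
        raise ValueError(f"head group must sit at the 4'-position: {name!r}")
    m = _NAME_RE.match(s)
    if not m:
        raise ValueError(f"malformed NDMM name {name!r}")
    head, linkage, first_txt, second_txt = m.groups()
    second = _parse_simple(second_txt)
    first = _parse_simple(first_txt) if first_txt else None
    if linkage == "2'/4'":
        linkage = "unresolved"
    return NDMMStructure(
        side_chain=second.side_chain,
        head=head,
        first_unit=first,
        linkage=linkage if first is not None else None,
    )


def render_name(s: NDMMStructure) -> str:
    """Canonical structure-based name; inverse of :func:`parse_name`."""
    if s.ndmm_class == "registry":
        raise ValueError("registry compounds have no grammar form")
    sc = s.side_chain
    core = "asc-{}{}C{}".format(
        "ω" if sc.attachment == "omega" else "",
        "Δ" if sc.unsaturated else "",
        sc.n_carbons,
    )
    parts = []
    if s.head is not None:
        parts.append(f"4'-{s.head}-")
    if s.first_unit is not None:
        link = s.linkage if s.linkage != "unresolved" else "2'/4'"
        parts.append(f"{link}-({render_name(s.first_unit)})-")
    parts.append(core)
    return "".join(parts)


def load_registry(path: str | Path) -> list[NDMMStructure]:
    """Read a compound registry CSV with columns name, formula, class, notes.

    Registry entries cover the highly modular PASC/NPAR chemicals whose
    structures are catalogued at the molecular-formula level rather than
    assembled combinatorially.
    """
    out: list[NDMMStructure] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                NDMMStructure(
                    registry_id=row["name"].strip(),
                    registry_formula=parse_formula(row["formula"].strip()),
                )
            )
    return out
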