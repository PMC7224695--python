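"""NDMM assembly, diagnostic fragments and the nomenclature grammar."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ndmmkit.formula import parse_formula
from ndmmkit.structures import (
    NDMMStructure,
    SideChain,
    assemble_ndmm,
    charged_formula,
    diagnostic_fragments,
    parse_name,
    render_name,
)


class TestAssembly:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            # sugar C6H12O4 + chain - one glycosidic water
            (dict(chain_length=7), "C13H24O6"),
            (dict(chain_length=5), "C11H20O6"),
            (dict(chain_length=7, unsaturated=True), "C13H22O6"),
            (dict(chain_length=3, attachment="omega"), "C9H16O6"),
            # head group adds an ester bond (another water out)
            (dict(chain_length=5, head="UB"), "C16H28N2O8"),
            (dict(chain_length=4, head="UP"), "C14H24N2O8"),
        ],
    )
    def test_simple_and_headed_formulas(self, kwargs, expected):
        assert assemble_ndmm(**kwargs).formula == parse_formula(expected)

    def test_dimer_formula(self):
        unit = assemble_ndmm(7)
        dasc1 = assemble_ndmm(7, first_unit=unit, linkage="4'")
        # 2 x C13H24O6 - H2O
        assert dasc1.formula == parse_formula("C26H46O11")
        assert dasc1.ndmm_class == "DASC"

    def test_headed_dimer(self):
        first = assemble_ndmm(5)
        s = assemble_ndmm(4, head="UB", first_unit=first, linkage="2'")
        assert s.ndmm_class == "UBAS"
        assert s.formula == parse_formula("C26H44N2O13")
        assert s.n_condensation_bonds == 3

    def test_class_labels(self):
        assert assemble_ndmm(5).ndmm_class == "simple"
        assert assemble_ndmm(5, head="UP").ndmm_class == "UPAS"

    def test_unsupported_chain_length(self):
        with pytest.raises(ValueError):
            assemble_ndmm(2)
        with pytest.raises(ValueError):
            assemble_ndmm(12)

    def test_head_position_restricted(self):
        with pytest.raises(ValueError):
            assemble_ndmm(5, head="UB", head_position="2'")

    def test_linkage_without_first_unit(self):
        with pytest.raises(ValueError):
            NDMMStructure(side_chain=SideChain(5), linkage="2'")

    def test_registry_structure(self):
        s = NDMMStructure(
            registry_id="npar#1", registry_formula=parse_formula("C10H10O5")
        )
        assert s.ndmm_class == "registry"
        assert s.formula == parse_formula("C10H10O5")
        with pytest.raises(ValueError):
            render_name(s)


class TestDiagnosticFragments:
    def test_dasc_fragment_matches_printed_ion(self):
        dasc3 = parse_name("2'-(asc-C5)-asc-C4")
        (neutral, ion), = diagnostic_fragments(dasc3)
        assert neutral == parse_formula("C17H28O8")
        assert charged_formula(neutral, ion.adduct) == parse_formula(
            "C17H28NaO8+"
        )
        assert ion.polarity == "positive"

    def test_unsaturated_dasc_fragment(self):
        dasc14 = parse_name("4'-(asc-ΔC7)-asc-C5")
        (neutral, ion), = diagnostic_fragments(dasc14)
        assert charged_formula(neutral, ion.adduct) == parse_formula(
            "C19H30NaO8+"
        )

    def test_ubas_cation(self):
        (neutral, ion), = diagnostic_fragments(assemble_ndmm(9, head="UB"))
        assert charged_formula(neutral, ion.adduct) == parse_formula(
            "C11H19N2O5+"
        )
        assert ion.adduct == "M+H"

    def test_upas_anion(self):
        (neutral, ion), = diagnostic_fragments(assemble_ndmm(4, head="UP"))
        assert charged_formula(neutral, ion.adduct) == parse_formula(
            "C4H7N2O3-"
        )
        assert ion.polarity == "negative"

    def test_no_rule_for_simple(self):
        with pytest.raises(ValueError):
            diagnostic_fragments(assemble_ndmm(5))


simple_structures = st.builds(
    assemble_ndmm,
    st.integers(min_value=3, max_value=11),
    unsaturated=st.booleans(),
    attachment=st.sampled_from(["omega_minus_1", "omega"]),
)
structures = st.one_of(
    simple_structures,
    st.builds(
        lambda second, first, linkage, head: assemble_ndmm(
            second.side_chain.n_carbons,
            unsaturated=second.side_chain.unsaturated,
            attachment=second.side_chain.attachment,
            first_unit=first,
            linkage=linkage,
            head=head,
        ),
        simple_structures,
        simple_structures,
        st.sampled_from(["2'", "4'", "unresolved"]),
        st.sampled_from([None, "UB", "UP"]),
    ),
)


class TestNomenclature:
    @pytest.mark.parametrize(
        "name,cls,length",
        [
            ("asc-C5", "simple", 5),
            ("asc-ωC3", "simple", 3),
            ("asc-ΔC7", "simple", 7),
            ("2'-(asc-C5)-asc-C4", "DASC", 4),
            ("4'-(asc-ΔC7)-asc-ΔC7", "DASC", 7),
            ("4'-UB-asc-C5", "UBAS", 5),
            ("4'-UP-2'-(asc-C5)-asc-C4", "UPAS", 4),
            ("4'-UB-2'-(asc-C5)-asc-C4", "UBAS", 4),
        ],
    )
    def test_parse_printed_names(self, name, cls, length):
        s = parse_name(name)
        assert s.ndmm_class == cls
        assert s.side_chain.n_carbons == length
        assert render_name(s) == name

    def test_parse_details(self):
        s = parse_name("4'-UB-2'-(asc-C5)-asc-C4")
        assert s.head == "UB"
        assert s.first_unit.side_chain.n_carbons == 5
        assert s.linkage == "2'"
        omega = parse_name("asc-ωC3")
        assert omega.side_chain.attachment == "omega"
        delta = parse_name("asc-ΔC7")
        assert delta.side_chain.unsaturated

    @pytest.mark.parametrize(
        "bad", ["asc-C", "ascr#9", "2'-UB-asc-C5", "4'-(asc-C5-asc-C4",
                "asc-ΔωC5"]
    )
    def test_malformed_names(self, bad):
        with pytest.raises(ValueError):
            parse_name(bad)

    @given(structures)
    def test_roundtrip_identity(self, s):
        assert parse_name(render_name(s)) == s
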