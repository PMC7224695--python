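"""Candidate library enumeration and spectral matching behaviour."""

import pytest

import ndmmkit as nk
from ndmmkit.formula import ion_mz
from ndmmkit.screen import LibraryConfig, ScreenConfig, Spectrum
from ndmmkit.structures import (
    UBAS_DIAGNOSTIC_NEUTRAL,
    IonSpec,
    parse_name,
)


class TestBuildLibrary:
    def test_small_enumeration_count(self):
        # 2 simple units; ordered dimer pairs (2x2) x 2 linkages = 8
        lib = nk.build_library(
            LibraryConfig(chain_lengths=(4, 5), dimers=True)
        )
        assert len(lib) == 10
        assert len({c.name for c in lib}) == 10

    def test_headed_unit_present(self):
        lib = nk.build_library(
            LibraryConfig(chain_lengths=(5,), heads=("UB",))
        )
        assert "4'-UB-asc-C5" in {c.name for c in lib}

    def test_empty_lengths_error(self):
        with pytest.raises(ValueError):
            nk.build_library(LibraryConfig(chain_lengths=()))

    def test_candidates_carry_adduct_mzs(self, full_library):
        for cand in full_library[:20]:
            for adduct, mz in cand.ions:
                assert mz == pytest.approx(ion_mz(cand.neutral, adduct))


def _spectrum(mz, polarity="positive", peaks=(), intensity=1.0e4, sid="s1"):
    return Spectrum(sid, mz, polarity, list(peaks), intensity)


class TestMatchSpectrum:
    def test_planted_dimer_matched(self, full_library):
        dasc1 = parse_name("4'-(asc-C7)-asc-C7")
        mz = ion_mz(dasc1.formula, "M+Na")
        res = nk.match_spectrum(
            _spectrum(mz), full_library, ScreenConfig()
        )
        assert any("4'-(asc-C7)-asc-C7" in r.isomers for r in res)

    def test_shifted_precursor_not_matched(self, full_library):
        dasc1 = parse_name("4'-(asc-C7)-asc-C7")
        mz = ion_mz(dasc1.formula, "M+Na") * (1 + 50e-6)
        res = nk.match_spectrum(
            _spectrum(mz), full_library, ScreenConfig(precursor_tol_ppm=5)
        )
        assert res == []

    def test_fragment_confirmation(self, full_library):
        ubas3 = parse_name("4'-UB-asc-C5")
        pre = ion_mz(ubas3.formula, "M+H")
        frag = ion_mz(UBAS_DIAGNOSTIC_NEUTRAL, "M+H")
        with_frag = nk.match_spectrum(
            _spectrum(pre, peaks=[(frag, 500.0)]),
            full_library,
            ScreenConfig(),
        )
        without = nk.match_spectrum(
            _spectrum(pre), full_library, ScreenConfig()
        )
        ub_hits = [r for r in with_frag if "4'-UB-asc-C5" in r.isomers]
        assert ub_hits and ub_hits[0].fragments_confirmed is True
        ub_miss = [r for r in without if "4'-UB-asc-C5" in r.isomers]
        assert ub_miss and ub_miss[0].fragments_confirmed is False

    def test_tolerance_monotonicity(self, full_library):
        dasc1 = parse_name("4'-(asc-C7)-asc-C7")
        mz = ion_mz(dasc1.formula, "M+Na") * (1 + 4e-6)
        s = _spectrum(mz)
        narrow = nk.match_spectrum(
            s, full_library, ScreenConfig(precursor_tol_ppm=5)
        )
        wide = nk.match_spectrum(
            s, full_library, ScreenConfig(precursor_tol_ppm=20)
        )
        narrow_keys = {(r.isomers, r.adduct) for r in narrow}
        wide_keys = {(r.isomers, r.adduct) for r in wide}
        assert narrow_keys <= wide_keys and narrow_keys

    def test_isomer_honesty(self, full_library):
        # 2'- and 4'-linked dimers are mass-identical: never a unique call
        dasc5 = parse_name("4'-(asc-C5)-asc-C5")
        mz = ion_mz(dasc5.formula, "M+Na")
        res = nk.match_spectrum(_spectrum(mz), full_library, ScreenConfig())
        hits = [r for r in res if "4'-(asc-C5)-asc-C5" in r.isomers]
        assert hits and len(hits[0].isomers) > 1
        assert "2'-(asc-C5)-asc-C5" in hits[0].isomers


class TestTargetedScreen:
    def test_finds_exactly_planted_spectra(self, full_library):
        frag = ion_mz(UBAS_DIAGNOSTIC_NEUTRAL, "M+H")
        ion = IonSpec.for_neutral(UBAS_DIAGNOSTIC_NEUTRAL, "M+H")
        spectra = [
            _spectrum(400.0 + i, peaks=[(frag, 100.0)] if i < 3 else [],
                      sid=f"s{i}")
            for i in range(10)
        ]
        hits = nk.targeted_fragment_screen(spectra, ion, ScreenConfig())
        assert hits == ["s0", "s1", "s2"]

    def test_ppm_window(self):
        frag = ion_mz(UBAS_DIAGNOSTIC_NEUTRAL, "M+H")
        ion = IonSpec.for_neutral(UBAS_DIAGNOSTIC_NEUTRAL, "M+H")
        cfg = ScreenConfig(fragment_tol_ppm=10)
        near = _spectrum(400.0, peaks=[(frag * (1 + 3e-6), 10.0)], sid="a")
        far = _spectrum(400.0, peaks=[(frag * (1 + 30e-6), 10.0)], sid="b")
        assert nk.targeted_fragment_screen([near, far], ion, cfg) == ["a"]


class TestClassification:
    @pytest.mark.parametrize(
        "intensity,call",
        [(1.2e3, "quantifiable"), (1.0e3, "quantifiable"),
         (9.9e2, "trace"), (5.0e2, "trace"), (0.0, "absent")],
    )
    def test_threshold_calls(self, intensity, call):
        assert nk.classify_abundance(intensity, ScreenConfig()) == call

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            nk.classify_abundance(-1.0, ScreenConfig())

    def test_threshold_monotonicity(self):
        lo = ScreenConfig(intensity_threshold=1e2)
        hi = ScreenConfig(intensity_threshold=1e5)
        # raising the threshold can only demote quantifiable -> trace
        for x in (0.0, 5e2, 2e3, 5e4):
            rank = {"absent": 0, "trace": 1, "quantifiable": 2}
            assert rank[nk.classify_abundance(x, hi)] <= rank[
                nk.classify_abundance(x, lo)
            ]
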