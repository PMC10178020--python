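"""Composite spectrum generation and the per-spectrum pipeline."""

import numpy as np
import pytest

from glycodec import Config
from glycodec.core_pattern import find_patterns
from glycodec.decomposer import (
    GLYCAN_MASS_KEY,
    decompose_spectrum,
    decompose_stream,
    make_glycan_spectrum,
    make_peptide_spectrum,
)
from glycodec.masses import OxoniumTable
from glycodec.simulator import CLEAN_PARAMS, SimParams, simulate_cohort
from glycodec.spectra_io import (
    Peak,
    Spectrum,
    charge_deconvolute,
    precursor_neutral_mass,
    prefilter_peaks,
)


def best_pattern(spectrum):
    return find_patterns(charge_deconvolute(spectrum))[0]


class TestMakePeptideSpectrum:
    def test_clean_simulation_contents(self, clean_glyco):
        spectrum, truth = clean_glyco
        pattern = best_pattern(spectrum)
        out = make_peptide_spectrum(spectrum, pattern)
        assert out.precursor_mz == pytest.approx(pattern.reference_mz)
        assert out.precursor_charge == 1
        cutoff = pattern.reference_mz + 0.05
        assert all(p.mz <= cutoff for p in out.peaks)
        oxo = OxoniumTable().mz_values
        assert not any(
            abs(p.mz - omz) <= 0.02 for p in out.peaks for omz in oxo
        )
        # the Y1 reference itself survives the truncation
        assert any(abs(p.mz - pattern.reference_mz) < 1e-6 for p in out.peaks)
        # none of the Y-ladder above Y1 remains
        for offset in (203.0794, 365.1322, 527.185, 689.2378):
            assert not any(
                abs(p.mz - (truth.true_y1_mz + offset)) < 0.01 for p in out.peaks
            )

    def test_no_edits_needed_changes_only_precursor(self):
        ref_mz = 1000.0
        peaks = [Peak(400.0, 50.0, 1), Peak(ref_mz, 100.0, 1),
                 Peak(ref_mz - 203.0794, 30.0, 1)]
        s = Spectrum("s", 1200.0, 2, peaks)
        pattern = find_patterns(s, min_reference_mz=850.0)[0]
        out = make_peptide_spectrum(s, pattern)
        assert [p.mz for p in out.peaks] == [p.mz for p in s.peaks]
        assert out.precursor_mz == ref_mz and out.precursor_charge == 1

    def test_foreign_pattern_rejected(self, clean_glyco):
        spectrum, _ = clean_glyco
        pattern = best_pattern(spectrum)
        other = Spectrum("other", 900.0, 2, [Peak(500.0, 10.0)])
        with pytest.raises(ValueError, match="does not derive"):
            make_peptide_spectrum(other, pattern)


class TestMakeGlycanSpectrum:
    def test_peaks_untouched_metadata_added(self, clean_glyco):
        spectrum, truth = clean_glyco
        pattern = best_pattern(spectrum)
        out = make_glycan_spectrum(spectrum, pattern)
        deconv = charge_deconvolute(spectrum)
        assert [p.mz for p in out.peaks] == [p.mz for p in deconv.peaks]
        assert out.metadata[GLYCAN_MASS_KEY] == pytest.approx(
            truth.true_glycan_mass, abs=0.05
        )


class TestDecomposeSpectrum:
    def test_mass_conservation_exact(self, clean_glyco):
        spectrum, _ = clean_glyco
        outcome = decompose_spectrum(spectrum)
        assert outcome.category == "decomposed"
        pair = outcome.pair
        total = pair.pattern.peptide_moiety_mass + pair.pattern.glycan_moiety_mass
        assert total == pytest.approx(precursor_neutral_mass(spectrum), abs=1e-9)
        assert pair.glycan_spectrum.metadata[GLYCAN_MASS_KEY] == pytest.approx(
            pair.pattern.glycan_moiety_mass
        )

    def test_glyco_no_pattern_flag(self):
        # oxonium ions present but nothing eligible as a reference peak
        peaks = [Peak(204.0867, 100.0), Peak(366.1395, 80.0), Peak(500.0, 60.0)]
        s = Spectrum("stub", 1200.0, 2, peaks)
        outcome = decompose_spectrum(s)
        assert outcome.category == "glyco-no-pattern"
        assert outcome.oxonium.is_glycopeptide is True

    def test_non_glyco_passthrough_untouched(self):
        peaks = [Peak(500.0, 100.0), Peak(900.0, 80.0)]
        s = Spectrum("plain", 1000.0, 2, peaks)
        outcome = decompose_spectrum(s)
        assert outcome.category == "non-glyco"
        assert outcome.spectrum is s and outcome.pair is None


class TestDecomposeStream:
    def test_mixed_clean_cohort(self):
        spectra, truth = simulate_cohort(50, 50, CLEAN_PARAMS)
        outcomes, counts = decompose_stream(spectra)
        assert counts == {
            "non-glyco": 50,
            "decomposed": 50,
            "glyco-no-pattern": 0,
            "error": 0,
        }
        assert sum(counts.values()) == len(spectra) == len(outcomes)
        labels = dict(zip(truth.identifier, truth.label))
        for o in outcomes:
            expected = "decomposed" if labels[o.spectrum.identifier] == "glyco" else "non-glyco"
            assert o.category == expected

    def test_empty_input(self):
        outcomes, counts = decompose_stream([])
        assert outcomes == [] and sum(counts.values()) == 0

    def test_peptide_spectrum_keeps_all_by_ions_below_y1(self):
        spectra, truth = simulate_cohort(5, 0, CLEAN_PARAMS)
        outcomes, _ = decompose_stream(spectra)
        t_by_id = truth.set_index("identifier")
        for o in outcomes:
            pep = o.pair.peptide_spectrum
            y1 = t_by_id.loc[o.spectrum.identifier, "true_y1_mz"]
            parent = prefilter_peaks(charge_deconvolute(o.spectrum), 15.0)
            oxo = OxoniumTable().mz_values
            expected = [
                p.mz
                for p in parent.peaks
                if p.mz <= y1 + 0.05
                and not any(abs(p.mz - m) <= 0.02 for m in oxo)
            ]
            assert [p.mz for p in pep.peaks] == pytest.approx(expected)

    def test_bad_spectrum_logged_not_fatal(self):
        good = Spectrum("ok", 1000.0, 2, [Peak(500.0, 100.0)])
        bad = Spectrum("bad", 1000.0, None, [Peak(204.0867, 100.0)])
        outcomes, counts = decompose_stream([good, bad])
        assert counts["non-glyco"] == 1
        # unknown precursor charge only matters once a pattern is attempted;
        # the oxonium-only spectrum fails there and is recorded, not raised
        assert len(outcomes) == 2
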