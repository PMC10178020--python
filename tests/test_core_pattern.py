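"""Core Y-ion pattern search: reference gating, matching, ranking, grouping."""

import numpy as np
import pytest

from glycodec.core_pattern import (
    PatternMatch,
    candidate_references,
    find_patterns,
    group_isotope_patterns,
    match_pattern,
    rank_patterns,
)
from glycodec.masses import PROTON, MONOSACCHARIDE_MASSES
from glycodec.spectra_io import Peak, Spectrum, charge_deconvolute, precursor_neutral_mass


def spec(peaks, mz=1500.0, z=2):
    return Spectrum("s", mz, z, peaks)


class TestCandidateReferences:
    def test_mass_and_intensity_gates(self):
        s = spec([Peak(800.0, 100.0), Peak(900.0, 50.0)])
        refs = candidate_references(s)
        assert [p.mz for p in refs] == [900.0]

    def test_boundaries_inclusive(self):
        s = spec([Peak(850.0, 10.0), Peak(900.0, 100.0)])
        refs = candidate_references(s)
        assert [p.mz for p in refs] == [850.0, 900.0]

    def test_all_below_min_mz(self):
        s = spec([Peak(500.0, 100.0), Peak(700.0, 90.0)])
        assert candidate_references(s) == []

    def test_empty_spectrum(self):
        assert candidate_references(spec([])) == []


class TestMatchPattern:
    def test_full_template_on_clean_simulation(self, clean_glyco):
        spectrum, truth = clean_glyco
        deconv = charge_deconvolute(spectrum)
        ref = min(deconv.peaks, key=lambda p: abs(p.mz - truth.true_y1_mz))
        m = match_pattern(deconv, ref)
        assert m is not None
        assert m.n_matched == 8
        assert m.peptide_moiety_mass == pytest.approx(
            truth.true_peptide_mass, abs=0.02
        )

    def test_reference_alone_is_no_match(self):
        ref = Peak(1000.0, 100.0)
        assert match_pattern(spec([ref]), ref) is None

    def test_tolerance_boundary_second_peak(self):
        # co-matching peak at +203.12: |203.12 - 203.0794| = 0.0406 <= 0.05
        ref = Peak(1000.0, 100.0)
        s = spec([ref, Peak(1203.12, 50.0)])
        m = match_pattern(s, ref)
        assert m is not None and m.n_matched == 2
        # tighter tolerance loses the peak
        assert match_pattern(s, ref, mz_tolerance=0.03) is None

    def test_mass_bookkeeping(self):
        ref = Peak(1000.0, 100.0)
        s = spec([ref, Peak(1203.1, 50.0)], mz=1500.0, z=2)
        m = match_pattern(s, ref)
        assert m.peptide_moiety_mass == pytest.approx(
            1000.0 - PROTON - MONOSACCHARIDE_MASSES["HexNAc"]
        )
        assert m.peptide_moiety_mass + m.glycan_moiety_mass == pytest.approx(
            precursor_neutral_mass(s), abs=1e-9
        )

    def test_nonpositive_glycan_mass_invalidated(self):
        # precursor neutral mass ~997, below the implied peptide mass
        ref = Peak(1400.0, 100.0)
        s = spec([ref, Peak(1603.1, 50.0)], mz=998.0, z=1)
        assert match_pattern(s, ref) is None

    def test_shrinking_tolerance_never_gains_matches(self, clean_glyco):
        spectrum, truth = clean_glyco
        deconv = charge_deconvolute(spectrum)
        ref = min(deconv.peaks, key=lambda p: abs(p.mz - truth.true_y1_mz))
        wide = match_pattern(deconv, ref, mz_tolerance=0.05)
        for tol in (0.02, 0.005, 0.001):
            narrow = match_pattern(deconv, ref, mz_tolerance=tol)
            n = 0 if narrow is None else narrow.n_matched
            assert n <= wide.n_matched


def pm(n, intensity, mz=1000.0):
    return PatternMatch(mz, intensity, (0.0,) * n, n, 500.0, 800.0)


class TestRankPatterns:
    def test_matches_then_intensity(self):
        ranked = rank_patterns([pm(8, 500.0), pm(8, 900.0), pm(3, 1e6)])
        assert [(m.n_matched, m.reference_intensity) for m in ranked] == [
            (8, 900.0),
            (8, 500.0),
            (3, 1e6),
        ]
        assert [m.rank for m in ranked] == [1, 2, 3]

    def test_single_match_rank_one(self):
        (m,) = rank_patterns([pm(4, 10.0)])
        assert m.rank == 1

    def test_tie_broken_by_ascending_mz(self):
        ranked = rank_patterns([pm(5, 10.0, mz=910.0), pm(5, 10.0, mz=900.0)])
        assert [m.reference_mz for m in ranked] == [900.0, 910.0]

    def test_empty(self):
        assert rank_patterns([]) == []


class TestGroupIsotopePatterns:
    def test_one_isotope_apart_grouped(self):
        groups = group_isotope_patterns([pm(5, 1.0, 1000.0), pm(5, 1.0, 1001.00335)])
        assert len(groups) == 1 and len(groups[0]) == 2

    def test_far_apart_separate(self):
        groups = group_isotope_patterns([pm(5, 1.0, 1000.0), pm(5, 1.0, 1005.0)])
        assert len(groups) == 2

    def test_singleton(self):
        groups = group_isotope_patterns([pm(5, 1.0, 1000.0)])
        assert len(groups) == 1 and len(groups[0]) == 1

    def test_transitive_chain(self):
        ms = [pm(5, 1.0, 1000.0), pm(5, 1.0, 1001.00335), pm(5, 1.0, 1002.0067)]
        groups = group_isotope_patterns(ms)
        assert len(groups) == 1 and len(groups[0]) == 3


class TestFindPatterns:
    def test_rank1_recovers_truth_on_clean_spectrum(self, clean_glyco):
        spectrum, truth = clean_glyco
        ranked = find_patterns(charge_deconvolute(spectrum))
        assert ranked
        best = ranked[0]
        assert best.rank == 1
        assert best.n_matched == 8
        assert best.peptide_moiety_mass == pytest.approx(
            truth.true_peptide_mass, abs=0.02
        )
        assert best.glycan_moiety_mass == pytest.approx(
            truth.true_glycan_mass, abs=0.05
        )
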