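"""Fragment ladders, peak matching and sequence-tag inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bithionin.chem_core import PROTON_MASS, WATER, residue_mass
from bithionin.ms_match import (
    FragmentIon,
    PeakList,
    fragment_ladder,
    infer_sequence_tag,
    match_peaks,
)
from bithionin.synthetic_data import GeneratorConfig, gen_spectrum

H2O = WATER.monoisotopic_mass()

peptides = st.text(alphabet="GASPVTCLINDQKEMHFRYW", min_size=2, max_size=15)


class TestLadder:
    def test_diglycine_b1(self):
        ions = {i.name: i for i in fragment_ladder("GG")}
        assert ions["b1(1+)"].mz == pytest.approx(
            residue_mass("G") + PROTON_MASS, abs=1e-6)

    def test_diglycine_complementarity(self):
        ions = {i.name: i for i in fragment_ladder("GG")}
        total = 2 * residue_mass("G") + H2O
        assert ions["b1(1+)"].mz + ions["y1(1+)"].mz == pytest.approx(
            total + 2 * PROTON_MASS, abs=1e-9)

    @given(peptides)
    @settings(max_examples=100, deadline=None)
    def test_complementarity_random_peptides(self, seq):
        ions = {(i.series, i.index): i.mz for i in fragment_ladder(seq)}
        total = sum(residue_mass(a) for a in seq) + H2O
        n = len(seq)
        for i in range(1, n):
            assert ions[("b", i)] + ions[("y", n - i)] == pytest.approx(
                total + 2 * PROTON_MASS, abs=1e-9)

    def test_cz_series_offsets(self):
        ions = {i.name: i for i in fragment_ladder("GAV", series=("b", "y", "c", "z"))}
        nh3 = 17.02655
        assert ions["c1(1+)"].mz - ions["b1(1+)"].mz == pytest.approx(nh3, abs=1e-4)
        assert ions["y1(1+)"].mz - ions["z1(1+)"].mz == pytest.approx(nh3, abs=1e-4)

    def test_unknown_series_rejected(self):
        with pytest.raises(ValueError):
            fragment_ladder("GAV", series=("b", "q"))

    def test_crosslink_suppression(self, product7):
        """No b/y ions from cleavages strictly inside the macrocycle span."""
        ions = fragment_ladder(product7, charges=(1,))
        b_indices = {i.index for i in ions if i.series == "b"}
        n = len(product7.positions)
        # cleavages 11..26 cut through the Cys-11..AED-27 crosslink
        assert b_indices == set(range(1, 11))
        y_indices = {i.index for i in ions if i.series == "y"}
        assert y_indices == {n - i for i in range(1, 11)}

    def test_suppress_is_subset_of_labile(self, product7):
        suppress = {(i.series, i.index, i.charge)
                    for i in fragment_ladder(product7, charges=(1, 2))}
        labile = {(i.series, i.index, i.charge)
                  for i in fragment_ladder(product7, charges=(1, 2),
                                           crosslink_mode="labile")}
        assert suppress < labile


class TestMatching:
    def test_single_match_four_ppm(self):
        ions = [FragmentIon("b", 1, 1, 100.0)]
        peaks = PeakList(np.array([100.0004]), np.array([1.0]))
        report = match_peaks(ions, peaks, tolerance_ppm=5.0)
        assert len(report.matches) == 1
        assert report.matches[0].ppm == pytest.approx(4.0, abs=1e-6)

    def test_hundred_ppm_away_unmatched(self):
        ions = [FragmentIon("b", 1, 1, 999.9)]
        peaks = PeakList(np.array([1000.0]), np.array([1.0]))
        report = match_peaks(ions, peaks, tolerance_ppm=5.0)
        assert not report.matches
        assert list(report.unmatched_peaks) == [1000.0]

    def test_empty_theoretical_is_empty_report(self):
        peaks = PeakList(np.array([500.0]), np.array([1.0]))
        report = match_peaks([], peaks, 5.0)
        assert report.matches == [] and report.fraction_matched == 0.0

    def test_each_peak_used_once(self):
        ions = fragment_ladder("GGG")
        peaks = PeakList(np.array([ions[0].mz]), np.array([1.0]))
        report = match_peaks(ions, peaks, tolerance_ppm=50.0)
        assert len(report.matches) == 1

    def test_recovery_from_synthetic_spectrum(self, product11):
        """With jitter at half the tolerance, nearly every ladder ion is
        recovered despite decoy injection."""
        ions = fragment_ladder(product11, charges=(1, 2))
        cfg = GeneratorConfig(seed=11, ppm_sd=1.5)
        peaks, truth = gen_spectrum(cfg, ions)
        report = match_peaks(ions, peaks, tolerance_ppm=5.0)
        assert report.fraction_matched >= 0.95

    def test_noiseless_spectrum_fully_matched(self, product11):
        ions = fragment_ladder(product11, charges=(1,))
        cfg = GeneratorConfig(seed=3, ppm_sd=0.0, decoy_count=0)
        peaks, _ = gen_spectrum(cfg, ions)
        report = match_peaks(ions, peaks, tolerance_ppm=1.0)
        assert report.fraction_matched == 1.0
        assert report.coverage == {"b": 1.0, "y": 1.0}

    def test_decoy_only_spectrum_no_matches(self, product11):
        ions = fragment_ladder(product11, charges=(1,))
        rng = np.random.default_rng(0)
        peaks = PeakList(rng.uniform(2000.0, 2100.0, size=40), np.ones(40))
        report = match_peaks([i for i in ions if i.mz < 1900], peaks, 1.0)
        assert not report.matches


class TestSequenceTag:
    def test_dha_aaa_isomer_pair(self):
        peaks = PeakList(np.array([500.0, 569.0215]), np.ones(2))
        tag = infer_sequence_tag(peaks, tolerance_ppm=20.0)
        assert tag.steps[0].candidates == ("Aaa", "Dha")
        assert tag.steps[0].isomeric

    def test_dhb_delta(self):
        peaks = PeakList(np.array([500.0, 583.0371]), np.ones(2))
        tag = infer_sequence_tag(peaks, tolerance_ppm=20.0)
        assert "Dhb" in tag.steps[0].candidates

    def test_glycine_delta(self):
        peaks = PeakList(np.array([500.0, 557.02146]), np.ones(2))
        tag = infer_sequence_tag(peaks, tolerance_ppm=20.0)
        assert tag.steps[0].candidates == ("G",)

    def test_unassignable_delta_diagnosed(self):
        peaks = PeakList(np.array([500.0, 530.0]), np.ones(2))
        tag = infer_sequence_tag(peaks, tolerance_ppm=5.0)
        assert not tag.steps and tag.unassigned == [pytest.approx(30.0)]

    def test_ladder_reads_back_ground_truth(self, product11):
        """A clean b-ion ladder reads back the product's residue codes
        (up to mass-isomer ambiguity)."""
        ions = sorted((i for i in fragment_ladder(product11, series=("b",))),
                      key=lambda i: i.index)
        peaks = PeakList(np.array([i.mz for i in ions]), np.ones(len(ions)))
        tag = infer_sequence_tag(peaks, tolerance_ppm=5.0)
        truth = [product11.residues[p] for p in product11.positions][1:len(tag.steps) + 1]
        for step, expected in zip(tag.steps, truth):
            assert expected in step.candidates

    def test_needs_two_peaks(self):
        with pytest.raises(ValueError):
            infer_sequence_tag(PeakList(np.array([100.0]), np.array([1.0])), 5.0)


class TestPeakListIO:
    def test_tsv_round_trip(self, tmp_path):
        peaks = PeakList(np.array([300.5, 100.1, 200.2]), np.array([3.0, 1.0, 2.0]))
        assert list(peaks.mz) == [100.1, 200.2, 300.5]  # sorted on load
        path = tmp_path / "peaks.tsv"
        peaks.to_tsv(path)
        loaded = PeakList.from_tsv(path)
        assert np.allclose(loaded.mz, peaks.mz)

    def test_mgf_round_trip(self, tmp_path):
        path = tmp_path / "spec.mgf"
        path.write_text("BEGIN IONS\nTITLE=synthetic\nPEPMASS=500.0\n"
                        "100.5 10.0\n200.5 20.0\nEND IONS\n")
        peaks = PeakList.from_mgf(path)
        assert np.allclose(peaks.mz, [100.5, 200.5])

    def test_nonpositive_mz_rejected(self):
        with pytest.raises(ValueError):
            PeakList(np.array([-1.0]), np.array([1.0]))
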