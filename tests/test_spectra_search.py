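"""Spectrum matching: masses, fragments, tolerances, scoring, localization."""

import math

import numpy as np
import pytest

from neoligand.spectra_search import (
    MODIFICATIONS,
    PROTON,
    WATER,
    ObservedSpectrum,
    PeptideIndex,
    SearchTolerances,
    binomial_tail_score,
    candidate_lookup,
    delta_score,
    enumerate_placements,
    generate_by_ions,
    localize_sites,
    match_probability,
    peptide_mass,
    read_mgf,
    score_match,
    search_spectra,
    write_mgf,
)

# independent monoisotopic residue masses (frozen reference values)
RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}


def spectrum_for(sequence, placements=(), charge=2, extra_mz=(), sid="s1"):
    theo = generate_by_ions(sequence, placements, charge)
    mz = np.concatenate([theo, np.asarray(extra_mz, dtype=float)])
    return ObservedSpectrum(
        spectrum_id=sid,
        precursor_mz=(peptide_mass(sequence, placements) + charge * PROTON) / charge,
        charge=charge,
        mz=mz,
        intensity=np.ones_like(mz),
    )


class TestPeptideMass:
    def test_phospho_delta_exact(self):
        pep = "AKSLYR"
        assert peptide_mass(pep, (("ph", 2),)) - peptide_mass(pep) == pytest.approx(
            79.9663304, abs=1e-9
        )

    def test_oxidation_delta_exact(self):
        pep = "AMKLR"
        assert peptide_mass(pep, (("ox", 1),)) - peptide_mass(pep) == pytest.approx(
            15.994915, abs=1e-9
        )

    def test_acetylation_delta_exact(self):
        pep = "AMKLR"
        assert peptide_mass(pep, (("ac", -1),)) - peptide_mass(pep) == pytest.approx(
            42.010565, abs=1e-9
        )

    def test_plain_mass_against_independent_table(self):
        pep = "SIINFEKL"
        expected = sum(RESIDUE_MASS[a] for a in pep) + 18.010565
        assert peptide_mass(pep) == pytest.approx(expected, abs=2e-4)

    def test_phospho_on_non_sty_rejected(self):
        with pytest.raises(ValueError):
            peptide_mass("AAAA", (("ph", 0),))


class TestFragments:
    def test_nine_mer_gives_16_singly_charged(self):
        assert generate_by_ions("SIINFEKLA", charge=1).size == 16

    def test_mass_balance_of_complementary_ions(self):
        # neutral(b_i) + neutral(y_{n-i}) = precursor neutral + water... b+y
        # singly-charged pair: b_i + y_{n-i} = M + water-less bookkeeping
        pep = "SIINFEKL"
        ions = generate_by_ions(pep, charge=1)
        b1 = RESIDUE_MASS["S"] + PROTON
        y7 = sum(RESIDUE_MASS[a] for a in pep[1:]) + 18.010565 + PROTON
        m = peptide_mass(pep)
        assert b1 + y7 == pytest.approx(m + 2 * PROTON, abs=2e-4)
        assert any(abs(ions - b1) < 2e-3) and any(abs(ions - y7) < 2e-3)

    def test_phospho_shifts_only_fragments_containing_site(self):
        pep = "AAAASAAAA"  # site at index 4
        plain = generate_by_ions(pep, charge=1)
        mod = generate_by_ions(pep, (("ph", 4),), charge=1)
        delta = MODIFICATIONS["ph"].delta_mass
        # b1..b4 and y1..y4 unshifted; b5..b8 and y5..y8 shifted
        unshifted = sum(1 for x in plain if any(abs(mod - x) < 1e-9))
        shifted = sum(1 for x in plain if any(abs(mod - (x + delta)) < 1e-9))
        assert unshifted == 8 and shifted == 8

    def test_too_short_to_fragment(self):
        with pytest.raises(ValueError):
            generate_by_ions("A")


class TestCandidateLookup:
    def _index(self, sequence="SIINFEKL"):
        return PeptideIndex({sequence: []}, {}, enabled_mods=())

    @pytest.mark.parametrize("ppm, expected", [(5, True), (6, True), (7, False)])
    def test_precursor_boundary_inclusive(self, ppm, expected):
        index = self._index()
        m = peptide_mass("SIINFEKL")
        obs = m * (1 + ppm * 1e-6)
        spectrum = ObservedSpectrum("s", (obs + 2 * PROTON) / 2, 2,
                                    np.array([200.0]), np.array([1.0]))
        hits = candidate_lookup(spectrum, index, SearchTolerances())
        assert bool(hits) is expected

    def test_empty_index(self):
        index = PeptideIndex({}, {})
        spectrum = ObservedSpectrum("s", 500.0, 2, np.array([200.0]), np.array([1.0]))
        assert candidate_lookup(spectrum, index) == []


class TestScoring:
    def test_matches_exact_binomial_tail_oracle(self):
        k, n, p = 8, 16, 0.01
        expected_tail = sum(
            math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
        )
        assert binomial_tail_score(k, n, p) == pytest.approx(
            -10 * math.log10(expected_tail), rel=1e-9
        )

    def test_zero_matches_scores_zero(self):
        assert binomial_tail_score(0, 16, 0.01) == 0.0

    def test_monotone_in_matched_count(self):
        scores = [binomial_tail_score(k, 16, 0.01) for k in range(17)]
        assert scores == sorted(scores)

    def test_complete_spectrum_dominates_other_candidates(self):
        spectrum = spectrum_for("SIINFEKL")
        full, _, _ = score_match(spectrum, "SIINFEKL")
        other, _, _ = score_match(spectrum, "SIINFEKK")
        assert full > other

    def test_recalibration_within_tolerance_is_symmetric(self):
        spectrum = spectrum_for("SIINFEKL")
        shifted = ObservedSpectrum(
            "s2", spectrum.precursor_mz * (1 + 3e-6), spectrum.charge,
            spectrum.mz * (1 + 5e-6), spectrum.intensity,
        )
        s0, k0, n0 = score_match(spectrum, "SIINFEKL")
        s1, k1, n1 = score_match(shifted, "SIINFEKL")
        assert (k0, n0) == (k1, n1) and s0 == pytest.approx(s1)


class TestDeltaScore:
    def test_single_candidate_delta_is_score(self):
        assert delta_score([(42.0, "PEPTIDE", ())]) == 42.0

    def test_same_sequence_different_placement_is_alternative(self):
        ranked = [(42.0, "AKSLYR", (("ph", 2),)), (30.0, "AKSLYR", (("ph", 4),))]
        assert delta_score(ranked) == 12.0

    def test_tie_between_distinct_sequences_gives_zero(self):
        ranked = [(42.0, "AAAAKR", ()), (42.0, "AAALKR", ())]
        assert delta_score(ranked) == 0.0

    def test_duplicate_assignment_skipped(self):
        ranked = [(42.0, "AAAAKR", ()), (42.0, "AAAAKR", ()), (30.0, "AAALKR", ())]
        assert delta_score(ranked) == 12.0


class TestLocalization:
    def test_single_site_probability_one(self):
        spectrum = spectrum_for("AAASAAAK", (("ph", 3),))
        probs = localize_sites(spectrum, "AAASAAAK", (("ph", 3),))
        assert probs == {4: 1.0}

    def test_symmetric_evidence_splits_evenly(self):
        # both sites' site-determining ions absent -> identical isomer scores
        pep = "ASAASAAK"
        theo1 = generate_by_ions(pep, (("ph", 1),), 2)
        theo2 = generate_by_ions(pep, (("ph", 4),), 2)
        common = np.array(sorted(set(np.round(theo1, 6)) & set(np.round(theo2, 6))))
        spectrum = ObservedSpectrum(
            "s", (peptide_mass(pep, (("ph", 1),)) + 2 * PROTON) / 2, 2,
            common, np.ones_like(common),
        )
        probs = localize_sites(spectrum, pep, (("ph", 1),))
        assert probs[2] == pytest.approx(0.5) and probs[5] == pytest.approx(0.5)

    def test_score_gap_20_gives_0990(self):
        # isomer scores differing by 20 -> 10^2 / (10^2 + 10^0) normalization
        w = 10.0**2 / (10.0**2 + 1.0)
        assert w == pytest.approx(0.990, abs=5e-4)

    def test_probabilities_sum_to_one(self, searched_cohort):
        for psm in searched_cohort["psms"]:
            if psm.site_localizations:
                assert sum(psm.site_localizations.values()) == pytest.approx(
                    1.0, abs=1e-9
                )


class TestPlacementEnumeration:
    def test_counts_bounded(self):
        pls = enumerate_placements("MSAYK")  # 1 M, S+Y sites
        # (1 + 2 ph) * (1 + 1 ox) * (1 + ac) = 12
        assert len(pls) == 12
        assert () in pls

    def test_disabled_mods(self):
        assert enumerate_placements("MSAYK", enabled=()) == [()]


class TestSearchEndToEnd:
    def test_noise_free_spectra_recover_true_peptide(self, small_cohort, searched_cohort):
        """On fixture spectra the planted peptide is the top candidate for
        >= 99% of the planted (non-noise) spectra."""
        truth = searched_cohort["truth"]
        psms = {p.spectrum_id: p for p in searched_cohort["psms"]}
        planted = [
            (sid, tp) for sid, tp in truth.spectrum_assignments.items()
            if not isinstance(tp, str)
        ]
        hits = sum(
            1 for sid, tp in planted
            if sid in psms and psms[sid].sequence == tp.sequence
        )
        assert hits / len(planted) >= 0.99

    def test_mgf_round_trip(self, tmp_path, small_cohort):
        spectra = small_cohort["spectra"][:5]
        path = tmp_path / "x.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert [s.spectrum_id for s in back] == [s.spectrum_id for s in spectra]
        for a, b in zip(spectra, back):
            assert a.charge == b.charge
            assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-5)
            np.testing.assert_allclose(a.mz, b.mz, atol=1e-4)
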