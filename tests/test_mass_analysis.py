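"""Residue-mass deltas, species enumeration, and peak assignment."""

import numpy as np
import pytest

from scrkit.mass_analysis import (
    AmbiguousAssignmentWarning,
    DeconvolutedSpectrum,
    ResidueMassTable,
    SpeciesHypothesis,
    assign_peaks,
    enumerate_species,
    pick_peaks,
    protein_average_mass,
    residue_delta,
)
from scrkit.synthetic_data import SpectrumConfig, gen_spectrum

# frozen standard atomic average masses (independent of the mass backend)
M_H = 1.008
M_N = 14.007


class TestResidueDelta:
    @pytest.mark.parametrize(
        "from_aa, to_aa, shift",
        [("R", "Y", 7), ("R", "pAzF", 32), ("R", "pAmF", 6)],
    )
    def test_characteristic_shifts_at_an_arginine_site(self, from_aa, to_aa, shift,
                                                       mass_table):
        assert residue_delta(from_aa, to_aa, mass_table, rounded=True) == shift

    def test_self_substitution_is_zero(self, mass_table):
        for aa in ("G", "R", "pAzF"):
            assert residue_delta(aa, aa, mass_table) == 0.0

    def test_unknown_residue_named(self, mass_table):
        with pytest.raises(KeyError, match="'B'"):
            residue_delta("R", "B", mass_table)

    def test_compositional_consistency_of_noncanonical_residues(self, mass_table):
        # azide replaces a ring hydrogen: Phe -> pAzF adds N3 and removes H
        assert residue_delta("F", "pAzF", mass_table) == pytest.approx(
            3 * M_N - M_H, abs=0.02
        )
        # reduction of the azide to the amine: pAzF -> pAmF swaps N3 for NH2
        assert residue_delta("pAzF", "pAmF", mass_table) == pytest.approx(
            (M_N + 2 * M_H) - 3 * M_N, abs=0.02
        )


class TestProteinMass:
    def test_empty_chain_is_water(self, mass_table):
        assert protein_average_mass("", mass_table) == pytest.approx(18.015, abs=0.01)

    def test_diglycine(self, mass_table):
        assert protein_average_mass("GG", mass_table) == pytest.approx(132.12, abs=0.01)

    def test_permutation_invariance(self, mass_table):
        assert protein_average_mass("ACDEFGH", mass_table) == pytest.approx(
            protein_average_mass("HGFEDCA", mass_table), abs=1e-9
        )

    def test_single_site_swap_adds_the_residue_delta(self, mass_table):
        base = protein_average_mass("MKRLV", mass_table)
        swapped = protein_average_mass("MKYLV", mass_table)
        assert swapped - base == pytest.approx(
            residue_delta("R", "Y", mass_table), abs=1e-9
        )

    def test_noncanonical_residues_in_sequence_list(self, mass_table):
        seq = ["M", "K", "pAzF", "L"]
        assert protein_average_mass(seq, mass_table) == pytest.approx(
            sum(mass_table[a] for a in seq) + mass_table.water
        )


class TestEnumerateSpecies:
    def test_tyrosine_reassignment_species_set(self, mass_table):
        hyps = enumerate_species(
            8308.0, ["R", "Y"], {"methyl": mass_table.modifications["methyl"]},
            mass_table,
        )
        assert sorted(round(h.mass_da) for h in hyps) == [8308, 8315, 8322, 8329]

    def test_reduced_ncaa_species_appear_at_published_masses(self, mass_table):
        hyps = enumerate_species(
            8308.0, ["R", "pAmF"], {"methyl": mass_table.modifications["methyl"]},
            mass_table,
        )
        masses = {round(h.mass_da) for h in hyps}
        assert {8314, 8328} <= masses

    def test_single_option_no_mods(self, mass_table):
        hyps = enumerate_species(8308.0, ["R"], table=mass_table)
        assert len(hyps) == 1
        assert hyps[0].mass_da == pytest.approx(8308.0)

    def test_count_is_options_times_mod_subsets(self, mass_table):
        hyps = enumerate_species(
            8308.0, ["R", "Y", "pAzF"], {"m1": 14.0, "m2": 80.0}, mass_table
        )
        assert len(hyps) == 3 * 2 ** 2  # all masses here are distinct

    def test_nearby_hypotheses_are_deduplicated(self, mass_table):
        hyps = enumerate_species(8308.0, ["R"], {"tiny": 0.05}, mass_table)
        assert len(hyps) == 1

    def test_empty_options_rejected(self, mass_table):
        with pytest.raises(ValueError, match="site option"):
            enumerate_species(8308.0, [], table=mass_table)


class TestAssignPeaks:
    def hyps(self):
        return [
            SpeciesHypothesis("R", 8308.0),
            SpeciesHypothesis("Y", 8315.0),
            SpeciesHypothesis("R+methyl", 8322.0),
            SpeciesHypothesis("Y+methyl", 8329.0),
        ]

    def test_generator_species_all_assigned(self):
        spectrum = gen_spectrum(SpectrumConfig(seed=2))
        peaks = pick_peaks(spectrum)
        result = assign_peaks(peaks, self.hyps(), tolerance_da=1.5)
        assert {a.hypothesis.label for a in result.assignments} == \
            {"R", "Y", "R+methyl", "Y+methyl"}
        assert result.unassigned == ()

    def test_far_peak_left_unassigned(self):
        spectrum = DeconvolutedSpectrum([8350.0], [100.0])
        result = assign_peaks(spectrum, self.hyps())
        assert result.assignments == ()
        assert result.unassigned == ((8350.0, 100.0),)

    def test_tie_breaks_to_lower_mass(self):
        two = [SpeciesHypothesis("lo", 100.0), SpeciesHypothesis("hi", 101.0)]
        midway = DeconvolutedSpectrum([100.5], [1.0])
        with pytest.warns(AmbiguousAssignmentWarning):
            result = assign_peaks(midway, two, tolerance_da=1.5)
        assert result.assignments[0].hypothesis.label == "lo"
        assert result.assignments[0].ambiguous

    def test_never_assigns_outside_tolerance(self):
        rng = np.random.default_rng(0)
        masses = np.sort(rng.uniform(8300, 8340, size=30))
        masses = masses[np.concatenate(([True], np.diff(masses) > 0))]
        spectrum = DeconvolutedSpectrum(masses, np.ones(len(masses)))
        result = assign_peaks(spectrum, self.hyps(), tolerance_da=1.0)
        for a in result.assignments:
            assert abs(a.delta_da) <= 1.0
        assert len(result.assignments) + len(result.unassigned) == len(masses)

    def test_abundances_sum_to_one_when_any_assigned(self):
        spectrum = gen_spectrum(SpectrumConfig(seed=4))
        result = assign_peaks(pick_peaks(spectrum), self.hyps())
        assert sum(result.species_abundance().values()) == pytest.approx(1.0)

    def test_tyr_vs_amine_species_ambiguity_is_surfaced(self, mass_table):
        """+6 (pAmF) and +7 (Tyr) species cannot be separated at 1.5 Da."""
        hyps = enumerate_species(8308.0, ["R", "Y", "pAmF"], table=mass_table)
        peak = DeconvolutedSpectrum([8314.5], [1.0])
        with pytest.warns(AmbiguousAssignmentWarning, match="pAmF"):
            assign_peaks(peak, hyps, tolerance_da=1.5)

    def test_invalid_inputs_rejected(self):
        spectrum = DeconvolutedSpectrum([8308.0], [1.0])
        with pytest.raises(ValueError, match="tolerance"):
            assign_peaks(spectrum, self.hyps(), tolerance_da=0.0)
        with pytest.raises(ValueError, match="hypothesis"):
            assign_peaks(spectrum, [])


def test_spectrum_csv_round_trip(tmp_path):
    spectrum = gen_spectrum(SpectrumConfig(seed=9))
    path = tmp_path / "spec.csv"
    spectrum.to_csv(path)
    back = DeconvolutedSpectrum.from_csv(path)
    assert np.allclose(back.mass_da, spectrum.mass_da)
    assert np.allclose(back.intensity, spectrum.intensity)
    (tmp_path / "bad.csv").write_text("mass,intensity\n1,2\n")
    with pytest.raises(ValueError, match="mass_da"):
        DeconvolutedSpectrum.from_csv(tmp_path / "bad.csv")
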