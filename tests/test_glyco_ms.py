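"""Digestion, mass arithmetic, fragment ladders, matching, localization."""

import numpy as np
import pytest

from h2agc import (
    DEFAULT_MASS_TABLE,
    HEXNAC,
    Peptide,
    Spectrum,
    digest,
    ion_mz,
    localize_glycosite,
    match_spectrum,
    neutral_mass,
    pair_precursors,
    peptide_mass,
    theoretical_fragments,
)
from h2agc.simulate import SimConfig, sim_localization_pair, sim_spectrum

from conftest import random_peptide

PROTON = DEFAULT_MASS_TABLE.proton
WATER = DEFAULT_MASS_TABLE.water


class TestDigest:
    @pytest.mark.parametrize(
        "protein,expected",
        [
            ("AKGK", [("AK", 1, 2), ("GK", 3, 4)]),
            ("AKPG", [("AK", 1, 2), ("PG", 3, 4)]),  # Lys-C cleaves K-P
            ("KKK", [("K", 1, 1), ("K", 2, 2), ("K", 3, 3)]),
            ("GGG", [("GGG", 1, 3)]),
        ],
    )
    def test_cleavage_rule(self, protein, expected):
        peps = digest(protein)
        assert [(p.sequence, p.start_pos, p.end_pos) for p in peps] == expected

    def test_mouse_h2a_yields_g37_k74(self, ref_h2a, g37k74):
        assert (g37k74.start_pos, g37k74.end_pos, len(g37k74)) == (37, 74, 38)

    def test_unknown_residue_named_with_position(self):
        with pytest.raises(ValueError, match=r"'B' at position 3"):
            digest("AKBG")

    def test_missed_cleavages(self):
        peps = digest("AKGKC", missed_cleavages=1)
        spans = {(p.sequence, p.start_pos, p.end_pos) for p in peps}
        assert ("AKGK", 1, 4) in spans and ("GKC", 3, 5) in spans
        assert ("AK", 1, 2) in spans and ("GK", 3, 4) in spans

    def test_reconstruction_invariant(self, rng):
        """Concatenated 0-missed-cleavage digest reproduces the protein and
        the peptide count equals (#K before the last residue) + 1."""
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(25):
            n = int(rng.integers(1, 120))
            protein = "".join(alphabet[i] for i in rng.integers(0, 20, n))
            peps = digest(protein)
            assert "".join(p.sequence for p in peps) == protein
            expected = sum(1 for aa in protein[:-1] if aa == "K") + 1
            assert len(peps) == expected


class TestMassArithmetic:
    def test_single_glycine_peptide(self):
        assert peptide_mass(Peptide("G", 1, 1)) == pytest.approx(75.03203, abs=1e-5)

    def test_g37_k74_neutral_mass(self, g37k74):
        assert peptide_mass(g37k74) == pytest.approx(3978.0486, abs=1e-3)

    def test_hexnac_additivity(self, g37k74):
        modified = Peptide(
            g37k74.sequence, 37, 74, ((40, HEXNAC, "HexNAc"),)
        )
        assert peptide_mass(modified) == pytest.approx(
            peptide_mass(g37k74) + 203.079373, abs=1e-9
        )

    @pytest.mark.parametrize(
        "mass,charge,expected",
        [
            (3978.0486, 3, 1327.02),  # unmodified G37-K74
            (4181.1280, 3, 1394.72),  # + one HexNAc
            (0.0, 1, 1.00728),  # bare proton
        ],
    )
    def test_ion_mz_reported_values(self, mass, charge, expected):
        assert round(ion_mz(mass, charge), 2) == pytest.approx(
            round(expected, 2), abs=5e-3
        )

    def test_charge_below_one_rejected(self):
        with pytest.raises(ValueError):
            ion_mz(1000.0, 0)

    def test_charge_consistency(self, rng):
        """z * mz - z * proton recovers the neutral mass for z in 1..4."""
        for _ in range(20):
            m = float(rng.uniform(100, 5000))
            for z in range(1, 5):
                assert neutral_mass(ion_mz(m, z), z) == pytest.approx(m, abs=1e-9)

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError):
            Peptide("", 1, 0)


class TestPairPrecursors:
    def test_known_precursor_pair(self):
        pairs = pair_precursors([(1327.02, 3), (1394.72, 3)], tol_ppm=20)
        assert pairs == [((1327.02, 3), (1394.72, 3))]

    def test_unrelated_ions_do_not_pair(self):
        assert pair_precursors([(500.0, 1), (600.0, 1)]) == []

    def test_cross_charge_pairing(self):
        m = 2000.0
        light = (ion_mz(m, 2), 2)
        heavy = (ion_mz(m + HEXNAC, 3), 3)
        assert pair_precursors([heavy, light], tol_ppm=5) == [(light, heavy)]

    def test_brute_force_oracle_with_planted_pairs(self, rng):
        """pair_precursors equals an all-pairs scan on random ions with
        planted HexNAc pairs."""
        ions = [(float(rng.uniform(400, 1800)), int(rng.integers(1, 4)))
                for _ in range(50)]
        planted = []
        for _ in range(5):
            m = float(rng.uniform(1500, 4000))
            z1, z2 = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            light, heavy = (ion_mz(m, z1), z1), (ion_mz(m + HEXNAC, z2), z2)
            ions += [light, heavy]
            planted.append((light, heavy))

        def brute(ions, delta, tol_ppm):
            out = []
            for a in ions:
                for b in ions:
                    ma, mb = neutral_mass(*a), neutral_mass(*b)
                    if abs(mb - ma - delta) <= tol_ppm * 1e-6 * mb:
                        out.append((a, b))
            return sorted(out, key=lambda p: neutral_mass(*p[0]))

        got = pair_precursors(ions, HEXNAC, 10.0)
        assert got == brute(ions, HEXNAC, 10.0)
        for pair in planted:
            assert pair in got


class TestTheoreticalFragments:
    def test_y1_of_g37_k74(self, g37k74):
        ions = theoretical_fragments(g37k74, max_charge=1)
        y1 = next(i for i in ions if i.series == "y" and i.index_y == 1)
        assert y1.mz == pytest.approx(147.11280, abs=1e-4)
        assert y1.composition_span == (38, 38)

    def test_y33_doubly_charged(self, g37k74):
        ions = theoretical_fragments(g37k74, max_charge=2)
        y33 = next(
            i for i in ions
            if i.series == "y" and i.index_y == 33 and i.charge == 2
        )
        assert y33.mz == pytest.approx(1714.9304, abs=1e-3)
        assert y33.composition_span == (6, 38)  # local span of residues 42-74

    def test_internal_y33_b15(self, g37k74):
        ions = theoretical_fragments(g37k74, max_charge=1, include_internal=True)
        ion = next(
            i for i in ions
            if i.series == "internal_by" and i.index_y == 33 and i.index_b == 15
        )
        assert ion.mz == pytest.approx(984.5625, abs=1e-3)
        assert ion.composition_span == (6, 15)

    def test_labile_loss_vs_retained(self, g37k74):
        """With the labile model, fragment masses ignore the HexNAc delta;
        with glycan_retained, site-containing fragments gain exactly 203."""
        modified = Peptide(g37k74.sequence, 37, 74, ((40, HEXNAC, "Gc"),))
        labile = {(i.series, i.index_b, i.index_y, i.charge): i.mz
                  for i in theoretical_fragments(modified, 1)}
        naked = {(i.series, i.index_b, i.index_y, i.charge): i.mz
                 for i in theoretical_fragments(g37k74, 1)}
        assert labile == naked
        retained = {(i.series, i.index_b, i.index_y, i.charge): i.mz
                    for i in theoretical_fragments(modified, 1, glycan_retained=True)}
        # b3 (local 1-3) excludes site local 4; b4 includes it
        assert retained[("b", 3, None, 1)] == pytest.approx(naked[("b", 3, None, 1)])
        assert retained[("b", 4, None, 1)] == pytest.approx(
            naked[("b", 4, None, 1)] + HEXNAC
        )

    def test_by_complementarity(self, rng):
        """b_i + y_{n-i} at z=1 equals M + 2 protons for unmodified peptides."""
        for _ in range(30):
            pep = random_peptide(rng)
            n = len(pep)
            ions = {(i.series, i.index_b, i.index_y): i.mz
                    for i in theoretical_fragments(pep, 1)}
            total = peptide_mass(pep) + 2 * PROTON
            for i in range(1, n):
                b = ions[("b", i, None)]
                y = ions[("y", None, n - i)]
                assert b + y == pytest.approx(total, abs=1e-5)


class TestMatchSpectrum:
    def _spectrum_from(self, ions, shift_ppm=0.0):
        peaks = tuple(sorted(
            (i.mz * (1 + shift_ppm * 1e-6), 100.0) for i in ions
        ))
        return Spectrum(500.0, 2, peaks)

    def test_self_match_zero_error(self, g37k74):
        ions = theoretical_fragments(g37k74, 1)[:10]
        annotated = match_spectrum(self._spectrum_from(ions), ions, 10.0)
        assert len(annotated.matches) == 10
        assert all(abs(err) < 1e-9 for _, _, err in annotated.matches)

    def test_shifted_peaks_do_not_match(self, g37k74):
        ions = theoretical_fragments(g37k74, 1)[:10]
        annotated = match_spectrum(self._spectrum_from(ions, 50.0), ions, 10.0)
        assert annotated.matches == ()

    def test_recovery_under_jitter_and_noise(self, g37k74):
        """>= 95% of true ions matched at 5 ppm jitter with 100 noise peaks."""
        rates = []
        for seed in range(20):
            spectrum, truth = sim_spectrum(
                g37k74, jitter_ppm=5.0, n_noise=100, config=SimConfig(seed)
            )
            ions = theoretical_fragments(g37k74, 2)
            annotated = match_spectrum(spectrum, ions, tol_ppm=20.0)
            matched = {
                (i.series, i.index_b, i.index_y, i.charge)
                for i in annotated.matched_ions()
            }
            hits = sum(
                (i.series, i.index_b, i.index_y, i.charge) in matched
                for i in truth
            )
            rates.append(hits / len(truth))
        assert np.mean(rates) >= 0.95


class TestLocalizeGlycosite:
    def _annotate_pair(self, peptide, unmod_spec, mod_spec, tol=10.0):
        ions = theoretical_fragments(peptide, 3)
        return (
            match_spectrum(unmod_spec, ions, tol),
            match_spectrum(mod_spec, ions, tol),
        )

    def test_y33_confines_site_to_g37_e41(self, g37k74):
        """Modification-specific y33 (z=2,3) -> window 37-41, call Ser40."""
        ions = theoretical_fragments(g37k74, 3)
        y33 = [i for i in ions if i.series == "y" and i.index_y == 33
               and i.charge in (2, 3)]
        shared = [i for i in ions
                  if not (i.series == "y" and i.index_y >= 33)]
        unmod = Spectrum(1327.02, 3, tuple(sorted((i.mz, 1.0) for i in shared)))
        mod = Spectrum(
            1394.72, 3, tuple(sorted((i.mz, 1.0) for i in shared + y33))
        )
        result = localize_glycosite(
            self._annotate_pair(g37k74, unmod, mod), g37k74
        )
        assert result.window == (37, 41)
        assert result.candidate_sites == (40,)
        assert result.call == 40
        assert "y33^2+" in result.evidence and "y33^3+" in result.evidence

    def test_no_specific_ions_is_ambiguous(self, g37k74):
        """Identical spectra: window is the whole peptide, S40 and T59 tie."""
        ions = theoretical_fragments(g37k74, 2)
        spec = Spectrum(1327.02, 3, tuple(sorted((i.mz, 1.0) for i in ions)))
        result = localize_glycosite(
            self._annotate_pair(g37k74, spec, spec), g37k74
        )
        assert result.window == (37, 74)
        assert result.candidate_sites == (40, 59)
        assert result.call == "ambiguous"
        assert result.evidence == ()

    def test_planted_site_on_synthetic_peptide(self):
        """ACSTK with the mod at S3 and a full specific y-ladder calls 3."""
        pep = Peptide("ACSTK", 1, 5)
        unmod, mod = sim_localization_pair(pep, 3, config=SimConfig(7))
        result = localize_glycosite(self._annotate_pair(pep, unmod, mod), pep)
        assert result.call == 3

    def test_recovery_noiseless_and_noisy(self, g37k74):
        """Planted-site recovery: 100% noiseless; >= 90% at 5 ppm + noise."""
        noiseless = noisy = 0
        for seed in range(20):
            u, m = sim_localization_pair(g37k74, 40, config=SimConfig(seed))
            res = localize_glycosite(self._annotate_pair(g37k74, u, m), g37k74)
            noiseless += res.call == 40
            u, m = sim_localization_pair(
                g37k74, 40, jitter_ppm=5.0, n_noise=100, config=SimConfig(seed)
            )
            # match at ~4 sigma of the jitter so shared ions are not lost
            # from one spectrum by chance and misread as specific
            res = localize_glycosite(
                self._annotate_pair(g37k74, u, m, tol=20.0), g37k74
            )
            noisy += res.call == 40
        assert noiseless == 20
        assert noisy >= 18
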