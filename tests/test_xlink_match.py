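"""In-silico digestion, crosslink enumeration and isotope-coded selection."""

import itertools

import numpy as np
import pytest
from pyteomics import mass as pytmass

from spychap import synthetic_data as sd
from spychap import xlink_match as xl
from spychap.constants import HYDROGEN_MONO, N15_N14_MASS_DIFF, WATER_MONO
from spychap.errors import InvalidInputError


class TestDigest:
    def test_trypsin_basic(self):
        frags = xl.digest("MKRA", xl.TRYPSIN)
        assert sorted(f.sequence for f in frags) == ["A", "MK", "R"]

    def test_trypsin_missed_cleavages(self):
        frags = xl.digest("MKRA", xl.TRYPSIN, max_missed=1)
        assert sorted(f.sequence for f in frags) == ["A", "MK", "MKR", "R", "RA"]

    def test_trypsin_cleaves_before_proline(self):
        # R-P junctions are cleaved (no proline exception)
        frags = xl.digest("ARPAAKG", xl.TRYPSIN)
        assert sorted(f.sequence for f in frags) == ["AR", "G", "PAAK"]

    def test_proteinase_k_matches_substring_enumeration(self):
        seq = "MKRAGW"
        frags = xl.digest(seq, xl.PROTEINASE_K, min_len=3, max_len=4)
        expected = sorted(
            seq[i:i + L]
            for L in (3, 4)
            for i in range(len(seq) - L + 1)
        )
        assert sorted(f.sequence for f in frags) == expected
        assert len(frags) == 7

    def test_coordinates_map_back_to_parent(self):
        seq = "MKRAGWKLPESTR"
        for enzyme, kwargs in [
            (xl.TRYPSIN, {"max_missed": 2}),
            (xl.PROTEINASE_K, {"min_len": 2, "max_len": 5}),
        ]:
            for f in xl.digest(seq, enzyme, **kwargs):
                assert seq[f.start - 1:f.end] == f.sequence

    def test_trypsin_fragments_reconstitute_parent(self):
        seq = "MKRAGWKLPESTR"
        frags = xl.digest(seq, xl.TRYPSIN, max_missed=0)
        joined = "".join(f.sequence for f in sorted(frags, key=lambda f: f.start))
        assert joined == seq

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            xl.digest("", xl.TRYPSIN)
        with pytest.raises(InvalidInputError):
            xl.digest("MKR", xl.TRYPSIN, max_missed=-1)
        with pytest.raises(InvalidInputError):
            xl.digest("MKXR", xl.TRYPSIN)


class TestMassAndComposition:
    def test_glycine_monoisotopic(self):
        assert xl.peptide_mass("G") == pytest.approx(75.03203, abs=1e-5)

    @pytest.mark.parametrize(
        "seq, n", [("SISD", 4), ("KR", 6), ("QNH", 3 + 1 + 1 + 2), ("W", 2)]
    )
    def test_nitrogen_counts(self, seq, n):
        assert xl.peptide_nitrogens(seq) == n

    def test_nitrogens_at_least_length(self):
        for seq in ("SISD", "MKRAGW", "PEPTIDE"):
            assert xl.peptide_nitrogens(seq) >= len(seq)

    def test_crosslink_mass_additivity_vs_elemental_oracle(self):
        """Candidate masses agree with an independent elemental-composition
        calculation of the condensed pair."""
        pa = xl.PeptideFragment("A", 1, 2, "KA")
        pb = xl.PeptideFragment("B", 1, 2, "EG")
        cands = xl.enumerate_candidates([pa], [pb], "EDC", protein_b_length=2)
        comp = (
            pytmass.Composition(sequence="KA")
            + pytmass.Composition(sequence="EG")
            - pytmass.Composition(formula="H2O")
        )
        oracle = pytmass.calculate_mass(composition=comp)
        for c in cands:
            # fast_mass and the elemental route agree to sub-ppm
            assert c.theoretical_mass == pytest.approx(oracle, abs=1e-5)


class TestEnumerateCandidates:
    def test_cbdps_requires_amines(self):
        pa = xl.PeptideFragment("A", 5, 8, "ASTG")
        pb = xl.PeptideFragment("B", 3, 6, "SDEV")
        assert xl.enumerate_candidates([pa], [pb], "CBDPS", 500.0) == []

    def test_picup_single_tyrosine_pair(self):
        pa = xl.PeptideFragment("A", 1, 3, "AYA")
        pb = xl.PeptideFragment("B", 1, 3, "GYG")
        cands = xl.enumerate_candidates([pa], [pb], "PICUP")
        assert len(cands) == 1
        expected = xl.peptide_mass("AYA") + xl.peptide_mass("GYG") - 2 * HYDROGEN_MONO
        assert cands[0].theoretical_mass == pytest.approx(expected, abs=1e-9)
        assert (cands[0].linked_residue_a, cands[0].linked_residue_b) == (2, 2)

    def test_edc_sites_include_protein_cterm(self):
        pa = xl.PeptideFragment("A", 1, 2, "KA")
        pb = xl.PeptideFragment("B", 1, 2, "EG")
        cands = xl.enumerate_candidates([pa], [pb], "EDC", protein_b_length=2)
        linked_b = sorted(c.linked_residue_b for c in cands)
        assert linked_b == [1, 2]  # E side chain and the C-terminal carboxyl
        expected = xl.peptide_mass("KA") + xl.peptide_mass("EG") - WATER_MONO
        assert all(c.theoretical_mass == pytest.approx(expected) for c in cands)

    def test_cbdps_nterm_alpha_amine_counts(self):
        pa = xl.PeptideFragment("A", 1, 4, "ASTG")  # protein N-terminal peptide
        pb = xl.PeptideFragment("B", 2, 5, "AKTG")
        cands = xl.enumerate_candidates([pa], [pb], "CBDPS", 500.0)
        assert len(cands) == 1
        assert cands[0].linked_residue_a == 1
        assert cands[0].isotope_delta == pytest.approx(8.05)

    def test_unknown_chemistry(self):
        with pytest.raises(InvalidInputError):
            xl.enumerate_candidates([], [], "DSSO")


class TestIsotopePairSelect:
    def test_cbdps_delta(self):
        pairs = xl.isotope_pair_select(
            [(1000.000, 1.0), (1008.050, 0.5)], "cbdps", tol=0.01
        )
        assert len(pairs) == 1

    def test_abas_delta(self):
        pairs = xl.isotope_pair_select(
            [(1000.000, 1.0), (1006.020, 0.5)], "abas", tol=0.01
        )
        assert len(pairs) == 1

    def test_n15_delta_from_nitrogen_count(self):
        n = xl.peptide_nitrogens("SISD")
        assert n == 4
        delta = n * N15_N14_MASS_DIFF
        assert delta == pytest.approx(3.98814, abs=1e-5)
        pairs = xl.isotope_pair_select(
            [(1000.000, 1.0), (1000.0 + 3.988, 0.5)], "n15",
            candidate_nitrogens=4, tol=0.01,
        )
        assert len(pairs) == 1

    def test_n15_requires_nitrogen_count(self):
        with pytest.raises(InvalidInputError):
            xl.isotope_pair_select([(1000.0, 1.0)], "n15")

    def test_n15_delta_strictly_increasing_in_nitrogens(self):
        peptides = ["SISD", "SISDK", "KEIEK", "LKEIEKEN"]
        deltas = [xl.peptide_nitrogens(p) * N15_N14_MASS_DIFF for p in peptides]
        ns = [xl.peptide_nitrogens(p) for p in peptides]
        order = np.argsort(ns)
        assert np.all(np.diff(np.asarray(deltas)[order]) > 0)

    def test_perfect_precision_recall_on_spiked_features(self):
        """At zero mass noise, every generated pair and nothing else is
        selected from a feature list with interleaved decoys."""
        pa = xl.digest("MKRAGWK", xl.TRYPSIN, parent="A", max_missed=1,
                       min_len=2, max_len=7)
        pb = xl.digest("AYKES", xl.PROTEINASE_K, parent="B", min_len=3, max_len=4)
        cands = xl.enumerate_candidates(pa, pb, "CBDPS", 509.0)[:5]
        syn = sd.gen_xlink_features(cands, "cbdps")
        decoys = [(700.0 + 13.7 * i, 1.0) for i in range(20)]
        features = list(syn.data) + decoys
        pairs = xl.isotope_pair_select(features, "cbdps", tol=0.001)
        got = {(round(a[0], 4), round(b[0], 4)) for a, b in pairs}
        expected = {
            (round(c.theoretical_mass, 4), round(c.theoretical_mass + 8.05, 4))
            for c in cands
        }
        assert got == expected


class TestMatchObserved:
    def _candidate(self, mass=2000.0):
        pa = xl.PeptideFragment("A", 1, 3, "AYA")
        pb = xl.PeptideFragment("B", 1, 3, "GYG")
        c = xl.enumerate_candidates([pa], [pb], "PICUP")[0]
        return c

    def test_exact_match_zero_ppm(self):
        c = self._candidate()
        hits = xl.match_observed([c], c.theoretical_mass, ppm_tol=10)
        assert len(hits) == 1 and hits[0].ppm_error == pytest.approx(0.0, abs=1e-9)

    def test_outside_tolerance_excluded(self):
        c = self._candidate()
        off = c.theoretical_mass * (1 + 20e-6)  # 2x a 10 ppm tolerance
        assert xl.match_observed([c], off, ppm_tol=10) == []

    def test_true_pair_ranked_first_among_decoys(self):
        """A +0.5 ppm true candidate outranks 1000 random-mass decoys."""
        rng = np.random.default_rng(42)
        true = self._candidate()
        observed = true.theoretical_mass * (1 + 0.5e-6)
        decoys = []
        for i, m in enumerate(rng.uniform(500.0, 4000.0, 1000)):
            frag = xl.PeptideFragment("A", 1, 3, "AYA")
            decoys.append(
                xl.CrosslinkCandidate(
                    peptide_a=frag, peptide_b=frag,
                    linked_residue_a=2, linked_residue_b=2,
                    chemistry="PICUP", theoretical_mass=float(m),
                )
            )
        hits = xl.match_observed(decoys + [true], observed, ppm_tol=50.0)
        assert hits[0].theoretical_mass == true.theoretical_mass
        assert abs(hits[0].ppm_error) == pytest.approx(0.5, abs=1e-6)

    def test_report_table_shape(self):
        c = self._candidate()
        hits = xl.match_observed([c], c.theoretical_mass, ppm_tol=10)
        table = xl.candidates_to_table(hits)
        for col in ("mass_da", "delta_ppm", "start_1", "end_1", "residue_1",
                    "sequence_1", "chemistry"):
            assert col in table.columns
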