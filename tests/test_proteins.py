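"""Physicochemical profiling: MW, charge/pI, motif scans, composition."""

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings
from hypothesis import strategies as st

from phakit import (
    aa_composition,
    compute_mw,
    compute_pi,
    count_aakp,
    net_charge,
    read_fasta,
    scan_phac_box,
    segment_profile,
)
from phakit.proteins import ProteinRecord
from phakit.simulate import ProteinSpec, gen_protein

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=120)


class TestReadFasta:
    def test_single_record(self, write_fasta):
        recs = read_fasta(write_fasta([("x", "MKV")]))
        assert len(recs) == 1
        assert recs[0].id == "x" and recs[0].sequence == "MKV"

    def test_wrapped_sequence_concatenated(self, write_fasta):
        seq = "MKV" * 50
        recs = read_fasta(write_fasta([("wrapped", seq)], wrap=60))
        assert recs[0].sequence == seq

    def test_lowercase_and_stop_symbol_normalized(self, write_fasta):
        recs = read_fasta(write_fasta([("y", "mkvv*")]))
        assert recs[0].sequence == "MKVV"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(p)

    def test_duplicate_ids_rejected_by_name(self, write_fasta):
        path = write_fasta([("dup", "MKV"), ("dup", "MKA")])
        with pytest.raises(ValueError, match="dup"):
            read_fasta(path)

    def test_ambiguity_codes_parse_but_fail_mw_pi(self, write_fasta):
        rec = read_fasta(write_fasta([("amb", "MKB")]))[0]
        assert rec.sequence == "MKB"
        with pytest.raises(ValueError, match="'B' at position 3"):
            compute_mw(rec.sequence)
        with pytest.raises(ValueError, match="'B'"):
            compute_pi(rec.sequence)


class TestMolecularWeight:
    def test_single_glycine(self):
        # glycine average residue mass 57.0519 Da plus one water
        assert compute_mw("G") == pytest.approx(0.07507, abs=1e-5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_mw("")

    @given(s1=peptides, s2=peptides)
    @settings(max_examples=50, deadline=None)
    def test_additivity_minus_one_water(self, s1, s2):
        water_kda = 18.01524e-3
        assert compute_mw(s1 + s2) == pytest.approx(
            compute_mw(s1) + compute_mw(s2) - water_kda, abs=1e-9)

    def test_agrees_with_biopython_average_masses(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                     size=rng.integers(10, 500)))
            bp = ProteinAnalysis(seq).molecular_weight() / 1000.0
            assert compute_mw(seq) == pytest.approx(bp, rel=2e-4)


class TestChargeAndPi:
    def test_fully_protonated_at_ph0_deprotonated_at_ph14(self):
        for seq in ("MKV", "DDDD", "KKKK", "ACDEFGHIKLMNPQRSTVWY"):
            assert net_charge(seq, 0.0) > 0
            assert net_charge(seq, 14.0) < 0

    @given(seq=peptides, ph=st.floats(0.5, 13.0))
    @settings(max_examples=80, deadline=None)
    def test_charge_strictly_decreasing_in_ph(self, seq, ph):
        assert net_charge(seq, ph) > net_charge(seq, ph + 0.5)

    def test_poly_lysine_is_strongly_basic(self):
        assert compute_pi("KKKKKKKKKK") > 10

    def test_charge_at_pi_below_tolerance(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                     size=rng.integers(5, 200)))
            assert abs(net_charge(seq, compute_pi(seq))) < 1e-4

    def test_matches_dense_grid_oracle(self):
        # independent oracle: zero crossing of the charge curve located
        # on a 1e-4-step pH grid
        rng = np.random.default_rng(17)
        grid = np.arange(0.0, 14.0001, 1e-4)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                     size=rng.integers(5, 200)))
            charges = np.array([net_charge(seq, p) for p in grid[::100]])
            i = int(np.argmax(charges <= 0))  # coarse bracket, 0.01 steps
            fine = grid[(grid >= grid[::100][i - 1]) & (grid <= grid[::100][i])]
            qs = np.array([net_charge(seq, p) for p in fine])
            oracle = float(fine[np.argmin(np.abs(qs))])
            assert compute_pi(seq) == pytest.approx(oracle, abs=0.01)

    def test_matches_biopython_with_terminal_adjustments(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                     size=rng.integers(10, 400)))
            mine = compute_pi(seq, terminal_adjustments=True)
            if not 4.2 < mine < 11.8:   # biopython clamps to [4.05, 12]
                continue
            assert mine == pytest.approx(
                ProteinAnalysis(seq).isoelectric_point(), abs=0.01)

    def test_unknown_pka_set_rejected(self):
        with pytest.raises(ValueError, match="unknown pKa set"):
            compute_pi("MKV", pka_set="nosuch")


class TestMotifScans:
    @pytest.mark.parametrize("seq, expected", [
        ("AASYCIGAA", [("phac_box_5", 3, "SYCIG")]),
        ("AGNCQAGA", [("phac_box_6", 2, "GNCQAG")]),
        ("AAAAA", []),
        # a 6-mer match suppresses the 5-mer starting at the same residue
        ("SYCIGG", [("phac_box_6", 1, "SYCIGG")]),
        ("GYCLGMSYCVG", [("phac_box_5", 1, "GYCLG"),
                         ("phac_box_5", 7, "SYCVG")]),
    ])
    def test_phac_box_examples(self, seq, expected):
        hits = [(h.motif_name, h.start, h.matched_seq)
                for h in scan_phac_box(seq)]
        assert hits == expected

    def test_catalytic_cysteine_invariant(self):
        for h in scan_phac_box("AASYCIGAAGNCQAGA"):
            assert h.catalytic_cys_index == h.start + 2
            assert "AASYCIGAAGNCQAGA"[h.catalytic_cys_index - 1] == "C"
            assert ("AASYCIGAAGNCQAGA"[h.start - 1:
                                       h.start - 1 + len(h.matched_seq)]
                    == h.matched_seq)

    @pytest.mark.parametrize("region, n", [
        ("AAKPAAKP", 2),
        ("AAKAAKP", 1),
        ("AAAKP", 1),
        ("AAKPPP", 1),
        ("", 0),
    ])
    def test_aakp_counting(self, region, n):
        assert count_aakp(region) == n

    @given(pad=st.text(alphabet="GHILMV", max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_aakp_count_invariant_under_nonmatching_prefix(self, pad):
        assert count_aakp(pad + "AAKPAAKP") == 2


class TestSegmentProfile:
    def test_extended_architecture(self, phac2_like):
        record, truth = phac2_like
        prof = segment_profile(record)
        assert prof.length_aa == 993
        assert prof.cterm_length_aa == 380
        assert prof.aakp_count_cterm == truth["n_aakp"]
        assert any(h.start == truth["box_position"]
                   for h in prof.phac_box_hits)
        assert 0 < prof.pi_n_segment < 14 and 0 < prof.pi_c_segment < 14

    def test_basic_cterm_raises_pi_above_catalytic_segment(self, phac2_like):
        # the Lys/Arg-enriched tail must be markedly more basic
        record, _ = phac2_like
        prof = segment_profile(record)
        assert prof.pi_c_segment - prof.pi_n_segment > 3

    def test_short_sequence_gives_catalytic_only_profile(self):
        rec = ProteinRecord(id="short", sequence="MKV" * 33 + "A")  # 100 aa
        prof = segment_profile(rec)
        assert prof.pi_c_segment is None
        assert prof.cterm_length_aa == 0

    def test_invalid_boundary_rejected(self, phac2_like):
        with pytest.raises(ValueError, match="boundary"):
            segment_profile(phac2_like[0], boundary=0)


class TestClassification:
    def test_extended_variant_called_on_large_box_positive(self, phac2_like):
        prof = segment_profile(phac2_like[0])
        assert prof.variant_call == "phac2_extended"

    def test_ordinary_class_i_size_range(self):
        rec, _ = gen_protein(ProteinSpec(seed=9, catalytic_len=630,
                                         cterm_len=0, box_motif="GYCLG",
                                         n_aakp=0))
        prof = segment_profile(rec, boundary=613)
        assert 55 <= prof.mw_kda <= 80
        assert prof.variant_call == "phac1_like"

    def test_no_box_means_unclassified(self):
        rec = ProteinRecord(id="nobox", sequence="MKVLDETQ" * 40)
        prof = segment_profile(rec, boundary=100)
        assert not prof.phac_box_hits
        assert prof.variant_call == "unclassified"


class TestComposition:
    def test_pure_basic_region(self):
        comp = aa_composition("KKRR")
        assert comp.group_fractions["positive_kr"] == 1.0

    def test_pure_small_nonpolar_region(self):
        comp = aa_composition("GAGA")
        assert comp.group_fractions["small_nonpolar"] == 1.0

    @given(seq=peptides)
    @settings(max_examples=50, deadline=None)
    def test_fractions_partition_to_one(self, seq):
        comp = aa_composition(seq)
        assert sum(comp.fractions.values()) == pytest.approx(1, abs=1e-9)
        assert sum(comp.group_fractions.values()) == pytest.approx(1, abs=1e-9)

    def test_planted_kr_enrichment_recovered(self, phac2_like):
        record, truth = phac2_like
        comp = aa_composition(record.sequence[truth["catalytic_len"]:])
        kr = comp.group_fractions["positive_kr"]
        assert kr == pytest.approx(truth["cterm_kr_fraction"], abs=1e-9)
        assert kr == pytest.approx(0.20, abs=0.03)
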