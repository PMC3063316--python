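import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsedit import (
    EditingSite,
    HexamerSet,
    ScoringMatrix,
    TranscriptFeature,
    ValidationError,
    apply_edit,
    classify_region,
    diff_ese,
    diff_ess,
    load_bundled_hexamers,
    load_bundled_matrices,
    scan_ese,
    scan_ess,
    translate_codon_change,
)
from tsedit.effects import load_hexamers, load_matrix, require_supported

seqs = st.text(alphabet="ACGT", min_size=1, max_size=30)

TOY_MATRIX = ScoringMatrix(
    "toy", np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]]), threshold=1.5
)
FOUR_HEXAMERS = HexamerSet(
    "four", frozenset({"GGGAGG", "TAGGTA", "TTAGGT", "CTTAGG"})
)


class TestApplyEdit:
    def test_single_substitution(self):
        assert apply_edit("TAGGTA", 2) == "TGGGTA"

    def test_single_base(self):
        assert apply_edit("A", 1) == "G"

    def test_non_adenosine_rejected_reporting_base(self):
        with pytest.raises(ValidationError, match="'G'"):
            apply_edit("TTAGGT", 4)

    def test_position_out_of_range(self):
        with pytest.raises(ValidationError):
            apply_edit("ACGT", 5)


class TestScanEse:
    def test_all_zero_matrix_below_threshold(self):
        zero = ScoringMatrix("zero", np.zeros((3, 4)), threshold=0.1)
        assert scan_ese("ACGTACGTACGT", zero) == []

    def test_toy_matrix_hand_scored(self, toy_matrix):
        # windows: "AA" = 1, "AG" = 2; only "AG" reaches threshold 1.5
        hits = scan_ese("AAG", toy_matrix)
        assert [(h.start, h.score) for h in hits] == [(2, 2.0)]

    def test_threshold_above_max_score(self, toy_matrix):
        high = ScoringMatrix("toy", toy_matrix.weights, threshold=2.5)
        assert scan_ese("AAG", high) == []

    def test_sequence_shorter_than_width_empty(self, toy_matrix):
        assert scan_ese("A", toy_matrix) == []

    def test_equality_counts_as_functional(self, toy_matrix):
        exact = ScoringMatrix("toy", toy_matrix.weights, threshold=2.0)
        assert [h.start for h in scan_ese("AG", exact)] == [1]

    @given(seq=seqs)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_count_completeness(self, seq):
        from tsedit.effects import _window_scores

        assert len(_window_scores(seq, TOY_MATRIX)) == max(0, len(seq) - 2 + 1)


class TestDiffEse:
    def test_edit_destroys_functional_window(self, toy_matrix):
        # "AAG" -> "AGG": window 2 "AG" (score 2) decays to "GG" (score 1),
        # while window 1 "AA" (score 1) rises to "AG" (score 2)
        lost, gained = diff_ese("AAG", 2, [toy_matrix])
        assert [(h.start, h.motif) for h in lost] == [(2, "toy")]
        assert [(h.start, h.score) for h in gained] == [(1, 2.0)]

    def test_edit_far_from_any_hit_changes_nothing(self, toy_matrix):
        lost, gained = diff_ese("AGCCCCCA", 8, [toy_matrix])
        assert lost == [] and gained == []

    def test_edit_creates_functional_window(self):
        w = np.full((2, 4), 0.0)
        w[0, 2] = 2.0  # reward G at position 1
        w[1, 2] = 1.0
        m = ScoringMatrix("gain", w, threshold=2.5)
        # "AG" scores 1 -> edit position 1 -> "GG" scores 3
        lost, gained = diff_ese("AG", 1, [m])
        assert lost == [] and [(h.start, h.score) for h in gained] == [(1, 3.0)]

    @given(seq=seqs, data=st.data())
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_diff_locality_non_overlapping_hits_unchanged(self, seq, data):
        """Editing position p leaves every window not spanning p identical."""
        from tsedit.effects import _window_scores

        a_positions = [i + 1 for i, ch in enumerate(seq) if ch == "A"]
        if not a_positions:
            return
        pos = data.draw(st.sampled_from(a_positions))
        before = _window_scores(seq, TOY_MATRIX)
        after = _window_scores(apply_edit(seq, pos), TOY_MATRIX)
        for i, (s0, s1) in enumerate(zip(before, after)):
            if not (i + 1 <= pos <= i + 2):
                assert s0 == s1


class TestScanEss:
    def test_overlapping_hexamers_both_reported(self, paper_hexamers):
        hits = scan_ess("TTAGGTA", paper_hexamers)
        assert [(h.start, h.motif) for h in hits] == [(1, "TTAGGT"), (2, "TAGGTA")]

    def test_no_match(self, paper_hexamers):
        assert scan_ess("CCCCCCC", paper_hexamers) == []

    def test_sequence_shorter_than_six(self, paper_hexamers):
        assert scan_ess("TTAGG", paper_hexamers) == []


class TestDiffEss:
    def test_edit_destroys_overlapping_hexamers(self, paper_hexamers):
        # TTAGGTA -> TTGGGTA at position 3 removes both silencers
        lost, gained = diff_ess("TTAGGTA", 3, paper_hexamers)
        assert {h.motif for h in lost} == {"TTAGGT", "TAGGTA"}
        assert gained == []

    def test_edit_creates_hexamer(self, paper_hexamers):
        lost, gained = diff_ess("GGAAGG", 3, paper_hexamers)
        assert lost == [] and [(h.start, h.motif) for h in gained] == [(1, "GGGAGG")]

    def test_edit_far_from_hits(self, paper_hexamers):
        lost, gained = diff_ess("GGGAGGCCCCA", 11, paper_hexamers)
        assert lost == [] and gained == []

    @given(seq=st.text(alphabet="ACGT", min_size=6, max_size=30), data=st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_brute_force_rescan_oracle(self, seq, data):
        """diff equals the set difference of full scans restricted to
        windows covering the edited position."""
        a_positions = [i + 1 for i, ch in enumerate(seq) if ch == "A"]
        if not a_positions:
            return
        pos = data.draw(st.sampled_from(a_positions))
        lost, gained = diff_ess(seq, pos, FOUR_HEXAMERS)
        before = {h for h in scan_ess(seq, FOUR_HEXAMERS)
                  if h.start <= pos <= h.start + 5}
        after = {h for h in scan_ess(apply_edit(seq, pos), FOUR_HEXAMERS)
                 if h.start <= pos <= h.start + 5}
        assert set(lost) == before - after
        assert set(gained) == after - before


STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class TestTranslateCodonChange:
    def test_serine_to_glycine_recoding(self):
        change = translate_codon_change("AGC", 1)
        assert (change.ref_residue, change.protein_position, change.alt_residue) == (
            "S", 1, "G",
        )

    def test_synonymous_third_base(self):
        change = translate_codon_change("GCA", 3)
        assert change.ref_residue == change.alt_residue == "A"
        assert change.synonymous

    def test_met_to_val_at_cds_start(self):
        change = translate_codon_change("ATGTAA", 1)
        assert (change.ref_residue, change.protein_position, change.alt_residue) == (
            "M", 1, "V",
        )

    def test_stop_codons(self):
        still_stop = translate_codon_change("TAA", 2)  # TAA -> TGA
        assert still_stop.ref_residue == "*" and still_stop.alt_residue == "*"
        assert not still_stop.stop_loss
        lost = translate_codon_change("TGA", 3)  # TGA -> TGG, Trp
        assert lost.stop_loss and lost.alt_residue == "W"

    def test_protein_position_is_codon_index(self):
        change = translate_codon_change("ATGGCTAGC", 7)  # AGC is codon 3
        assert change.protein_position == 3

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValidationError, match="multiple of 3"):
            translate_codon_change("ATGA", 4)

    def test_non_adenosine_rejected(self):
        with pytest.raises(ValidationError):
            translate_codon_change("TGC", 2)

    def test_all_codons_against_lookup_oracle(self):
        for codon, ref in STANDARD_CODE.items():
            for offset, base in enumerate(codon):
                if base != "A":
                    continue
                edited = codon[:offset] + "G" + codon[offset + 1 :]
                change = translate_codon_change(codon, offset + 1)
                assert change.ref_residue == ref
                assert change.alt_residue == STANDARD_CODE[edited]
                assert change.protein_position == 1


class TestClassifyRegion:
    FEATURES = [
        TranscriptFeature("tx1", "chr10", "-", 44192900, 44192950, "3UTR"),
        TranscriptFeature("tx2", "chr10", "-", 44192910, 44192960, "intron"),
        TranscriptFeature("tx3", "chr10", "-", 44190000, 44190100, "CDS"),
    ]

    def test_cds_containment(self):
        site = EditingSite("chr10", "-", 44190050)
        assert classify_region(site, self.FEATURES) == [("tx3", "CDS")]

    def test_isoform_dependent_labels_all_reported(self):
        site = EditingSite("chr10", "-", 44192920)
        labels = classify_region(site, self.FEATURES)
        assert labels == [("tx1", "3UTR"), ("tx2", "intron")]

    def test_uncovered_site_intergenic(self):
        site = EditingSite("chr9", "+", 5)
        assert classify_region(site, self.FEATURES) == [(None, "intergenic")]

    def test_strand_mismatch_not_contained(self):
        site = EditingSite("chr10", "+", 44190050)
        assert classify_region(site, self.FEATURES) == [(None, "intergenic")]

    def test_cds_priority_over_intron_within_transcript(self):
        feats = [
            TranscriptFeature("tx", "chr1", "+", 10, 50, "intron"),
            TranscriptFeature("tx", "chr1", "+", 20, 30, "CDS"),
        ]
        assert classify_region(EditingSite("chr1", "+", 25), feats) == [("tx", "CDS")]


class TestResources:
    def test_bundled_hexamer_set_contains_published_four(self):
        hexes = load_bundled_hexamers().hexamers
        assert {"GGGAGG", "TAGGTA", "TTAGGT", "CTTAGG"} <= hexes

    def test_bundled_matrices_shapes_and_thresholds(self):
        mats = {m.name: m for m in load_bundled_matrices()}
        assert mats["SF2/ASF"].width == 7 and mats["SF2/ASF"].threshold == 1.956
        assert mats["SC35"].width == 8 and mats["SC35"].threshold == 2.383
        assert mats["SRp40"].width == 7 and mats["SRp40"].threshold == 2.67
        assert mats["SRp55"].width == 6 and mats["SRp55"].threshold == 2.676

    def test_matrix_file_round_trip(self, tmp_path, toy_matrix):
        p = tmp_path / "toy.tsv"
        p.write_text(
            "# name: toy\n# threshold: 1.5\nA\tC\tG\tT\n"
            "1.0\t0.0\t0.0\t0.0\n0.0\t0.0\t1.0\t0.0\n"
        )
        m = load_matrix(p)
        assert m.width == 2 and np.allclose(m.weights, toy_matrix.weights)

    def test_hexamer_file_loader_validates(self, tmp_path):
        p = tmp_path / "h.txt"
        p.write_text("GGGAGG\nbadhex\n")
        with pytest.raises(ValidationError):
            load_hexamers(p)

    def test_external_predictor_analyses_raise(self):
        with pytest.raises(NotImplementedError, match="external"):
            require_supported("phosphorylation")
        require_supported("ese")  # supported path is a no-op


class TestFeatureFiles:
    def test_tsv_features(self, tmp_path):
        from tsedit.effects import read_features

        p = tmp_path / "f.tsv"
        p.write_text(
            "transcript_id\tchrom\tstrand\tstart\tend\tlabel\n"
            "tx1\tchr1\t+\t100\t200\tCDS\n"
        )
        feats = read_features(p)
        assert feats == [TranscriptFeature("tx1", "chr1", "+", 100, 200, "CDS")]

    def test_gff3_cds_and_derived_intron(self, tmp_path):
        from tsedit.effects import read_features

        p = tmp_path / "f.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=tx1\n"
            "chr1\tsrc\texon\t100\t200\t.\t+\t.\tID=e1;Parent=tx1\n"
            "chr1\tsrc\texon\t300\t500\t.\t+\t.\tID=e2;Parent=tx1\n"
            "chr1\tsrc\tCDS\t150\t400\t.\t+\t0\tID=c1;Parent=tx1\n"
        )
        feats = read_features(p)
        assert TranscriptFeature("tx1", "chr1", "+", 150, 400, "CDS") in feats
        assert TranscriptFeature("tx1", "chr1", "+", 201, 299, "intron") in feats
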