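"""ORF prediction, the 50-nt NMD boundary and the instability index."""

import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils import ProtParamData

from ampliso.orf import (
    OrfParams, classify_novel_exon_consequence, instability_index,
    last_junction_tc, predict_orf, spliced_sequence,
)

from conftest import make_model


class FakeGenome(dict):
    pass


def build_two_exon_gene(exon1_cds: str, exon2_cds: str, gap: int = 100):
    """Plus-strand two-exon toy gene; returns (model, genome, start, stop)."""
    seq1 = "ATG" + exon1_cds
    seq2 = exon2_cds
    genome_seq = "A" * 10 + seq1 + "N" * gap + seq2 + "A" * 10
    e1 = (10, 10 + len(seq1))
    e2 = (10 + len(seq1) + gap, 10 + len(seq1) + gap + len(seq2))
    model = make_model([e1, e2], chrom="c")
    return model, FakeGenome(c=genome_seq), e1[0]


class TestSplicedSequence:
    def test_plus_strand_concatenation(self):
        g = FakeGenome(c="xxATGxxxxTAAxx")
        model = make_model([(2, 5), (9, 12)], chrom="c")
        assert spliced_sequence(model, g) == "ATGTAA"

    def test_minus_strand_reverse_complement(self):
        g = FakeGenome(c="xxATGxxxxTAAxx")
        model = make_model([(2, 5), (9, 12)], chrom="c", strand="-")
        assert spliced_sequence(model, g) == "TTACAT"

    def test_single_exon_substring(self):
        g = FakeGenome(c="ACGTACGT")
        assert spliced_sequence(make_model([(2, 6)], chrom="c"), g) == "GTAC"


def _nmd_case(distance: int):
    """Two-exon transcript with a PTC exactly ``distance`` nt upstream of the
    final junction (measured from the first base of the stop codon)."""
    # exon1: ATG + filler + TGA + tail so that junction - stop_start == distance
    filler_codons = 40
    tail = distance - 3  # bases between the stop codon's end and the junction
    assert tail >= 0
    exon1_cds = "GCT" * filler_codons + "TGA" + "C" * tail
    model, genome, start = build_two_exon_gene(exon1_cds, "GGGTAG" + "G" * 60)
    return model, genome, start


class TestNmdRule:
    @pytest.mark.parametrize(
        "distance,verdict",
        [
            (100, "likely_NMD"),
            (51, "likely_NMD"),
            (50, "NMD_escape_lastexon_proximal"),
            (49, "NMD_escape_lastexon_proximal"),
            (35, "NMD_escape_lastexon_proximal"),
            (3, "NMD_escape_lastexon_proximal"),
        ],
    )
    def test_boundary(self, distance, verdict):
        model, genome, start = _nmd_case(distance)
        res = predict_orf(model, genome, start, None)
        assert res.verdict == verdict
        assert res.ptc_distance_to_last_junction == distance

    def test_mono_exon_never_nmd(self):
        g = FakeGenome(c="AA" + "ATG" + "GCT" * 5 + "TGA" + "C" * 200)
        model = make_model([(2, 2 + 3 + 15 + 3 + 200)], chrom="c")
        res = predict_orf(model, g, 2, None)
        assert res.verdict == "coding"
        assert last_junction_tc(model) is None

    def test_stop_in_final_exon_is_coding(self):
        model, genome, start = build_two_exon_gene("GCT" * 10, "GCTTAGGGG")
        res = predict_orf(model, genome, start, None)
        assert res.verdict == "coding"


class TestPredictOrf:
    def test_canonical_transcript_is_coding_with_canonical_length(self):
        exon1 = "GCT" * 10
        model, genome, start = build_two_exon_gene(exon1, "GCTGCT" + "TAG" + "CCC")
        stop_genomic = model.exons[1][0] + 6
        res = predict_orf(model, genome, start, stop_genomic)
        assert res.verdict == "coding"
        assert res.start_policy == "canonical"
        assert res.frame_retained
        assert res.protein_length == 13  # Met + 10 aa in exon1 + 2 in exon2

    def test_alternative_start_fallback(self):
        model, genome, start = build_two_exon_gene("GCT" * 10, "GCTTAGCCC")
        # canonical start position outside the model's exons
        res = predict_orf(
            model, genome, canonical_start=0, canonical_stop=None,
            params=OrfParams(alternative_starts=(start,)),
        )
        assert res.start_policy == "alternative"
        assert res.verdict == "coding"

    def test_longest_orf_fallback_and_unknown(self):
        model, genome, start = build_two_exon_gene("GCT" * 10, "GCTTAGCCC")
        res = predict_orf(model, genome, None, None)
        assert res.start_policy == "longest_orf"
        g = FakeGenome(c="CCCCCCCCCCCCCCCCCCCC")
        model2 = make_model([(2, 18)], chrom="c")
        assert predict_orf(model2, g, None, None).verdict == "unknown"


class TestNovelExonConsequence:
    def _host(self, novel_exon_seq: str, tail_exons=("GCTGCTTAGCCC",)):
        """Three-exon host: ATG exon, novel exon, final exon with stop."""
        seq1 = "ATG" + "GCT" * 6
        parts = ["A" * 10, seq1, "N" * 50, novel_exon_seq, "N" * 50]
        exons = [(10, 10 + len(seq1))]
        pos = 10 + len(seq1) + 50
        exons.append((pos, pos + len(novel_exon_seq)))
        pos += len(novel_exon_seq) + 50
        for t in tail_exons:
            parts.append(t)
            exons.append((pos, pos + len(t)))
            pos += len(t)
        parts.append("A" * 10)
        genome = FakeGenome(c="".join(parts))
        model = make_model(exons, chrom="c")
        stop_g = exons[-1][0] + 6
        return model, genome, exons[0][0], stop_g, tuple(exons[1])

    def test_frame_preserving_exon_is_orf(self):
        # 42-nt exon, length divisible by 3, no stop codons
        model, genome, start, stop, ne = self._host("GCA" * 14)
        assert classify_novel_exon_consequence(ne, model, genome, start, stop) == "ORF"

    def test_ptc_far_from_junction(self):
        model, genome, start, stop, ne = self._host(
            "TAG" + "C" * 55, tail_exons=("GCTGCTTAGCCC",)
        )
        assert classify_novel_exon_consequence(ne, model, genome, start, stop) == "PTC"

    def test_ptc_within_window(self):
        # stop 35 nt from the final junction: 32 exon bases after the stop
        # codon plus nothing else upstream of the last junction
        model, genome, start, stop, ne = self._host("TAG" + "C" * 32)
        assert classify_novel_exon_consequence(ne, model, genome, start, stop) == "PTC(<50nt)"

    def test_utr_exon(self):
        # stop before the novel exon: exon sits in the 3' UTR
        seq1 = "ATG" + "GCT" * 3 + "TGATTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTT"
        genome = FakeGenome(c="A" * 10 + seq1 + "N" * 50 + "GGGGGG" + "N" * 50 + "CCCTAGCCC")
        e1 = (10, 10 + len(seq1))
        e2 = (e1[1] + 50, e1[1] + 50 + 6)
        e3 = (e2[1] + 50, e2[1] + 50 + 9)
        model = make_model([e1, e2, e3], chrom="c")
        out = classify_novel_exon_consequence(e2, model, genome, 10, None)
        assert out == "UTR"

    def test_exon_not_in_model_is_an_error(self):
        model, genome, start, stop, ne = self._host("GCA" * 14)
        with pytest.raises(ValueError):
            classify_novel_exon_consequence((1, 5), model, genome, start, stop)


class TestInstabilityIndex:
    def test_dipeptide_closed_form(self):
        w = ProtParamData.DIWV["W"]["W"]
        assert instability_index("WW").value == pytest.approx(5 * w)

    def test_homopolymer_closed_form(self):
        # A-A has dipeptide weight 1.0: II = 10 (L-1) / L
        assert ProtParamData.DIWV["A"]["A"] == 1.0
        for L in (2, 5, 50):
            assert instability_index("A" * L).value == pytest.approx(10 * (L - 1) / L)

    @pytest.mark.parametrize("protein", ["MKWVTFISLLFLFSSAYS", "ACDEFGHIKLMNPQRSTVWY", "QQQQR"])
    def test_matches_reference_implementation(self, protein):
        ours = instability_index(protein).value
        theirs = ProteinAnalysis(protein).instability_index()
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_unstable_flag_threshold(self):
        assert not instability_index("A" * 10).unstable  # II < 10

    def test_nonstandard_residue_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            instability_index("ABA")
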