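"""Structural classification, novel-exon detection and splice motifs."""

import itertools

import pytest

from ampliso.classify import (
    classify_isoform, detect_novel_exons, load_novel_exon_validation,
    splice_motif,
)

from conftest import make_model

EXONS = [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)]


def brute_force_classify(model, reference):
    """Independent oracle: enumerate reference junction/site sets explicitly."""
    ref_chains = set()
    junctions = set()
    donors = set()
    acceptors = set()
    ref_introns = set()
    for t in reference:
        chain = tuple((a[1], b[0]) for a, b in zip(t.exons, t.exons[1:]))
        ref_chains.add(chain)
        for j in chain:
            junctions.add(j)
            donors.add(j[0])
            acceptors.add(j[1])
            ref_introns.add(j)
    chain = tuple((a[1], b[0]) for a, b in zip(model.exons, model.exons[1:]))
    if chain in ref_chains:
        return "FSM", "none"
    any_novel_site = any(s not in donors or e not in acceptors for s, e in chain)
    if any_novel_site:
        return "NNC", "ALO"
    has_ir = any(
        ex[0] < i[0] and i[1] < ex[1] for ex in model.exons for i in ref_introns
    )
    if has_ir:
        return "NIC", "IR"
    any_novel_junction = any(j not in junctions for j in chain)
    return ("NIC", "COS") if any_novel_junction else ("NIC", "COJ")


class TestClassifyIsoform:
    def test_fsm(self, toy_reference):
        model = make_model(EXONS)
        call = classify_isoform(model, toy_reference)
        assert (call.category, call.subcategory) == ("FSM", "none")

    def test_exon_skip_coj_when_junction_annotated_elsewhere(self, toy_reference):
        # e1-e3-e5: junction e1->e3 exists in tC and e3->e5 in tB, but no
        # reference transcript has this chain -> recombination of known
        # junctions
        model = make_model([EXONS[0], EXONS[2], EXONS[4]])
        call = classify_isoform(model, toy_reference)
        assert (call.category, call.subcategory) == ("NIC", "COJ")

    def test_exon_skip_cos_when_sites_known_junction_not(self, toy_reference):
        # skipping e3: donor 400 and acceptor 700 are both annotated but never
        # paired in any reference transcript
        model = make_model([EXONS[0], EXONS[1], EXONS[3], EXONS[4]])
        call = classify_isoform(model, toy_reference)
        assert (call.category, call.subcategory) == ("NIC", "COS")
        assert (400, 700) in call.novel_junctions

    def test_shifted_acceptor_is_nnc_alo(self, toy_reference):
        # acceptor shifted +98 nt from any annotated site
        model = make_model([EXONS[0], (300 + 98, 400), EXONS[2], EXONS[3], EXONS[4]])
        call = classify_isoform(model, toy_reference)
        assert (call.category, call.subcategory) == ("NNC", "ALO")
        assert 398 in call.novel_sites

    def test_retained_intron_is_nic_ir(self, toy_reference):
        # e1 and e2 fused: the exon [100,400) spans the complete e1-e2 intron
        model = make_model([(100, 400), EXONS[2], EXONS[3], EXONS[4]])
        call = classify_isoform(model, toy_reference)
        assert (call.category, call.subcategory) == ("NIC", "IR")
        assert (200, 300) in call.retained_introns

    def test_mono_exon_reported_outside_three_classes(self, toy_reference):
        call = classify_isoform(make_model([(150, 450)]), toy_reference)
        assert call.category == "mono-exon"

    def test_agrees_with_brute_force_oracle(self, toy_reference):
        """Exhaustive comparison over all sub-chains and shifted variants."""
        cases = []
        for r in (2, 3, 4, 5):
            for combo in itertools.combinations(range(5), r):
                cases.append([EXONS[i] for i in combo])
        # site shifts on the internal boundaries
        for delta in (-7, 7):
            cases.append([(100, 200), (300 + delta, 400), (500, 600), (900, 1000)])
            cases.append([(100, 200), (300, 400 + delta), (900, 1000)])
        # retained introns
        cases.append([(100, 400), (500, 600), (900, 1000)])
        cases.append([(100, 200), (300, 600), (700, 800), (900, 1000)])
        n_spliced = 0
        for exons in cases:
            model = make_model(exons)
            if not model.is_spliced:
                continue
            n_spliced += 1
            call = classify_isoform(model, toy_reference)
            assert (call.category, call.subcategory) == brute_force_classify(model, toy_reference), exons
        assert n_spliced > 20

    def test_every_spliced_isoform_gets_exactly_one_category(self, toy_reference):
        for r in (2, 3, 4, 5):
            for combo in itertools.combinations(range(5), r):
                call = classify_isoform(make_model([EXONS[i] for i in combo]), toy_reference)
                assert call.category in {"FSM", "NIC", "NNC"}


class TestNovelExons:
    def test_detection_size_and_label(self, toy_reference):
        # 42-nt exon between e2 (canonical exon 2) and e3
        model = make_model([EXONS[0], EXONS[1], (430, 472), EXONS[2], EXONS[4]])
        out = detect_novel_exons(model, toy_reference)
        assert len(out) == 1
        ne = out[0]
        assert ne.size == 42
        assert (ne.start, ne.end) == (431, 472)  # 1-based inclusive
        assert ne.label == "2a"

    def test_all_overlapping_gives_empty(self, toy_reference):
        assert detect_novel_exons(make_model(EXONS), toy_reference) == []

    def test_partial_overlap_is_not_novel(self, toy_reference):
        model = make_model([(150, 250), EXONS[1]])
        assert detect_novel_exons(model, toy_reference) == []

    def test_invariant_to_reference_order(self, toy_reference):
        model = make_model([EXONS[0], (430, 472), EXONS[2]])
        a = detect_novel_exons(model, toy_reference, canonical_id="tA")
        b = detect_novel_exons(model, list(reversed(toy_reference)), canonical_id="tA")
        assert a == b

    def test_two_novel_exons_between_same_hosts_get_letters(self, toy_reference):
        model = make_model([EXONS[0], (220, 240), (260, 280), EXONS[1]])
        labels = [ne.label for ne in detect_novel_exons(model, toy_reference)]
        assert labels == ["1a", "1b"]

    def test_minus_strand_numbering(self):
        # on the minus strand exon 1 is the rightmost
        ref = [make_model([(100, 200), (300, 400), (500, 600)], strand="-")]
        model = make_model([(100, 200), (230, 260), (300, 400), (500, 600)], strand="-")
        out = detect_novel_exons(model, ref)
        assert [ne.label for ne in out] == ["2a"]


class FakeGenome(dict):
    pass


class TestSpliceMotif:
    GENOME = FakeGenome(chr1="AAAAAGTTTTTTTTAGAAAAA")
    #                        ^ intron [5,16): GT........AG

    def test_canonical_gt_ag_plus(self):
        m = splice_motif((5, 16), self.GENOME, "chr1", "+")
        assert (m.donor, m.acceptor) == ("GT", "AG")
        assert m.canonical

    def test_gc_ag_is_canonical(self):
        g = FakeGenome(chr1="AAAAAGCTTTTTTTAGAAAAA")
        m = splice_motif((5, 16), g, "chr1", "+")
        assert (m.donor, m.acceptor) == ("GC", "AG") and m.canonical

    def test_minus_strand_reverse_complement(self):
        # CT....AC on the forward strand reads GT..AG on the minus strand
        g = FakeGenome(chr1="AAAAACTTTTTTTTACAAAAA")
        m = splice_motif((5, 16), g, "chr1", "-")
        assert (m.donor, m.acceptor) == ("GT", "AG") and m.canonical

    def test_noncanonical_flagged(self):
        g = FakeGenome(chr1="AAAAACTTTTTTTTACAAAAA")
        m = splice_motif((5, 16), g, "chr1", "+")
        assert (m.donor, m.acceptor) == ("CT", "AC") and not m.canonical

    def test_out_of_bounds_is_an_error(self):
        with pytest.raises(ValueError):
            splice_motif((5, 100), self.GENOME, "chr1", "+")


class TestValidationTable:
    def test_sizes_consistent_with_coordinates(self):
        df = load_novel_exon_validation()
        assert (df["size"] == df["end"] - df["start"] + 1).all()
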