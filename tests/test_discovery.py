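"""Splice-site correction and intron-chain collapsing."""

import pytest

from ampliso.discovery import (
    DiscoveryParams, ReferenceSites, collapse_by_chain, correct_splice_sites,
    match_reference_chain, reciprocal_overlap,
)
from ampliso.ingest import AlignedRead

from conftest import make_model


def read_with_blocks(blocks, rid="r", sample="s", strand="+"):
    introns = [(a[1], b[0]) for a, b in zip(blocks, blocks[1:])]
    r = AlignedRead(
        read_id=rid, chrom="chr1", strand=strand, blocks=[tuple(b) for b in blocks],
        introns=introns, accuracy=1.0, sample_id=sample,
    )
    r.validate()
    return r


class TestSpliceCorrection:
    def test_snap_to_annotated_within_window(self):
        reads = [read_with_blocks([(900, 1003), (1100, 1200)])]
        sites = ReferenceSites(starts=frozenset({1000}), ends=frozenset({1100}))
        correct_splice_sites(reads, sites, wobble_nt=5)
        assert reads[0].introns == [(1000, 1100)]
        assert reads[0].blocks == [(900, 1000), (1100, 1200)]

    def test_modal_clustering_away_from_annotation(self):
        """Boundaries with no annotated site nearby snap to the cluster mode."""
        reads = [read_with_blocks([(900, 1010), (1100, 1200)], rid=f"a{i}") for i in range(30)]
        reads += [read_with_blocks([(900, 1008), (1100, 1200)], rid=f"b{i}") for i in range(2)]
        sites = ReferenceSites(starts=frozenset({1000}), ends=frozenset({1100}))
        # 1010 and 1008 are both >5 nt from the annotated 1000
        correct_splice_sites(reads, sites, wobble_nt=5)
        # oracle: brute-force mode of {1010 x30, 1008 x2} within +-5 of each
        assert all(r.introns[0][0] == 1010 for r in reads)

    def test_wobble_zero_is_identity(self):
        reads = [read_with_blocks([(900, 1003), (1100, 1200)])]
        sites = ReferenceSites(starts=frozenset({1000}), ends=frozenset({1100}))
        correct_splice_sites(reads, sites, wobble_nt=0)
        assert reads[0].introns == [(1003, 1100)]

    def test_degenerate_snap_leaves_boundary_and_flags(self):
        # exon between the introns is only 3 nt; snapping would erase it
        reads = [read_with_blocks([(100, 200), (203, 206), (300, 400)])]
        sites = ReferenceSites(starts=frozenset({206}), ends=frozenset({203}))
        # snapping intron1 end 203->? and intron2 start 206->? would collapse
        # the middle exon to nothing
        sites = ReferenceSites(starts=frozenset({200, 207}), ends=frozenset({204, 300}))
        correct_splice_sites(reads, sites, wobble_nt=5)
        r = reads[0]
        r.validate()
        assert all(e > s for s, e in r.blocks)


class TestCollapse:
    def test_single_chain_single_model(self):
        reads = [read_with_blocks([(0, 100), (200, 300)], rid=f"r{i}") for i in range(100)]
        models = collapse_by_chain(reads, DiscoveryParams(), reference=[])
        assert len(models) == 1
        assert models[0].support == 100
        assert models[0].intron_chain == ((100, 200),)

    def test_min_fraction_threshold_arithmetic(self):
        """990 + 10 reads: 10 >= max(3, 0.001 x 1000) so both chains survive."""
        reads = [read_with_blocks([(0, 100), (200, 300)], rid=f"a{i}") for i in range(990)]
        reads += [read_with_blocks([(0, 100), (250, 300)], rid=f"b{i}") for i in range(10)]
        models = collapse_by_chain(
            reads, DiscoveryParams(wobble_nt=0), reference=[]
        )
        assert sorted(m.support for m in models) == [10, 990]

    def test_rare_chain_dropped_at_depth(self):
        """1 supporting read among 10,000: 1 < max(3, 10) -> dropped."""
        reads = [read_with_blocks([(0, 100), (200, 300)], rid=f"a{i}") for i in range(9999)]
        reads += [read_with_blocks([(0, 100), (250, 300)], rid="lone")]
        models = collapse_by_chain(reads, DiscoveryParams(wobble_nt=0), reference=[])
        assert [m.support for m in models] == [9999]

    def test_partition_and_support_bound(self):
        reads = [read_with_blocks([(0, 100), (200, 300)], rid=f"a{i}") for i in range(5)]
        reads += [read_with_blocks([(0, 100), (250, 300)], rid=f"b{i}") for i in range(4)]
        reads += [read_with_blocks([(0, 90)], rid=f"m{i}") for i in range(3)]
        models = collapse_by_chain(reads, DiscoveryParams(), reference=[])
        assert sum(m.support for m in models) <= len(reads)
        # chains are distinct: every read supports at most one model
        chains = [m.intron_chain for m in models if m.is_spliced]
        assert len(chains) == len(set(chains))

    def test_lowering_min_fraction_is_monotone(self):
        reads = [read_with_blocks([(0, 100), (200, 300)], rid=f"a{i}") for i in range(50)]
        reads += [read_with_blocks([(0, 100), (250, 300)], rid=f"b{i}") for i in range(5)]
        strict = collapse_by_chain(
            reads, DiscoveryParams(min_fraction_by_gene=0.5), reference=[]
        )
        loose = collapse_by_chain(
            reads, DiscoveryParams(min_fraction_by_gene=0.001), reference=[]
        )
        assert {m.intron_chain for m in strict} <= {m.intron_chain for m in loose}

    def test_idempotence_of_collapse(self):
        reads = [read_with_blocks([(0, 100), (200, 300), (400, 500)], rid=f"a{i}") for i in range(10)]
        reads += [read_with_blocks([(0, 100), (400, 500)], rid=f"b{i}") for i in range(10)]
        models = collapse_by_chain(reads, DiscoveryParams(), reference=[])
        regen = [read_with_blocks(m.exons, rid=f"g{i}_{j}") for i, m in enumerate(models) for j in range(5)]
        again = collapse_by_chain(regen, DiscoveryParams(), reference=[])
        assert {m.intron_chain for m in again} == {m.intron_chain for m in models}

    def test_novel_naming_by_support_rank(self):
        ref = [make_model([(0, 100), (200, 300)], isoform_id="ENST1")]
        reads = [read_with_blocks([(0, 100), (200, 300)], rid=f"a{i}") for i in range(20)]
        reads += [read_with_blocks([(0, 100), (250, 300)], rid=f"b{i}") for i in range(10)]
        reads += [read_with_blocks([(0, 100), (230, 300)], rid=f"c{i}") for i in range(5)]
        models = collapse_by_chain(reads, DiscoveryParams(wobble_nt=0), reference=ref)
        by_id = {m.isoform_id: m for m in models}
        assert not by_id["ENST1"].is_novel
        assert by_id["Tx1"].support == 10 and by_id["Tx2"].support == 5

    def test_closed_mode_drops_novel_chains(self):
        ref = [make_model([(0, 100), (200, 300)], isoform_id="ENST1")]
        reads = [read_with_blocks([(0, 100), (200, 300)], rid=f"a{i}") for i in range(20)]
        reads += [read_with_blocks([(0, 100), (250, 300)], rid=f"b{i}") for i in range(10)]
        models = collapse_by_chain(
            reads, DiscoveryParams(wobble_nt=0, novelty_mode="closed"), reference=ref
        )
        assert [m.isoform_id for m in models] == ["ENST1"]


class TestReferenceMatching:
    def test_fsm_ignores_terminal_ends(self):
        ref = [make_model([(100, 200), (300, 400)], isoform_id="ENST-A")]
        model = make_model([(70, 200), (300, 430)])
        assert match_reference_chain(model, ref) == "ENST-A"

    def test_different_chain_no_match(self):
        ref = [make_model([(100, 200), (300, 400)], isoform_id="ENST-A")]
        model = make_model([(100, 200), (310, 400)])
        assert match_reference_chain(model, ref) is None

    def test_mono_exon_reciprocal_overlap(self):
        ref = [make_model([(100, 200)], isoform_id="ENST-M")]
        # oracle by brute force: [120,220) vs [100,200): overlap 80,
        # 80/100 = 0.8 >= 0.5 both sides -> match
        assert reciprocal_overlap((120, 220), (100, 200)) == pytest.approx(0.8)
        assert match_reference_chain(make_model([(120, 220)]), ref) == "ENST-M"
        # [190,400) vs [100,200): overlap 10 -> no match
        assert match_reference_chain(make_model([(190, 400)]), ref) is None
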