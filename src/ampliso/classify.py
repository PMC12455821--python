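"""Structural classification against a reference annotation.

Spliced isoforms fall into exactly one of three categories:

* FSM — full splice match: intron chain identical to a reference transcript
  (terminal exon ends may differ).
* NIC — novel in catalogue: every junction uses only annotated splice sites;
  subcategory COJ (known junctions recombined), COS (two known sites paired
  in a junction never annotated together) or IR (an exon spans a complete
  reference intron; IR takes precedence by convention).
* NNC — novel not in catalogue: at least one splice site absent from the
  annotation (subcategory ALO).

Mono-exonic isoforms are reported outside the three classes unless they match
a mono-exonic reference. Novel exons are model exons with zero overlap to any
reference exon of the gene; splice motifs are read from the genome and
flagged canonical for GT-AG, GC-AG or AT-AC pairs on the annotated strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import pandas as pd

from .discovery import IsoformModel, match_reference_chain

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
CANONICAL_MOTIFS = {("GT", "AG"), ("GC", "AG"), ("AT", "AC")}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class StructuralCall:
    category: str  # FSM / NIC / NNC / mono-exon
    subcategory: str  # COJ / COS / IR / ALO / none
    novel_junctions: list[tuple[int, int]] = field(default_factory=list)
    novel_sites: list[int] = field(default_factory=list)
    retained_introns: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class NovelExon:
    """A model exon absent from the reference, 1-based inclusive coordinates."""

    gene: str
    label: str
    chrom: str
    start: int
    end: int
    classification: str = ""

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SpliceMotif:
    donor: str
    acceptor: str

    @property
    def canonical(self) -> bool:
        return (self.donor, self.acceptor) in CANONICAL_MOTIFS


class ReferenceCatalog:
    """Junction/site/intron/exon sets of a gene's reference transcripts."""

    def __init__(self, reference: Sequence[IsoformModel]):
        self.transcripts = list(reference)
        self.junctions: set[tuple[int, int]] = set()
        self.donor_side: set[int] = set()  # intron start coordinates
        self.acceptor_side: set[int] = set()  # intron end coordinates
        self.chains: set[tuple[tuple[int, int], ...]] = set()
        self.exons: list[tuple[int, int]] = []
        for t in reference:
            self.chains.add(t.intron_chain)
            self.exons.extend(t.exons)
            for (s, e) in t.intron_chain:
                self.junctions.add((s, e))
                self.donor_side.add(s)
                self.acceptor_side.add(e)


def classify_isoform(
    model: IsoformModel, reference: Sequence[IsoformModel] | ReferenceCatalog
) -> StructuralCall:
    """Assign the structural category and subcategory of one isoform."""
    cat = reference if isinstance(reference, ReferenceCatalog) else ReferenceCatalog(reference)

    if not model.is_spliced:
        if match_reference_chain(model, cat.transcripts) is not None:
            return StructuralCall(category="FSM", subcategory="none")
        return StructuralCall(category="mono-exon", subcategory="none")

    chain = model.intron_chain
    if chain in cat.chains:
        return StructuralCall(category="FSM", subcategory="none")

    novel_sites: list[int] = []
    novel_junctions: list[tuple[int, int]] = []
    for (s, e) in chain:
        s_known = s in cat.donor_side
        e_known = e in cat.acceptor_side
        if not s_known:
            novel_sites.append(s)
        if not e_known:
            novel_sites.append(e)
        if (s, e) not in cat.junctions:
            novel_junctions.append((s, e))

    retained = [
        intron
        for intron in sorted(cat.junctions)
        if any(ex[0] < intron[0] and intron[1] < ex[1] for ex in model.exons)
    ]

    if novel_sites:
        return StructuralCall(
            category="NNC", subcategory="ALO",
            novel_junctions=novel_junctions, novel_sites=novel_sites,
            retained_introns=retained,
        )
    if retained:
        sub = "IR"
    elif novel_junctions:
        sub = "COS"
    else:
        sub = "COJ"
    return StructuralCall(
        category="NIC", subcategory=sub,
        novel_junctions=novel_junctions, retained_introns=retained,
    )


def _canonical_reference(reference: Sequence[IsoformModel]) -> IsoformModel:
    # longest spliced length as the default canonical transcript
    return max(
        reference,
        key=lambda t: (sum(e - s for s, e in t.exons), t.isoform_id),
    )


def detect_novel_exons(
    model: IsoformModel,
    reference: Sequence[IsoformModel],
    canonical_id: str | None = None,
) -> list[NovelExon]:
    """Model exons with zero overlap to every reference exon of the gene.

    Labels follow "<upstream canonical exon number><letter>" in genomic
    order, numbering exons along the canonical transcript in its direction
    of transcription.
    """
    if not reference:
        return []
    ref_exons = [e for t in reference for e in t.exons]
    novel = [
        ex for ex in model.exons
        if all(min(ex[1], r[1]) - max(ex[0], r[0]) <= 0 for r in ref_exons)
    ]
    if not novel:
        return []
    if canonical_id is not None:
        canonical = next(t for t in reference if t.isoform_id == canonical_id)
    else:
        canonical = _canonical_reference(reference)
    can_exons = list(canonical.exons)
    numbered = (
        list(enumerate(can_exons, start=1))
        if model.strand == "+"
        else list(zip(range(len(can_exons), 0, -1), can_exons))
    )

    def upstream_number(ex: tuple[int, int]) -> int:
        if model.strand == "+":
            cands = [n for n, ce in numbered if ce[1] <= ex[0]]
            return max(cands) if cands else 0
        cands = [n for n, ce in numbered if ce[0] >= ex[1]]
        return max(cands) if cands else 0

    out: list[NovelExon] = []
    per_host: dict[int, int] = {}
    for ex in sorted(novel):
        host = upstream_number(ex)
        idx = per_host.get(host, 0)
        per_host[host] = idx + 1
        label = f"{host}{chr(ord('a') + idx)}"
        out.append(
            NovelExon(
                gene=model.gene_id, label=label, chrom=model.chrom,
                start=ex[0] + 1, end=ex[1],
            )
        )
    return out


def splice_motif(
    junction: tuple[int, int],
    genome: Mapping[str, object],
    chrom: str,
    strand: str,
) -> SpliceMotif:
    """Donor/acceptor dinucleotides of one intron, strand-aware.

    ``junction`` is the intron as a 0-based half-open genomic interval;
    ``genome`` is any mapping of contig name to sliceable sequence
    (e.g. a pyfaidx.Fasta).
    """
    s, e = junction
    if e - s < 4 or s < 0:
        raise ValueError(f"intron [{s},{e}) too short or out of bounds")
    seq = str(genome[chrom][s:e])
    if len(seq) < e - s:
        raise ValueError(f"intron [{s},{e}) outside sequence bounds of {chrom}")
    seq = seq.upper()
    if strand == "+":
        return SpliceMotif(donor=seq[:2], acceptor=seq[-2:])
    return SpliceMotif(donor=revcomp(seq[-2:]), acceptor=revcomp(seq[:2]))


def load_novel_exon_validation() -> pd.DataFrame:
    """Packaged validated-novel-exon table with sizes computed from coordinates."""
    with resources.files("ampliso.data").joinpath("novel_exon_validation.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["size"] = df["end"] - df["start"] + 1
    return df


__all__ = [
    "CANONICAL_MOTIFS",
    "NovelExon",
    "ReferenceCatalog",
    "SpliceMotif",
    "StructuralCall",
    "classify_isoform",
    "detect_novel_exons",
    "load_novel_exon_validation",
    "revcomp",
    "splice_motif",
]
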