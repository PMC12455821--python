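"""Isoform discovery: splice-site correction and intron-chain collapsing.

Reads merged across samples are first corrected: each junction boundary within
a wobble window of an annotated donor/acceptor is snapped to it, and
boundaries far from any annotated site are snapped to the modal observed
position of their local cluster. Corrected reads are then collapsed into
candidate isoform models, one per distinct intron chain, with a support
threshold of max(min_reads_abs, min_fraction_by_gene x total gene reads).
Discovery is fully open by default (the novel-discovery-rate analog is 1):
chains absent from the annotation become novel candidates named Tx1..TxN.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from statistics import median_low
from typing import Iterable, Sequence

from .ingest import AlignedRead


@dataclass
class IsoformModel:
    """An isoform as an ordered chain of exon blocks on one strand.

    ``exons`` are 0-based half-open genomic intervals; the intron chain is
    derived from them and is the identity key for matching and assignment.
    """

    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    support: int = 0
    is_novel: bool = False
    cds: list[tuple[int, int]] | None = None

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_spliced(self) -> bool:
        return len(self.exons) > 1

    def validate(self) -> None:
        for (s, e) in self.exons:
            if e <= s:
                raise ValueError(f"empty exon [{s},{e}) in {self.isoform_id}")
        for (a, b) in zip(self.exons, self.exons[1:]):
            if b[0] <= a[1]:
                raise ValueError(f"exons overlap/out of order in {self.isoform_id}")


@dataclass(frozen=True)
class DiscoveryParams:
    wobble_nt: int = 5
    min_fraction_by_gene: float = 0.001
    min_reads_abs: int = 3
    novelty_mode: str = "open"  # "open" (NDR-analog 1) or "closed"

    def __post_init__(self) -> None:
        if self.wobble_nt < 0:
            raise ValueError("wobble_nt must be >= 0")
        if not (0.0 <= self.min_fraction_by_gene <= 1.0):
            raise ValueError("min_fraction_by_gene must be in [0, 1]")
        if self.novelty_mode not in ("open", "closed"):
            raise ValueError("novelty_mode must be 'open' or 'closed'")


@dataclass(frozen=True)
class ReferenceSites:
    """Annotated junction boundary positions of a gene, per side.

    ``starts`` holds intron start coordinates (the boundary after a donor
    exon), ``ends`` intron end coordinates. Both are genomic, 0-based.
    """

    starts: frozenset[int]
    ends: frozenset[int]

    @classmethod
    def from_models(cls, models: Iterable[IsoformModel]) -> "ReferenceSites":
        starts: set[int] = set()
        ends: set[int] = set()
        for m in models:
            for (s, e) in m.intron_chain:
                starts.add(s)
                ends.add(e)
        return cls(frozenset(starts), frozenset(ends))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Fraction of reciprocal overlap between two intervals (min of the two)."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _snap_table(
    observed: Counter[int], annotated: frozenset[int], wobble: int
) -> dict[int, int]:
    """Target position for every observed boundary position.

    Annotated site within +-wobble wins (nearest; ties -> smaller coordinate);
    otherwise the modal observed position within +-wobble (ties -> smaller).
    """
    table: dict[int, int] = {}
    ann = sorted(annotated)
    for p in observed:
        if wobble == 0:
            table[p] = p
            continue
        near = [a for a in ann if abs(a - p) <= wobble]
        if near:
            table[p] = min(near, key=lambda a: (abs(a - p), a))
            continue
        cluster = [(q, c) for q, c in observed.items() if abs(q - p) <= wobble]
        table[p] = min(cluster, key=lambda qc: (-qc[1], qc[0]))[0]
    return table


def correct_splice_sites(
    reads: Sequence[AlignedRead],
    reference_sites: ReferenceSites,
    wobble_nt: int = 5,
) -> list[AlignedRead]:
    """Snap read junction boundaries to annotated or modal positions.

    A boundary whose snap would produce an empty exon or intron is left
    unsnapped and the read is flagged. Reads are modified in place and
    returned for chaining.
    """
    obs_starts: Counter[int] = Counter()
    obs_ends: Counter[int] = Counter()
    for r in reads:
        for (s, e) in r.introns:
            obs_starts[s] += 1
            obs_ends[e] += 1
    snap_s = _snap_table(obs_starts, reference_sites.starts, wobble_nt)
    snap_e = _snap_table(obs_ends, reference_sites.ends, wobble_nt)

    for r in reads:
        if not r.introns:
            continue
        introns = list(r.introns)
        for i, (s, e) in enumerate(introns):
            ns, ne = snap_s[s], snap_e[e]
            # bounds the snapped intron must respect
            lo = introns[i - 1][1] if i > 0 else r.blocks[0][0]
            hi = introns[i + 1][0] if i + 1 < len(introns) else r.blocks[-1][1]
            if ns <= lo:
                ns = s
                r.flagged = True
            if ne >= hi:
                ne = e
                r.flagged = True
            if ne <= ns:
                ns, ne = s, e
                r.flagged = True
            introns[i] = (ns, ne)
        # rebuild blocks from corrected introns, keeping terminal read ends
        bounds = [r.blocks[0][0]]
        for (s, e) in introns:
            bounds.extend([s, e])
        bounds.append(r.blocks[-1][1])
        blocks = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]
        if all(e > s for s, e in blocks) and all(
            b[0] > a[1] for a, b in zip(blocks, blocks[1:])
        ):
            r.blocks = blocks
            r.introns = introns
        else:
            r.flagged = True
    return list(reads)


def _cluster_mono_exon(reads: Sequence[AlignedRead]) -> list[list[AlignedRead]]:
    """Greedy >=50% reciprocal-overlap clustering of unspliced reads."""
    clusters: list[list[AlignedRead]] = []
    reps: list[tuple[int, int]] = []
    for r in sorted(reads, key=lambda r: (r.start, r.end, r.read_id)):
        iv = (r.start, r.end)
        best, best_ov = -1, 0.0
        for i, rep in enumerate(reps):
            ov = reciprocal_overlap(iv, rep)
            if ov >= 0.5 and ov > best_ov:
                best, best_ov = i, ov
        if best >= 0:
            clusters[best].append(r)
        else:
            clusters.append([r])
            reps.append(iv)
    return clusters


def match_reference_chain(
    model: IsoformModel, reference: Sequence[IsoformModel]
) -> str | None:
    """Reference transcript id whose intron chain equals the model's.

    Terminal exon ends need not match (full-splice-match semantics); among
    several chain-identical references the one with closest terminal ends
    wins. Mono-exonic models match a mono-exonic reference at >=50%
    reciprocal overlap.
    """
    if model.is_spliced:
        hits = [t for t in reference if t.is_spliced and t.intron_chain == model.intron_chain]
        if not hits:
            return None
        return min(
            hits,
            key=lambda t: (abs(t.start - model.start) + abs(t.end - model.end), t.isoform_id),
        ).isoform_id
    span = (model.start, model.end)
    hits = [
        (reciprocal_overlap(span, (t.start, t.end)), t.isoform_id)
        for t in reference
        if not t.is_spliced
    ]
    hits = [h for h in hits if h[0] >= 0.5]
    if not hits:
        return None
    return max(hits, key=lambda h: (h[0], h[1]))[1]


def collapse_by_chain(
    reads: Sequence[AlignedRead],
    params: DiscoveryParams,
    reference: Sequence[IsoformModel],
    gene_id: str = "gene",
    strand: str | None = None,
) -> list[IsoformModel]:
    """Collapse corrected reads into supported isoform models.

    One candidate per distinct corrected intron chain (mono-exon reads form
    clusters by reciprocal overlap). Candidates below the support threshold
    are dropped. Internal exon boundaries come from the chain; terminal
    start/end are the medians of the supporting reads' terminal positions.
    Chains identical to a reference transcript inherit its id; novel chains
    are provisionally named Tx1..TxN in decreasing support order.
    """
    if not reads:
        return []
    chrom = reads[0].chrom
    if strand is None:
        strand = reads[0].strand
    total = len(reads)
    threshold = max(params.min_reads_abs, params.min_fraction_by_gene * total)

    groups: dict[tuple, list[AlignedRead]] = defaultdict(list)
    mono: list[AlignedRead] = []
    for r in reads:
        if r.introns:
            groups[r.intron_chain].append(r)
        else:
            mono.append(r)

    candidates: list[IsoformModel] = []
    for chain, members in groups.items():
        if len(members) < threshold:
            continue
        start = median_low([m.start for m in members])
        end = median_low([m.end for m in members])
        bounds = [start]
        for (s, e) in chain:
            bounds.extend([s, e])
        bounds.append(end)
        exons = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]
        model = IsoformModel(
            isoform_id="", gene_id=gene_id, chrom=chrom, strand=strand,
            exons=exons, support=len(members),
        )
        model.validate()
        candidates.append(model)

    for cluster in _cluster_mono_exon(mono):
        if len(cluster) < threshold:
            continue
        start = median_low([m.start for m in cluster])
        end = median_low([m.end for m in cluster])
        candidates.append(
            IsoformModel(
                isoform_id="", gene_id=gene_id, chrom=chrom, strand=strand,
                exons=[(start, end)], support=len(cluster),
            )
        )

    named: list[IsoformModel] = []
    novel: list[IsoformModel] = []
    for m in candidates:
        ref_id = match_reference_chain(m, reference)
        if ref_id is not None:
            m.isoform_id = ref_id
            m.is_novel = False
            named.append(m)
        else:
            m.is_novel = True
            novel.append(m)
    if params.novelty_mode == "closed":
        novel = []
    novel.sort(key=lambda m: (-m.support, m.start, m.end))
    for i, m in enumerate(novel, start=1):
        m.isoform_id = f"Tx{i}"
    out = named + novel
    out.sort(key=lambda m: (m.start, m.end, m.isoform_id))
    return out


__all__ = [
    "DiscoveryParams",
    "IsoformModel",
    "ReferenceSites",
    "collapse_by_chain",
    "correct_splice_sites",
    "match_reference_chain",
    "reciprocal_overlap",
]
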