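"""ORF prediction, premature-stop / NMD assessment, and protein instability.

Translation starts at the canonical start codon when that genomic position is
exonic in the isoform, falls back to annotated alternative starts, then to
the longest open reading frame. A premature termination codon (PTC) more
than 50 nt upstream of the final exon-exon junction (distance measured from
the first base of the stop codon, in transcript coordinates) is predicted to
trigger nonsense-mediated decay; a PTC within 50 nt (inclusive) escapes.
Mono-exonic transcripts have no junction and are never called NMD.

The instability index is Expasy ProtParam's dipeptide statistic
II = (10/L) x sum DIWV(aa_i, aa_i+1); proteins above 40 are conventionally
predicted unstable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import ProtParamData

from .classify import revcomp
from .discovery import IsoformModel

STOP_CODONS = set(standard_dna_table.stop_codons)
START_CODON = "ATG"


@dataclass(frozen=True)
class OrfParams:
    nmd_window_nt: int = 50
    alternative_starts: tuple[int, ...] = ()  # genomic 5'-base positions

    def __post_init__(self) -> None:
        if self.nmd_window_nt <= 0:
            raise ValueError("nmd_window_nt must be > 0")


@dataclass
class OrfResult:
    verdict: str  # coding / likely_NMD / NMD_escape_lastexon_proximal / unknown
    start_genomic: int | None = None
    stop_genomic: int | None = None
    protein_length: int = 0
    ptc_distance_to_last_junction: int | None = None
    frame_retained: bool = False
    start_policy: str = "none"  # canonical / alternative / longest_orf / none
    start_tc: int | None = None  # transcript coordinate of the start codon
    stop_tc: int | None = None  # transcript coordinate of the stop codon's first base


class Instability(NamedTuple):
    value: float
    unstable: bool


def spliced_sequence(model: IsoformModel, genome: Mapping[str, object]) -> str:
    """Exonic sequence concatenated 5'->3' on the annotated strand."""
    parts = []
    for (s, e) in model.exons:
        seq = str(genome[model.chrom][s:e])
        if len(seq) < e - s:
            raise ValueError(f"exon [{s},{e}) outside sequence of {model.chrom}")
        parts.append(seq.upper())
    seq = "".join(parts)
    return revcomp(seq) if model.strand == "-" else seq


def genomic_to_transcript(model: IsoformModel, gpos: int) -> int | None:
    """Transcript coordinate (0-based) of a genomic position; None if intronic."""
    off = 0
    if model.strand == "+":
        for (s, e) in model.exons:
            if s <= gpos < e:
                return off + (gpos - s)
            off += e - s
    else:
        for (s, e) in reversed(model.exons):
            if s <= gpos < e:
                return off + (e - 1 - gpos)
            off += e - s
    return None


def transcript_to_genomic(model: IsoformModel, tpos: int) -> int:
    off = 0
    exons = model.exons if model.strand == "+" else list(reversed(model.exons))
    for (s, e) in exons:
        ln = e - s
        if tpos < off + ln:
            return s + (tpos - off) if model.strand == "+" else e - 1 - (tpos - off)
        off += ln
    raise IndexError(f"transcript position {tpos} beyond transcript length")


def last_junction_tc(model: IsoformModel) -> int | None:
    """Transcript coordinate of the final exon-exon junction (None if mono-exonic)."""
    if not model.is_spliced:
        return None
    lens = [e - s for s, e in model.exons]
    if model.strand == "-":
        lens = lens[::-1]
    return sum(lens[:-1])


def _first_stop(seq: str, start_tc: int) -> int | None:
    for i in range(start_tc, len(seq) - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            return i
    return None


def _longest_orf_start(seq: str) -> int | None:
    best: tuple[int, int] | None = None  # (-length, start)
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != START_CODON:
            continue
        stop = _first_stop(seq, i)
        length = (stop - i) if stop is not None else (len(seq) - i)
        if best is None or (-length, i) < best:
            best = (-length, i)
    return None if best is None else best[1]


def predict_orf(
    model: IsoformModel,
    genome: Mapping[str, object],
    canonical_start: int | None,
    canonical_stop: int | None,
    params: OrfParams = OrfParams(),
) -> OrfResult:
    """Predict the ORF of an isoform and its NMD consequence.

    ``canonical_start`` / ``canonical_stop`` are the genomic positions of the
    5' base of the annotated start codon and the first base of the annotated
    stop codon; either may be None when no CDS annotation exists, in which
    case the longest-ORF fallback applies.
    """
    seq = spliced_sequence(model, genome)
    junction = last_junction_tc(model)

    start_tc: int | None = None
    policy = "none"
    if canonical_start is not None:
        start_tc = genomic_to_transcript(model, canonical_start)
        if start_tc is not None and seq[start_tc:start_tc + 3] == START_CODON:
            policy = "canonical"
        else:
            start_tc = None
    if start_tc is None:
        for alt in params.alternative_starts:
            tc = genomic_to_transcript(model, alt)
            if tc is not None and seq[tc:tc + 3] == START_CODON:
                start_tc, policy = tc, "alternative"
                break
    if start_tc is None:
        tc = _longest_orf_start(seq)
        if tc is not None:
            start_tc, policy = tc, "longest_orf"
    if start_tc is None:
        return OrfResult(verdict="unknown", start_policy="none")

    stop_tc = _first_stop(seq, start_tc)
    start_g = transcript_to_genomic(model, start_tc)
    if stop_tc is None:
        return OrfResult(
            verdict="unknown", start_genomic=start_g, start_policy=policy,
            start_tc=start_tc,
        )
    stop_g = transcript_to_genomic(model, stop_tc)
    n_aa = (stop_tc - start_tc) // 3
    at_canonical = canonical_stop is not None and stop_g == canonical_stop
    frame_retained = at_canonical and policy == "canonical"

    if junction is None:
        verdict, dist = "coding", None
    else:
        dist = junction - stop_tc
        if at_canonical or dist <= 0:
            verdict, dist = "coding", (dist if dist is not None and dist > 0 else None)
        elif dist > params.nmd_window_nt:
            verdict = "likely_NMD"
        else:
            verdict = "NMD_escape_lastexon_proximal"
    return OrfResult(
        verdict=verdict, start_genomic=start_g, stop_genomic=stop_g,
        protein_length=n_aa, ptc_distance_to_last_junction=dist,
        frame_retained=frame_retained, start_policy=policy,
        start_tc=start_tc, stop_tc=stop_tc,
    )


def translate(seq: str, start_tc: int, stop_tc: int) -> str:
    table = standard_dna_table.forward_table
    aas = []
    for i in range(start_tc, stop_tc, 3):
        codon = seq[i:i + 3]
        aas.append(table.get(codon, "X"))
    return "".join(aas)


def classify_novel_exon_consequence(
    novel_exon: tuple[int, int],
    host_model: IsoformModel,
    genome: Mapping[str, object],
    canonical_start: int | None,
    canonical_stop: int | None,
    params: OrfParams = OrfParams(),
) -> str:
    """Consequence of a novel exon on its host isoform's reading frame.

    Returns one of ``UTR`` (exon entirely outside the translated region),
    ``ORF`` (frame preserved, no stop introduced), ``PTC`` (introduced stop
    more than 50 nt from the final junction) or ``PTC(<50nt)``.
    ``novel_exon`` is a 0-based half-open genomic interval.
    """
    if tuple(novel_exon) not in {tuple(e) for e in host_model.exons}:
        raise ValueError(f"exon {novel_exon} is not an exon of {host_model.isoform_id}")
    res = predict_orf(host_model, genome, canonical_start, canonical_stop, params)
    if res.verdict == "unknown" or res.start_tc is None:
        return "UTR"
    g5 = novel_exon[0] if host_model.strand == "+" else novel_exon[1] - 1
    g3 = novel_exon[1] - 1 if host_model.strand == "+" else novel_exon[0]
    a = genomic_to_transcript(host_model, g5)
    b = genomic_to_transcript(host_model, g3)
    assert a is not None and b is not None
    orf_end = res.stop_tc + 3 if res.stop_tc is not None else len(spliced_sequence(host_model, genome))
    if b < res.start_tc or (res.stop_tc is not None and a >= orf_end):
        return "UTR"
    if res.verdict == "likely_NMD":
        return "PTC"
    if res.verdict == "NMD_escape_lastexon_proximal":
        return "PTC(<50nt)"
    return "ORF"


def instability_index(protein: str) -> Instability:
    """Expasy ProtParam instability index with the conventional flag at 40."""
    protein = protein.upper()
    if len(protein) < 2:
        raise ValueError("protein must have length >= 2")
    diwv = ProtParamData.DIWV
    total = 0.0
    for i, (a, b) in enumerate(zip(protein, protein[1:])):
        if a not in diwv:
            raise ValueError(f"nonstandard residue {a!r} at position {i}")
        if b not in diwv:
            raise ValueError(f"nonstandard residue {b!r} at position {i + 1}")
        total += diwv[a][b]
    value = 10.0 / len(protein) * total
    return Instability(value=value, unstable=value > 40.0)


__all__ = [
    "Instability",
    "OrfParams",
    "OrfResult",
    "classify_novel_exon_consequence",
    "genomic_to_transcript",
    "instability_index",
    "last_junction_tc",
    "predict_orf",
    "spliced_sequence",
    "transcript_to_genomic",
    "translate",
]
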