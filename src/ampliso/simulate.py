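"""Synthetic spike-in-style amplicon experiments with known ground truth.

The generator emulates a spike-in RNA variant (SIRV-like) design: a
multi-isoform synthetic gene whose isoforms share an exon pool and the two
terminal exons (the primer sites), mixed at known concentrations (an equal
mix E0 and two skewed mixes E1/E2), reverse-transcribed and PCR-amplified to
full-length molecules, and sequenced as error-bearing long reads. Reads are
emitted directly as alignments (SAM) against the synthetic genome so no
external aligner is needed; substitutions and indels are injected at
configurable rates with the CIGAR and NM tag updated consistently, and a
configurable fraction of reads is truncated from the 5' or 3' end by a
geometric length to mimic RT/PCR artifacts. Ground truth (GTF, concentration
table, per-isoform read counts) is emitted alongside.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pysam

from .discovery import IsoformModel
from .gtf import GeneParams, PrimerPair, write_gtf

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Read-level noise model.

    Defaults emulate high-quality nanopore pass reads after basecalling
    (~3% total error, mostly substitutions) with occasional truncated
    molecules from incomplete reverse transcription.
    """

    reads_per_replicate: int = 10_000
    sub_rate: float = 0.02
    ins_rate: float = 0.005
    del_rate: float = 0.005
    truncation_prob: float = 0.05
    truncation_mean_nt: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if not (0.0 <= self.truncation_prob <= 1.0):
            raise ValueError("truncation_prob must be in [0, 1]")
        if self.reads_per_replicate < 1:
            raise ValueError("reads_per_replicate must be >= 1")


@dataclass
class SimGene:
    """A synthetic multi-isoform gene over a shared exon pool."""

    gene_id: str
    chrom: str
    strand: str
    exon_pool: list[tuple[int, int]]
    isoforms: list[tuple[int, ...]]  # exon-index chains
    isoform_ids: list[str]
    canonical_index: int = 0

    def blocks(self, isoform: int) -> list[tuple[int, int]]:
        return [self.exon_pool[i] for i in self.isoforms[isoform]]


@dataclass(frozen=True)
class MixDesign:
    mixes: dict[str, tuple[float, ...]]
    replicates_per_mix: int = 3

    def __post_init__(self) -> None:
        for name, v in self.mixes.items():
            if any(x < 0 for x in v) or abs(sum(v) - 1.0) > 1e-9:
                raise ValueError(f"mix {name} must be non-negative and sum to 1")


def default_mix_design(n_isoforms: int = 5, replicates_per_mix: int = 3) -> MixDesign:
    """Equal mix E0 plus two mirrored two-fold dilution series E1/E2."""
    eq = tuple(1.0 / n_isoforms for _ in range(n_isoforms))
    w = np.array([2.0 ** -i for i in range(n_isoforms)])
    skew = tuple(w / w.sum())
    return MixDesign(
        mixes={"E0": eq, "E1": skew, "E2": tuple(reversed(skew))},
        replicates_per_mix=replicates_per_mix,
    )


class SimRead(NamedTuple):
    name: str
    pos: int  # 0-based leftmost reference position
    cigar: str
    seq: str
    nm: int


def make_locus(
    n_exons: int = 8,
    n_isoforms: int = 5,
    seed: int = 0,
    gene_id: str = "GENE1",
    chrom: str = "synth1",
    strand: str = "+",
    exon_len: tuple[int, int] = (80, 250),
    intron_len: tuple[int, int] = (60, 300),
    flank: int = 200,
) -> tuple[SimGene, str, list[IsoformModel]]:
    """Build a synthetic locus: gene model, genome sequence, truth transcripts.

    All isoforms share the first and last exon (the primer sites) and have
    distinct exon-index chains; intron boundaries carry canonical splice
    motifs in the genome (GT..AG on the annotated strand).
    """
    if n_isoforms < 2:
        raise ValueError("n_isoforms must be >= 2")
    max_extra = 2 ** max(0, n_exons - 2) - 1  # non-canonical chains available
    if n_exons < 3 or n_isoforms - 1 > max_extra:
        raise ValueError(
            f"cannot build {n_isoforms} distinct isoforms from {n_exons} exons"
        )
    rng = np.random.default_rng(seed)
    pos = flank
    pool: list[tuple[int, int]] = []
    for i in range(n_exons):
        ln = int(rng.integers(exon_len[0], exon_len[1] + 1))
        pool.append((pos, pos + ln))
        pos += ln + int(rng.integers(intron_len[0], intron_len[1] + 1))
    glen = pool[-1][1] + flank
    genome = rng.choice(_BASES, size=glen)
    donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
    for (s, e) in pool[:-1]:
        genome[e], genome[e + 1] = donor[0], donor[1]
    for (s, e) in pool[1:]:
        genome[s - 2], genome[s - 1] = acceptor[0], acceptor[1]

    chains: list[tuple[int, ...]] = [tuple(range(n_exons))]
    seen = {chains[0]}
    while len(chains) < n_isoforms:
        middle = [i for i in range(1, n_exons - 1) if rng.random() < 0.5]
        chain = tuple([0] + middle + [n_exons - 1])
        if chain in seen or len(chain) < 2:
            continue
        seen.add(chain)
        chains.append(chain)

    ids = [f"{gene_id}.{k + 1}" for k in range(n_isoforms)]
    gene = SimGene(
        gene_id=gene_id, chrom=chrom, strand=strand, exon_pool=pool,
        isoforms=chains, isoform_ids=ids, canonical_index=0,
    )
    truth = [
        IsoformModel(
            isoform_id=ids[k], gene_id=gene_id, chrom=chrom, strand=strand,
            exons=gene.blocks(k),
        )
        for k in range(n_isoforms)
    ]
    return gene, "".join(genome), truth


def _merge_ops(ops: list[tuple[str, int]]) -> str:
    out: list[tuple[str, int]] = []
    for op, ln in ops:
        if ln == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return "".join(f"{ln}{op}" for op, ln in out)


def _mutate(base: str, rng: np.random.Generator) -> str:
    alts = [b for b in "ACGT" if b != base]
    return alts[int(rng.integers(0, len(alts)))]


def _emit_read(
    blocks: list[tuple[int, int]],
    genome: str,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[int, str, str, int]:
    """Build (pos, cigar, seq, nm) for one read over the given exon blocks."""
    T = sum(e - s for s, e in blocks)
    n_sub = int(rng.binomial(T, params.sub_rate)) if params.sub_rate else 0
    n_del = int(rng.binomial(T, params.del_rate)) if params.del_rate else 0
    n_ins = int(rng.binomial(T, params.ins_rate)) if params.ins_rate else 0
    # interior offsets only, so alignments never start/end with I or D
    sub_pos: set[int] = set()
    del_pos: set[int] = set()
    if n_sub and T > 2:
        sub_pos = set(int(x) for x in rng.choice(np.arange(1, T - 1), size=min(n_sub, T - 2), replace=False))
    if n_del and T > 2:
        cand = rng.choice(np.arange(1, T - 1), size=min(n_del, T - 2), replace=False)
        del_pos = {int(x) for x in cand} - sub_pos
    ins_at: Counter[int] = Counter()
    if n_ins and T > 2:
        for x in rng.integers(1, T - 1, size=n_ins):
            ins_at[int(x)] += 1

    ops: list[tuple[str, int]] = []
    seq_parts: list[str] = []
    t = 0
    prev_end: int | None = None
    for (s, e) in blocks:
        if prev_end is not None:
            ops.append(("N", s - prev_end))
        prev_end = e
        t0, t1 = t, t + (e - s)
        if not sub_pos and not del_pos and not ins_at:
            ops.append(("=", e - s))
            seq_parts.append(genome[s:e])
            t = t1
            continue
        evs = sorted(
            {o for o in sub_pos if t0 <= o < t1}
            | {o for o in del_pos if t0 <= o < t1}
            | {o for o in ins_at if t0 <= o < t1}
        )
        cur = t0
        for o in evs:
            if o > cur:
                ops.append(("=", o - cur))
                seq_parts.append(genome[s + (cur - t0):s + (o - t0)])
            if o in ins_at:
                k = ins_at[o]
                ops.append(("I", k))
                seq_parts.append("".join(_mutate("N", rng) for _ in range(k)))
            if o in del_pos:
                ops.append(("D", 1))
                cur = o + 1
            elif o in sub_pos:
                ops.append(("X", 1))
                seq_parts.append(_mutate(genome[s + (o - t0)], rng))
                cur = o + 1
            else:
                cur = o
        if cur < t1:
            ops.append(("=", t1 - cur))
            seq_parts.append(genome[s + (cur - t0):e])
        t = t1

    nm = len(sub_pos) + len(del_pos) + sum(ins_at.values())
    return blocks[0][0], _merge_ops(ops), "".join(seq_parts), nm


def _truncate_blocks(
    blocks: list[tuple[int, int]],
    clip: int,
    from_left: bool,
) -> list[tuple[int, int]]:
    """Remove ``clip`` aligned bases from one genomic end (whole + partial exons)."""
    out = list(blocks)
    if from_left:
        while out and clip >= out[0][1] - out[0][0]:
            clip -= out[0][1] - out[0][0]
            out.pop(0)
        if out and clip > 0:
            out[0] = (out[0][0] + clip, out[0][1])
    else:
        while out and clip >= out[-1][1] - out[-1][0]:
            clip -= out[-1][1] - out[-1][0]
            out.pop()
        if out and clip > 0:
            out[-1] = (out[-1][0], out[-1][1] - clip)
    return out


def simulate_reads(
    gene: SimGene,
    genome: str,
    mix: Sequence[float],
    params: SimParams,
    sample_id: str = "sample",
    seed: int | None = None,
) -> tuple[list[SimRead], dict[str, int]]:
    """Draw reads from a concentration vector and render them as alignments.

    Returns the reads and the per-isoform drawn counts (the sample's ground
    truth). Deterministic for a given seed.
    """
    if len(mix) != len(gene.isoforms):
        raise ValueError("mix length must equal the number of isoforms")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    counts = rng.multinomial(params.reads_per_replicate, np.asarray(mix, dtype=float))
    truth = {gene.isoform_ids[k]: int(c) for k, c in enumerate(counts)}
    reads: list[SimRead] = []
    rid = 0
    for k, c in enumerate(counts):
        base_blocks = gene.blocks(k)
        total = sum(e - s for s, e in base_blocks)
        for _ in range(int(c)):
            blocks = base_blocks
            if params.truncation_prob and rng.random() < params.truncation_prob:
                clip = int(rng.geometric(1.0 / params.truncation_mean_nt))
                clip = min(clip, total - 50)
                if clip > 0:
                    five_prime = bool(rng.random() < 0.5)
                    from_left = five_prime if gene.strand == "+" else not five_prime
                    blocks = _truncate_blocks(base_blocks, clip, from_left)
            pos, cigar, seq, nm = _emit_read(blocks, genome, params, rng)
            reads.append(SimRead(name=f"{sample_id}_r{rid}", pos=pos, cigar=cigar, seq=seq, nm=nm))
            rid += 1
    return reads, truth


def write_sam(
    path: str | Path, chrom: str, chrom_len: int, reads: Sequence[SimRead],
    strand: str = "+",
) -> None:
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": chrom, "LN": chrom_len}]}
    flag = 16 if strand == "-" else 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            a.query_sequence = r.seq
            a.set_tag("NM", r.nm)
            out.write(a)


def write_fastq(path: str | Path, reads: Sequence[SimRead]) -> None:
    with open(path, "w") as out:
        for r in reads:
            out.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_fasta(path: str | Path, contigs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as out:
        for name, seq in contigs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


@dataclass
class LocusFixture:
    gene: SimGene
    truth: list[IsoformModel]
    params_file: Path
    sample_sams: dict[str, Path]
    sample_to_mix: dict[str, str]
    concentrations: dict[str, dict[str, float]]  # mix -> isoform -> fraction
    truth_counts: dict[str, dict[str, int]]  # sample -> isoform -> reads


@dataclass
class SirvExperiment:
    outdir: Path
    genome_fasta: Path
    truth_gtf: Path
    concentrations_tsv: Path
    loci: list[LocusFixture]


def make_sirv_experiment(
    outdir: str | Path,
    seed: int = 0,
    sim_params: SimParams | None = None,
    mix_design: MixDesign | None = None,
    n_isoforms: int = 5,
) -> SirvExperiment:
    """Emit a complete two-locus spike-in-style fixture, seed-deterministic.

    Two synthetic genes with ``n_isoforms`` isoforms each are sequenced under
    three mixes (equal E0 and skewed E1/E2) with the configured replicates
    per mix; every sample gets its own SAM. Ground-truth GTF, concentration
    table and per-gene parameters files are written alongside.
    """
    outdir = Path(outdir).resolve()
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    params = sim_params or SimParams()
    design = mix_design or default_mix_design(n_isoforms)
    rng = np.random.default_rng(seed)

    spec = [("AMPV5", "synthV5", 8), ("AMPV6", "synthV6", 9)]
    contigs: dict[str, str] = {}
    all_truth: list[IsoformModel] = []
    loci: list[LocusFixture] = []
    conc_rows: list[str] = []
    for gene_id, chrom, n_exons in spec:
        locus_seed = int(rng.integers(0, 2**31 - 1))
        gene, genome, truth = make_locus(
            n_exons=n_exons, n_isoforms=n_isoforms, seed=locus_seed,
            gene_id=gene_id, chrom=chrom,
        )
        contigs[chrom] = genome
        all_truth.extend(truth)
        first, last = gene.exon_pool[0], gene.exon_pool[-1]
        primer = PrimerPair(
            fwd=(first[0], first[0] + 20), rvr=(last[1] - 20, last[1]),
            chrom=chrom, label="pair1",
        )
        gp = GeneParams(
            gene_id=gene_id, chrom=chrom, strand=gene.strand,
            primer_pairs=[primer],
            reference_gtf=str(outdir / "truth.gtf"),
            genome_fasta=str(outdir / "genome.fasta"),
        )
        params_file = outdir / f"{gene_id}_params.txt"
        gp.save(params_file)

        sample_sams: dict[str, Path] = {}
        sample_to_mix: dict[str, str] = {}
        truth_counts: dict[str, dict[str, int]] = {}
        concentrations = {
            mix: {gene.isoform_ids[k]: v[k] for k in range(n_isoforms)}
            for mix, v in design.mixes.items()
        }
        for mix, vec in design.mixes.items():
            for rep in range(1, design.replicates_per_mix + 1):
                sid = f"{gene_id}_{mix}_rep{rep}"
                rseed = int(rng.integers(0, 2**31 - 1))
                reads, counts = simulate_reads(
                    gene, genome, vec, params, sample_id=sid, seed=rseed
                )
                sam = outdir / "alignments" / f"{sid}.sam"
                write_sam(sam, chrom, len(genome), reads, strand=gene.strand)
                sample_sams[sid] = sam
                sample_to_mix[sid] = mix
                truth_counts[sid] = counts
        for mix, per_iso in concentrations.items():
            for iso, v in per_iso.items():
                conc_rows.append(f"{gene_id}\t{iso}\t{mix}\t{v}\n")
        loci.append(
            LocusFixture(
                gene=gene, truth=truth, params_file=params_file,
                sample_sams=sample_sams, sample_to_mix=sample_to_mix,
                concentrations=concentrations, truth_counts=truth_counts,
            )
        )

    genome_fasta = outdir / "genome.fasta"
    write_fasta(genome_fasta, contigs)
    truth_gtf = outdir / "truth.gtf"
    write_gtf(all_truth, truth_gtf, source="sim")
    conc_tsv = outdir / "concentrations.tsv"
    with open(conc_tsv, "w") as out:
        out.write("gene_id\tisoform_id\tmix\tconcentration\n")
        out.writelines(conc_rows)
    return SirvExperiment(
        outdir=outdir, genome_fasta=genome_fasta, truth_gtf=truth_gtf,
        concentrations_tsv=conc_tsv, loci=loci,
    )


__all__ = [
    "LocusFixture",
    "MixDesign",
    "SimGene",
    "SimParams",
    "SimRead",
    "SirvExperiment",
    "default_mix_design",
    "make_locus",
    "make_sirv_experiment",
    "simulate_reads",
    "write_fasta",
    "write_fastq",
    "write_sam",
]
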