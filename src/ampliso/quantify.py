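"""Primer filtering, read assignment, TPM/proportion computation, expression filter.

Abundance is the count of full-length molecules assigned to each isoform:
TPM_i = counts_i / sum_j counts_j x 1e6 per sample, with no effective-length
normalization (amplicon reads are whole molecules, so molecule counts — not
base coverage — are the abundance unit). Proportions are within-gene
fractions. The expression filter keeps an isoform only if it reaches
``tpm_minimum`` in at least ``required_sample_count`` samples, and values are
re-normalized over the survivors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .discovery import IsoformModel, reciprocal_overlap
from .gtf import ConfigurationError, PrimerPair
from .ingest import AlignedRead


@dataclass(frozen=True)
class FilterParams:
    """Expression-filter settings (defaults from spike-in optimization)."""

    tpm_minimum: float = 5000.0
    samples_minimum: float | int = 0.25

    def __post_init__(self) -> None:
        if self.tpm_minimum < 0:
            raise ValueError("tpm_minimum must be >= 0")
        _check_samples_minimum(self.samples_minimum)


def _check_samples_minimum(v: float | int) -> None:
    if isinstance(v, bool) or v <= 0:
        raise ValueError("samples_minimum must be a fraction in (0,1] or a positive integer")
    if isinstance(v, float) and v > 1.0:
        raise ValueError("fractional samples_minimum must be <= 1")


@dataclass
class ExpressionMatrix:
    """Isoform x sample counts with derived TPM and within-gene proportions."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    proportion: pd.DataFrame
    unassigned: pd.Series  # per-sample unassigned read counts

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, unassigned: pd.Series | None = None) -> "ExpressionMatrix":
        tpm, prop = compute_tpm(counts)
        if unassigned is None:
            unassigned = pd.Series(0, index=counts.columns)
        return cls(counts=counts, tpm=tpm, proportion=prop, unassigned=unassigned)

    @property
    def isoforms(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, isoform_ids: Sequence[str], renormalize: bool = True) -> "ExpressionMatrix":
        counts = self.counts.loc[list(isoform_ids)]
        if renormalize:
            return ExpressionMatrix.from_counts(counts, self.unassigned)
        return ExpressionMatrix(
            counts=counts, tpm=self.tpm.loc[list(isoform_ids)],
            proportion=self.proportion.loc[list(isoform_ids)],
            unassigned=self.unassigned,
        )

    def rename(self, mapping: Mapping[str, str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            counts=self.counts.rename(index=mapping),
            tpm=self.tpm.rename(index=mapping),
            proportion=self.proportion.rename(index=mapping),
            unassigned=self.unassigned,
        )


def primer_filter(
    models: Sequence[IsoformModel], primers: Sequence[PrimerPair]
) -> tuple[list[IsoformModel], list[IsoformModel]]:
    """Split models into (retained, removed) by primer-span overlap.

    A model is retained iff its genomic span overlaps BOTH the forward and
    the reverse primer interval by at least 1 nt for at least one primer
    pair; this enforces full-length amplicon support and removes truncation
    artifacts.
    """
    if not primers:
        raise ConfigurationError("no primer pair supplied")
    kept, removed = [], []
    for m in models:
        span = (m.start, m.end)
        ok = any(
            min(span[1], p.fwd[1]) - max(span[0], p.fwd[0]) >= 1
            and min(span[1], p.rvr[1]) - max(span[0], p.rvr[0]) >= 1
            for p in primers
        )
        (kept if ok else removed).append(m)
    return kept, removed


def assign_reads(
    reads: Sequence[AlignedRead],
    models: Sequence[IsoformModel],
    mode: str = "strict",
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each read to a model by exact corrected intron chain.

    Spliced reads go to the unique model with an identical chain; mono-exon
    reads to the mono-exon model they overlap >=50% reciprocally. Reads
    matching no retained model are counted per sample as unassigned. In
    ``lenient`` mode a spliced read whose chain is a contiguous sub-chain of
    one or more models is split fractionally equally among them.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError("mode must be 'strict' or 'lenient'")
    samples = sorted({r.sample_id for r in reads})
    ids = [m.isoform_id for m in models]
    acc: dict[tuple[str, str], float] = {}
    un: dict[str, int] = {s: 0 for s in samples}

    by_chain = {m.intron_chain: m.isoform_id for m in models if m.is_spliced}
    mono = [m for m in models if not m.is_spliced]

    def subchain_hosts(chain: tuple) -> list[str]:
        k = len(chain)
        hosts = []
        for m in models:
            c = m.intron_chain
            if len(c) > k and any(c[i:i + k] == chain for i in range(len(c) - k + 1)):
                hosts.append(m.isoform_id)
        return hosts

    for r in reads:
        if r.introns:
            mid = by_chain.get(r.intron_chain)
            if mid is not None:
                acc[(mid, r.sample_id)] = acc.get((mid, r.sample_id), 0.0) + 1
                continue
            if mode == "lenient":
                hosts = subchain_hosts(r.intron_chain)
                if hosts:
                    for h in hosts:
                        acc[(h, r.sample_id)] = acc.get((h, r.sample_id), 0.0) + 1.0 / len(hosts)
                    continue
            un[r.sample_id] += 1
        else:
            span = (r.start, r.end)
            best, best_ov = None, 0.0
            for m in mono:
                ov = reciprocal_overlap(span, (m.start, m.end))
                if ov >= 0.5 and ov > best_ov:
                    best, best_ov = m.isoform_id, ov
            if best is not None:
                acc[(best, r.sample_id)] = acc.get((best, r.sample_id), 0.0) + 1
            else:
                un[r.sample_id] += 1
    counts = pd.DataFrame(0.0, index=ids, columns=samples)
    for (mid, sid), v in acc.items():
        counts.at[mid, sid] = v
    if mode == "strict":
        counts = counts.astype(int)
    return counts, pd.Series(un, index=samples, dtype=int)


def compute_tpm(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample TPM and within-gene proportion from assigned counts.

    Samples with zero assigned reads yield all-zero columns.
    """
    totals = counts.sum(axis=0)
    safe = totals.replace(0, 1)
    prop = counts.div(safe, axis=1)
    tpm = prop * 1e6
    return tpm, prop


def required_sample_count(n_samples: int, samples_minimum: float | int) -> int:
    """Minimum number of samples an isoform must pass the TPM threshold in.

    A fraction f maps to max(1, floor(f x n_samples)); an integer k is capped
    at the cohort size.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    _check_samples_minimum(samples_minimum)
    if isinstance(samples_minimum, int):
        return min(samples_minimum, n_samples)
    return max(1, math.floor(samples_minimum * n_samples))


def expression_filter(
    matrix: ExpressionMatrix, params: FilterParams, renormalize: bool = True
) -> tuple[list[str], ExpressionMatrix]:
    """Apply the TPM / sample-support filter; return retained ids and matrix.

    An isoform is retained iff tpm >= tpm_minimum in at least
    required_sample_count samples. TPM and proportions are re-normalized over
    the retained set unless ``renormalize`` is False.
    """
    need = required_sample_count(len(matrix.samples), params.samples_minimum)
    passing = (matrix.tpm >= params.tpm_minimum).sum(axis=1)
    retained = [i for i in matrix.isoforms if passing[i] >= need]
    return retained, matrix.subset(retained, renormalize=renormalize)


def renumber_novel_by_tpm(
    models: Sequence[IsoformModel], matrix: ExpressionMatrix
) -> tuple[list[IsoformModel], ExpressionMatrix]:
    """Re-assign TxN names to novel isoforms by decreasing total TPM.

    Ties break toward the leftmost genomic start. Reference-matching ids are
    untouched. Returns renamed models and a matrix with renamed rows.
    """
    novel = [m for m in models if m.is_novel]
    totals = matrix.tpm.sum(axis=1)
    order = sorted(novel, key=lambda m: (-totals.get(m.isoform_id, 0.0), m.start, m.end))
    mapping = {m.isoform_id: f"Tx{i}" for i, m in enumerate(order, start=1)}
    out = []
    for m in models:
        if m.isoform_id in mapping:
            m = IsoformModel(
                isoform_id=mapping[m.isoform_id], gene_id=m.gene_id, chrom=m.chrom,
                strand=m.strand, exons=list(m.exons), support=m.support,
                is_novel=True, cds=m.cds,
            )
        out.append(m)
    return out, matrix.rename(mapping)


__all__ = [
    "ExpressionMatrix",
    "FilterParams",
    "assign_reads",
    "compute_tpm",
    "expression_filter",
    "primer_filter",
    "renumber_novel_by_tpm",
    "required_sample_count",
]
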