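"""Benchmarking discovery and quantification against a ground-truth annotation.

Discovery is scored by exact intron-chain matching (mono-exonic isoforms by
>=50% reciprocal overlap): each truth chain matches at most one call, every
other call is a false positive. Quantification is scored as the Spearman
rank correlation of known concentrations vs observed TPM over the union of
truth and called isoforms, zero-filling both sides so that missed isoforms
and spurious calls both hurt. Reference-annotation robustness is probed with
insufficient (transcripts removed) and over-annotated (decoy transcripts
added) variants of the truth GTF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .discovery import IsoformModel, match_reference_chain


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    annotation_label: str = "complete"
    spearman_rho: float | None = None

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if not p and not r:
            return 0.0
        if p is None or r is None:
            return None
        return 2 * p * r / (p + r) if (p + r) else 0.0


def match_calls_to_truth(
    called: Sequence[IsoformModel], truth: Sequence[IsoformModel]
) -> dict[str, str]:
    """Map called isoform id -> truth isoform id (chain-exact, mono-exon 50% RO).

    Each truth isoform is consumed by at most one call.
    """
    available = list(truth)
    mapping: dict[str, str] = {}
    for c in called:
        hit = match_reference_chain(c, available)
        if hit is not None:
            mapping[c.isoform_id] = hit
            available = [t for t in available if t.isoform_id != hit]
    return mapping


def score_discovery(
    called: Sequence[IsoformModel],
    truth: Sequence[IsoformModel],
    annotation_label: str = "complete",
) -> BenchmarkResult:
    mapping = match_calls_to_truth(called, truth)
    tp = len(mapping)
    return BenchmarkResult(
        tp=tp, fp=len(called) - tp, fn=len(truth) - tp,
        annotation_label=annotation_label,
    )


def spearman_vs_truth(
    observed: Mapping[str, float], truth: Mapping[str, float]
) -> float | None:
    """Spearman rho over the union of keys, zero-filling either side.

    Returns None when fewer than 3 isoforms are involved or a side is
    constant (undefined correlation).
    """
    keys = sorted(set(observed) | set(truth))
    if len(keys) < 3:
        return None
    x = np.array([truth.get(k, 0.0) for k in keys])
    y = np.array([observed.get(k, 0.0) for k in keys])
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    return float(sps.spearmanr(x, y).statistic)


def score_quantification(
    called: Sequence[IsoformModel],
    tpm_by_sample: "Mapping[str, Mapping[str, float]] | object",
    truth: Sequence[IsoformModel],
    concentrations: Mapping[str, Mapping[str, float]],
    sample_to_mix: Mapping[str, str],
) -> tuple[float | None, dict[str, float | None]]:
    """Per-mix and averaged Spearman of known vs observed expression.

    ``tpm_by_sample``: isoform x sample TPM (a pandas DataFrame or nested
    mapping); ``concentrations``: mix -> isoform -> known concentration.
    Called isoforms are renamed to their matching truth id (by chain) before
    comparison; unmatched calls keep their own id and so zero-fill the truth
    side.
    """
    import pandas as pd

    tpm = pd.DataFrame(tpm_by_sample) if not isinstance(tpm_by_sample, pd.DataFrame) else tpm_by_sample
    mapping = match_calls_to_truth(called, truth)
    renamed = tpm.rename(index=mapping)
    per_mix: dict[str, float | None] = {}
    for mix, conc in concentrations.items():
        cols = [s for s in renamed.columns if sample_to_mix.get(s) == mix]
        if not cols:
            continue
        obs = renamed[cols].mean(axis=1)
        per_mix[mix] = spearman_vs_truth(obs.to_dict(), dict(conc))
    vals = [v for v in per_mix.values() if v is not None]
    mean_rho = float(np.mean(vals)) if vals else None
    return mean_rho, per_mix


def perturb_annotation(
    truth: Sequence[IsoformModel],
    remove_fraction: float = 0.0,
    add_count: int = 0,
    seed: int = 0,
) -> list[IsoformModel]:
    """Insufficient/over-annotated variants of a truth annotation.

    Removes a seeded random ``remove_fraction`` of transcripts (rounded), then
    adds ``add_count`` decoys built by recombining existing exons into intron
    chains absent from the truth set. Deterministic under ``seed``.
    """
    if len(truth) < 2:
        raise ValueError("need at least 2 truth transcripts")
    rng = np.random.default_rng(seed)
    models = sorted(truth, key=lambda m: m.isoform_id)
    n_remove = int(round(remove_fraction * len(models)))
    if n_remove >= len(models):
        raise ValueError("remove_fraction would leave zero transcripts")
    if n_remove:
        drop = set(rng.choice(len(models), size=n_remove, replace=False))
        models = [m for i, m in enumerate(models) if i not in drop]

    existing = {m.intron_chain for m in truth}
    exon_pool = sorted({e for m in truth for e in m.exons})
    decoys: list[IsoformModel] = []
    attempts = 0
    while len(decoys) < add_count and attempts < 1000 * max(1, add_count):
        attempts += 1
        k = int(rng.integers(2, max(3, len(exon_pool) + 1)))
        idx = sorted(rng.choice(len(exon_pool), size=min(k, len(exon_pool)), replace=False))
        exons: list[tuple[int, int]] = []
        for i in idx:
            ex = exon_pool[i]
            if exons and ex[0] <= exons[-1][1]:
                continue
            exons.append(ex)
        if len(exons) < 2:
            continue
        chain = tuple((a[1], b[0]) for a, b in zip(exons, exons[1:]))
        if chain in existing:
            continue
        existing.add(chain)
        proto = truth[0]
        decoys.append(
            IsoformModel(
                isoform_id=f"decoy{len(decoys) + 1}", gene_id=proto.gene_id,
                chrom=proto.chrom, strand=proto.strand, exons=exons, is_novel=False,
            )
        )
    if len(decoys) < add_count:
        raise ValueError(
            f"could only construct {len(decoys)} of {add_count} decoy transcripts"
        )
    return models + decoys


__all__ = [
    "BenchmarkResult",
    "match_calls_to_truth",
    "perturb_annotation",
    "score_discovery",
    "score_quantification",
    "spearman_vs_truth",
]
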