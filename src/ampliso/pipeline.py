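"""End-to-end pipeline: ingest -> discovery -> quantify -> classify -> ORF -> stats.

One run processes one amplified gene locus. The stage order is fixed:
per-sample downsampling and accuracy filtering, merge, splice-site
correction, intron-chain collapsing, primer-coordinate filtering,
read-to-isoform assignment, TPM/proportion computation, the expression
filter (with re-normalization), support-ranked renaming of novel isoforms,
structural classification, novel-exon detection and ORF/NMD prediction, and
optionally the two-group proportion test. Outputs are a filtered GTF, an
expression TSV, classification and ORF report TSVs, a novel-exon table and
a plain-text summary with a per-stage filter audit.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from . import classify as _classify
from . import orf as _orf
from .discovery import (
    DiscoveryParams, IsoformModel, ReferenceSites, collapse_by_chain,
    correct_splice_sites,
)
from .gtf import ConfigurationError, GeneParams, read_gtf, write_gtf
from .ingest import AlignedRead, IngestParams, ingest_sample
from .quantify import (
    ExpressionMatrix, FilterParams, assign_reads, expression_filter,
    primer_filter, renumber_novel_by_tpm,
)
from .stats import group_proportion_test, results_frame


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class FilterAudit:
    discovered: int = 0
    removed_by_primer: int = 0
    removed_by_expression: int = 0
    retained: int = 0

    def check(self) -> None:
        assert self.discovered == (
            self.retained + self.removed_by_primer + self.removed_by_expression
        )


@dataclass
class RunResult:
    models: list[IsoformModel]
    matrix: ExpressionMatrix
    calls: dict[str, _classify.StructuralCall]
    novel_exons: list[_classify.NovelExon]
    orf_results: dict[str, _orf.OrfResult]
    audit: FilterAudit
    group_results: pd.DataFrame | None = None
    outdir: Path | None = None


def _canonical_cds(reference: Sequence[IsoformModel], strand: str) -> tuple[int | None, int | None]:
    """Canonical start/stop genomic positions from reference CDS records.

    The transcript with the longest CDS is canonical; the start is the 5'
    base of its CDS, the stop the first base after the CDS 3' end (the stop
    codon is conventionally excluded from GTF CDS features).
    """
    with_cds = [t for t in reference if t.cds]
    if not with_cds:
        return None, None
    can = max(with_cds, key=lambda t: (sum(e - s for s, e in t.cds), t.isoform_id))
    lo = can.cds[0][0]
    hi = can.cds[-1][1]
    if strand == "+":
        return lo, hi
    # minus strand: start codon's 5' base is the rightmost CDS base; the stop
    # codon occupies [lo-3, lo) and its first transcript base is lo-1
    return hi - 1, lo - 1


def run_pipeline(
    params_file: str | Path,
    sample_alignments: Mapping[str, str | Path],
    outdir: str | Path,
    ingest_params: IngestParams = IngestParams(),
    discovery_params: DiscoveryParams = DiscoveryParams(),
    filter_params: FilterParams = FilterParams(),
    orf_params: _orf.OrfParams = _orf.OrfParams(),
    group_map: Mapping[str, str] | None = None,
    assignment_mode: str = "strict",
) -> RunResult:
    """Run the full single-locus workflow and write all result files.

    ``sample_alignments`` maps sample id -> SAM/BAM path. On a stage error
    partial outputs are removed and a StageError naming the stage is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run(params_file, sample_alignments, outdir, ingest_params,
                    discovery_params, filter_params, orf_params, group_map,
                    assignment_mode)
    except StageError:
        shutil.rmtree(outdir, ignore_errors=True)
        raise


def _run(
    params_file, sample_alignments, outdir: Path, ingest_params,
    discovery_params, filter_params, orf_params, group_map, assignment_mode,
) -> RunResult:
    try:
        gp = GeneParams.load(params_file)
        reference = read_gtf(gp.reference_gtf, gene_id=gp.gene_id) if gp.reference_gtf else []
        genome = Fasta(gp.genome_fasta) if gp.genome_fasta else None
    except Exception as exc:
        raise StageError("config", exc)

    try:
        reads: list[AlignedRead] = []
        for sid in sorted(sample_alignments):
            reads.extend(
                ingest_sample(sample_alignments[sid], sid, ingest_params,
                              strand=gp.strand, chrom=gp.chrom)
            )
        if not sample_alignments:
            raise ConfigurationError("at least one sample is required")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ingest", exc)

    try:
        sites = ReferenceSites.from_models(reference)
        reads = correct_splice_sites(reads, sites, discovery_params.wobble_nt)
        discovered = collapse_by_chain(
            reads, discovery_params, reference, gene_id=gp.gene_id, strand=gp.strand
        )
    except Exception as exc:
        raise StageError("discovery", exc)

    audit = FilterAudit(discovered=len(discovered))
    try:
        kept, removed = primer_filter(discovered, gp.primer_pairs)
        audit.removed_by_primer = len(removed)
        counts, unassigned = assign_reads(reads, kept, mode=assignment_mode)
        matrix = ExpressionMatrix.from_counts(counts, unassigned)
        retained_ids, matrix = expression_filter(matrix, filter_params)
        audit.removed_by_expression = len(kept) - len(retained_ids)
        models = [m for m in kept if m.isoform_id in set(retained_ids)]
        audit.retained = len(models)
        audit.check()
        models, matrix = renumber_novel_by_tpm(models, matrix)
    except Exception as exc:
        raise StageError("quantify", exc)

    try:
        catalog = _classify.ReferenceCatalog(reference)
        calls = {m.isoform_id: _classify.classify_isoform(m, catalog) for m in models}
        novel_exons: list[_classify.NovelExon] = []
        exon_host: dict[tuple, IsoformModel] = {}
        if reference:
            for m in models:
                for ne in _classify.detect_novel_exons(m, reference):
                    key = (ne.start, ne.end)
                    if key not in exon_host:
                        exon_host[key] = m
                        novel_exons.append(ne)
    except Exception as exc:
        raise StageError("classify", exc)

    orf_results: dict[str, _orf.OrfResult] = {}
    classified_exons: list[_classify.NovelExon] = []
    if genome is not None:
        try:
            can_start, can_stop = _canonical_cds(reference, gp.strand)
            for m in models:
                orf_results[m.isoform_id] = _orf.predict_orf(
                    m, genome, can_start, can_stop, orf_params
                )
            for ne in novel_exons:
                host = exon_host[(ne.start, ne.end)]
                consequence = _orf.classify_novel_exon_consequence(
                    (ne.start - 1, ne.end), host, genome, can_start, can_stop, orf_params
                )
                classified_exons.append(
                    _classify.NovelExon(
                        gene=ne.gene, label=ne.label, chrom=ne.chrom,
                        start=ne.start, end=ne.end, classification=consequence,
                    )
                )
            novel_exons = classified_exons
        except Exception as exc:
            raise StageError("orf", exc)

    group_results = None
    if group_map is not None:
        try:
            res = group_proportion_test(matrix.proportion, group_map)
            group_results = results_frame(res)
        except Exception as exc:
            raise StageError("stats", exc)

    try:
        _write_outputs(outdir, gp, models, matrix, calls, novel_exons,
                       orf_results, audit, group_results, genome)
    except Exception as exc:
        raise StageError("report", exc)

    return RunResult(
        models=models, matrix=matrix, calls=calls, novel_exons=novel_exons,
        orf_results=orf_results, audit=audit, group_results=group_results,
        outdir=outdir,
    )


def _write_outputs(outdir, gp, models, matrix, calls, novel_exons,
                   orf_results, audit, group_results, genome) -> None:
    write_gtf(models, outdir / f"{gp.gene_id}_isoforms.gtf")

    expr = pd.concat(
        {"counts": matrix.counts, "tpm": matrix.tpm, "proportion": matrix.proportion},
        names=["metric", "isoform_id"],
    )
    expr.to_csv(outdir / f"{gp.gene_id}_expression.tsv", sep="\t")
    matrix.unassigned.rename("unassigned_reads").to_csv(
        outdir / f"{gp.gene_id}_unassigned.tsv", sep="\t"
    )

    rows = []
    for m in models:
        c = calls[m.isoform_id]
        o = orf_results.get(m.isoform_id)
        motifs = []
        if genome is not None:
            for j in m.intron_chain:
                sm = _classify.splice_motif(j, genome, m.chrom, m.strand)
                motifs.append(f"{sm.donor}-{sm.acceptor}")
        rows.append({
            "isoform_id": m.isoform_id, "gene_id": m.gene_id,
            "category": c.category, "subcategory": c.subcategory,
            "n_exons": len(m.exons), "support": m.support,
            "novel": m.is_novel, "splice_motifs": ",".join(motifs),
            "all_canonical_motifs": all(
                mm in {"GT-AG", "GC-AG", "AT-AC"} for mm in motifs
            ) if motifs else "",
            "orf_verdict": o.verdict if o else "",
            "protein_length": o.protein_length if o else "",
            "ptc_distance": (o.ptc_distance_to_last_junction if o else ""),
        })
    pd.DataFrame(rows).to_csv(
        outdir / f"{gp.gene_id}_classification.tsv", sep="\t", index=False
    )

    ne_rows = [
        {"gene": ne.gene, "novel_exon": ne.label, "chrom": ne.chrom,
         "start": ne.start, "end": ne.end, "size_nt": ne.size,
         "classification": ne.classification}
        for ne in novel_exons
    ]
    pd.DataFrame(ne_rows, columns=["gene", "novel_exon", "chrom", "start",
                                   "end", "size_nt", "classification"]).to_csv(
        outdir / f"{gp.gene_id}_novel_exons.tsv", sep="\t", index=False
    )

    if group_results is not None:
        group_results.to_csv(outdir / f"{gp.gene_id}_group_test.tsv", sep="\t", index=False)

    (outdir / f"{gp.gene_id}_summary.txt").write_text(
        summary_report(gp, models, matrix, calls, novel_exons, orf_results, audit)
    )


def summary_report(gp, models, matrix, calls, novel_exons, orf_results, audit) -> str:
    """Plain-text run summary: category counts, novel share, filter audit."""
    lines = [f"gene: {gp.gene_id}", f"samples: {len(matrix.samples)}", ""]
    cat_counts: dict[str, int] = {}
    sub_counts: dict[str, int] = {}
    for c in calls.values():
        cat_counts[c.category] = cat_counts.get(c.category, 0) + 1
        if c.subcategory != "none":
            sub_counts[c.subcategory] = sub_counts.get(c.subcategory, 0) + 1
    lines.append("isoform categories:")
    for cat in ("FSM", "NIC", "NNC", "mono-exon"):
        if cat in cat_counts:
            lines.append(f"  {cat}: {cat_counts[cat]}")
    if sub_counts:
        lines.append("subcategories:")
        for sub in ("COJ", "COS", "IR", "ALO"):
            if sub in sub_counts:
                lines.append(f"  {sub}: {sub_counts[sub]}")
    novel_ids = [m.isoform_id for m in models if m.is_novel]
    total = matrix.counts.values.sum()
    novel_reads = matrix.counts.loc[novel_ids].values.sum() if novel_ids else 0
    pct = 100.0 * novel_reads / total if total else 0.0
    lines.append(f"\nreads assigned to novel isoforms: {pct:.1f}%")
    if novel_exons:
        lines.append("\nnovel exons (1-based inclusive; size = end - start + 1):")
        for ne in novel_exons:
            lines.append(
                f"  {ne.gene}\t{ne.label}\t{ne.chrom}:{ne.start}-{ne.end}"
                f"\t{ne.size} nt\t{ne.classification}"
            )
    if orf_results:
        verd: dict[str, int] = {}
        for o in orf_results.values():
            verd[o.verdict] = verd.get(o.verdict, 0) + 1
        lines.append("\nORF verdicts:")
        for k in sorted(verd):
            lines.append(f"  {k}: {verd[k]}")
    lines.append(
        f"\nfilter audit: discovered={audit.discovered} "
        f"removed_by_primer={audit.removed_by_primer} "
        f"removed_by_expression={audit.removed_by_expression} "
        f"retained={audit.retained}"
    )
    return "\n".join(lines) + "\n"


__all__ = [
    "FilterAudit",
    "RunResult",
    "StageError",
    "run_pipeline",
    "summary_report",
]
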