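"""Shared fixtures: toy annotations and a session-scoped simulated experiment."""

from __future__ import annotations

import pytest

from ampliso.discovery import IsoformModel
from ampliso.pipeline import run_pipeline
from ampliso.simulate import SimParams, make_sirv_experiment


def make_model(exons, isoform_id="t1", gene_id="g", chrom="chr1", strand="+", **kw):
    m = IsoformModel(
        isoform_id=isoform_id, gene_id=gene_id, chrom=chrom, strand=strand,
        exons=[tuple(e) for e in exons], **kw,
    )
    m.validate()
    return m


@pytest.fixture
def toy_reference():
    """Five-exon gene with three annotated transcripts.

    Exons: e1 [100,200) e2 [300,400) e3 [500,600) e4 [700,800) e5 [900,1000).
    tA uses all five; tB skips e4 (so the e3->e5 junction is annotated);
    tC skips e2.
    """
    e = [(100, 200), (300, 400), (500, 600), (700, 800), (900, 1000)]
    return [
        make_model(e, isoform_id="tA"),
        make_model([e[0], e[1], e[2], e[4]], isoform_id="tB"),
        make_model([e[0], e[2], e[3], e[4]], isoform_id="tC"),
    ]


@pytest.fixture(scope="session")
def sirv_zero_error(tmp_path_factory):
    """Zero-error spike-in-style fixture: 2 loci x 5 isoforms, 3 mixes x 3
    replicates, 10,000 reads per sample."""
    outdir = tmp_path_factory.mktemp("sirv0")
    return make_sirv_experiment(
        outdir, seed=11,
        sim_params=SimParams(
            reads_per_replicate=10_000, sub_rate=0.0, ins_rate=0.0,
            del_rate=0.0, truncation_prob=0.0, seed=11,
        ),
    )


@pytest.fixture(scope="session")
def sirv_pipeline_results(sirv_zero_error, tmp_path_factory):
    """Default-parameter pipeline results for each locus of the fixture."""
    outdir = tmp_path_factory.mktemp("sirv0_runs")
    results = {}
    for loc in sirv_zero_error.loci:
        results[loc.gene.gene_id] = run_pipeline(
            loc.params_file, loc.sample_sams, outdir / loc.gene.gene_id
        )
    return results
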