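"""GTF reading/writing and the per-gene parameters file.

Internal coordinates are 0-based half-open; GTF text is 1-based inclusive.
Reading and writing round-trip exactly on exon coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils

from .discovery import IsoformModel


class GtfParseError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


def _validate_gtf_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                s, e = int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(f"{path}: line {lineno}: non-integer coordinates")
            if s < 1 or e < s:
                raise GtfParseError(f"{path}: line {lineno}: invalid interval {s}-{e}")


def read_gtf(path: str | Path, gene_id: str | None = None) -> list[IsoformModel]:
    """Load transcript models (exons, optional CDS) from a GTF file.

    Only records of the requested gene are returned when ``gene_id`` is
    given. Transcripts are sorted by genomic start then id.
    """
    _validate_gtf_lines(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes.get("gene_id", [""])[0]
        tid = feat.attributes.get("transcript_id", [""])[0]
        if not tid:
            raise GtfParseError(f"{path}: {feat.featuretype} without transcript_id")
        if gene_id is not None and gid != gene_id:
            continue
        iv = (feat.start - 1, feat.end)  # to 0-based half-open
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, ivs in exons.items():
        gid, chrom, strand = meta[tid]
        m = IsoformModel(
            isoform_id=tid, gene_id=gid, chrom=chrom, strand=strand,
            exons=sorted(ivs), cds=sorted(cds[tid]) if tid in cds else None,
        )
        m.validate()
        models.append(m)
    models.sort(key=lambda m: (m.start, m.isoform_id))
    return models


def write_gtf(models: Iterable[IsoformModel], path: str | Path, source: str = "ampliso") -> None:
    """Write transcript + exon (+ CDS) features, 1-based inclusive."""
    models = sorted(models, key=lambda m: (m.chrom, m.start, m.isoform_id))
    with open(path, "w") as out:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.isoform_id}";'
            out.write(
                f"{m.chrom}\t{source}\ttranscript\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            for (s, e) in m.exons:
                out.write(
                    f"{m.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            for (s, e) in m.cds or []:
                out.write(
                    f"{m.chrom}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t{attrs}\n"
                )


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer intervals, 0-based half-open, fwd left of rvr."""

    fwd: tuple[int, int]
    rvr: tuple[int, int]
    chrom: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.fwd[0] >= self.rvr[0]:
            raise ConfigurationError("forward primer must precede reverse primer")

    @classmethod
    def from_1based(cls, fwd_start: int, fwd_end: int, rvr_start: int, rvr_end: int,
                    chrom: str = "", label: str = "") -> "PrimerPair":
        return cls((fwd_start - 1, fwd_end), (rvr_start - 1, rvr_end), chrom, label)


@dataclass
class GeneParams:
    """Per-gene run configuration from the parameters file.

    The file is flat key=value text; primer coordinates are 1-based inclusive
    in the file and converted on load. ``primer_pair`` may repeat.
    """

    gene_id: str
    chrom: str
    strand: str
    primer_pairs: list[PrimerPair]
    reference_gtf: str = ""
    genome_fasta: str = ""

    @classmethod
    def load(cls, path: str | Path) -> "GeneParams":
        kv: dict[str, str] = {}
        pairs: list[PrimerPair] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigurationError(f"{path}: line {lineno}: expected key=value")
                key, val = (p.strip() for p in line.split("=", 1))
                if key == "primer_pair":
                    try:
                        f, r = val.split(",")
                        fs, fe = (int(x) for x in f.split("-"))
                        rs, re_ = (int(x) for x in r.split("-"))
                    except ValueError:
                        raise ConfigurationError(
                            f"{path}: line {lineno}: primer_pair must be "
                            "'fwd_start-fwd_end,rvr_start-rvr_end' (1-based inclusive)"
                        )
                    pairs.append(PrimerPair.from_1based(fs, fe, rs, re_, label=f"pair{len(pairs) + 1}"))
                else:
                    kv[key] = val
        for req in ("gene_id", "chrom", "strand"):
            if req not in kv:
                raise ConfigurationError(f"{path}: missing required key '{req}'")
        if not pairs:
            raise ConfigurationError(f"{path}: at least one primer_pair is required")
        if kv["strand"] not in "+-":
            raise ConfigurationError(f"{path}: strand must be '+' or '-'")
        base = Path(path).parent
        def _resolve(p: str) -> str:
            return p if not p or Path(p).is_absolute() else str(base / p)
        gp = cls(
            gene_id=kv["gene_id"], chrom=kv["chrom"], strand=kv["strand"],
            primer_pairs=[PrimerPair(p.fwd, p.rvr, kv["chrom"], p.label) for p in pairs],
            reference_gtf=_resolve(kv.get("reference_gtf", "")),
            genome_fasta=_resolve(kv.get("genome_fasta", "")),
        )
        return gp

    def save(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write(f"gene_id={self.gene_id}\nchrom={self.chrom}\nstrand={self.strand}\n")
            if self.reference_gtf:
                out.write(f"reference_gtf={self.reference_gtf}\n")
            if self.genome_fasta:
                out.write(f"genome_fasta={self.genome_fasta}\n")
            for p in self.primer_pairs:
                out.write(
                    f"primer_pair={p.fwd[0] + 1}-{p.fwd[1]},{p.rvr[0] + 1}-{p.rvr[1]}\n"
                )


__all__ = [
    "ConfigurationError",
    "GeneParams",
    "GtfParseError",
    "PrimerPair",
    "read_gtf",
    "write_gtf",
]
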