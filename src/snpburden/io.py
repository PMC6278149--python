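"""Readers and writers for the standard formats the pipeline touches.

Dialects, precisely:

* **FASTA** — read via Biopython; sequences are uppercased on input and must
  be over ``A/C/G/T/N`` after normalization; duplicate contig ids are errors.
* **GFF3** — only ``CDS`` features are consumed; each must carry a ``Parent``
  (or ``ID``) attribute naming its gene/transcript. Segments are grouped per
  gene and sorted; a gene whose CDS length is not divisible by 3 is flagged
  ``partial``, not dropped. Mixed strands within one gene are an error.
  Parsed directly line-by-line so that errors can name the offending line.
* **VCF 4.x** — read via :mod:`cyvcf2`. Depth is taken from ``INFO/DP`` first,
  else from the first sample's ``FORMAT/DP``. Multi-allelic sites are split
  into one record per ALT, each inheriting the site depth. Under strict mode
  a missing DP is an error; under lenient mode depth is recorded as unknown.
* **InterProScan-style TSV** — first column gene id, any later column holding
  ``IPR######`` tokens contributes accessions; one merged record per gene.
* **gene-set lists** — plain text, one gene id per line, ``#`` comments.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from pathlib import Path

from Bio import SeqIO

from .models import (
    DomainAnnotation,
    GeneModel,
    GenomeSequence,
    IPR_PATTERN,
    SnpBurdenError,
    VariantRecord,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly lowercase) FASTA file into genome records."""
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SnpBurdenError(f"{path}: duplicate contig id {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    return out


def write_fasta(genomes: list[GenomeSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.contig_id}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = 9


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read CDS features from a GFF3 file and group them into gene models."""
    segments: "OrderedDict[str, list[tuple[int, int]]]" = OrderedDict()
    strands: dict[str, str] = {}
    contigs: dict[str, str] = {}
    notes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise SnpBurdenError(
                    f"{path}:{lineno}: expected {_GFF_COLS} tab-separated "
                    f"columns, got {len(cols)}"
                )
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            attr_map = _parse_attributes(attrs)
            gene = attr_map.get("Parent") or attr_map.get("ID")
            if not gene:
                raise SnpBurdenError(
                    f"{path}:{lineno}: CDS feature without Parent/ID attribute"
                )
            if gene in strands:
                if strands[gene] != strand:
                    raise SnpBurdenError(
                        f"{path}:{lineno}: gene {gene!r} has CDS on mixed strands"
                    )
                if contigs[gene] != seqid:
                    raise SnpBurdenError(
                        f"{path}:{lineno}: gene {gene!r} spans multiple contigs"
                    )
            else:
                strands[gene] = strand
                contigs[gene] = seqid
                notes[gene] = attr_map.get("Note", "")
            segments.setdefault(gene, []).append((int(start), int(end)))
    models = []
    for gene, segs in segments.items():
        segs.sort()
        length = sum(e - s + 1 for s, e in segs)
        models.append(
            GeneModel(
                gene_id=gene,
                contig_id=contigs[gene],
                strand=strands[gene],
                cds_segments=tuple(segs),
                annotation=notes[gene],
                partial=length % 3 != 0,
            )
        )
    return models


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Emit gene models as GFF3 (a gene feature plus one CDS line per segment)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            attrs = f"ID={m.gene_id}"
            if m.annotation:
                attrs += f";Note={m.annotation}"
            fh.write(
                f"{m.contig_id}\tsnpburden\tgene\t{span[0]}\t{span[1]}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            cds_attrs = f"Parent={m.gene_id}"
            if m.annotation:
                cds_attrs += f";Note={m.annotation}"
            for start, end in m.cds_segments:
                fh.write(
                    f"{m.contig_id}\tsnpburden\tCDS\t{start}\t{end}\t.\t"
                    f"{m.strand}\t0\t{cds_attrs}\n"
                )


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path, strict_depth: bool = False) -> list[VariantRecord]:
    """Read a VCF into variant records, splitting multi-allelic sites per ALT."""
    from cyvcf2 import VCF  # local import: cyvcf2 loads htslib

    out: list[VariantRecord] = []
    vcf = VCF(str(path))
    for site in vcf:
        depth = site.INFO.get("DP")
        if depth is None:
            try:
                fmt = site.format("DP")
            except KeyError:
                fmt = None
            if fmt is not None and len(fmt):
                val = int(fmt[0][0])
                depth = val if val >= 0 else None  # htslib missing sentinel
        if depth is None and strict_depth:
            raise SnpBurdenError(
                f"{path}: site {site.CHROM}:{site.POS} has no DP in INFO or "
                "FORMAT (strict mode)"
            )
        for alt in site.ALT:
            out.append(
                VariantRecord(
                    contig_id=site.CHROM,
                    pos=site.POS,
                    ref=site.REF,
                    alt=alt,
                    depth=int(depth) if depth is not None else None,
                )
            )
    return out


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(
    variants: list[VariantRecord],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write variant records as a minimal sites-only VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">\n'
        )
        if contig_lengths:
            for cid, length in contig_lengths.items():
                fh.write(f"##contig=<ID={cid},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = "." if v.depth is None else f"DP={v.depth}"
            fh.write(
                f"{v.contig_id}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\n"
            )


# ---------------------------------------------------------------------------
# Domain annotation tables

_IPR_TOKEN = re.compile(r"IPR\d{6}")


def read_domain_table(path: str | Path, strict: bool = False) -> list[DomainAnnotation]:
    """Read an InterProScan-style TSV into one merged record per gene.

    Column 1 is the gene/protein id. Any later column whose value is an
    ``IPR######`` token contributes an accession; other columns (analysis,
    e-value, coordinates ...) are ignored. A malformed value in a column that
    looks like it was meant to be an accession (starts with ``IPR``) is an
    error under strict mode and skipped with the row retained otherwise.
    """
    merged: "OrderedDict[str, set[str]]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            gene = cols[0].strip()
            accs = merged.setdefault(gene, set())
            for col in cols[1:]:
                col = col.strip()
                if IPR_PATTERN.match(col):
                    accs.add(col)
                elif col.startswith("IPR") and strict:
                    raise SnpBurdenError(
                        f"{path}:{lineno}: malformed IPR token {col!r}"
                    )
    return [
        DomainAnnotation(gene_id=g, ipr_accessions=frozenset(a))
        for g, a in merged.items()
    ]


def write_domain_table(annotations: list[DomainAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            for acc in sorted(ann.ipr_accessions):
                fh.write(f"{ann.gene_id}\t{acc}\n")


# ---------------------------------------------------------------------------
# Gene-set lists


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one id per line, '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(gene_ids: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in gene_ids:
            fh.write(g + "\n")
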