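"""Codon-level consequence annotation of SNPs against gene models.

The core operation maps a SNP into the spliced, strand-oriented coding
sequence of a gene, substitutes the alternate base into the affected codon,
translates both codons and classifies the change:

* ``synonymous``     — same amino acid, not a stop;
* ``nonsynonymous``  — different amino acid, no stop created or destroyed;
* ``stop_gain`` / ``stop_loss`` — a stop codon appears / disappears;
* ``stop_retained``  — one stop codon replaced by another;
* ``unknown``        — the codon contains N or an allele is not a plain base.

Codon numbering is 1-based from the CDS start: ``codon_index =
ceil(cds_pos / 3)``, and the compact notation ``<ref_aa><codon_index><alt_aa>``
(e.g. ``V624A``; synonymous changes read ``H50H``) uses that index. For genes
on the minus strand the variant alleles, which are always reported on the
genome's forward strand, are reverse-complemented before codon substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data import CodonTable

from .models import (
    CDS,
    EffectCall,
    GeneModel,
    INTERGENIC,
    INTRON,
    NONCODING,
    NONSYNONYMOUS,
    NUCLEOTIDES,
    STOP_GAIN,
    STOP_LOSS,
    STOP_RETAINED,
    SYNONYMOUS,
    SnpBurdenError,
    UNKNOWN,
    VariantRecord,
)

STOP = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def codon_to_aa(code_table: int = 1) -> dict[str, str]:
    """Codon -> single-letter amino acid ('*' for stop) for an NCBI table id."""
    table = CodonTable.unambiguous_dna_by_id[code_table]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = STOP
    return mapping


def spliced_cds(model: GeneModel, genome: Mapping[str, str]) -> str:
    """The strand-oriented coding sequence of a gene, introns removed."""
    contig = genome[model.contig_id]
    parts = [contig[start - 1 : end] for start, end in model.cds_segments]
    seq = "".join(parts)
    if model.strand == "-":
        seq = revcomp(seq)
    return seq


def map_to_gene(
    variant: VariantRecord, models: list[GeneModel]
) -> tuple[str | None, str]:
    """Assign a variant to (gene_id, region).

    Region is ``CDS`` if the position lies in a CDS segment of some gene on
    the variant's contig, ``intron`` if inside a gene's span but between its
    CDS segments, ``intergenic`` otherwise. When several genes overlap the
    position, CDS assignments win over intronic ones and ties break to the
    lexicographically smallest gene id; use :func:`overlapping_genes` for the
    full list.
    """
    hits = overlapping_genes(variant, models)
    if not hits:
        return None, INTERGENIC
    return hits[0]


def overlapping_genes(
    variant: VariantRecord, models: list[GeneModel]
) -> list[tuple[str, str]]:
    """All (gene_id, region) assignments covering the variant position,
    best first (CDS before intron, then gene id)."""
    hits = []
    for m in models:
        if m.contig_id != variant.contig_id:
            continue
        lo, hi = m.span
        if not lo <= variant.pos <= hi:
            continue
        region = CDS if m.contains(variant.pos) else INTRON
        hits.append((m.gene_id, region))
    hits.sort(key=lambda h: (h[1] != CDS, h[0]))
    return hits


def cds_coordinate(variant: VariantRecord, model: GeneModel) -> int:
    """1-based position of the variant within the spliced CDS.

    On the plus strand this is the offset of the genomic position within the
    concatenated segments in genome order; on the minus strand the coordinate
    is mirrored (``cds_length - offset + 1``) so that position 1 is always the
    first base of the coding sequence.
    """
    offset = 0
    for start, end in model.cds_segments:
        if start <= variant.pos <= end:
            offset += variant.pos - start + 1
            break
        offset += end - start + 1
    else:
        raise SnpBurdenError(
            f"variant {variant.contig_id}:{variant.pos} lies outside the CDS "
            f"segments of gene {model.gene_id!r}"
        )
    if model.strand == "-":
        return model.cds_length - offset + 1
    return offset


def classify_snp(
    variant: VariantRecord,
    model: GeneModel,
    genome: Mapping[str, str],
    code_table: int = 1,
) -> EffectCall:
    """Classify a CDS SNP as synonymous/nonsynonymous (or a stop change).

    The reference allele is checked against the genome base at the variant
    position; a mismatch is an error, since it almost always indicates a
    coordinate or strand bug upstream. A codon containing ``N`` or an allele
    outside plain A/C/G/T yields class ``unknown``.
    """
    if variant.vclass != "SNP":
        raise SnpBurdenError(
            f"variant {variant.contig_id}:{variant.pos} is an INDEL; only "
            "SNPs can be classified"
        )
    contig = genome[model.contig_id]
    genome_base = contig[variant.pos - 1]
    if genome_base != variant.ref and genome_base != "N":
        raise SnpBurdenError(
            f"reference allele mismatch at {variant.contig_id}:{variant.pos}: "
            f"VCF says {variant.ref!r}, genome has {genome_base!r}"
        )
    pos = cds_coordinate(variant, model)
    codon_index = (pos + 2) // 3
    codon_offset = pos - (codon_index - 1) * 3  # 1..3
    cds = spliced_cds(model, genome)
    ref_codon = cds[(codon_index - 1) * 3 : codon_index * 3]
    ref_base, alt_base = variant.ref, variant.alt
    if model.strand == "-":
        ref_base, alt_base = revcomp(ref_base), revcomp(alt_base)
    if genome_base != "N" and ref_codon[codon_offset - 1] != ref_base:
        raise SnpBurdenError(
            f"internal inconsistency at {variant.contig_id}:{variant.pos}: "
            f"spliced CDS base {ref_codon[codon_offset - 1]!r} != strand-"
            f"adjusted ref {ref_base!r}"
        )
    alt_codon = (
        ref_codon[: codon_offset - 1] + alt_base + ref_codon[codon_offset:]
    )
    common = dict(
        variant=variant,
        gene_id=model.gene_id,
        region=CDS,
        cds_pos=pos,
        codon_index=codon_index,
        codon_offset=codon_offset,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
    )
    if set(ref_codon + alt_codon) - NUCLEOTIDES:
        return EffectCall(klass=UNKNOWN, **common)
    aa = codon_to_aa(code_table)
    ref_aa, alt_aa = aa[ref_codon], aa[alt_codon]
    if ref_aa == alt_aa:
        klass = STOP_RETAINED if ref_aa == STOP else SYNONYMOUS
    elif alt_aa == STOP:
        klass = STOP_GAIN
    elif ref_aa == STOP:
        klass = STOP_LOSS
    else:
        klass = NONSYNONYMOUS
    return EffectCall(
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        klass=klass,
        notation=f"{ref_aa}{codon_index}{alt_aa}",
        **common,
    )


@dataclass
class AnnotationResult:
    """Effect calls plus any per-record errors collected in lenient mode."""

    calls: list[EffectCall] = field(default_factory=list)
    errors: list[tuple[VariantRecord, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)

    def class_counts(self, collapse_stops: bool = False) -> dict[str, int]:
        out: dict[str, int] = {}
        for call in self.calls:
            k = call.collapsed_klass() if collapse_stops else call.klass
            out[k] = out.get(k, 0) + 1
        return out


def annotate_all(
    snps: list[VariantRecord],
    models: list[GeneModel],
    genome: Mapping[str, str],
    code_table: int = 1,
    lenient: bool = True,
) -> AnnotationResult:
    """Annotate every SNP with its primary gene assignment and consequence.

    Noncoding SNPs are carried through with region labels (``intron`` /
    ``intergenic``) and class ``noncoding``. In lenient mode per-record
    errors (e.g. reference-allele mismatches) are collected into
    ``result.errors`` instead of aborting the run.
    """
    by_id = {m.gene_id: m for m in models}
    result = AnnotationResult()
    for snp in snps:
        hits = overlapping_genes(snp, models)
        overlaps = tuple(g for g, _ in hits[1:])
        if not hits:
            result.calls.append(
                EffectCall(variant=snp, gene_id=None, region=INTERGENIC,
                           klass=NONCODING)
            )
            continue
        gene_id, region = hits[0]
        if region != CDS:
            result.calls.append(
                EffectCall(variant=snp, gene_id=gene_id, region=region,
                           klass=NONCODING, overlaps=overlaps)
            )
            continue
        try:
            call = classify_snp(snp, by_id[gene_id], genome, code_table)
        except SnpBurdenError as exc:
            if not lenient:
                raise
            result.errors.append((snp, str(exc)))
            continue
        if overlaps:
            call = EffectCall(
                **{**call.__dict__, "overlaps": overlaps}
            )
        result.calls.append(call)
    return result


@dataclass(frozen=True)
class Translation:
    """A translated CDS: protein string plus stop-codon bookkeeping."""

    protein: str
    terminal_stop: bool
    internal_stops: tuple[int, ...]  # 1-based codon indices


def translate_cds(
    model: GeneModel, genome: Mapping[str, str], code_table: int = 1
) -> Translation:
    """Translate a complete gene model codon by codon.

    The trailing stop, if present, is dropped from the returned protein but
    recorded; internal stops are flagged (their codon indices reported) and
    translation still returned. Codons containing N translate to ``X``.
    """
    if model.partial:
        raise SnpBurdenError(
            f"gene {model.gene_id!r} is flagged partial; cannot translate"
        )
    cds = spliced_cds(model, genome)
    aa_map = codon_to_aa(code_table)
    residues = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        residues.append(aa_map.get(codon, "X"))
    terminal_stop = bool(residues) and residues[-1] == STOP
    if terminal_stop:
        residues = residues[:-1]
    internal = tuple(i + 1 for i, r in enumerate(residues) if r == STOP)
    return Translation(
        protein="".join(residues),
        terminal_stop=terminal_stop,
        internal_stops=internal,
    )
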