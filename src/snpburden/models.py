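"""Core data types shared across the pipeline.

Coordinate convention is uniform everywhere: 1-based, closed intervals on the
genome (forward) strand. CDS positions are 1-based within the spliced,
strand-oriented coding sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

NUCLEOTIDES = frozenset("ACGT")
GENOME_ALPHABET = frozenset("ACGTN")

#: region labels
CDS = "CDS"
INTRON = "intron"
INTERGENIC = "intergenic"

#: consequence classes
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP_GAIN = "stop_gain"
STOP_LOSS = "stop_loss"
STOP_RETAINED = "stop_retained"
NONCODING = "noncoding"
UNKNOWN = "unknown"

IPR_PATTERN = re.compile(r"^IPR\d{6}$")


class SnpBurdenError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: identifier plus its uppercase A/C/G/T/N sequence."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SnpBurdenError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence) - GENOME_ALPHABET
        if bad:
            offset = next(
                i for i, c in enumerate(self.sequence) if c in bad
            )
            raise SnpBurdenError(
                f"contig {self.contig_id!r}: non-alphabet character "
                f"{self.sequence[offset]!r} at offset {offset}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def genome_as_dict(genomes: list[GenomeSequence]) -> dict[str, str]:
    """Index a genome collection by contig id, enforcing unique ids."""
    out: dict[str, str] = {}
    for g in genomes:
        if g.contig_id in out:
            raise SnpBurdenError(f"duplicate contig id {g.contig_id!r}")
        out[g.contig_id] = g.sequence
    return out


@dataclass(frozen=True)
class GeneModel:
    """A stranded, possibly multi-exon CDS on one contig.

    ``cds_segments`` are 1-based closed ``(start, end)`` intervals in genome
    coordinates, sorted by start, non-overlapping. Models whose total CDS
    length is not divisible by 3 must be flagged ``partial`` (they are kept,
    but cannot be translated).
    """

    gene_id: str
    contig_id: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    annotation: str = ""
    partial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SnpBurdenError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.cds_segments:
            raise SnpBurdenError(f"gene {self.gene_id!r}: no CDS segments")
        prev_end = 0
        for start, end in self.cds_segments:
            if start < 1 or end < start:
                raise SnpBurdenError(
                    f"gene {self.gene_id!r}: bad segment ({start}, {end})"
                )
            if start <= prev_end:
                raise SnpBurdenError(
                    f"gene {self.gene_id!r}: segments overlap or are unsorted"
                )
            prev_end = end
        if self.cds_length % 3 != 0 and not self.partial:
            raise SnpBurdenError(
                f"gene {self.gene_id!r}: CDS length {self.cds_length} not "
                "divisible by 3 and model not flagged partial"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span from first CDS base to last (introns included)."""
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def contains(self, pos: int) -> bool:
        """True if ``pos`` falls inside any CDS segment."""
        return any(start <= pos <= end for start, end in self.cds_segments)


@dataclass(frozen=True)
class VariantRecord:
    """One called variant (SNP or INDEL) with its supporting read depth.

    ``depth`` is ``None`` when the caller did not report DP and the reader ran
    in lenient mode; such records carry ``depth_unknown``.
    """

    contig_id: str
    pos: int
    ref: str
    alt: str
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SnpBurdenError(f"variant at pos {self.pos}: pos must be >= 1")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or set(allele) - NUCLEOTIDES:
                raise SnpBurdenError(
                    f"variant {self.contig_id}:{self.pos}: {label} allele "
                    f"{allele!r} is empty or not over A/C/G/T"
                )
        if self.ref == self.alt:
            raise SnpBurdenError(
                f"variant {self.contig_id}:{self.pos}: ref == alt ({self.ref!r})"
            )
        if self.depth is not None and self.depth < 0:
            raise SnpBurdenError(
                f"variant {self.contig_id}:{self.pos}: negative depth"
            )

    @property
    def vclass(self) -> str:
        """'SNP' for 1:1 substitutions, 'INDEL' otherwise."""
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def depth_unknown(self) -> bool:
        return self.depth is None

    @property
    def ref_span(self) -> tuple[int, int]:
        """Closed genomic interval occupied by the reference allele."""
        return self.pos, self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class DomainAnnotation:
    """Protein-domain content of one gene: its set of InterPro accessions."""

    gene_id: str
    ipr_accessions: frozenset[str]

    def __post_init__(self) -> None:
        for acc in self.ipr_accessions:
            if not IPR_PATTERN.match(acc):
                raise SnpBurdenError(
                    f"gene {self.gene_id!r}: malformed IPR accession {acc!r}"
                )


@dataclass(frozen=True)
class TargetDomain:
    """One target InterPro accession with its gene-family label."""

    accession: str
    family: str
    description: str = ""
    mechanism: str = ""


@dataclass(frozen=True)
class EffectCall:
    """Region assignment and codon-level consequence of one variant.

    ``notation`` follows the compact amino-acid change style ``V624A``
    (reference residue, 1-based codon index, alternate residue); synonymous
    calls therefore read like ``H50H``. Codon-level fields are ``None``
    outside CDS regions.
    """

    variant: VariantRecord
    gene_id: str | None
    region: str
    cds_pos: int | None = None
    codon_index: int | None = None
    codon_offset: int | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    klass: str = NONCODING
    notation: str | None = None
    overlaps: tuple[str, ...] = ()

    def collapsed_klass(self) -> str:
        """Two-way class with stop categories folded in (nsSNP/sSNP style)."""
        if self.klass in (STOP_GAIN, STOP_LOSS):
            return NONSYNONYMOUS
        if self.klass == STOP_RETAINED:
            return SYNONYMOUS
        return self.klass


@dataclass(frozen=True)
class FilterConfig:
    """Retention thresholds for called variants.

    ``depth_min`` is inclusive (a variant with depth exactly ``depth_min`` is
    kept). ``indel_window`` is the maximum distance, in nt and inclusive, at
    which an INDEL disqualifies a SNP. ``strict_depth`` removes records with
    unknown depth; otherwise they are retained and flagged in the report.
    """

    depth_min: int = 5
    indel_window: int = 10
    strict_depth: bool = False

    def __post_init__(self) -> None:
        if self.depth_min < 0 or self.indel_window < 0:
            raise SnpBurdenError("depth_min and indel_window must be >= 0")


@dataclass
class FilterReport:
    """Accounting of one filter application: what was removed and why."""

    n_input: int = 0
    n_retained: int = 0
    removed: list[tuple[VariantRecord, str]] = field(default_factory=list)
    flagged_unknown_depth: list[VariantRecord] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def counts_by_reason(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.removed:
            out[reason] = out.get(reason, 0) + 1
        return out


@dataclass(frozen=True)
class BurdenSummary:
    """Per-gene SNP counts and per-kb rates against CDS length."""

    gene_id: str
    gene_length: int
    n_snp: int
    n_s: int
    n_ns: int
    n_other: int = 0  # stop/unknown classes when not collapsed

    @property
    def rate_snp(self) -> float:
        return 1000.0 * self.n_snp / self.gene_length

    @property
    def rate_s(self) -> float:
        return 1000.0 * self.n_s / self.gene_length

    @property
    def rate_ns(self) -> float:
        return 1000.0 * self.n_ns / self.gene_length


@dataclass(frozen=True)
class SetBurden:
    """Pooled burden over a gene set.

    Pooled rates are length-weighted: total class count over total CDS length,
    scaled to 1 kb. ``mean_rate_*`` are the unweighted means of per-gene rates,
    reported alongside for reference.
    """

    set_name: str
    total_length: int
    n_snp: int
    n_s: int
    n_ns: int
    genes: tuple[BurdenSummary, ...]

    @property
    def rate_snp(self) -> float:
        return 1000.0 * self.n_snp / self.total_length

    @property
    def rate_s(self) -> float:
        return 1000.0 * self.n_s / self.total_length

    @property
    def rate_ns(self) -> float:
        return 1000.0 * self.n_ns / self.total_length

    @property
    def mean_rate_snp(self) -> float:
        return sum(g.rate_snp for g in self.genes) / len(self.genes)

    @property
    def mean_rate_s(self) -> float:
        return sum(g.rate_s for g in self.genes) / len(self.genes)

    @property
    def mean_rate_ns(self) -> float:
        return sum(g.rate_ns for g in self.genes) / len(self.genes)


@dataclass(frozen=True)
class HighNsRule:
    """Rule flagging highly polymorphic genes by nonsynonymous content.

    Defaults require at least two nsSNPs and more nsSNPs than sSNPs.
    """

    min_ns: int = 2
    require_ns_exceeds_s: bool = True

    def __post_init__(self) -> None:
        if self.min_ns < 1:
            raise SnpBurdenError("min_ns must be >= 1")

    def matches(self, s: BurdenSummary) -> bool:
        if s.n_ns < self.min_ns:
            return False
        if self.require_ns_exceeds_s and not s.n_ns > s.n_s:
            return False
        return True
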