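"""The packaged housekeeping-gene SNP inventory.

This module ships the published per-gene SNP table for the chromium-tolerant
*A. flavus* strain contrasted with the reference strain: 128 housekeeping
genes with their CDS lengths, nucleotide-change tokens (``T1871C``),
amino-acid-change tokens (``V624A``) and printed synonymous/nonsynonymous
status. It is the in-package comparator set for burden statistics and the
concordance target for the codon classifier.

Positions in nucleotide tokens are read as 1-based coordinates within the
spliced CDS, so the codon index is ``ceil(pos / 3)``; rows whose printed
amino-acid index disagrees with that reading, or whose tokens use non-ACGT
bases, are flagged rather than reinterpreted. The table is transcribed
verbatim — including three rows with unequal token lists — and guarded by a
checksum.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .effects import codon_to_aa
from .models import (
    CDS,
    EffectCall,
    NONSYNONYMOUS,
    NUCLEOTIDES,
    SYNONYMOUS,
    SnpBurdenError,
    VariantRecord,
)

FIXTURE_SHA256 = "e4f9c276849fb6ad90ab1c61237b6bde860dbfb286586c791fbba9458fcb413d"

_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z])$")

AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ChangeToken:
    """One parsed change token: reference symbol, 1-based position, alternate."""

    ref: str
    pos: int
    alt: str

    @classmethod
    def parse(cls, token: str, context: str = "") -> "ChangeToken":
        m = _TOKEN.match(token)
        if not m:
            raise SnpBurdenError(
                f"unparsable change token {token!r}"
                + (f" in {context}" if context else "")
            )
        return cls(m.group(1), int(m.group(2)), m.group(3))

    @property
    def text(self) -> str:
        return f"{self.ref}{self.pos}{self.alt}"


@dataclass(frozen=True)
class HousekeepingRow:
    """One gene of the housekeeping inventory."""

    reference_gene_id: str
    test_gene_id: str
    annotation: str
    gene_length: int
    nucleotide_changes: tuple[str, ...]
    aa_changes: tuple[str, ...]
    statuses: tuple[str, ...]

    @property
    def n_changes(self) -> int:
        return len(self.nucleotide_changes)

    @property
    def n_s(self) -> int:
        return sum(s == "sSNPs" for s in self.statuses)

    @property
    def n_ns(self) -> int:
        return sum(s == "nsSNPs" for s in self.statuses)

    @property
    def unpaired(self) -> bool:
        """True when the printed token lists have unequal length."""
        return len(self.nucleotide_changes) != len(self.aa_changes)

    def paired_tokens(self) -> list[tuple[ChangeToken, ChangeToken, str]]:
        """(nucleotide, amino-acid, status) triples for the pairable tokens.

        In the few rows printing more nucleotide tokens than amino-acid
        tokens, pairing follows the codon rule: each amino-acid token is
        matched to the nucleotide token whose ``ceil(pos/3)`` equals its
        index, in order; leftovers stay unpaired.
        """
        nucl = [ChangeToken.parse(t, self.test_gene_id)
                for t in self.nucleotide_changes]
        aa = [ChangeToken.parse(t, self.test_gene_id) for t in self.aa_changes]
        sts = list(self.statuses)
        if len(nucl) == len(aa):
            return list(zip(nucl, aa, sts))
        out = []
        ni = 0
        for a, s in zip(aa, sts):
            while ni < len(nucl) and math.ceil(nucl[ni].pos / 3) != a.pos:
                ni += 1
            if ni < len(nucl):
                out.append((nucl[ni], a, s))
                ni += 1
        return out

    def ambiguous_tokens(self) -> list[str]:
        """Tokens kept verbatim but unusable for codon checks: non-ACGT
        bases, ref == alt, or an ``X`` amino acid."""
        bad = []
        for t in self.nucleotide_changes:
            tok = ChangeToken.parse(t, self.test_gene_id)
            if {tok.ref, tok.alt} - NUCLEOTIDES or tok.ref == tok.alt:
                bad.append(t)
        for t in self.aa_changes:
            tok = ChangeToken.parse(t, self.test_gene_id)
            if {tok.ref, tok.alt} - AA_LETTERS:
                bad.append(t)
        return bad


@dataclass(frozen=True)
class HousekeepingTable:
    rows: tuple[HousekeepingRow, ...]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def total_length(self) -> int:
        return sum(r.gene_length for r in self.rows)

    @property
    def n_changes(self) -> int:
        return sum(r.n_changes for r in self.rows)

    @property
    def n_s(self) -> int:
        return sum(r.n_s for r in self.rows)

    @property
    def n_ns(self) -> int:
        return sum(r.n_ns for r in self.rows)


def load_housekeeping_table(path: str | Path | None = None) -> HousekeepingTable:
    """Load the packaged housekeeping SNP inventory (or a same-dialect TSV).

    When loading the packaged copy its SHA-256 checksum is verified; a
    mismatch is an error, since every downstream comparison depends on the
    transcription being byte-exact.
    """
    verify = path is None
    if path is None:
        ref = resources.files("snpburden") / "data" / "housekeeping_snps.tsv"
        with resources.as_file(ref) as p:
            return _load(p, verify)
    return _load(Path(path), verify)


def _load(path: Path, verify: bool) -> HousekeepingTable:
    data = path.read_bytes()
    if verify:
        digest = hashlib.sha256(data).hexdigest()
        if digest != FIXTURE_SHA256:
            raise SnpBurdenError(
                f"housekeeping fixture checksum mismatch: {digest} != "
                f"{FIXTURE_SHA256}"
            )
    rows = []
    header_seen = False
    for line in data.decode().splitlines():
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True  # column header line
            continue
        cols = line.split("\t")
        if len(cols) != 7:
            raise SnpBurdenError(f"{path}: malformed row: {line!r}")
        ref_id, test_id, annot, length, nucl, aa, status = cols
        split = lambda s: tuple(s.split(",")) if s else ()
        row = HousekeepingRow(
            reference_gene_id=ref_id,
            test_gene_id=test_id,
            annotation=annot,
            gene_length=int(length),
            nucleotide_changes=split(nucl),
            aa_changes=split(aa),
            statuses=split(status),
        )
        if row.gene_length <= 0:
            raise SnpBurdenError(f"{path}: non-positive length for {test_id}")
        if len(row.aa_changes) != len(row.statuses):
            raise SnpBurdenError(
                f"{path}: row {test_id}: {len(row.aa_changes)} aa tokens vs "
                f"{len(row.statuses)} statuses"
            )
        rows.append(row)
    return HousekeepingTable(rows=tuple(rows))


def to_effect_calls(table: HousekeepingTable) -> list[EffectCall]:
    """Expand every printed token pair into an EffectCall.

    Positions are CDS-relative; the class comes from the printed status, not
    from re-translation (the inventory carries no sequence). One call per
    amino-acid token, so the count equals the table's total status count.
    """
    calls = []
    for row in table.rows:
        for nucl, aa, status in row.paired_tokens():
            klass = SYNONYMOUS if status == "sSNPs" else NONSYNONYMOUS
            variant = None
            if not ({nucl.ref, nucl.alt} - NUCLEOTIDES) and nucl.ref != nucl.alt:
                variant = VariantRecord(
                    contig_id=row.test_gene_id, pos=nucl.pos,
                    ref=nucl.ref, alt=nucl.alt, depth=None,
                )
            codon_index = aa.pos
            offset = nucl.pos - (math.ceil(nucl.pos / 3) - 1) * 3
            calls.append(
                EffectCall(
                    variant=variant,
                    gene_id=row.test_gene_id,
                    region=CDS,
                    cds_pos=nucl.pos,
                    codon_index=codon_index,
                    codon_offset=offset,
                    ref_aa=aa.ref,
                    alt_aa=aa.alt,
                    klass=klass,
                    notation=aa.text,
                )
            )
    return calls


def is_cds_consistent(
    nucl: ChangeToken, aa: ChangeToken, status: str, code_table: int = 1
) -> bool:
    """Check one token pair against the CDS-coordinate reading.

    Consistent means: plain A/C/G/T nucleotides with ref != alt, valid amino
    acids, ``ceil(pos/3)`` equals the printed codon index, the printed status
    agrees with residue identity, and some codon context realises the pair
    (see :func:`reconstruct_codon_context`).
    """
    if {nucl.ref, nucl.alt} - NUCLEOTIDES or nucl.ref == nucl.alt:
        return False
    if {aa.ref, aa.alt} - AA_LETTERS:
        return False
    if math.ceil(nucl.pos / 3) != aa.pos:
        return False
    if (aa.ref == aa.alt) != (status == "sSNPs"):
        return False
    return reconstruct_codon_context(nucl, aa, code_table) is not None


def reconstruct_codon_context(
    nucl: ChangeToken, aa: ChangeToken, code_table: int = 1
) -> str | None:
    """Find a reference codon realising a printed token pair, or None.

    The codon must carry the nucleotide reference base at the within-codon
    offset implied by the CDS position, translate to the printed reference
    residue, and translate to the printed alternate residue once the base is
    substituted. Deterministic: the lexicographically smallest such codon is
    returned.
    """
    aa_map = codon_to_aa(code_table)
    codon_index = math.ceil(nucl.pos / 3)
    offset = nucl.pos - (codon_index - 1) * 3  # 1..3
    for codon in sorted(aa_map):
        if codon[offset - 1] != nucl.ref:
            continue
        if aa_map[codon] != aa.ref:
            continue
        mutated = codon[: offset - 1] + nucl.alt + codon[offset:]
        if aa_map[mutated] == aa.alt:
            return codon
    return None


def consistent_pairs(
    table: HousekeepingTable, code_table: int = 1
) -> list[tuple[HousekeepingRow, ChangeToken, ChangeToken, str]]:
    """All token pairs of the table that pass :func:`is_cds_consistent`."""
    out = []
    for row in table.rows:
        for nucl, aa, status in row.paired_tokens():
            if is_cds_consistent(nucl, aa, status, code_table):
                out.append((row, nucl, aa, status))
    return out
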