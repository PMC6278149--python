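"""Domain-based candidate gene screening.

A gene is a chromium-tolerance candidate when its InterPro domain content
intersects a target list of accessions curated from experimentally verified
bacterial metal-resistance genes. The packaged default target list holds the
ten accessions observed in *A. flavus* across six gene-family labels (chrA,
chrE, chrR, mdrL/yfmO, recG, ruvB); a user-supplied TSV can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .models import (
    DomainAnnotation,
    IPR_PATTERN,
    SnpBurdenError,
    TargetDomain,
)


@dataclass(frozen=True)
class TargetDomainList:
    """Mapping of target IPR accession -> family label (+ description)."""

    entries: dict[str, TargetDomain]

    def __post_init__(self) -> None:
        for acc, entry in self.entries.items():
            if not IPR_PATTERN.match(acc):
                raise SnpBurdenError(f"malformed target accession {acc!r}")
            if not entry.family:
                raise SnpBurdenError(f"target {acc}: empty family label")

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(self.entries)

    def family_of(self, accession: str) -> str:
        return self.entries[accession].family


def load_target_domains(path: str | Path | None = None) -> TargetDomainList:
    """Load a target-domain TSV (accession, family, description, mechanism).

    With no path the packaged default list is used. Duplicate accessions with
    conflicting family labels are an error.
    """
    if path is None:
        ref = resources.files("snpburden") / "data" / "target_domains.tsv"
        with resources.as_file(ref) as p:
            return load_target_domains(p)
    entries: dict[str, TargetDomain] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = (line.split("\t") + ["", "", ""])[:4]
            acc, family, desc, mech = (c.strip() for c in cols)
            if acc in entries and entries[acc].family != family:
                raise SnpBurdenError(
                    f"target accession {acc} listed twice with conflicting "
                    f"families {entries[acc].family!r} and {family!r}"
                )
            entries[acc] = TargetDomain(acc, family, desc, mech)
    return TargetDomainList(entries=entries)


def write_target_domains(targets: TargetDomainList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for acc in sorted(targets.entries):
            e = targets.entries[acc]
            fh.write(f"{acc}\t{e.family}\t{e.description}\t{e.mechanism}\n")


@dataclass
class CandidateSet:
    """Genes carrying at least one target accession, with match details."""

    gene_ids: set[str] = field(default_factory=set)
    matched_accessions: dict[str, frozenset[str]] = field(default_factory=dict)
    matched_families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": g,
                "accessions": ",".join(sorted(self.matched_accessions[g])),
                "families": ",".join(self.matched_families[g]),
            }
            for g in sorted(self.gene_ids)
        ]
        return pd.DataFrame(rows, columns=["gene_id", "accessions", "families"])


def select_candidates(
    annotations: list[DomainAnnotation], targets: TargetDomainList
) -> CandidateSet:
    """Select genes whose accession set intersects the target list."""
    if not targets.entries:
        raise SnpBurdenError("empty target domain list: selection undefined")
    out = CandidateSet()
    for ann in annotations:
        matched = ann.ipr_accessions & targets.accessions
        if not matched:
            continue
        out.gene_ids.add(ann.gene_id)
        # merge when a gene appears in several annotation records
        prev = out.matched_accessions.get(ann.gene_id, frozenset())
        combined = prev | matched
        out.matched_accessions[ann.gene_id] = combined
        fams = sorted({targets.family_of(a) for a in combined})
        out.matched_families[ann.gene_id] = tuple(fams)
    return out


def tally_by_domain(
    annotations: list[DomainAnnotation], targets: TargetDomainList
) -> pd.DataFrame:
    """Per-accession gene counts, one row per target accession.

    The counting unit is genes containing at least one instance of the
    accession, not domain instances; zero-count accessions are included.
    """
    genes_by_acc: dict[str, set[str]] = {a: set() for a in targets.entries}
    for ann in annotations:
        for acc in ann.ipr_accessions & targets.accessions:
            genes_by_acc[acc].add(ann.gene_id)
    rows = [
        {
            "family": targets.family_of(acc),
            "accession": acc,
            "n_genes": len(genes_by_acc[acc]),
        }
        for acc in targets.entries
    ]
    return pd.DataFrame(rows, columns=["family", "accession", "n_genes"])
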