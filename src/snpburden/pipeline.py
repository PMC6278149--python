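"""End-to-end orchestration: read -> filter -> select -> annotate -> burden.

Every run writes its intermediate tables plus a manifest (config echo, input
checksums, package version, and the stage-count funnel: candidates, SNP-free
candidates, candidates with only synonymous changes, high-nsSNP candidates)
so that a run is reproducible and auditable from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .burden import compare_sets, flag_high_ns, gene_burden, set_burden
from .candidates import load_target_domains, select_candidates, tally_by_domain
from .effects import annotate_all
from .filtering import apply_variant_filters
from .housekeeping import load_housekeeping_table
from .io import read_domain_table, read_fasta, read_gene_list, read_gff3, read_vcf
from .models import (
    BurdenSummary,
    CDS,
    FilterConfig,
    HighNsRule,
    SYNONYMOUS,
    SetBurden,
    SnpBurdenError,
    genome_as_dict,
)

#: per-kb rates printed in the published housekeeping footer, one decimal
PRINTED_FOOTER = {"snp": 0.9, "s": 0.7, "ns": 0.4}


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    ``comparator_genes`` names a gene list inside the dataset to contrast
    the candidates against; when absent the packaged housekeeping inventory
    is the comparator.
    """

    genome: Path
    gff3: Path
    vcf: Path
    domains: Path
    outdir: Path
    targets: Path | None = None
    comparator_genes: Path | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    high_ns: HighNsRule = field(default_factory=HighNsRule)
    genetic_code: int = 1
    collapse_stops: bool = True
    bootstrap_reps: int = 1000
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        for name in ("genome", "gff3", "vcf", "domains", "outdir"):
            setattr(self, name, Path(getattr(self, name)))
        for name in ("targets", "comparator_genes"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))

    def validate(self) -> None:
        for name in ("genome", "gff3", "vcf", "domains"):
            p = getattr(self, name)
            if not p.exists():
                raise SnpBurdenError(f"input path for {name} missing: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "filter" in raw:
            raw["filter"] = FilterConfig(**raw["filter"])
        if "high_ns" in raw:
            raw["high_ns"] = HighNsRule(**raw["high_ns"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _calls_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        v = c.variant
        rows.append(
            {
                "contig": v.contig_id if v else "",
                "pos": v.pos if v else "",
                "ref": v.ref if v else "",
                "alt": v.alt if v else "",
                "depth": v.depth if v else "",
                "gene_id": c.gene_id or "",
                "region": c.region,
                "cds_pos": c.cds_pos or "",
                "codon_index": c.codon_index or "",
                "ref_codon": c.ref_codon or "",
                "alt_codon": c.alt_codon or "",
                "klass": c.klass,
                "notation": c.notation or "",
                "overlaps": ",".join(c.overlaps),
            }
        )
    return pd.DataFrame(rows)


def housekeeping_set_burden(table=None) -> SetBurden:
    """The packaged housekeeping inventory as a SetBurden comparator.

    Counts follow the printed per-token statuses; in the few rows printing
    more nucleotide than amino-acid tokens the extra changes count toward
    the SNP total but to neither class.
    """
    table = table if table is not None else load_housekeeping_table()
    summaries = [
        BurdenSummary(
            gene_id=r.test_gene_id,
            gene_length=r.gene_length,
            n_snp=r.n_changes,
            n_s=r.n_s,
            n_ns=r.n_ns,
            n_other=r.n_changes - r.n_s - r.n_ns,
        )
        for r in table.rows
    ]
    return set_burden(summaries, "housekeeping")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written)."""
    cfg.validate()
    cfg.outdir.mkdir(parents=True, exist_ok=True)

    genomes = read_fasta(cfg.genome)
    genome = genome_as_dict(genomes)
    models = read_gff3(cfg.gff3)
    variants = read_vcf(cfg.vcf, strict_depth=cfg.strict)
    annotations = read_domain_table(cfg.domains, strict=cfg.strict)
    targets = load_target_domains(cfg.targets)

    retained, report = apply_variant_filters(variants, cfg.filter)
    removed_rows = pd.DataFrame(
        [
            {"contig": v.contig_id, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "depth": "" if v.depth is None else v.depth, "reason": reason}
            for v, reason in report.removed
        ]
    )
    removed_rows.to_csv(cfg.outdir / "filter_removed.tsv", sep="\t", index=False)
    filter_summary = {
        "n_input": report.n_input,
        "n_retained": report.n_retained,
        "removed_by_reason": report.counts_by_reason(),
        "flagged_unknown_depth": len(report.flagged_unknown_depth),
    }

    cands = select_candidates(annotations, targets)
    cands.to_frame().to_csv(cfg.outdir / "candidates.tsv", sep="\t", index=False)
    tally_by_domain(annotations, targets).to_csv(
        cfg.outdir / "domain_tally.tsv", sep="\t", index=False
    )

    result = annotate_all(retained, models, genome, cfg.genetic_code,
                          lenient=not cfg.strict)
    _calls_frame(result.calls).to_csv(
        cfg.outdir / "effects.tsv", sep="\t", index=False
    )

    by_gene: dict[str, list] = {}
    for call in result.calls:
        if call.region == CDS and call.gene_id:
            by_gene.setdefault(call.gene_id, []).append(call)
    summaries = [
        gene_burden(by_gene.get(m.gene_id, []), m,
                    collapse_stops=cfg.collapse_stops)
        for m in models
    ]
    pd.DataFrame(
        [
            {"gene_id": s.gene_id, "gene_length": s.gene_length,
             "n_snp": s.n_snp, "n_s": s.n_s, "n_ns": s.n_ns,
             "n_other": s.n_other, "rate_snp": round(s.rate_snp, 4),
             "rate_s": round(s.rate_s, 4), "rate_ns": round(s.rate_ns, 4)}
            for s in summaries
        ]
    ).to_csv(cfg.outdir / "burden_genes.tsv", sep="\t", index=False)

    by_id = {s.gene_id: s for s in summaries}
    cand_summaries = [by_id[g] for g in sorted(cands.gene_ids) if g in by_id]
    funnel = _funnel(cands, cand_summaries, cfg.high_ns)

    manifest = {
        "tool": "snpburden",
        "version": __version__,
        "seed": cfg.seed,
        "config": _config_echo(cfg),
        "input_checksums": {
            name: _sha256(getattr(cfg, name))
            for name in ("genome", "gff3", "vcf", "domains")
        },
        "filter": filter_summary,
        "funnel": funnel,
        "annotation_errors": len(result.errors),
        "class_counts": result.class_counts(collapse_stops=cfg.collapse_stops),
    }

    if cand_summaries:
        cand_set = set_burden(cand_summaries, "candidates")
        if cfg.comparator_genes is not None:
            comp_ids = set(read_gene_list(cfg.comparator_genes))
            comp_summaries = [s for s in summaries if s.gene_id in comp_ids]
            comp_set = set_burden(comp_summaries, cfg.comparator_genes.stem)
        else:
            comp_set = housekeeping_set_burden()
        comparison = compare_sets(cand_set, comp_set,
                                  bootstrap_reps=cfg.bootstrap_reps,
                                  seed=cfg.seed)
        comp_json = {
            "label": comparison.label,
            "bootstrap_reps": comparison.bootstrap_reps,
            "note": comparison.note,
            "sets": {
                s.set_name: {
                    "total_length": s.total_length, "n_snp": s.n_snp,
                    "n_s": s.n_s, "n_ns": s.n_ns,
                    "rate_snp": round(s.rate_snp, 4),
                    "rate_s": round(s.rate_s, 4),
                    "rate_ns": round(s.rate_ns, 4),
                }
                for s in (cand_set, comp_set)
            },
            "ratios": [dataclasses.asdict(r) for r in comparison.ratios],
        }
        (cfg.outdir / "comparison.json").write_text(
            json.dumps(comp_json, indent=2) + "\n"
        )
        manifest["comparison"] = {
            r.klass: r.ratio for r in comparison.ratios
        }

    (cfg.outdir / "filter_summary.json").write_text(
        json.dumps(filter_summary, indent=2) + "\n"
    )
    (cfg.outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _config_echo(cfg: PipelineConfig) -> dict:
    raw = dataclasses.asdict(cfg)
    return {
        k: (str(v) if isinstance(v, Path) else v) for k, v in raw.items()
    }


def _funnel(cands, cand_summaries, rule: HighNsRule) -> dict:
    with_snps = [s for s in cand_summaries if s.n_snp > 0]
    only_syn = [
        s for s in with_snps if s.n_s == s.n_snp and s.n_ns == 0
    ]
    high = flag_high_ns(with_snps, rule)
    return {
        "candidates": len(cands),
        "candidates_snp_free": len(cands) - len(with_snps),
        "candidates_with_snps": len(with_snps),
        "candidates_only_synonymous": len(only_syn),
        "candidates_high_ns": len(high),
        "high_ns_gene_ids": [s.gene_id for s in high],
        "high_ns_rule": {"min_ns": rule.min_ns,
                         "require_ns_exceeds_s": rule.require_ns_exceeds_s},
    }


def run_fixture_check() -> dict:
    """Recompute the housekeeping pooled per-kb rates and compare them with
    the published footer at one-decimal rounding.

    Returns a report dict with one entry per rate class: the computed pooled
    rate, its one-decimal presentation, the printed value and a pass flag.
    """
    hk = housekeeping_set_burden()
    checks = {}
    for klass, computed in (
        ("snp", hk.rate_snp), ("s", hk.rate_s), ("ns", hk.rate_ns)
    ):
        printed = PRINTED_FOOTER[klass]
        rounded = round(computed, 1)
        checks[klass] = {
            "computed": computed,
            "rounded": rounded,
            "printed": printed,
            "pass": rounded == printed,
        }
    return {
        "n_genes": len(hk.genes),
        "total_length": hk.total_length,
        "n_snp": hk.n_snp,
        "n_s": hk.n_s,
        "n_ns": hk.n_ns,
        "checks": checks,
    }
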