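"""Synthetic genomes with planted, ground-truthed variants.

The generator emulates the structure of a resequencing study of a multi-gene
fungal genome: several contigs carrying stranded, possibly multi-exon CDSs;
SNPs planted inside coding sequence with *known* synonymous/nonsynonymous
status (chosen by codon translation at planting time, respecting strand);
noncoding SNPs; small INDELs; per-variant read depths from a negative
binomial; and a controllable fraction of SNPs forced below the depth
threshold or placed within the INDEL-vicinity window, so that filter and
classifier behaviour can be checked against planted truth exactly.

It does not simulate reads, alignment or variant calling — the planted VCF
stands in for a caller's output — and gene sequences are random nucleotides,
not homologues of any real gene.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .effects import codon_to_aa, revcomp, spliced_cds, translate_cds
from .io import write_domain_table, write_fasta, write_gff3, write_gene_list, write_vcf
from .models import (
    GeneModel,
    GenomeSequence,
    NONCODING,
    NONSYNONYMOUS,
    SYNONYMOUS,
    SnpBurdenError,
    VariantRecord,
)

_BASES = "ACGT"
STOP = "*"

#: decoy (non-target) accessions handed to non-candidate genes
_DECOY_ACCESSIONS = tuple(f"IPR90000{i}" for i in range(1, 9))


@dataclass(frozen=True)
class PlantedCounts:
    """How many variants of each intended class to plant."""

    synonymous: int = 50
    nonsynonymous: int = 50
    noncoding: int = 30
    indels: int = 20

    @property
    def n_snps(self) -> int:
        return self.synonymous + self.nonsynonymous + self.noncoding

    @property
    def total(self) -> int:
        return self.n_snps + self.indels


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic dataset; same spec => same bytes.

    ``depth_mean`` / ``depth_dispersion`` parameterize a negative binomial
    (dispersion is the NB size parameter; variance = mean + mean^2/size).
    ``low_depth_fraction`` of the planted SNPs get depths drawn uniformly
    below ``depth_threshold`` instead; ``near_indel_fraction`` of the planted
    SNPs (taken from the noncoding pool) are placed within ``indel_window``
    nt of a planted INDEL. ``candidate_domain_fraction`` of genes receive at
    least one target InterPro accession.
    """

    seed: int = 0
    n_contigs: int = 3
    contig_length: int = 60_000
    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (1, 4)
    strand_fraction_plus: float = 0.5
    planted: PlantedCounts = field(default_factory=PlantedCounts)
    depth_mean: float = 200.0
    depth_dispersion: float = 10.0
    low_depth_fraction: float = 0.1
    near_indel_fraction: float = 0.1
    candidate_domain_fraction: float = 0.25
    depth_threshold: int = 5
    indel_window: int = 10

    def __post_init__(self) -> None:
        p = self.planted
        if min(p.synonymous, p.nonsynonymous, p.noncoding, p.indels) < 0:
            raise SnpBurdenError("planted counts must be non-negative")
        for name in ("strand_fraction_plus", "low_depth_fraction",
                     "near_indel_fraction", "candidate_domain_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SnpBurdenError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise SnpBurdenError("exons_per_gene must be a range with 1 <= lo <= hi")
        if self.n_contigs < 1 or self.n_genes < 0 or self.contig_length < 1000:
            raise SnpBurdenError("need >=1 contig of >=1000 nt")


@dataclass(frozen=True)
class TruthVariant:
    contig_id: str
    pos: int
    ref: str
    alt: str
    depth: int
    vclass: str
    intended_region: str
    intended_class: str
    gene_id: str | None
    low_depth: bool
    near_indel: bool


@dataclass(frozen=True)
class TruthGene:
    gene_id: str
    accessions: tuple[str, ...]
    is_candidate: bool


@dataclass
class TruthTable:
    variants: list[TruthVariant]
    genes: list[TruthGene]

    def variants_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(v) for v in self.variants])

    def genes_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g.gene_id, "accessions": ",".join(g.accessions),
             "is_candidate": g.is_candidate}
            for g in self.genes
        ]
        return pd.DataFrame(rows)

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.variants:
            out[v.intended_class] = out.get(v.intended_class, 0) + 1
        return out


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    genomes: list[GenomeSequence]
    models: list[GeneModel]
    variants: list[VariantRecord]
    annotations: list  # list[DomainAnnotation]
    truth: TruthTable

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the dataset in the pipeline's input dialects; deterministic."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "vcf": outdir / "variants.vcf",
            "domains": outdir / "domains.tsv",
            "truth_variants": outdir / "truth_variants.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
            "candidates": outdir / "candidate_genes.txt",
            "background": outdir / "background_genes.txt",
        }
        write_fasta(self.genomes, paths["genome"])
        write_gff3(self.models, paths["gff3"])
        write_vcf(self.variants, paths["vcf"],
                  {g.contig_id: len(g) for g in self.genomes})
        write_domain_table(self.annotations, paths["domains"])
        self.truth.variants_frame().to_csv(
            paths["truth_variants"], sep="\t", index=False)
        self.truth.genes_frame().to_csv(
            paths["truth_genes"], sep="\t", index=False)
        cand = [g.gene_id for g in self.truth.genes if g.is_candidate]
        rest = [g.gene_id for g in self.truth.genes if not g.is_candidate]
        write_gene_list(cand, paths["candidates"])
        write_gene_list(rest, paths["background"])
        return paths


def spec_from_yaml(path: str | Path) -> SimulationSpec:
    """Read a SimulationSpec from a flat YAML mapping (documented keys =
    the dataclass fields; ``planted`` is a nested mapping)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "planted" in raw:
        raw["planted"] = PlantedCounts(**raw["planted"])
    if "exons_per_gene" in raw:
        raw["exons_per_gene"] = tuple(raw["exons_per_gene"])
    return SimulationSpec(**raw)


def spec_to_yaml(spec: SimulationSpec, path: str | Path) -> None:
    raw = dataclasses.asdict(spec)
    raw["exons_per_gene"] = list(spec.exons_per_gene)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# generation


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate a dataset with planted ground truth; see module docstring."""
    rng = np.random.default_rng(spec.seed)
    contigs = [f"contig{i + 1}" for i in range(spec.n_contigs)]
    seqs = {
        c: "".join(_BASES[b] for b in rng.integers(0, 4, spec.contig_length))
        for c in contigs
    }
    models = _place_genes(spec, rng, contigs)
    genome = dict(seqs)

    aa_map = codon_to_aa(1)
    used: set[tuple[str, int]] = set()
    planted: list[_Plant] = []

    for klass, count in (
        (SYNONYMOUS, spec.planted.synonymous),
        (NONSYNONYMOUS, spec.planted.nonsynonymous),
    ):
        _plant_coding(spec, rng, models, genome, aa_map, klass, count,
                      used, planted)

    n_near = int(round(spec.near_indel_fraction * spec.planted.n_snps))
    if n_near > spec.planted.noncoding:
        raise SnpBurdenError(
            f"infeasible spec: near_indel_fraction asks for {n_near} "
            f"near-INDEL SNPs but only {spec.planted.noncoding} noncoding "
            "SNPs are planted (the near-INDEL subset is drawn from them)"
        )
    if n_near > 0 and spec.planted.indels == 0:
        raise SnpBurdenError(
            "infeasible spec: near_indel_fraction > 0 with no planted INDELs"
        )
    _plant_noncoding(spec, rng, models, genome,
                     spec.planted.noncoding - n_near, used, planted)
    indels = _plant_indels(spec, rng, models, genome, used, planted)
    _plant_near_indel(spec, rng, models, genome, n_near, indels, used, planted)

    _assign_depths(spec, rng, planted)
    _self_check_coding(spec, models, genome, planted)

    planted.sort(key=lambda p: (p.contig_id, p.pos))
    variants = [
        VariantRecord(p.contig_id, p.pos, p.ref, p.alt, p.depth)
        for p in planted
    ]
    truth_variants = [
        TruthVariant(
            contig_id=p.contig_id, pos=p.pos, ref=p.ref, alt=p.alt,
            depth=p.depth, vclass=p.vclass, intended_region=p.region,
            intended_class=p.klass, gene_id=p.gene_id,
            low_depth=p.low_depth, near_indel=p.near_indel,
        )
        for p in planted
    ]
    annotations, truth_genes = _assign_domains(spec, rng, models)
    return SimulatedDataset(
        spec=spec,
        genomes=[GenomeSequence(c, seqs[c]) for c in contigs],
        models=models,
        variants=variants,
        annotations=annotations,
        truth=TruthTable(variants=truth_variants, genes=truth_genes),
    )


@dataclass
class _Plant:
    contig_id: str
    pos: int
    ref: str
    alt: str
    region: str
    klass: str
    gene_id: str | None
    vclass: str
    depth: int = 0
    low_depth: bool = False
    near_indel: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.pos, self.pos + len(self.ref) - 1


def _place_genes(
    spec: SimulationSpec, rng: np.random.Generator, contigs: list[str]
) -> list[GeneModel]:
    margin, models = 300, []
    gene_no = 0
    ci = 0
    cursor = margin
    while gene_no < spec.n_genes:
        if ci >= len(contigs):
            raise SnpBurdenError(
                f"infeasible spec: placed {gene_no}/{spec.n_genes} genes; "
                "binding constraint is total contig space "
                f"({spec.n_contigs} x {spec.contig_length} nt)"
            )
        k = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        n_codons = int(rng.integers(60, 181))
        cds_len = 3 * n_codons
        seg_base = cds_len // k
        seg_lens = [seg_base] * k
        seg_lens[-1] += cds_len - seg_base * k
        intron_lens = [int(rng.integers(40, 101)) for _ in range(k - 1)]
        strand = "+" if rng.random() < spec.strand_fraction_plus else "-"
        span = sum(seg_lens) + sum(intron_lens)
        if cursor + span > spec.contig_length - margin:
            ci += 1
            cursor = margin
            continue
        segs, at = [], cursor
        for j, sl in enumerate(seg_lens):
            segs.append((at, at + sl - 1))
            at += sl
            if j < k - 1:
                at += intron_lens[j]
        gene_no += 1
        models.append(
            GeneModel(
                gene_id=f"g{gene_no:03d}",
                contig_id=contigs[ci],
                strand=strand,
                cds_segments=tuple(segs),
                annotation="synthetic",
            )
        )
        cursor = segs[-1][1] + int(rng.integers(150, 301))
    return models


def _genome_position(model: GeneModel, cds_pos: int) -> int:
    """Inverse of the CDS coordinate mapping: spliced position -> genome."""
    fwd = cds_pos if model.strand == "+" else model.cds_length - cds_pos + 1
    left = fwd
    for start, end in model.cds_segments:
        seg = end - start + 1
        if left <= seg:
            return start + left - 1
        left -= seg
    raise SnpBurdenError(f"cds_pos {cds_pos} outside gene {model.gene_id}")


def _plant_coding(spec, rng, models, genome, aa_map, klass, count,
                  used, planted) -> None:
    if count == 0:
        return
    coding_models = list(models)
    if not coding_models:
        raise SnpBurdenError("infeasible spec: coding SNPs planted but no genes")
    total_codons = sum(m.cds_length // 3 for m in coding_models)
    if count > total_codons:
        raise SnpBurdenError(
            f"infeasible spec: {count} {klass} SNPs requested but only "
            f"{total_codons} codon positions exist"
        )
    done, attempts = 0, 0
    max_attempts = 200 * count + 1000
    while done < count:
        attempts += 1
        if attempts > max_attempts:
            raise SnpBurdenError(
                f"infeasible spec: could not place {count} {klass} SNPs "
                f"(placed {done}); binding constraint is available codon "
                "positions free of earlier plants"
            )
        m = coding_models[int(rng.integers(len(coding_models)))]
        cds = spliced_cds(m, genome)
        codon_i = int(rng.integers(1, m.cds_length // 3 + 1))
        codon = cds[(codon_i - 1) * 3 : codon_i * 3]
        choices = []
        for off in (1, 2, 3):
            cds_pos = (codon_i - 1) * 3 + off
            gpos = _genome_position(m, cds_pos)
            if (m.contig_id, gpos) in used:
                continue
            for alt in _BASES:
                if alt == codon[off - 1]:
                    continue
                mutated = codon[: off - 1] + alt + codon[off:]
                ref_aa, alt_aa = aa_map[codon], aa_map[mutated]
                if klass == SYNONYMOUS:
                    ok = ref_aa == alt_aa and ref_aa != STOP
                else:
                    ok = (ref_aa != alt_aa and ref_aa != STOP
                          and alt_aa != STOP)
                if ok:
                    choices.append((cds_pos, gpos, codon[off - 1], alt))
        if not choices:
            continue
        cds_pos, gpos, ref_b, alt_b = choices[int(rng.integers(len(choices)))]
        if m.strand == "-":
            ref_g, alt_g = revcomp(ref_b), revcomp(alt_b)
        else:
            ref_g, alt_g = ref_b, alt_b
        used.add((m.contig_id, gpos))
        planted.append(
            _Plant(m.contig_id, gpos, ref_g, alt_g, "CDS", klass,
                   m.gene_id, "SNP")
        )
        done += 1


def _region_of(pos: int, contig: str, models) -> tuple[str, str | None]:
    for m in models:
        if m.contig_id != contig:
            continue
        lo, hi = m.span
        if lo <= pos <= hi:
            return ("CDS" if m.contains(pos) else "intron"), m.gene_id
    return "intergenic", None


def _random_alt(rng, ref: str) -> str:
    alts = [b for b in _BASES if b != ref]
    return alts[int(rng.integers(3))]


def _plant_noncoding(spec, rng, models, genome, count, used, planted) -> None:
    contigs = sorted(genome)
    done, attempts = 0, 0
    while done < count:
        attempts += 1
        if attempts > 200 * count + 1000:
            raise SnpBurdenError(
                "infeasible spec: could not place noncoding SNPs; binding "
                "constraint is noncoding genome space"
            )
        c = contigs[int(rng.integers(len(contigs)))]
        pos = int(rng.integers(1, len(genome[c]) + 1))
        if (c, pos) in used:
            continue
        region, gene_id = _region_of(pos, c, models)
        if region == "CDS":
            continue
        ref = genome[c][pos - 1]
        if ref == "N":
            continue
        used.add((c, pos))
        planted.append(
            _Plant(c, pos, ref, _random_alt(rng, ref), region, NONCODING,
                   gene_id, "SNP")
        )
        done += 1


def _plant_indels(spec, rng, models, genome, used, planted) -> list[_Plant]:
    count = spec.planted.indels
    contigs = sorted(genome)
    snp_positions = [(p.contig_id, p.pos) for p in planted]
    out: list[_Plant] = []
    done, attempts = 0, 0
    while done < count:
        attempts += 1
        if attempts > 500 * count + 1000:
            raise SnpBurdenError(
                "infeasible spec: could not place INDELs far enough from "
                "planted SNPs; binding constraint is intergenic space vs "
                "indel_window"
            )
        c = contigs[int(rng.integers(len(contigs)))]
        length = int(rng.integers(1, 6))  # 1-5 nt inserted/deleted
        is_del = bool(rng.integers(2))
        span_len = 1 + length if is_del else 1
        pos = int(rng.integers(2, len(genome[c]) - span_len))
        span = (pos, pos + span_len - 1)
        region, _ = _region_of(pos, c, models)
        if region != "intergenic":
            continue
        if any((c, p) in used for p in range(span[0], span[1] + 1)):
            continue
        # keep every already-planted SNP strictly outside the window
        near = any(
            cc == c and _gap(sp, span) <= spec.indel_window
            for cc, sp in snp_positions
        )
        if near:
            continue
        ref = genome[c][pos - 1 : pos - 1 + span_len]
        if "N" in ref:
            continue
        if is_del:
            alt = ref[0]
        else:
            ins = "".join(_BASES[b] for b in rng.integers(0, 4, length))
            alt = ref + ins
        for p in range(span[0], span[1] + 1):
            used.add((c, p))
        plant = _Plant(c, pos, ref, alt, "intergenic", "indel", None, "INDEL")
        planted.append(plant)
        out.append(plant)
        done += 1
    return out


def _gap(snp_pos: int, span: tuple[int, int]) -> int:
    if snp_pos < span[0]:
        return span[0] - snp_pos
    if snp_pos > span[1]:
        return snp_pos - span[1]
    return 0


def _plant_near_indel(spec, rng, models, genome, count, indels, used,
                      planted) -> None:
    done, attempts = 0, 0
    while done < count:
        attempts += 1
        if attempts > 500 * count + 1000:
            raise SnpBurdenError(
                "infeasible spec: could not place near-INDEL SNPs; binding "
                "constraint is free noncoding positions inside the window"
            )
        ind = indels[int(rng.integers(len(indels)))]
        lo, hi = ind.span
        d = int(rng.integers(1, spec.indel_window + 1))
        pos = lo - d if rng.integers(2) else hi + d
        c = ind.contig_id
        if not 1 <= pos <= len(genome[c]):
            continue
        if (c, pos) in used:
            continue
        region, gene_id = _region_of(pos, c, models)
        if region == "CDS":
            continue
        ref = genome[c][pos - 1]
        if ref == "N":
            continue
        used.add((c, pos))
        planted.append(
            _Plant(c, pos, ref, _random_alt(rng, ref), region, NONCODING,
                   gene_id, "SNP", near_indel=True)
        )
        done += 1


def _assign_depths(spec, rng, planted: list[_Plant]) -> None:
    snps = [p for p in planted if p.vclass == "SNP"]
    eligible = [p for p in snps if not p.near_indel]
    n_low = int(round(spec.low_depth_fraction * len(snps)))
    if n_low > len(eligible):
        raise SnpBurdenError(
            "infeasible spec: low_depth_fraction exceeds the SNPs eligible "
            "for low depth (near-INDEL SNPs are excluded)"
        )
    low_idx = set(
        rng.choice(len(eligible), size=n_low, replace=False).tolist()
    ) if n_low else set()
    r = spec.depth_dispersion
    p_nb = r / (r + spec.depth_mean)
    for i, plant in enumerate(eligible):
        if i in low_idx:
            plant.low_depth = True
            plant.depth = int(rng.integers(0, spec.depth_threshold))
    for plant in planted:
        if plant.low_depth:
            continue
        d = 0
        while d < spec.depth_threshold:
            d = int(rng.negative_binomial(r, p_nb))
        plant.depth = d


def _self_check_coding(spec, models, genome, planted: list[_Plant]) -> None:
    """Generation-time invariant: re-translate every mutated CDS and confirm
    the intended class, independently of the planting logic."""
    by_id = {m.gene_id: m for m in models}
    for p in planted:
        if p.region != "CDS" or p.vclass != "SNP":
            continue
        m = by_id[p.gene_id]
        ref_prot = translate_cds(m, genome).protein
        mutated = dict(genome)
        s = mutated[p.contig_id]
        assert s[p.pos - 1] == p.ref
        mutated[p.contig_id] = s[: p.pos - 1] + p.alt + s[p.pos :]
        alt_prot = translate_cds(m, mutated).protein
        n_diff = sum(a != b for a, b in zip(ref_prot, alt_prot))
        observed = SYNONYMOUS if n_diff == 0 else NONSYNONYMOUS
        if observed != p.klass or len(ref_prot) != len(alt_prot):
            raise SnpBurdenError(
                f"simulator self-check failed at {p.contig_id}:{p.pos} "
                f"({p.gene_id}): intended {p.klass}, translation says "
                f"{observed}"
            )


def _assign_domains(spec, rng, models):
    from .candidates import load_target_domains
    from .models import DomainAnnotation

    targets = sorted(load_target_domains().accessions)
    n_cand = int(round(spec.candidate_domain_fraction * len(models)))
    cand_idx = set(
        rng.choice(len(models), size=n_cand, replace=False).tolist()
    ) if n_cand else set()
    annotations, truth_genes = [], []
    for i, m in enumerate(models):
        if i in cand_idx:
            k = int(rng.integers(1, 3))
            accs = tuple(
                targets[j] for j in sorted(
                    rng.choice(len(targets), size=k, replace=False).tolist()
                )
            )
        else:
            k = int(rng.integers(0, 3))
            accs = tuple(
                _DECOY_ACCESSIONS[j] for j in sorted(
                    rng.choice(len(_DECOY_ACCESSIONS), size=k,
                               replace=False).tolist()
                )
            )
        if accs:
            annotations.append(
                DomainAnnotation(gene_id=m.gene_id,
                                 ipr_accessions=frozenset(accs))
            )
        truth_genes.append(
            TruthGene(gene_id=m.gene_id, accessions=accs,
                      is_candidate=i in cand_idx)
        )
    return annotations, truth_genes
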