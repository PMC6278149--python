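"""Codon-level classification: exhaustive and translation oracles, strand
handling, coordinate mapping."""

import itertools

import pytest
from Bio.Seq import Seq

from snpburden.effects import (
    annotate_all,
    cds_coordinate,
    classify_snp,
    map_to_gene,
    overlapping_genes,
    revcomp,
    translate_cds,
)
from snpburden.models import (
    GeneModel,
    NONSYNONYMOUS,
    SYNONYMOUS,
    SnpBurdenError,
    VariantRecord,
)
from snpburden.simulate import SimulationSpec, simulate_dataset

BASES = "ACGT"


def single_gene(seq, strand="+", gene_id="g1", contig="c1"):
    """A one-segment gene covering the whole contig sequence."""
    model = GeneModel(gene_id=gene_id, contig_id=contig, strand=strand,
                      cds_segments=((1, len(seq)),))
    return model, {contig: seq}


def oracle_class(ref_codon, alt_codon):
    """Independent classification by translating whole codons (Biopython)."""
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "stop_retained" if ref_aa == "*" else "synonymous"
    if alt_aa == "*":
        return "stop_gain"
    if ref_aa == "*":
        return "stop_loss"
    return "nonsynonymous"


class TestExhaustiveCodonOracle:
    def test_all_576_single_substitutions_match_translation(self):
        """Every (codon, offset, alt) substitution classifies identically to
        direct translation of the mutated codon."""
        n_checked = 0
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            model, genome = single_gene(codon)
            for offset in (1, 2, 3):
                for alt in BASES:
                    if alt == codon[offset - 1]:
                        continue
                    v = VariantRecord("c1", offset, codon[offset - 1], alt, 30)
                    call = classify_snp(v, model, genome)
                    alt_codon = (
                        codon[: offset - 1] + alt + codon[offset:]
                    )
                    assert call.ref_codon == codon
                    assert call.alt_codon == alt_codon
                    assert call.klass == oracle_class(codon, alt_codon)
                    # codons differ at exactly the claimed offset
                    diffs = [i + 1 for i in range(3)
                             if call.ref_codon[i] != call.alt_codon[i]]
                    assert diffs == [call.codon_offset]
                    n_checked += 1
        assert n_checked == 576


class TestCdsCoordinate:
    def test_plus_strand_boundary(self):
        model = GeneModel("g1", "c1", "+", ((101, 400),))
        assert cds_coordinate(VariantRecord("c1", 101, "A", "C"), model) == 1
        assert cds_coordinate(VariantRecord("c1", 400, "A", "C"), model) == 300

    def test_minus_strand_mirror_boundary(self):
        model = GeneModel("g1", "c1", "-", ((101, 400),))
        assert cds_coordinate(VariantRecord("c1", 400, "A", "C"), model) == 1
        assert cds_coordinate(VariantRecord("c1", 101, "A", "C"), model) == 300

    def test_position_outside_segments_is_an_error(self):
        model = GeneModel("g1", "c1", "+", ((101, 400),))
        with pytest.raises(SnpBurdenError, match="outside"):
            cds_coordinate(VariantRecord("c1", 500, "A", "C"), model)

    def test_agrees_with_splice_and_search_oracle(self, sim_default):
        """Mark the genome base with a sentinel, physically splice the CDS
        and find the sentinel: its index must equal cds_coordinate."""
        genome = {g.contig_id: g.sequence for g in sim_default.genomes}
        for model in sim_default.models[:30]:
            seq = genome[model.contig_id]
            for start, end in model.cds_segments:
                for pos in (start, (start + end) // 2, end):
                    marked = seq[: pos - 1] + "!" + seq[pos:]
                    parts = [marked[s - 1 : e] for s, e in model.cds_segments]
                    spliced = "".join(parts)
                    if model.strand == "-":
                        # reverse; '!' is not complemented but keeps its slot
                        spliced = spliced[::-1]
                    expected = spliced.index("!") + 1
                    v = VariantRecord("c1x" if False else model.contig_id,
                                      pos, "A", "C")
                    assert cds_coordinate(v, model) == expected


class TestClassifyExamples:
    def _gene_with_codon(self, codon_index, codon, n_codons=None):
        n = n_codons or codon_index
        filler = "GGC"
        seq = filler * (codon_index - 1) + codon + filler * (n - codon_index)
        return single_gene(seq)

    def test_published_nonsynonymous_token_V624A(self):
        # CDS pos 1871 is offset 2 of codon 624; GTG(V) -> GCG(A)
        model, genome = self._gene_with_codon(624, "GTG")
        v = VariantRecord("c1", 1871, "T", "C", 30)
        call = classify_snp(v, model, genome)
        assert call.klass == NONSYNONYMOUS
        assert call.notation == "V624A"

    def test_published_synonymous_token_H50H(self):
        # CDS pos 150 is offset 3 of codon 50; CAC(H) -> CAT(H)
        model, genome = self._gene_with_codon(50, "CAC")
        v = VariantRecord("c1", 150, "C", "T", 30)
        call = classify_snp(v, model, genome)
        assert call.klass == SYNONYMOUS
        assert call.notation == "H50H"

    def test_minus_strand_alleles_are_reverse_complemented(self):
        # genome CCA | CAT | GGG; gene on '-': spliced = CCC ATG TGG
        model, genome = single_gene("CCACATGGG", strand="-")
        # genome pos 5 (A) is CDS pos 5 => codon 2 offset 2: ATG -> ACG (M->T)
        v = VariantRecord("c1", 5, "A", "G", 30)
        call = classify_snp(v, model, genome)
        assert call.ref_codon == "ATG" and call.alt_codon == "ACG"
        assert call.klass == NONSYNONYMOUS
        assert call.notation == "M2T"

    def test_reference_mismatch_is_an_error(self):
        model, genome = single_gene("ATGGCTCAT")
        v = VariantRecord("c1", 2, "A", "C", 30)  # genome has T
        with pytest.raises(SnpBurdenError, match="mismatch"):
            classify_snp(v, model, genome)

    def test_codon_with_N_is_unknown(self):
        model, genome = single_gene("ATGGNTCAT")
        v = VariantRecord("c1", 4, "G", "A", 30)
        call = classify_snp(v, model, genome)
        assert call.klass == "unknown"


class TestMapToGene:
    def test_regions(self, toy_models):
        mk = lambda pos: VariantRecord("contig1", pos, "A", "C", 30)
        assert map_to_gene(mk(15), toy_models) == ("geneA", "CDS")
        assert map_to_gene(mk(25), toy_models) == ("geneA", "intron")
        assert map_to_gene(mk(35), toy_models) == (None, "intergenic")
        assert map_to_gene(mk(45), toy_models) == ("geneB", "CDS")

    def test_overlapping_genes_prefer_cds_then_smallest_id(self):
        a = GeneModel("gB", "c1", "+", ((1, 30),))
        b = GeneModel("gA", "c1", "+", ((1, 30),))
        c = GeneModel("gC", "c1", "+", ((1, 6), (25, 30)))  # intronic at 10
        v = VariantRecord("c1", 10, "A", "C", 30)
        hits = overlapping_genes(v, [a, b, c])
        assert hits == [("gA", "CDS"), ("gB", "CDS"), ("gC", "intron")]
        assert map_to_gene(v, [a, b, c]) == ("gA", "CDS")

    def test_region_assignments_match_planted_truth(self, sim_default):
        genome = {g.contig_id: g.sequence for g in sim_default.genomes}
        snps = [v for v in sim_default.variants if v.vclass == "SNP"]
        result = annotate_all(snps, sim_default.models, genome)
        truth = {
            (v.contig_id, v.pos): (v.intended_region, v.gene_id)
            for v in sim_default.truth.variants if v.vclass == "SNP"
        }
        assert not result.errors
        for call in result.calls:
            key = (call.variant.contig_id, call.variant.pos)
            region, gene = truth[key]
            assert call.region == region
            assert call.gene_id == gene


class TestTranslateCds:
    def test_trailing_stop_dropped_and_recorded(self):
        model, genome = single_gene("ATGGCTTAA")
        t = translate_cds(model, genome)
        assert t.protein == "MA" and t.terminal_stop
        assert t.internal_stops == ()

    def test_strand_symmetry(self):
        fwd = "ATGGCTTAA"
        model_f, genome_f = single_gene(fwd)
        model_r, genome_r = single_gene(revcomp(fwd), strand="-")
        assert translate_cds(model_f, genome_f) == translate_cds(
            model_r, genome_r
        )

    def test_internal_stop_flagged_but_translated(self):
        model, genome = single_gene("ATGTAAGCT")
        t = translate_cds(model, genome)
        assert t.internal_stops == (2,)
        assert t.protein == "M*A"

    def test_agrees_with_biopython_on_simulated_genes(self, sim_default):
        genome = {g.contig_id: g.sequence for g in sim_default.genomes}
        for model in sim_default.models:
            seq = "".join(
                genome[model.contig_id][s - 1 : e]
                for s, e in model.cds_segments
            )
            if model.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            expected = str(Seq(seq).translate())
            mine = translate_cds(model, genome)
            full = mine.protein + ("*" if mine.terminal_stop else "")
            assert full == expected


class TestAnnotateAll:
    def test_empty_input(self, sim_default):
        genome = {g.contig_id: g.sequence for g in sim_default.genomes}
        assert len(annotate_all([], sim_default.models, genome)) == 0

    def test_class_counts_recover_planted_mix(self, sim_clean):
        genome = {g.contig_id: g.sequence for g in sim_clean.genomes}
        snps = [v for v in sim_clean.variants if v.vclass == "SNP"]
        counts = annotate_all(snps, sim_clean.models, genome).class_counts(
            collapse_stops=True
        )
        assert counts["synonymous"] == 50
        assert counts["nonsynonymous"] == 50
        assert counts["noncoding"] == 20

    def test_lenient_mode_collects_reference_mismatches(self, toy_models,
                                                        toy_genome):
        genome = {toy_genome.contig_id: toy_genome.sequence}
        bad = VariantRecord("contig1", 11, "C", "G", 30)  # genome has A
        result = annotate_all([bad], toy_models, genome, lenient=True)
        assert len(result.calls) == 0 and len(result.errors) == 1
        with pytest.raises(SnpBurdenError):
            annotate_all([bad], toy_models, genome, lenient=False)


def _mirror_dataset(ds):
    """Reverse-complement every contig and remap models and variants."""
    genomes = {g.contig_id: revcomp(g.sequence) for g in ds.genomes}
    lengths = {g.contig_id: len(g.sequence) for g in ds.genomes}
    models = [
        GeneModel(
            gene_id=m.gene_id, contig_id=m.contig_id,
            strand="-" if m.strand == "+" else "+",
            cds_segments=tuple(sorted(
                (lengths[m.contig_id] - e + 1, lengths[m.contig_id] - s + 1)
                for s, e in m.cds_segments
            )),
        )
        for m in ds.models
    ]
    variants = [
        VariantRecord(
            v.contig_id, lengths[v.contig_id] - v.pos + 1,
            revcomp(v.ref), revcomp(v.alt), v.depth,
        )
        for v in ds.variants if v.vclass == "SNP"
    ]
    return genomes, models, variants


def test_strand_mirroring_preserves_class_multiset(sim_clean):
    """Re-expressing the whole dataset on the opposite strand leaves the
    multiset of consequence classes unchanged."""
    genome = {g.contig_id: g.sequence for g in sim_clean.genomes}
    snps = [v for v in sim_clean.variants if v.vclass == "SNP"]
    direct = annotate_all(snps, sim_clean.models, genome)
    m_genome, m_models, m_snps = _mirror_dataset(sim_clean)
    mirrored = annotate_all(m_snps, m_models, m_genome)
    assert not direct.errors and not mirrored.errors
    assert direct.class_counts() == mirrored.class_counts()
    # stronger: per-variant classes match after coordinate remapping
    length = {g.contig_id: len(g.sequence) for g in sim_clean.genomes}
    direct_by_pos = {
        (c.variant.contig_id, c.variant.pos): c.klass for c in direct.calls
    }
    for call in mirrored.calls:
        orig = (call.variant.contig_id,
                length[call.variant.contig_id] - call.variant.pos + 1)
        assert direct_by_pos[orig] == call.klass
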