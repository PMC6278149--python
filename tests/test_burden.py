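import math

import pytest

from snpburden.burden import compare_sets, flag_high_ns, gene_burden, set_burden
from snpburden.effects import annotate_all
from snpburden.housekeeping import load_housekeeping_table
from snpburden.models import (
    BurdenSummary,
    EffectCall,
    GeneModel,
    HighNsRule,
    SnpBurdenError,
    VariantRecord,
)
from snpburden.pipeline import housekeeping_set_burden


def call(klass, gene="g1"):
    v = VariantRecord("c1", 1, "A", "C", 30)
    return EffectCall(variant=v, gene_id=gene, region="CDS", klass=klass)


def summary(gene, length, n_s, n_ns):
    return BurdenSummary(gene_id=gene, gene_length=length,
                         n_snp=n_s + n_ns, n_s=n_s, n_ns=n_ns)


class TestGeneBurden:
    def test_direct_arithmetic(self):
        calls = [call("nonsynonymous"), call("nonsynonymous"),
                 call("synonymous")]
        s = gene_burden(calls, 1000, gene_id="g1")
        assert (s.rate_snp, s.rate_s, s.rate_ns) == (3.0, 1.0, 2.0)

    def test_zero_calls_zero_rates(self):
        s = gene_burden([], 500, gene_id="g1")
        assert s.rate_snp == s.rate_s == s.rate_ns == 0.0

    def test_zero_length_is_an_error(self):
        with pytest.raises(SnpBurdenError, match="length"):
            gene_burden([], 0, gene_id="g1")

    def test_collapse_folds_stop_classes_into_ns(self):
        calls = [call("stop_gain"), call("synonymous")]
        collapsed = gene_burden(calls, 300, gene_id="g1", collapse_stops=True)
        assert collapsed.n_ns == 1 and collapsed.n_other == 0
        kept = gene_burden(calls, 300, gene_id="g1", collapse_stops=False)
        assert kept.n_ns == 0 and kept.n_other == 1

    def test_counts_match_planted_truth_per_gene(self, sim_clean):
        genome = {g.contig_id: g.sequence for g in sim_clean.genomes}
        snps = [v for v in sim_clean.variants if v.vclass == "SNP"]
        result = annotate_all(snps, sim_clean.models, genome)
        by_gene = {}
        for c in result.calls:
            if c.region == "CDS":
                by_gene.setdefault(c.gene_id, []).append(c)
        truth = {}
        for v in sim_clean.truth.variants:
            if v.intended_region == "CDS":
                t = truth.setdefault(v.gene_id, {"synonymous": 0,
                                                 "nonsynonymous": 0})
                t[v.intended_class] += 1
        models = {m.gene_id: m for m in sim_clean.models}
        for gene, expected in truth.items():
            s = gene_burden(by_gene[gene], models[gene])
            assert s.n_s == expected["synonymous"]
            assert s.n_ns == expected["nonsynonymous"]


class TestSetBurden:
    def test_single_gene_set_equals_gene_rates(self):
        g = summary("g1", 2000, 3, 1)
        s = set_burden([g], "solo")
        assert (s.rate_snp, s.rate_s, s.rate_ns) == (
            g.rate_snp, g.rate_s, g.rate_ns
        )

    def test_empty_set_is_an_error(self):
        with pytest.raises(SnpBurdenError):
            set_burden([], "empty")

    def test_pooled_rate_is_length_weighted_not_mean(self):
        a, b = summary("a", 1000, 10, 0), summary("b", 9000, 0, 0)
        s = set_burden([a, b], "two")
        assert s.rate_s == pytest.approx(1.0)       # 10 / 10000 kb
        assert s.mean_rate_s == pytest.approx(5.0)  # (10 + 0) / 2

    def test_pooled_rate_lies_between_min_and_max_gene_rates(self, sim_clean):
        genome = {g.contig_id: g.sequence for g in sim_clean.genomes}
        snps = [v for v in sim_clean.variants if v.vclass == "SNP"]
        result = annotate_all(snps, sim_clean.models, genome)
        by_gene = {}
        for c in result.calls:
            if c.region == "CDS":
                by_gene.setdefault(c.gene_id, []).append(c)
        summaries = [
            gene_burden(by_gene.get(m.gene_id, []), m)
            for m in sim_clean.models
        ]
        s = set_burden(summaries, "all")
        rates = [g.rate_snp for g in summaries]
        assert min(rates) <= s.rate_snp <= max(rates)

    def test_scale_equivariance(self):
        genes = [summary("a", 900, 2, 1), summary("b", 2100, 0, 3)]
        doubled = [summary(g.gene_id, 2 * g.gene_length, 2 * g.n_s,
                           2 * g.n_ns) for g in genes]
        s1, s2 = set_burden(genes, "x"), set_burden(doubled, "x")
        assert s1.rate_snp == pytest.approx(s2.rate_snp)
        assert s1.rate_ns == pytest.approx(s2.rate_ns)

    def test_housekeeping_pooled_rates_match_one_pass_recount(self):
        """Independent oracle: a single pass over the raw fixture rows."""
        table = load_housekeeping_table()
        tot_len = n = ns = s = 0
        for row in table.rows:
            tot_len += row.gene_length
            n += len(row.nucleotide_changes)
            s += sum(x == "sSNPs" for x in row.statuses)
            ns += sum(x == "nsSNPs" for x in row.statuses)
        hk = housekeeping_set_burden()
        assert hk.rate_snp == pytest.approx(1000 * n / tot_len)
        assert hk.rate_s == pytest.approx(1000 * s / tot_len)
        assert hk.rate_ns == pytest.approx(1000 * ns / tot_len)


class TestHighNsFlag:
    def test_default_rule_threshold(self):
        sums = [summary("a", 999, 0, 0), summary("b", 999, 0, 1),
                summary("c", 999, 0, 3), summary("d", 999, 0, 7)]
        flagged = flag_high_ns(sums)
        assert [s.gene_id for s in flagged] == ["d", "c"]

    def test_relaxed_rule_takes_every_gene_with_one_ns(self):
        sums = [summary("a", 999, 5, 1), summary("b", 999, 0, 0)]
        rule = HighNsRule(min_ns=1, require_ns_exceeds_s=False)
        assert [s.gene_id for s in flag_high_ns(sums, rule)] == ["a"]

    def test_require_ns_exceeds_s(self):
        sums = [summary("a", 999, 5, 3)]
        assert flag_high_ns(sums) == []
        assert len(flag_high_ns(sums, HighNsRule(
            min_ns=2, require_ns_exceeds_s=False))) == 1

    def test_monotone_in_min_ns(self):
        sums = [summary(f"g{i}", 999, 0, i) for i in range(8)]
        prev = None
        for min_ns in range(1, 9):
            now = {s.gene_id for s in flag_high_ns(
                sums, HighNsRule(min_ns=min_ns))}
            if prev is not None:
                assert now <= prev
            prev = now

    def test_sorted_by_ns_rate_then_id(self):
        sums = [summary("b", 1000, 0, 4), summary("a", 1000, 0, 4),
                summary("c", 500, 0, 4)]
        assert [s.gene_id for s in flag_high_ns(sums)] == ["c", "a", "b"]


class TestCompareSets:
    def test_identical_sets_have_unit_ratios(self):
        genes = [summary("a", 1200, 4, 2), summary("b", 1800, 1, 5)]
        s = set_burden(genes, "x")
        comp = compare_sets(s, s, bootstrap_reps=200, seed=1)
        for r in comp.ratios:
            assert r.ratio == pytest.approx(1.0)
            assert r.ci_low <= 1.0 <= r.ci_high

    def test_published_style_ratio(self):
        # one set at 11 ns/kb vs a comparator at 0.4 ns/kb -> ratio 27.5
        a = set_burden([summary("a", 1000, 0, 11)], "candidates")
        b = set_burden([summary("b", 10000, 0, 4)], "housekeeping")
        comp = compare_sets(a, b, bootstrap_reps=10, seed=0)
        assert comp.ratio_for("ns").ratio == pytest.approx(27.5)

    def test_zero_denominator_is_undefined_not_infinite(self):
        a = set_burden([summary("a", 1000, 1, 1)], "a")
        b = set_burden([summary("b", 1000, 0, 0)], "b")
        comp = compare_sets(a, b, bootstrap_reps=10, seed=0)
        assert comp.ratio_for("ns").ratio is None

    def test_bootstrap_interval_contains_point_ratio(self):
        genes_a = [summary(f"a{i}", 1000 + 37 * i, i % 3, i % 2)
                   for i in range(12)]
        genes_b = [summary(f"b{i}", 900 + 53 * i, 1 + i % 2, i % 3)
                   for i in range(12)]
        a, b = set_burden(genes_a, "a"), set_burden(genes_b, "b")
        comp = compare_sets(a, b, bootstrap_reps=1000, seed=2)
        for r in comp.ratios:
            assert r.ci_low <= r.ratio <= r.ci_high
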