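"""Contrast the SNP burden of candidate genes against housekeeping genes.

The comparison reports per-class pooled-rate ratios (candidates over
comparator) with a gene-level bootstrap interval — the interval is an
uncertainty add-on beyond the raw rates.
"""

from snpburden import (
    SimulationSpec,
    annotate_all,
    compare_sets,
    gene_burden,
    load_target_domains,
    select_candidates,
    set_burden,
    simulate_dataset,
)
from snpburden.pipeline import housekeeping_set_burden

ds = simulate_dataset(SimulationSpec(seed=21, n_genes=120, n_contigs=4,
                                     contig_length=120_000))
genome = {g.contig_id: g.sequence for g in ds.genomes}
snps = [v for v in ds.variants if v.vclass == "SNP"]
calls = annotate_all(snps, ds.models, genome)
by_gene = {}
for c in calls:
    if c.region == "CDS":
        by_gene.setdefault(c.gene_id, []).append(c)

cands = select_candidates(ds.annotations, load_target_domains())
models = {m.gene_id: m for m in ds.models}
cand_set = set_burden(
    [gene_burden(by_gene.get(g, []), models[g]) for g in sorted(cands.gene_ids)],
    "candidates",
)
hk = housekeeping_set_burden()

comp = compare_sets(cand_set, hk, bootstrap_reps=1000, seed=21)
print(f"{comp.label}  (bootstrap reps: {comp.bootstrap_reps})")
for r in comp.ratios:
    ratio = "undefined" if r.ratio is None else f"{r.ratio:5.2f}"
    print(f"  {r.klass:4s}: {r.rate_a:6.3f}/kb vs {r.rate_b:6.3f}/kb  "
          f"ratio {ratio}  CI [{r.ci_low:.2f}, {r.ci_high:.2f}]")
print("\nA ratio above 1 means the candidate set carries a higher per-kb "
      "burden than the housekeeping comparator; here the simulated genome "
      "plants SNPs uniformly, so ratios reflect that uniformity.")
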