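"""Generate a synthetic genome with planted, ground-truthed variants.

The simulator emulates a resequencing comparison: a few contigs carrying
stranded multi-exon genes, coding SNPs planted with known synonymous or
nonsynonymous status, noncoding SNPs, small INDELs, and per-variant read
depths — plus a truth table recording every plant.
"""

from pathlib import Path

from snpburden import SimulationSpec, simulate_dataset

spec = SimulationSpec(seed=7)
ds = simulate_dataset(spec)

print(f"genome: {len(ds.genomes)} contigs x {spec.contig_length:,} nt, "
      f"{len(ds.models)} genes")
print(f"planted variants: {ds.truth.class_counts()}")
print(f"forced low-depth SNPs: {sum(v.low_depth for v in ds.truth.variants)}")
print(f"near-INDEL SNPs:       {sum(v.near_indel for v in ds.truth.variants)}")

outdir = Path("scratch_example_data")
paths = ds.write(outdir)
print(f"\nwrote FASTA/GFF3/VCF/TSV inputs plus the truth table to {outdir}/:")
for name, p in paths.items():
    print(f"  {name:15s} {p.name}")
print("\nEvery downstream example can start from these files; the truth "
      "table is what the pipeline's output is checked against.")
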