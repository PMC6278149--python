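# Methods

## Scope and data model

The package covers the downstream-of-VCF half of a strain-resequencing
comparison: it consumes a reference genome (FASTA), gene models with CDS
features (GFF3), called variants with read depths (VCF 4.x) and per-gene
InterPro annotations (InterProScan-style TSV), and produces filtered SNPs,
codon-level consequence calls, candidate gene sets and per-kb burden
statistics. Read simulation, alignment and variant calling are out of
scope; the VCF is taken as a caller's output.

Coordinates are uniformly 1-based with closed intervals. A gene model is a
stranded list of non-overlapping CDS segments on one contig; models whose
CDS length is not divisible by 3 are retained but flagged `partial` and
excluded from translation. Multi-allelic VCF records are split per ALT,
each split inheriting the site depth; depth is read from `INFO/DP` first,
else from the first sample's `FORMAT/DP` (the depth's provenance in the
original study is unrecorded, so the reader accepts both).

## Variant filtering

Two retention rules, both inclusive at their boundary:

* depth ≥ `depth_min` (default 5; a depth-5 record is kept — the study's
  methods say "minimum read depth of 5" while its results say "> 5", and
  the methods phrasing is taken as authoritative, with the threshold
  configurable);
* a SNP is removed when its distance to the nearest INDEL on the same
  contig is ≤ `indel_window` (default 10 nt). The INDEL occupies its
  reference span `[pos, pos + |ref| − 1]`; distance is the positional gap
  to that span, 0 inside it. Measuring to the span rather than the anchor
  base is a documented choice — the source text gives only "(10 bp)".

`apply_variant_filters` evaluates both predicates against the full input
list, so a SNP near a low-depth INDEL is still removed; this makes the
retained set exactly invariant to rule order. The report attributes each
removal to the first failing rule in the fixed order depth → vicinity.
INDELs never appear in the output.

## Consequence classification

A SNP in a CDS segment gets a spliced coordinate: on the plus strand, its
offset within the concatenated segments in genome order; on the minus
strand the mirror `cds_length − offset + 1`. Codon index is
`⌈cds_pos / 3⌉` with the start codon as codon 1 — this convention
reproduces the published change-token pairs (T1871C→V624A, C158T→A53V,
C150T→H50H). For minus-strand genes the VCF alleles (always
forward-strand) are reverse-complemented before codon substitution. The
reference allele is checked against the genome base and a mismatch is an
error: it almost always betrays a coordinate or strand bug rather than
data noise.

The genetic code defaults to NCBI translation table 1 and is configurable
by table id. Stop-affecting changes get their own classes (`stop_gain`,
`stop_loss`, and `stop_retained` for stop→stop), because folding them
silently into the two-way split would violate the definition of a
synonymous change; burden statistics collapse them (gain/loss → nsSNP,
retained → sSNP) by default, since the published counts use the two-way
scheme. Codons containing N, and SNPs with non-ACGT alleles, classify as
`unknown` — never silently expanded. When genes overlap, the primary
assignment goes to a gene whose CDS contains the position, ties broken by
lexicographically smallest gene id, with all overlaps retained in a
secondary field.

Classification is verified two independent ways in the test suite: an
exhaustive oracle translating all 576 single-nucleotide substitutions of
the 64 codons, and a full-protein oracle that mutates the genome, splices
and translates the whole CDS (via Biopython, not the package's own codon
path) for every planted SNP.

## Candidate screening and burden

A gene is a candidate iff its accession set intersects the target list;
the packaged default list carries the ten accessions (six family labels)
relevant to chromium tolerance, and any TSV can replace it. Domain tallies
count genes containing an accession, not domain instances, and zero-count
accessions are reported. Family labels are annotations only — a gene
matching several families is one candidate.

Per-gene burden is `1000 · count / CDS length` per class. Set-level rates
are pooled and length-weighted (`Σ counts / Σ lengths × 1000`); the
unweighted mean of per-gene rates is reported alongside, since the two
differ whenever burden correlates with gene length. Presentation rounding
is one decimal, matching the published style; computation is never
rounded. The high-nsSNP flag defaults to nsSNPs ≥ 2 and nsSNPs > sSNPs —
an interpretation consistent with the published banding of highly
polymorphic genes, not a rule stated in the source, and fully
configurable. Set comparisons report per-class rate ratios; a zero
denominator yields an undefined (not infinite) ratio. The percentile
bootstrap (default 1000 gene-level resamples per set, seeded) is an
uncertainty add-on beyond the published analysis and is labelled as such
in output.

## The housekeeping inventory

`data/housekeeping_snps.tsv` is a verbatim transcription of the published
housekeeping-gene SNP table: 128 genes, 262,489 nt total CDS, 240
nucleotide-change tokens, 237 amino-acid tokens (157 sSNPs / 80 nsSNPs by
printed status). Transcription quirks are preserved and flagged rather
than corrected: three rows print more nucleotide than amino-acid tokens;
three tokens use non-ACGT reference bases (W1271A, K401C, Y2271G); one
token has ref = alt (A1683A); a handful of rows are inconsistent with the
CDS-coordinate reading (e.g. C1483G printed as P496A though
⌈1483/3⌉ = 495). The file is guarded by a SHA-256 checksum. Codon-level
concordance checks use only the self-consistent token pairs (213 of 237);
for each, a minimal gene is reconstructed whose codon context realises the
printed pair, and the classifier must reproduce the token and status
exactly.

**Known irreproducibility.** The published footer states 0.9 SNPs/kb,
0.7 sSNPs/kb and 0.4 nsSNPs/kb. Recomputing pooled length-weighted rates
over the transcription gives 0.914 → 0.9, 0.598 → 0.6 and 0.305 → 0.3.
The printed trio is internally impossible for any single-denominator
partition: 0.7 + 0.4 exceeds 0.9 beyond any rounding slack, since class
counts cannot sum above the total. Alternative conventions (class rates
over SNP-bearing genes only, mean-of-per-gene rates, non-expanded status
counts) were examined and none yields all three printed values; rates over
SNP-bearing genes only reproduce the 0.4 nsSNPs/kb figure but not the
sSNP figure. The package therefore reports the faithful recomputation,
`snpburden fixture-check` prints one pass line (total) and two fail lines,
and the corresponding acceptance test is expected to fail.

## The synthetic-data generator

The simulator emulates the study's structure at desk scale: by default 3
contigs of 60 kb carrying 60 genes of 60–180 codons with 1–4 exons
(introns 40–100 nt), strands balanced. Planted variants default to 50
synonymous, 50 nonsynonymous, 30 noncoding SNPs and 20 INDELs of 1–5 nt.
A coding plant picks a codon and an alternate base whose substituted codon
translates to the same (synonymous) or a different non-stop
(nonsynonymous) residue, then emits genome-strand alleles; at generation
time every coding plant is re-verified by translating the mutated CDS,
independently of the planting logic. Read depths are negative binomial
(the study reports only a threshold, not a distribution; defaults mean
200 — the study's sequencing coverage — and dispersion 10, resampled to
sit above the threshold), with a forced low-depth subset (default 10% of
SNPs) drawn uniformly below the threshold. Near-INDEL SNPs (default 10%
of SNPs) are taken from the noncoding pool and placed 1–10 nt from an
INDEL span; INDELs are intergenic and kept strictly more than one window
away from every other SNP. Low depth is never assigned to INDELs and the
low-depth and near-INDEL subsets are disjoint, so each removal has exactly
one cause and truth recovery is exact. Identical specs (including seed)
produce byte-identical output files.

What the simulator does not emulate: real gene sequences (random
nucleotides, so internal stops occur and are merely flagged), linkage or
clustering of variants, sequencing error, genotype uncertainty, or any
correlation between domain content and SNP burden — candidate genes are
chosen uniformly (default fraction 0.25; the study-scale fraction would
leave too few genes for set statistics at n = 60). Passing truth-recovery
tests therefore demonstrates the correctness of the pipeline's
bookkeeping, coordinates and codon arithmetic — not robustness to
caller noise.

## Acceptance computations and problem sizes

`scripts/acceptance.py` uses: the full housekeeping inventory (128
genes); the exhaustive 576-substitution codon oracle; the 213
self-consistent printed token pairs; and a 1,000-variant truth-recovery
run (5 contigs × 200 kb, 200 genes, 300/300/300/100 planted mix, 10%
low-depth, 10% near-INDEL, 20% candidate fraction). These sizes keep the
whole script near one second while exercising every stage; the
truth-recovery conditions are also frozen in the acceptance test suite.
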