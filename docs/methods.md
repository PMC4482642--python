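# Methods

This note documents the models, conventions and design choices behind
`genarch`, in the spirit of the methods documentation of statsmodels or
msprime: what each stage assumes, which knobs matter, and what the
synthetic-data validation does and does not demonstrate.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open (`[start, end)`), the BED
convention; GFF3 (1-based closed) and VCF (1-based) are converted once at
the parsing boundary and nowhere else.  Interval sets normalize on
construction: per sequence, intervals are sorted and merged, with
*adjacent* intervals merged too — a gap of zero bases is not an intergenic
space.  Strand is recorded but never enters length accounting; the
footprint arithmetic is strand-blind.  Union, complement, intersection and
subtraction are all validated against per-base bitmap oracles in the test
suite, including De Morgan duality as a property test.

Where a gene has several transcripts, the *canonical transcript* is the one
with the largest summed exon length, ties broken by lexicographic
transcript id.  Gene-level size metrics (exon sum, intron sum) come from
the canonical transcript; the gene *span* is the full annotated extent and
can exceed the canonical transcript's span via other isoforms, so span is
not forced to equal exon + intron sums.

## Content accounting

Two accounting modes are reported side by side.

- **summed** — exon and intron totals are added per transcript.  Bases
  shared by alternative transcripts count once per transcript, so class
  totals can exceed the genome size.  This matches the convention of
  published per-class content tables and is the default.
- **union** — every class is de-duplicated over the genome.  In this mode
  `exonic + intronic = transcript_footprint` exactly (bitmap-verified),
  where the unspliced transcript footprint is the union of transcript
  spans (exons + introns + UTRs).

Intergenic DNA is always the complement of the union of gene spans —
overlapping genes are merged before gaps are measured, and scaffold-end
flanks are not intergenic.  How the original analyses resolved overlapping
genes is not documented; union-first is the only convention under which
per-scaffold lengths partition exactly (gaps + gene union + flanks = total),
which the suite asserts.

The repeat "coding"/"noncoding" split is not standardized either: here a
repeat base is coding when it overlaps the exonic union (default) or,
selectable by flag, when it overlaps any gene span.  Percent-reduction and
footprint-fraction arithmetic round half-up at the printed precision
(whole percent for genome sizes, two decimals for fractions).

## Architecture statistics

The measured distributions — intergenic gaps, gene spans, protein sizes
(CDS/3 − 1 amino acids, subtracting the stop codon) — are heavy-tailed
nucleotide counts with severe heteroscedasticity and unbalanced group
sizes, so only one-way rank-based tests are run; interactions are out of
reach for these tests by construction.

- Kruskal–Wallis H is computed in-house with average ranks for ties and
  the standard tie correction `1 − Σ(t³−t)/(N³−N)`; p comes from the χ²
  upper tail at df = k−1.  The implementation is cross-checked against an
  independent reference implementation to 1e-10 in the tests, and against
  the hand-derived H = 3.857 for {1,2,3} vs {4,5,6}.  All-identical data
  is degenerate and flagged (H = 0, p = 1).
- Pairwise Wilcoxon rank-sum p-values use the exact distribution when both
  samples have ≤ 8 observations without ties, otherwise the normal
  approximation with continuity correction.  Bonferroni adjustment is
  `min(1, p·m)` with m the number of *tested* pairs (empty groups shrink m
  and are logged).

The full battery runs, per species, X-vs-autosome comparisons of all three
metrics, and per chromosome class, between-species Kruskal–Wallis plus
pairwise Wilcoxon tests.  Under null simulations the raw Kruskal–Wallis
p-values are uniform (KS-tested over 500 replicates in the acceptance
suite), and the signed-rank indel-bias test controls its type-I error at
the nominal level (its exact small-sample p is discrete, hence
conservative).

## Synteny

Ortholog tables may be many-to-many; they are reduced to 1:1 by keeping
the longest gene per group per species (ties by id) — a deterministic
reciprocal-best-by-length reduction.  Chaining sorts pairs by position in
species A and extends the running block while the gap to the previous
member is at most the join distance (default 50,000 bp) in *both* genomes
and the chromosome matches in both.  "Gap" is the distance between gene
bodies (end to start), not midpoints — the strictest consistent reading of
a "within 50 kb" rule; a single-genome mode (distance enforced in species
A only) is available by flag.  Chaining is order-invariant, partitions the
input, and the block count is monotone non-increasing in join distance —
all property-tested, with equality against an O(n²) transitive-closure
oracle over the neighbour-adjacency relation.

Single-member blocks on non-homologous chromosomes are lone translocations
and can be dropped; the chromosome homology map is always supplied
explicitly (identity by default for the simulator's shared scaffold
names), never inferred.  Divergent (ortholog-poor) regions are maximal
runs of tiling windows whose ortholog-bearing gene fraction is at or below
a density threshold, reported with gene and ortholog counts; geneless
windows count as ortholog-poor.  Indel size bias is a one-sample Wilcoxon
signed-rank test on per-block `ln(span_a/span_b)` with the span scatter
emitted so the comparison can be re-plotted.

## k-mer filter

Two passes: the spectrum counts every canonical (strand-collapsed,
odd-k so no self-complement) k-mer across the read set; the filter then
recounts each read against the spectrum.  Defaults are k = 15, more than
12 singleton k-mers ⇒ fail (sequencing errors), more than 51 k-mers with
count > 20,000 ⇒ fail (over-represented repeats).  The 20,000× abundance
threshold is a property of a ~560× dataset; it is configurable, and tests
use proportionally scaled thresholds on desk-scale read sets.  Windows
containing non-ACGT characters neither count in the spectrum nor against a
read.  Whether the original filter dropped single reads or whole pairs is
not recorded; both modes exist and `drop_pair` (both mates removed when
either fails) is the default, preserving pairing.  The spectrum persists
to a TSV sidecar so filtering is reproducible without a recount.

## Contamination screening

Scaffold profiles are GC fraction over ACGT bases only (ambiguity codes
excluded from the denominator) and mean per-base coverage, modelled in
(GC, log₁₀ coverage) space — coverage is multiplicative, so its log is the
natural axis.  The classifier fits one bivariate Gaussian per class
(target / contaminant) with empirical priors; posteriors follow from
Bayes' rule.  The published screen is described as a decision tree but
reports continuous probabilities with a p > 0.2 retention rule; a smooth
two-class model reproduces those semantics directly, and the permissive
0.2 threshold deliberately errs toward keeping sequence.  An independent
homology label (e.g. BLAST) overrides a low posterior.  Degenerate
training covariances get a small ridge; training requires at least five
labelled scaffolds per class.

## Variant sites and marker QC

Every base gets exactly one site class by precedence
`CDS_exon > UTR5 > UTR3 > intron > TSS > TE > intergenic`: coding
annotation beats repeat annotation, and the order is configurable and
logged.  The TSS class is a 200 bp window immediately upstream of each
transcript start (strand-aware, clipped at scaffold edges); the upstream
extent of a "transcription start site" class is a modelling choice, hence
the parameter.  Sites with depth > 600× (possible collapsed repeats),
quality < Q10 (Phred+33, 90% certainty; read from the VCF QUAL column,
with a flag for genotype-level quality), or missing DP are excluded from
both numerator and denominator, so the residual-polymorphism estimate is
unbiased under independent filtering.  The headline "genic" figure pools
CDS, UTRs and introns — the well-assembled gene bodies — and excludes
intergenic and repeat classes.

Marker QC, in order: flag markers whose parental-allele frequency (over
A/B calls; heterozygous and missing ignored by default, since RILs are
near-homozygous) exceeds 80% or falls below 20%; drop *all* markers on
scaffolds with more than five flagged markers (systematic distortion);
drop markers genotyped in fewer than 40 lines or with no informative
calls; collapse duplicate genotype patterns to one representative,
recording duplicates for re-addition after map estimation.  The procedure
is idempotent and its counts partition the input exactly.

## The synthetic-data generator

The generator emulates the contrasts the pipeline measures, not sequence
evolution.  An ancestral gene set is simulated — exon count 1 + Poisson(5)
(mean 6), exon lengths log-normal with mean ≈ 200 bp, intron and
intergenic lengths log-normal per chromosome class — and each derived
species then (i) deletes a fixed fraction of genes *with the intergenic
gap downstream of each*, mimicking loss of genes together with their
flanking DNA, (ii) rescales intron lengths per class (e.g. 1.5× on the X),
and (iii) moves genes to another chromosome at a set translocation rate.
Orthology is recorded for surviving genes; deserts of recorded orthology
can be planted in a window of set size.

Log-normal lengths are a modelling choice: real intron/intergenic
distributions are right-skewed and heavy-tailed, and `median = exp(μ)`
keeps the class medians interpretable.  Default medians (introns 250 bp;
intergenic 800 bp autosomal, 1,600 bp on the X) put per-gene totals and
gap medians in the order of magnitude of compact nematode genomes, with
the X-vs-autosome intergenic asymmetry those genomes show.  Defaults for
the derived species — 20% gene loss, 5% translocation (≈ 0.95 chromosome
retention) — mirror the observed scale of genome reduction and synteny
conservation.

Sequence content is i.i.d. with configurable GC (default 0.36); repeat
intervals are planted to a target density (default 15%) from a few motif
families and overwrite the sequence so k-mer abundance and GC signals are
real.  Reads are 180 bp fragments sampled uniformly, with per-base
substitution errors and an optional contaminant read fraction recorded in
the ground truth; quality scores are a constant Phred value.  The VCF
generator emits *all-sites* records (depth from a gamma-mixed Poisson,
variants planted per class at Bernoulli rates, and small fractions of
sites pushed above 600× or below Q10 to exercise the filters).  RIL
genotypes draw the parental A allele at 0.5, or at the distortion level on
planted scaffolds, with i.i.d. heterozygous and missing calls.

What passing tests on this generator shows: the accounting, chaining,
filtering and testing machinery recovers planted truth exactly (counts,
footprints) or within stated stochastic tolerance (rates, medians, test
power).  What it does not show: robustness to real-data pathologies the
generator omits — codon structure and substitution models, assembly
artifacts, alignment error, non-uniform coverage along chromosomes,
operonic near-zero gene spacing, or annotation errors.  Results on real
annotations inherit the quality of those annotations.

## Problem sizes and determinism

All randomness flows through a single seeded NumPy generator per
operation; a fixed seed fixes every output byte.  The validation suite
uses desk-scale problems chosen to make its statistical assertions sharp:
~10⁶ assayed genic sites for the residual-polymorphism recovery (3
binomial-SE tolerance around 0.01%), 1,000 genes per chromosome class ×
100 seeded runs for the X-intron power check (≥ 95% of runs significant
at α = 0.01), 3,000 ortholog pairs for retention (± 3 SE), 500 replicates
for null-calibration KS tests, and ≤ 200-gene instances for the O(n²)
synteny oracle.

## Known limitations

- The GFF3 reader handles the gene → mRNA → exon/CDS/UTR hierarchy used
  in practice here; exotic feature types (trans-spliced leaders, CDS
  without mRNA parents) are ignored rather than modelled.
- Union-mode "intronic" means bases inside a transcript span that are in
  no exon/UTR of *any* transcript, which under heavy isoform overlap is a
  conservative intron footprint.
- The contamination model is two-class with Gaussian class conditionals;
  multi-taxon contamination or coverage bimodality within a class would
  need a mixture extension (a depth-limited recursive-partition mode is
  the obvious alternative and the class boundary is the module contract,
  not the model family).
- The k-mer spectrum is an in-memory dict: fine for desk-scale and test
  data, not for a 560× whole-genome dataset; a disk-backed counter would
  slot in behind the same interface.
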