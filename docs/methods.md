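# Methods

## Model and estimator

A hybrid embryo carries mitochondria from the oocyte (maternal haplotype)
and, potentially, mitochondrial RNA delivered by the sperm (paternal
haplotype). At each diagnostic SNP the observed base counts from RNA-seq
reads are modelled as draws from a mixture: a read is paternal-derived with
probability *p* (the paternal fraction at that site) and maternal-derived
otherwise, and each sequenced base errs to one of the three other bases
with total probability *e* (substitution errors only; indels are excluded
by the aligner's CIGAR before counting). Heteroplasmy is estimated as

  ĥ = 1 − (maternal-allele count) / (four-base depth).

The denominator keeps third-allele reads, so sequencing error inflates ĥ
symmetrically instead of silently vanishing; under the error model the
estimator's expectation is

  E[ĥ] = p + e·(1 − 4p/3),

which reduces to *p* at *e* = 0. This matters for calibration checks: at
high total depth the error term dominates the standard error of the mean
(at p = 0.01, e = 10⁻³ and ~2×10⁵ total reads, the offset e·(1 − 4p/3) ≈
10⁻³ is larger than three standard errors ≈ 6.5×10⁻⁴), so the estimator's
across-SNP mean is validated against this analytic expectation, not against
the raw *p*. No error correction is applied to reported values — the
estimator is the plain maternal-frequency complement, matching how
heteroplasmy is conventionally quoted.

Sites with depth below `min_site_coverage` (default 20 reads) are masked
rather than imputed; the mask and its reason propagate through every
aggregation.

## SNP-table construction

The two parental genomes (~16.3 kb, >99% identical) are aligned with a
banded Needleman–Wunsch/Gotoh dynamic program (match +1, mismatch −1, gap
open −5, gap extend −1; a gap of length k costs 5 + k). The band (default
±256 diagonals) is two orders of magnitude wider than any plausible indel
between near-isogenic mitochondrial genomes; if the optimal path touches
the band edge the aligner refuses with "band too narrow" rather than
silently truncating, and a full-matrix mode is available behind a flag.
Only substitution columns become SNPs. Columns containing a gap or an
ambiguous base, and mismatch columns within 3 columns of a gap, are
excluded: mismatches flanking an indel are characteristically alignment
artifacts, and a parental-origin assay must not count them as diagnostic
sites. Circularity is carried as an annotation flag only — both genomes
are deposited with the conventional origin, so the linear alignment is
exact for them.

Feature annotation of SNPs resolves overlaps by the precedence
mt-tRNA > mt-rRNA > mt-mRNA > control region (tRNA genes punctuate the
mitochondrial transcript, so they win containment ties); positions in no
feature are `intergenic`. Ties inside one biotype go to the leftmost
feature, making annotation byte-deterministic.

## Allele counting

Reads are filtered by mapping quality (default ≥ 30, which operationalizes
"uniquely mapped" for both the STAR MAPQ-255 convention and general
aligners), base quality (default ≥ 20), and duplicate flags. Overlapping
bases of a read pair are counted once per site (fragment-level
deduplication, the standard allele-specific-expression practice), and a
read with a deletion or reference skip across the site contributes
nothing. Strand is ignored: mitochondrial transcription is strand-asymmetric
but the allele identity is not.

## Aggregation and enrichment

SNP→feature aggregation is a coverage-weighted mean of unmasked SNPs
(weighting by depth down-weights binomially noisier sites; an unweighted
mode exists for sensitivity analysis). Biotype values average a biotype's
features within each embryo first. Group enrichment is

  ratio = (mean over group embryos + ε) / (mean over control embryos + ε),

with ε = 10⁻⁴ guarding an empty control mean, and a percentile bootstrap
95% interval (default 1000 resamples, embryo-level resampling within each
group, seeded). Percentile rather than BCa because the reported statistic
is a simple ratio of means and the point estimate is always forced inside
the interval; embryos masked in a stratum are dropped from that stratum,
never imputed, and a stratum empty in either group is skipped with a
warning. At ε = 0 the ratio is exactly invariant to rescaling all
heteroplasmy values.

## Embryo sexing and clustering

Sex is called from Y-linked gene expression in CPM (hence library-size
invariant): female iff the summed Y CPM is exactly zero (the "exclusive
expression" criterion — any Y signal excludes a female call), male iff the
summed Y CPM reaches `min_cpm_sum` (default 5) and at least `min_detected`
(default 2) Y genes are detected, otherwise undetermined. Undetermined
embryos are excluded from sex-stratified analyses.

Clustering runs on log1p(CPM) of the mitochondrial transcriptome, PCA
(deterministic sign convention: the largest-magnitude loading of each
component is positive), then k-means with k chosen in 2..6 by mean
silhouette when not fixed. Graph-based community detection (the
Seurat/Louvain route common in single-cell work) was deliberately replaced:
the scientific target here is recovery of a discrete subpopulation and its
size, for which centroid clustering with an explicit model-selection
criterion is more transparent and fully reproducible from a seed. If all
embryos are identical the silhouette is undefined and a single cluster is
returned with a warning.

## Small-RNA fragment profiling

Reads (16–45 nt after the retention filter) are annotated by exact
substring search against reference sequences with at most 2 Hamming
mismatches — no indels, mirroring the short-read annotation regime of
cascade-style small-RNA pipelines at desk scale; genome-wide mapping is out
of scope. The class cascade miRNA > rRNA > tRNA > piRNA assigns the
biotype (rsRNA/tsRNA denote rRNA-/tRNA-derived fragments); the matched
parent's compartment tag gives nuclear vs mitochondrial origin, and a read
matching both compartments of the winning class is `ambiguous`. RPM
normalization scales each sample to 10⁶; the retention filter keeps
sequences with ≥ 0.01 RPM in *every* sample (inclusive threshold) and
length in [16, 45].

Fragment classes on a mature tRNA of length L use a 3-nt end tolerance:
5′ fragment if the read starts in the first 3 nt and ends before L−3,
3′ fragment if it reaches L−3 but starts after nt 3, full-length if both,
internal otherwise. The positional plots that motivate this rule show
sharply end-anchored coverage; 3 nt absorbs ragged processing ends without
mixing the classes. `biotype_log2fc` is deliberately lightweight plumbing —
log2 of pseudocounted RPM means with a label-permutation p-value — not a
re-implementation of count-model differential expression.

## The synthetic-data generator

The generator emulates the hybrid-cross study design end to end, with all
randomness derived from one seed through named substreams (so each output
is reproducible independently):

- **Haplotypes.** A random genome (default 16,300 bp) with 416 programmed
  substitutions placed uniformly subject to a 5-bp minimum spacing (exact
  combinatorial construction, so every admissible configuration is equally
  likely), annotated with the mammalian mtDNA architecture: 22 tRNA-sized,
  2 rRNA-sized and 13 mRNA-sized features plus a control region tiled over
  the genome.
- **Embryo reads.** Per feature, reads start uniformly inside the feature
  and are clipped to its 3′ end, which keeps feature-level paternal
  fractions exact by construction; each read copies the paternal haplotype
  with the embryo's feature-level probability, gets substitution errors at
  the configured rate, and is emitted as a sorted SAM record at its true
  position with mapping quality 60 — placement is known by construction, so
  no aligner runs and no download is needed. A site-level generator
  (`simulate_allele_counts`) draws Poisson depths and multinomial base
  counts directly for estimator tests at depths where per-read emission
  would be wasteful.
- **Group structure.** Default paternal fractions encode the study
  conditions: 1% baseline, mt-tRNA boosts of 12× (HFD_A), 2× (HFD_B) and
  3.5× (HFD_female) over LFD controls, 40 embryos per group at mean site
  depth 500. Between-embryo variability is a single gamma multiplier per
  embryo (mean 1, CV 0.3) shared across features — transmission through the
  oocyte bottleneck perturbs the whole embryo's paternal contribution, not
  each gene independently, and embryo-level spread of this order is what
  makes embryo-resampling bootstrap intervals meaningful.
- **Count matrices.** Negative-binomial (gamma–Poisson, dispersion 0.1)
  counts around lognormal gene means; four Y-linked genes at 20 CPM each in
  males and exactly zero in females; in treatment groups an exact 30% of
  male embryos (assigned by permutation — a designed simulation, not
  Bernoulli flips) carries a 3-fold mt-tRNA expression boost. Only the
  tRNA-tagged mitochondrial genes are boosted: a uniform boost of all
  mitochondrial genes would cancel under within-mito CPM normalization and
  is also not what the motivating observation (mt-tRNA overexpression in
  the minority subpopulation) describes.
- **Small RNA.** Reads sampled from synthetic reference bundles per
  configured biotype proportions; tRNA reads fragmented per the configured
  5′/3′/full mixture (default 0.6/0.3/0.1) with fragment lengths 16–45.
  Full-length reads span the entire parent tRNA (~70 nt, necessarily above
  the 45-nt fragment range — a read cannot both span a 70-nt tRNA and be
  ≤45 nt, so the length range applies to the fragment classes only).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: alignment and mapping artifacts (reads are
placed by construction), RNA modifications that obstruct reverse
transcription at specific tRNA positions, amplification and GC bias,
contamination between embryos, copy-number differences between mtDNA and
its transcripts, and any nuclear-mitochondrial sequence (NUMT)
cross-mapping. Results on real alignments depend on upstream mapping
quality in ways the simulation cannot probe.

## Problem sizes and numerical choices

The reproduction script and the statistical test suite run the study at
its design size: 416 SNPs on 16.3 kb, depth 500, 40 embryos per group for
enrichment (20 replicate cohorts, 1000 bootstrap resamples), 100-embryo
treatment cohorts for subpopulation clustering (50 replicates), 100 seeds
for SNP recovery and sexing, and 3×10⁴ reads for fragment mixtures —
sizes chosen so the whole battery completes in well under a minute per
experiment on one CPU. The enrichment experiment runs at zero sequencing
error: it isolates ratio recovery, while estimator behaviour under error is
quantified separately against the analytic expectation above. Histograms
use 50 bins on [0, 1] normalized to unit area. All tolerances in tests are
derived from binomial/multinomial standard errors of the quantity under
test, not tuned constants.

## Known limitations

- The aligner reports substitutions only; true indel variants between two
  mitochondrial haplotypes are deliberately invisible to the SNP table.
- The exact SNP count between two real accessions can depend on gap
  parameters near indel clusters; the count for the public accession pair
  is checked when the sequences are provided locally, and the gap-adjacent
  exclusion rule is the package's own choice where upstream conventions are
  unstated.
- `assign_reads` is quadratic in (reads × reference length) and meant for
  curated small-RNA reference bundles, not genome-scale search.
- The permutation test in `biotype_log2fc` has granularity limited by the
  number of label permutations at small sample sizes; it is exploratory
  plumbing, not a calibrated differential-expression method.
- k-means assumes roughly isotropic clusters in PC space; a subpopulation
  separable only along a curved manifold would need the graph-based
  methods this package intentionally does not wrap.
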