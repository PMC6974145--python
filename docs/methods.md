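# Methods

## Feature derivation

A gene model is a set of isoforms, each an ordered list of disjoint exon
intervals (internally 0-based half-open; GTF/VCF convert at the boundary,
BED is emitted natively half-open).

* **Exonic parts.** The boundary set is the union of all exon start/end
  coordinates; every elementary interval between consecutive boundaries
  covered by at least one exon becomes one part. Parts are numbered in
  ascending genomic order regardless of strand (`geneID:NNN`); strand only
  affects donor/acceptor labelling. The part lengths always sum to the
  length of the exon union (tested as an invariant).
* **Pseudo-transcript and introns.** Strictly overlapping exons are
  merged; abutting-but-not-overlapping intervals are deliberately kept
  separate, and the resulting zero-length gaps are dropped from the intron
  list. Introns are the remaining gaps; pseudo-exons and introns tile the
  gene span exactly.
* **Junctions and splice sites.** One junction per consecutive exon pair
  per isoform, keyed by (chrom, intron start, intron end, strand) with
  start < end always; on the minus strand the *biological* donor site is
  the endpoint with the larger coordinate, handled in the site accessors
  rather than the key. A splice site's activity is defined as the summed
  count of all junctions sharing that site. This is one specific reading
  of "site-level usage" — it makes total donor activity, total acceptor
  activity and total junction count identical by construction, which is
  tested as a conservation invariant.

## Quantification

* **Overhang filter.** A junction observation requires both flanking
  aligned blocks to span at least `min_overhang` nt (default 6); shorter
  overhangs align too unreliably to trust. A read with k gaps can
  contribute k observations, so junction column sums may exceed the
  read-count library size; library sizes therefore default to counted
  reads and the column-sum sanity check is disabled for multi-observation
  counters.
* **Union-rule counting.** For exonic parts and introns a read increments
  every feature any of its blocks overlaps by ≥ 1 nt, once per feature.
  Ambiguity handling is collapsed to this single rule; no fractional or
  discarded-ambiguous modes are offered.
* **Normalization.** RPKM = count·1e9/(library·length) for length-bearing
  features (parts, introns, transcripts, gene), RPM = count·1e6/library
  for junctions and splice sites. Both satisfy exact scale-invariance
  identities (tested to 1e-12).
* **PSI.** inclusion = (c78 + c89)/2, skip = c79,
  PSI = inclusion/(inclusion + skip). The halving reflects that one
  included molecule produces two inclusion junctions but one skipping
  molecule produces one skipping junction. An all-zero denominator is
  flagged undefined, never reported as 0.
* **Transcript EM.** Reads are grouped into junction-compatibility
  classes. Isoform k with J_k informative junctions emits junction reads
  with mass ∝ θ_k·J_k (the junction-level analogue of effective length),
  so abundances are recovered by dividing the E-step read shares by J_k.
  Exon-body reads compatible with every isoform form an uninformative
  class that contributes nothing to the likelihood. Uniform
  initialization, convergence at max|Δθ| < 1e-8 or 500 iterations,
  deterministic; the log-likelihood is non-decreasing and the optimum
  matches a 1e-3 grid search on two-isoform problems (tested).

## Association testing

OLS per feature: `y = μ + β·g + Cγ + ε`, two-sided t-test on β with the
residual degrees of freedom; fits go through statsmodels. Choices:

* Phenotypes are analyzed on the normalized scale without log transform by
  default; a `log1p` option exists.
* Missing dosages/phenotypes: listwise deletion, no imputation.
* A constant genotype is flagged `untestable` (a data property, not an
  error); rank-deficient covariates raise an error naming the column.
* A numerically perfect fit reports p at the float floor rather than 0,
  keeping p ∈ (0, 1].
* Conditional analysis appends the conditioning dosage as a covariate; if
  the two dosage vectors correlate with |r| > 0.999 the test is flagged
  `collinear` instead of fitted.
* Raw per-feature p-values are reported (a handful of features at one
  locus); a Benjamini–Hochberg helper is provided but off by default.
* Fixed effects only: relatedness/kinship corrections (mixed models) are
  out of scope and would be needed for family or mixed-ancestry cohorts.

The direction report compares sign(β) per feature with an expected
pattern; features expected "0" are checked for non-significance at the
chosen α instead. The packaged expectation covers the three-exon cassette
gene: skipped transcript −, e7–e8 +, e8–e9 +, e7–e9 −, cassette acceptor
and donor activities +, both flanking introns −, total gene 0. (The
modelled region stops at the downstream exon, so only the two introns
flanking the cassette appear; in a longer gene further introns touched by
co-regulated events would join the pattern.)

## Cell-line panel

The packaged 30-line panel stores each line's skipped-band call and the
two genotypes; the verbatim header of the band column ("550nt band
(Δexon 8)") is kept as metadata while the sequenced product length, 542 nt,
is the value the package uses. The classification rule — band absent iff
homozygous minor at either SNP — is stated, not fitted, and separates all
30 lines. The association is assessed with a first-principles
hypergeometric Fisher exact test (two-sided: sum of table probabilities ≤
the observed one, with a 1e-10 relative tie tolerance); it is validated
against a full exact-rational enumeration and against scipy in tests, but
the implementation is independent of both.

## Synthetic data: what it emulates, and what not

The generator reproduces the statistical structure the analysis assumes:

* **Two linked SNPs.** Haplotype frequencies solved exactly from (MAF1,
  MAF2, r², sign of D); infeasible r² values are rejected with the
  attainable maximum (D is bounded by the smallest margin product).
  Individuals are two independent haplotype draws (random mating).
  Defaults: MAFs 0.26 and 0.17, r² = 0.50 — the European-like setting; the
  Asian-like setting (MAFs ≈ 0.47, r² = 0.9) is exercised in tests.
* **Inclusion phenotype.** logit(PSI) = α + β_g·dosage₁ + pop + ε with
  α = logit(0.8) (skipping is the minor outcome at baseline), β_g = +1 per
  minor-allele copy (a testing convention, not a claim about the real
  locus), σ = 0.3, and a two-population 50/50 mixture with a +0.5 logit
  offset mirroring a population-of-origin covariate. Only SNP1 is causal;
  SNP2 associates through LD alone, which is what makes the conditional
  analysis falsifiable.
* **Counts.** Poisson at depth 100 junction-informative reads/sample:
  inclusion junctions at depth·PSI, skipping junction at depth·(1−PSI),
  flanking introns at depth·0.3·(1−PSI) + 2, exonic parts ∝ part length
  (cassette part additionally ∝ PSI). An optional gamma-Poisson
  overdispersion parameter exists (default 0 = pure Poisson).
* **Reads.** An optional block-list emitter produces junction-spanning
  reads with randomized overhangs for exercising the read-level counters;
  no sequences, no mapper, no fragment-length model.

What passing these simulations does **not** show: robustness to
overdispersed real RNA-seq counts (unless the overdispersion option is
used), to mapping artefacts, GC/length biases, unphased multi-locus LD
structure beyond two SNPs, or relatedness. The generator is a correctness
harness for the analysis chain, not a realism benchmark.

All randomness flows from one integer seed through spawned child
generators per stage, so identical configurations produce byte-identical
output bundles.

## The synthetic cassette gene

A three-exon gene (plus-strand, synthetic coordinates) with an inclusive
and a skipping isoform. The middle exon is 198 nt, and the exon-7/exon-9
primer anchors are placed so the in-silico amplicons are 740 nt
(inclusive) and 542 nt (skipping); their difference is the cassette length
by construction, a property tested over random isoform pairs. Primer
anchors are coordinate-based; no sequence matching or melting model. The
simulated causal SNP sits 75 nt inside the cassette exon and the proxy
36 nt upstream of the intron/exon boundary, mirroring the real geometry.

## Validation problem sizes

The packaged validation uses desk-scale sizes chosen to make the
statistical assertions sharp but quick: 2000 null replicates at n = 100
for type-I calibration (rejection rate 0.05 ± 0.01 at α = 0.05), 100
simulated cohorts at the default configuration for direction-pattern
recovery (≥ 7/8 signed features concordant in ≥ 90% of replicates), 60
cohorts for the conditional-collapse check (mean marginal |t| > 4, mean
conditional |t| < 2), 5000 individuals × 10 seeds for LD recovery
(±0.03), and 500 replicates for PSI estimator bias. Oracle-equivalence
checks (flattening vs per-coordinate sweep, junction counting vs per-read
recount, EM vs grid search, exact test vs rational enumeration) run on
randomized small inputs each suite run.

## Known limitations

* Single-locus, cis-only: no genome-wide scan machinery, no permutation
  FDR, no trans effects.
* The splice-site activity definition (junction sum) is one defensible
  reading; alternatives (e.g. coverage-based site usage) are not offered.
* The EM assumes junction reads only; exon-body evidence is discarded as
  uninformative rather than modelled.
* The minigene construct of the motivating system (shortened exon 7,
  vector splice sites, ~720/520/210-nt products) is represented only as
  in-silico amplicon evaluation over isoform models; no splicing-strength
  model is attempted, and those approximate product sizes are not
  asserted anywhere.
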