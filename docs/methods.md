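# Methods

## Problem and approach

Low-pass plasma cfDNA sequencing (a few fold genome coverage, no paired
germline genotypes) still contains somatic-variant signal: clonal
hematopoiesis in everyone, tumor-derived variants in cancer patients.
`freesv` screens candidate substitutions from pileup evidence alone,
quantifies how much of a sample's 96-context mutation profile is
attributable to tumor-like signatures rather than background noise, and
contrasts the fragments that *carry* each variant allele (Mut-DNA)
against those covering the reference allele at the same loci (Wt-DNA)
in size, end-motif usage, end-position concordance, nucleosome context,
and CpG methylation.  The per-sample contrasts plus the mutation
profile feed a gradient-boosted classifier evaluated under repeated
nested cross-validation.

## Variant screening

Pileup columns are built from fragment base observations (mapping
quality >= 60, base quality >= 30).  Fragment records store explicit
base calls only at genotyped or mismatching positions; every other
overlapping fragment implicitly supports the reference, so column depth
equals fragment coverage, as in a conventional pileup.

The candidate score is a transparent consensus stand-in: the
phred-scaled exact binomial tail probability that the alt observations
arise from sequencing error alone,

    qual = -10 log10 P(X >= alt_count),  X ~ Binomial(depth, eps / 3),

capped at 255, with per-base error rate `eps` defaulting to 1e-3.  This
preserves the `qual >= 30` retention semantics of consensus callers
while remaining exactly testable against an independent binomial
evaluation.  Columns below a depth floor (default 4) are not called:
the binomial score degenerates at depth 1-3, where a single
high-quality mismatch is formally improbable as error, and a floor is
standard caller practice.  In enzymatic-methyl-sequencing (`emseq`)
mode, T observations at reference-C columns are not eligible alt
alleles (unmethylated C reads as T); the rule is applied symmetrically
to A at reference-G columns to cover the reverse strand, since
strand-of-conversion is not modelled at the fragment level.

The filter cascade computes all flags independently per call, so it is
order-free by construction.  Retained calls are substitutions on
autosomes with a single non-reference allele, `qual >= 30` (30 passes),
no other candidate within 1 bp (the "continuous variant" window,
configurable), outside blacklisted regions, with locus coverage not
above the top coverage quantile of candidate loci (1% human, 10% mouse
defaults; quantiles are computed within the candidate set because a
genome-wide coverage distribution is not available from candidate
pileups), and with maximum population allele frequency <= 0.1% across
the supplied databases — unless the exact variant is in the supplied
cancer-hotspot set, which rescues it from the population filter only,
never from the quality, blacklist, or coverage filters.  Boundary
conventions are strict: 29.9 fails, 30 passes; exactly 0.1% passes.

Origin classification with paired genotypes: at loci with >= 30-fold
coverage in both PBMC and tumor (qualities >= 20), a PBMC minor allele
supported by >= 3 reads at a tumor-homozygous locus is called
clonal-hematopoiesis-derived (minor allele variant, major germline);
the mirror case is tumor-derived.  With deep PBMC data alone
(>= 300-fold), minor alleles at 2-30% frequency are attributed to
clonal hematopoiesis, since germline heterozygotes sit near 50%.

## Mutation profiles and deconvolution

Substitutions are binned into the standard 96 channels (six
pyrimidine-strand substitution types x 4 five-prime x 4 three-prime
bases; purine-reference calls are reverse complemented), ordered
substitution-major.  Profiles are normalized counts.

Deconvolution refits a profile against a fixed pool: COSMIC-style
signature columns (artifact-flagged columns removed before fitting, not
zero-weighted) plus "background signatures" — the profiles of randomly
selected control samples (seeded), which absorb platform noise and
clonal hematopoiesis.  With the basis fixed, non-negative matrix
factorization reduces to non-negative least squares; we run seeded
multiplicative updates to convergence (relative error change < 1e-8 or
10,000 iterations) and polish with an exact NNLS solve, keeping the
better solution.  Contributions are reported as fractions summing to 1
(profiles have heterogeneous mutation loads, so relative contributions
are the comparable quantity); the tumor-associated score is the summed
contribution of the non-background columns, and equals one minus the
background total by construction.  Fit quality is the cosine between
the input frequencies and the reconstruction.

## Fragmentomics

Fragment coordinates are 0-based half-open; the upstream (U) end is the
start, the downstream (D) end the last covered base (`end - 1`), and
the two ends are processed orientation-aware throughout.  Fragments
covering two or more retained variant loci are excluded from the
Mut/Wt partition; fragments with no usable base observation at their
locus, or a third allele, are dropped with counts.

* **Short-fragment fraction**: lengths <= 150 bp, boundary inclusive.
* **End motifs**: the reference 4-mer starting at the U end (forward
  strand) and the reverse-complemented 4-mer ending at the D end, i.e.
  each fragment contributes two 5'->3' motifs.  Motifs are read from
  the reference at the fragment coordinates, not from read bases:
  this makes them immune to sequencing errors and to enzymatic C-to-T
  conversion.  The CCCA entry of the 256-vector is the reported motif
  fraction.
* **Breakpoint motifs**: two reference bases outside the fragment plus
  the first two inside, per end, strand-oriented as above; the CTCC
  entry encodes the CT-5'-CC configuration.
* **Motif diversity**: Shannon entropy of the 256-motif distribution
  divided by ln 256, so 1 is uniform usage and 0 a single motif.
* **E-index**: a panel of healthy-control fragments defines per-position
  U-end and D-end counts; a sample's E-index is the mean over its
  fragments of the panel counts at its two end positions.  Panel counts
  are normalized to ends-per-million by default so values are
  comparable across panels of different depth; the raw-count variant is
  available behind a flag.
* **Nucleosome context**: for each end, the signed distance to the
  nearest annotated nucleosome center (negative upstream; ties broken
  toward the smaller coordinate), and the percentage of ends within
  +/- 50 bp of a center, boundary inclusive.

All five per-sample contrasts (Diff-size, Diff-CCCA, Diff-CTCC,
Diff-nucleosome, Diff-methylation) are oriented Mut minus Wt.
Undefined statistics (empty fragment class, no observations) propagate
as explicit `None`, never as silent zeros.

## Methylation

Methylation observations are per-fragment (CpG position, methylated)
pairs; conversion chemistry and strand collapsing are upstream
concerns.  To compare Mut- and Wt-DNA on the same CpGs, only sites
observed in at least one fragment of each class enter the densities
(matched globally per sample).  CpGs are stratified into promoters
(TSS +/- 500 bp), gene bodies (gene span minus promoter windows), and
intergenic regions; the precedence promoter > gene body > intergenic
makes the three classes a partition, which the source annotation alone
does not guarantee.  Density is `100 * C / (C + T)` per class, with
empty classes flagged undefined.  The classifier consumes the
gene-body Diff-methylation entry.

## Classifier

The base feature vector has 101 entries (96 profile frequencies + 5
contrasts); the extended vector appends four externally supplied
genome-wide summary columns (methylation, size, end motif, copy
number), for 105.  Undefined contrasts are median-imputed strictly
within each training fold.

Evaluation is stratified 10-fold nested cross-validation: within each
training split, a small gradient-boosted-tree grid (default
{100 trees, depth 2} and {300 trees, depth 1}, learning rate 0.1;
configurable) is tuned by inner 3-fold resampling on AUC, and the
held-out fold is scored by a model that never saw it.  The procedure
repeats with fresh fold assignments (per-repeat seeds spawned from one
master seed) and each sample's score is the average over repeats.
Stratification is used because small cohorts would otherwise risk
single-class folds.  Reporting: rank-statistic AUC with a
Hanley-McNeil Z-test against 0.5; the operating threshold is the
smallest cutoff achieving the target specificity (default 99%) on
controls — frozen from the training group when a model is applied to a
held-out test group — and sensitivity carries an exact Clopper-Pearson
95% interval.

## Synthetic cohorts

The generator's defaults are the study conditions; effects are
implemented at the fragment-sampling level conditional on the carried
allele, so every intermediate statistic is exercised honestly.

* Genome: 2 chromosomes x 400 kb of random sequence at GC 0.45, genes
  of 4 kb roughly every 15 kb, nucleosome centers every 185 bp with
  +/- 18 bp jitter.  Small relative to a human genome, but large enough
  that all 32 pyrimidine trinucleotide contexts are well represented.
* Variants: each sample draws background variants at 2.5e-4 per bp
  (~200 per sample — the 100-150k per 3 Gb sample seen in real
  low-pass data corresponds to a similar per-base rate) from a smooth
  shared background profile; cancer samples add signature-mixture
  draws so the expected tumor share equals `tumor_fraction` (default
  0.2).  Variant positions are sampled from genome positions matching
  the drawn trinucleotide context on either strand.  Allele fractions
  are uniform on [0.12, 0.35], the clonal-hematopoiesis-like regime.
* Fragments: ~10 fragments (Poisson) per variant locus; lengths from a
  two-component Gaussian mixture (88% at 166 +/- 9 bp, 12% at
  140 +/- 12 bp).  Placement over the offsets covering the locus is
  weighted by a deterministic cleavage-preference track (5% hotspot
  positions at weight 5, shared by all samples and the panel — this is
  what makes the panel end model informative), by motif factors, and by
  nucleosome-context factors.
* Mut effects (scaled by origin: tumor-derived fragments get the full
  effect, background/CH-derived ones half, reflecting the weaker but
  present effects in non-cancerous carriers): size shift -20 bp, CCCA
  and CTCC placement depletion 0.5, within-nucleosome end-weight
  enrichment 0.8, methylation shift -5 percentage points against
  region baselines (promoter 15%, gene body 80%, intergenic 70%).
* Errors: observed bases flip to a uniform other base at 1e-3 per
  observation, and stray mismatched calls are sprinkled along
  fragments at the same rate; every injected variant and every error
  site is recorded in the truth manifest.
* Everything derives from one master seed via spawned seed sequences;
  outputs are byte-identical across runs, and a cancer sample with
  `tumor_fraction = 0` consumes the identical random stream as a
  control.

What the generator does *not* emulate: per-base quality strings and
alignment artifacts, real genomic sequence composition (repeats,
CpG islands, mappability), copy-number structure, germline
polymorphisms, and conversion noise in the base calls of EM-seq-like
samples (methylation states are carried separately, so the pipeline's
`emseq` calling mode is exercised on scripted pileups instead).
Passing tests therefore demonstrate correctness of the statistics and
the end-to-end machinery under a controlled data-generating process,
not performance on real plasma data.

## Numerical choices and degenerate inputs

* Binomial qual capped at 255; depth floor 4 (above).
* Coverage quantile cut is strict (`>` the quantile), so tied
  coverages are never all removed.
* Deconvolution tolerance 1e-8 relative; rank-deficient pools log a
  warning and return the NNLS minimizer (ties resolved by the seeded
  multiplicative start).
* Nearest-nucleosome ties break toward the smaller coordinate; the
  +/- 50 bp window is inclusive.
* Empty fragment sets, empty classes, and one-sided contrasts return
  `None`; `roc_report` refuses single-class inputs; `build_end_model`
  refuses an empty panel.
* Fragment termini too close to a contig edge for a motif are skipped
  and counted.

## Problem sizes used in the checks

Deconvolution fidelity and monotonicity run on fragment-free variant
sets (10 controls + 8 cancers per tumor-fraction level, background
rate 8e-4 for tighter profiles).  Parameter recovery and the
classifier run on a 120-sample cohort (60/60) with 10-fold nested CV
repeated 5 times over a two-point tuning grid; the repeat count is
reduced from the 100 used for real cohorts because the averaged score
stabilizes quickly at this effect size, and the full setting is a
parameter away.

## Known limitations

* The consensus caller stand-in shares thresholds, not likelihoods,
  with production callers; absolute qual values differ.
* The "continuous variants" window (1 bp) and the per-candidate-set
  coverage quantile are interpretations of underspecified filters;
  both are configurable.
* The hotspot rescue applies to the population-frequency filter only;
  an alternative reading (hotspot annotation without rescue) is a
  switch away (`cosmic_rescue=False`).
* Whether the 0.1% allele-frequency threshold applies per database or
  to the maximum across databases is ambiguous; the maximum is used.
* Single-end data contributes two reference-derived motifs per
  fragment like paired-end data; if only one terminus is trusted, the
  caller must filter upstream.
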