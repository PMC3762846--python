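# Methods

## Profiles and the relationship matrix

The raw material is a samples × features table of non-negative integer
counts: reads aligned per contig (mapped, primary, non-supplementary SAM
records only; MAPQ threshold configurable, default 0), or k-mer counts.
Features with fewer than 10 reads in total across samples are removed
before any transformation (`filter_low_count`, strict `<`).

`build_profile` then applies, in order:

1. **Depth normalisation** (default on): each sample's counts are scaled to
   counts-per-million of that sample's total. Shotgun profiles carry
   relative, not absolute, abundance information, and per-feature
   standardisation alone does not remove depth differences between samples.
2. **Log transform**: log(value + pseudocount), pseudocount 1.0 by default.
   Count tables are zero-rich, so a shifted log is used rather than
   dropping zeros; the pseudocount is configurable and recorded in
   `transform_log`.
3. **Standardisation**: each feature column is centred to mean 0 and scaled
   to unit *population* variance (divide by n). Population variance makes
   trace(**G**) = n an exact identity, which the test suite exploits;
   sample variance (n − 1) is available by option. Columns that are
   constant across samples carry no information and are dropped, with the
   divisor m adjusted; their ids are recorded. Constant columns are
   detected by zero range rather than zero floating-point variance, which
   can round to a tiny nonzero value.

**G** = **XX**′/m is symmetrised against floating-point asymmetry. Note
that column centring puts the ones vector in the null space of **G**; all
downstream solves go through **G**ᵣᵣ + λ**I**, so no jitter is added.

## REML and BLUP

The mixed model is y = **1**μ + **Zg** + **e** with **Z** = **I**: one
record per sample, so repeated measurements (e.g. methane measured on two
days) must be averaged by the caller before fitting. Phenotypes can be
pre-adjusted for a known covariate by OLS residualisation
(`residualize_phenotype`, e.g. methane corrected for dry matter intake).

REML works on the reference block **G**ᵣᵣ only — target samples never
contribute to estimation. Writing V₀ = **G**ᵣᵣ + λ**I** with
λ = σ²e/σ²g, σ²g is profiled out in closed form
(σ̂²g = r′V₀⁻¹r/(n−1), r the GLS residual), leaving a one-dimensional
restricted likelihood in log λ. After one eigendecomposition of **G**ᵣᵣ
each likelihood evaluation is O(n). The optimiser scans a 256-point
log-spaced grid on λ ∈ [10⁻⁶, 10⁶] and refines the best bracket by bounded
scalar minimisation; the scan step guards against the occasional
multi-modal likelihood at small n, and the returned optimum is verified in
tests to beat an independent 200-point grid. λ at either bound triggers a
warning (upper bound ⇒ σ²g ≈ 0: no detectable microbiome signal). A
constant phenotype returns a flagged degenerate fit with both components
zero. μ̂ is the GLS estimate (1′V₀⁻¹1)⁻¹1′V₀⁻¹y.

BLUP for all samples is ĝ = **G**₍·,r₎V₀⁻¹(y − **1**μ̂), the predicted
phenotype ĝᵢ + μ̂. This is algebraically identical to solving Henderson's
mixed-model equations; the test suite checks the identity to 10⁻⁸ against
a direct MME solve on random instances (which requires an invertible
**G**, hence uncentred test matrices).

## Evaluation

- **Cross-validation**: seeded random partition into k near-equal folds
  (optionally stratified by a binary label); each fold is predicted from
  the remaining folds with variance components re-estimated per fold, and
  predictions are collated so each sample is predicted exactly once.
  Per-fold correlations are reported alongside the collated r. **G** is
  built once over all samples; only phenotypes of the held-out fold are
  withheld.
- **Two-population validation**: count tables are restricted to shared
  features, **G** is built over the sample union, training uses the
  reference only, r is computed on the validation samples. Sample overlap
  between the populations is rejected.
- **Binary traits** are coded 0 = case, 1 = normal, fitted as continuous
  values and thresholded at 0.5 (prediction > 0.5 ⇒ normal; ties go to
  case). No logistic link is used — the linear-model-plus-threshold route
  is the method's own convention. AUC is the rank-based Mann–Whitney
  statistic with half-credit for ties; the null baseline is the
  majority-class predictor.
- **Bootstrap CIs**: percentile bootstrap over (predicted, observed) pairs,
  default 10,000 resamples, 2.5th/97.5th percentiles; degenerate resamples
  with a constant vector are redrawn. The resampling loop is vectorised;
  coverage for a bivariate normal with ρ = 0.5 at n = 50 measures ~0.93 in
  the test suite (percentile intervals for correlations are mildly
  anti-conservative at this n, which is inherent to the method, not a
  defect of the implementation).

## Reads and k-mers

`qc_read` removes 3′ bases one at a time until at most 3 bases with Phred
quality < 15 remain (implemented as the equivalent longest-prefix scan),
then discards reads shorter than 50 bp or with mean Phred quality < 30.
The mean-quality filter applies to the *trimmed* read and uses the
arithmetic mean of Phred integers, not of error probabilities — the
simpler rule, chosen because it is directly testable; the original
pipeline's order of operations is not fully specified, and this choice is
documented rather than hidden. Deduplication keys on the exact forward
base string (no reverse-complement collapsing) and keeps first
occurrences; it is a deliberately simple stand-in for dedicated
decloning tools.

K-mer counting takes every K-length substring of the first 1,000,000 reads
per sample (configurable), skipping substrings containing N;
non-canonical by default with a `canonical=True` option, since either
convention is defensible. The k-mer count table keeps only k-mers observed
in *every* sample, so it has no zeros by construction, and then flows
through the same profile/G/BLUP pipeline as contig counts.

## Synthetic data generator

The generator produces the statistical structure the predictor assumes,
with known ground truth:

- **Community**: contig log-abundances are normal with s.d. 1.5 (a skewed,
  uneven community on the natural scale). Between-sample variation is a
  low-rank-plus-noise perturbation of the shared log-abundance vector:
  5 latent community gradients (diet/enterotype-like axes, overall s.d.
  0.8) move correlated blocks of contigs together, plus contig-wise
  independent noise (s.d. 0.5). The latent gradients give **G** genuine
  between-sample structure — real microbiome samples differ along a small
  number of strong axes — and without them σ²g is barely identifiable at
  desk scale.
- **Counts**: per-sample depth is log-normal around 50,000 reads (CV 0.3);
  counts are multinomial given depth and the sample's relative abundances.
- **Phenotype**: effects β are drawn normal on the standardised profile
  columns of the causal contigs (by default every contig — the
  infinitesimal-style architecture BLUP assumes; a sparse large-effect
  option exists to stress the per-contig baseline). g = **X**β and the
  noise are rescaled so the *realised* variance ratio var(g)/var(g + e)
  equals the requested microbiability m² exactly (the noise is
  orthogonalised to g in-sample first). The continuous phenotype is
  μ + g + e with μ = 25.75 by default (a methane-like g CH₄/kg DMI scale).
- **Binary traits**: the liability g + e is thresholded at the
  (1 − prevalence) quantile; the top `prevalence` mass are cases (0).
- **Two-cohort fixture**: 40 reference + 24 validation samples over 600
  shared contigs, one set of contig effects, within-cohort phenotype s.d.
  2.5; the reference cohort's treatment half has 20% of the control mean
  subtracted, emulating a methane-mitigating feed trial. The shift is a
  pure diet effect on the phenotype (it does not alter the microbiome), so
  it acts as structured noise during training — cross-cohort accuracy is
  correspondingly moderate, which is the realistic regime.

What the generator does **not** emulate: taxonomic structure, read-level
sequences, compositional zero-inflation beyond the multinomial, phenotype
× environment interactions, or diet-driven microbiome change. Passing
tests therefore demonstrate the statistical machinery under the model's
own assumptions, not performance on real rumen or gut data.

## Experiment designs and problem sizes

Reference-size, extreme-phenotype and contig-subset experiments evaluate
many sub-designs against one jointly standardised profile: the profile and
**G** are built once over the sample union, and replicates index into
them. For feature subsets this is exact — standardisation is per-feature,
so the **G** of a subset is X[:, S]X[:, S]′/|S|. Depth subsampling draws
from each sample's count vector without replacement (multivariate
hypergeometric), equivalent in distribution to subsampling reads before
counting.

The per-contig baseline filters contigs with < 100 reads in either
population, fits phenotype ~ profile-value per contig in the reference,
ranks by slope p-value (two-sided t; ties by |t|, then feature id), and
predicts validation samples by averaging the top-N single-contig models.
Profiles for this baseline are standardised within each population over
its full feature table, so depth scaling does not depend on which contigs
survive filtering; a raw-count option is provided.

The bundled test and acceptance runs use n = 100–200 samples and
m = 400–1000 contigs with 10–20 replicate datasets — sizes chosen so
variance-component estimates and trend contrasts are stable while the
whole suite stays fast. Accuracy magnitudes at these sizes are smaller
than with hundreds of thousands of contigs and deeper sequencing; the
qualitative contrasts (size, extremeness, subset variance) are what the
experiments assert.

## Known limitations

- Single random effect only: no host-genetic term, no extra fixed effects
  beyond the intercept, no multi-component models.
- The percentile bootstrap is not BCa; its coverage is slightly below
  nominal for correlations at small n.
- REML at n < ~30 has wide sampling variance for m²; boundary estimates
  (σ²g = 0) occur and are warned about rather than suppressed.
- Deduplication and k-mer counting are exact-match and strand-naive by
  default; adapter trimming and paired-end logic are out of scope.
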