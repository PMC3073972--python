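# Methods

## The screening model

A 3′ DGE-tag library reduces each transcript to (ideally) one 21 nt
barcode: the 3′-most NlaIII site (CATG) with the 17 nt downstream of it.
Tag counts are then a direct proxy for transcript abundance, and a
transcript whose tags appear in only one developmental-stage library is
a stage-specific expression candidate — for a pest insect, a
larva-specific, highly expressed gene is a promising dsRNA target.

`dgescreen` models this as four components: a virtual tag database over
a given unigene set, a clean-tag filter over raw tag observations,
tag→unigene expression profiling with stage-specific calling, and the
downstream wet-lab analytics (bioassay and qPCR).

### Virtual tag database

Every CATG occurrence with a full, N-free 17-mer downstream on the sense
strand is an eligible site. The **canonical** tag is the 3′-most
eligible site: the library chemistry primes from the poly(A) tail and
captures the last NlaIII fragment, so only that site should appear in a
real library. `build_tag_index` defaults to canonical-only; an
`all-sites` mode exists for sensitivity analysis because incomplete
digestion can expose internal sites. Tags are keyed by their 17-mer
(the anchor is constant), matching is exact and case-insensitive, and a
17-mer carried by two or more unigenes is classed *ambiguous* and never
credits a unigene — mapping over a 4^17 ≈ 1.7 × 10^10 space makes
chance collisions negligible but assembly redundancy does produce them.
Antisense scanning is deliberately absent: DGE libraries are stranded.

### Clean-tag filter

Three filters in a fixed order — (1) any-N low-quality, (2) adaptor
(exact or adaptor-prefix match; the default adaptor list is empty),
(3) per-library copy number < 2 after aggregation — so each removed
observation is attributed to exactly one category and the accounting is
additive in both total-tag and unique-tag units. The order itself is a
design choice; the categories are standard but any attribution of a tag
that is both N-containing and singleton must be unambiguous for the
report identities to hold. Copy number exactly 2 is kept (the threshold
is "less than 2"). Observations may be 21 nt CATG-prefixed reads
(default; prefix validated on N-free tags) or bare 17-mers.

### Profiling and target calling

`map_tags` asserts a conservation identity after every run: per stage,
uniquely-mapped + ambiguous + unmapped tag copies equal the clean-tag
total. Stage-specific calling has two modes because "stage specific" is
used in two senses in practice:

- **strict** — nonzero in exactly one stage (presence/absence);
- **dominance** (default: fold ≥ 3, min_count ≥ 100) — the top stage
  exceeds the best other stage by a fold threshold, which tolerates
  trace counts in other stages (leaky expression, index hopping) and
  matches how published target lists include genes with minor
  off-stage counts.

Strict calls are a subset of dominance calls at equal min_count.
Ranking is by called-stage copy number, descending, with lexicographic
tag tie-breaks for determinism. Tags-per-million is provided as the
library-size normalisation appropriate to tag counts; RPKM (1e9·C/(N·L))
is in `seqstats` for read-based abundance.

### Assembly statistics

N50 follows the cumulative definition: order lengths longest to
shortest and accumulate until the sum *strictly exceeds* half the total;
ties at exactly half continue to the next length. Length classes are
half-open [lo, hi) with a final open class, so a boundary-length
sequence falls in the class it opens. Report rounding is half-up
(integer nt for means, 2 dp for percentages), which reproduces the
printed arithmetic of classical assembly tables.

### Bioassay

Abbott's correction (T−C)/(100−C)×100 removes control mortality;
negative corrected values are clamped to zero with a warning. One
published corrected cell (DS28 vs the dsEYFP control) recomputes to
92.14 from the printed means against a printed 92.13 — corrections in
that table were evidently applied to unrounded replicate means, and two
further cells (DS3, DS34) show the same ±0.01 effect; the package
corrects whatever means it is given and rounds half-up at the reporting
layer only.

The dose–response model is a probit regression of corrected mortality
on log10 dose, fitted by IRLS (statsmodels GLM, binomial family, probit
link, dose-group sizes as variance weights). LC50 = 10^(−intercept/slope).
The 95% limits are Fieller fiducial limits on −intercept/slope; when
the residual deviance exceeds its degrees of freedom the covariance is
inflated by the heterogeneity factor and Student's t replaces the
normal critical value (Finney's classical recipe); when Fieller's
g ≥ 1 the interval degenerates and a delta-method interval is returned
flagged `fieller_valid=False`. Control mortality is handled by Abbott
pre-correction using the dose-0 row rather than by a natural-response
parameter in the likelihood — it matches the corrected-mortality
workflow the rest of the analysis uses; a likelihood-based natural
response term would be the main alternative and is out of scope.

### qPCR

Livak 2^−ΔΔCt with efficiency fixed at 2 and replicate aggregation on
the ΔCt scale; the replicate sd maps to the conventional asymmetric
fold range 2^−(ΔΔCt ± sd). No Pfaffl efficiency correction is offered.

## The synthetic generator

The generator emulates the study conditions so the pipeline can be
validated against a planted truth: four stage libraries (egg, larva,
pupa, adult), each a multinomial sample of canonical tags proportional
to a lognormal expression model, corrupted by per-base substitutions,
N-masking, and unique junk singleton tags, at exactly `library_depth`
observations per library.

Default scale mirrors the emulated experiment: 45,750 unigenes and
3.5 M tags per library. Noise defaults derive from the observed
raw-to-clean attrition of such libraries: N-contamination 0.004
(≈ 14,412 low-quality of 3,695,998 raw) and singleton junk 0.03
(≈ 112,937 of 3,695,998); the substitution rate is unpublished and
defaults to 0.001 as a typical short-read value. Tests and the
acceptance studies use smaller explicit configs (documented below).

Deliberate modelling choices:

- **Substitution-only errors, confined to the 17 variable bases.** Tags
  are fixed-length, so indels are not representable; and a read whose
  CATG anchor is corrupted would fail the enzyme-site check upstream of
  tag counting, so anchor errors are not modelled. N-contamination can
  mask any of the 21 positions (the N filter runs before the prefix
  check, so such reads are counted low-quality, as in real pipelines).
- **Junk singletons are unique CATG-prefixed 21-mers rejected against
  the true tag set**, guaranteeing the copy-number filter — not the
  mapping step — is what removes them.
- **Canonical tags are made distinct across unigenes** (colliding
  records are resampled). Collisions in a 4^17 space are vanishingly
  rare at realistic set sizes; enforcing distinctness makes exact
  recovery statements (below) well-posed.
- **Shared transcripts are expressed at the same baseline in every
  stage**; each stage column is scaled to sum to the library depth. The
  lognormal spread (σ = 0.5 in tests) keeps the least-expressed
  transcript's expected count far enough above the copy-2 threshold
  that presence/absence is informative rather than dominated by
  sampling zeros.
- The dose-0 control row of simulated assays uses the same binomial
  machinery as treatment rows; Abbott correction consumes it downstream.

What the generator does **not** model: read-level RNA-seq (no 75 bp
paired-end reads, no assembly), base-quality scores, PCR duplicates,
adaptor contamination (the emulated accounting shows zero adaptors),
library-prep biases (3′ bias, incomplete digestion), or cross-library
batch effects. Passing recovery tests therefore demonstrate the
*pipeline logic* — filtering attribution, mapping conservation, call
semantics, estimator correctness — not robustness to every artefact of
real sequencing data.

## Problem sizes and numerical choices

- Screening-recovery studies: 400 unigenes, 200,000 tags per library,
  specific fraction 0.10 per stage (balanced), lognormal σ = 0.5.
  Noise-free strict calls at min_count = 2 recover the planted labels
  exactly; at substitution rate 0.005 with 2% junk, strict recall at
  min_count = 100 stays ≥ 0.95 (an exact tag loses only
  1 − 0.995^17 ≈ 8% of its copies to substitutions, and error variants
  are overwhelmingly removed as singletons).
- LC50 recovery: 500 simulated assays of the published design (true
  LC50 60 ng/µl, slope 4 probits/log10, control mortality 0.11, doses
  20–100 ng/µl, 300 larvae/dose). Across seeds the median estimate sits
  within 0.5% of truth and Fieller coverage near 0.94.
- Oracle cross-checks run brute-force scans on 1,000 random 1 kb
  sequences (tag extraction) and 1,000 random length multisets (N50).
- GLM convergence tolerance 1e-12; noiseless probit inputs are
  recovered to better than 1e-6 relative. Exact 0/1 proportions at
  extreme doses are legitimate inputs to the ML fit; degenerate
  all-0/all-1 responses and non-positive slopes raise errors instead of
  returning meaningless estimates.
- Rounding helpers use decimal half-up, applied only at the reporting
  layer; all internal arithmetic is unrounded floats.
- Determinism: every generator call builds its own
  `numpy.random.Generator` keyed by (seed, operation[, stage]); no
  global random state is touched, and identical config + seed gives
  byte-identical files.

## Known limitations

- Exact-match mapping only; one substitution in a real tag silently
  becomes an unmapped (or, rarely, wrongly mapped) tag. A
  mismatch-tolerant mode would need an edit-distance index and a
  collision policy.
- Ambiguous tags are reported but discarded from unigene counts; an EM
  reassignment of shared tags is out of scope.
- The strict/dominance dichotomy does not test differential expression
  statistically; no replicate libraries exist in this design, so calls
  are descriptive, not inferential.
- Abbott pre-correction ignores the sampling error of the control
  group, which mildly narrows the LC50 fiducial intervals (coverage
  ≈ 0.94 rather than 0.95 in the recovery study).
- The Venn partition treats presence as count > 0 in the clean table;
  with very deep libraries even trace cross-stage leakage flips
  membership, which is why the dominance screening mode exists.
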