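# Methods

This note documents the statistical procedures the package implements, the
synthetic data model used to validate them, the parameter choices that were
genuinely open, and what the validation does and does not establish.

## Analysis procedures

### Taxonomy by majority vote (`taxvote`)

Each genome's predicted ORFs carry candidate protein hits with bit scores,
e-values and (possibly partial) lineages.  Per ORF, hits with e-value at or
above the cutoff (default 1e-5, the conventional blastp significance level;
exposed as a flag since no stronger convention exists for this step) are
discarded and the highest-scoring survivor is kept, with bit-score ties
broken by the lexicographically smallest protein id so annotation never
depends on input row order.  Each rank is then voted independently over the
retained ORFs: the plurality taxon wins; plurality ties yield
`UNCLASSIFIED`, as do genomes with fewer than two retained ORFs.  Plurality
(rather than a strict >50% majority) maximizes annotation yield while the
tie rule keeps ambiguous genomes unassigned.  No parent–child consistency
is enforced between ranks; ranks with conflicting assignments are left as
the votes fall.

### Filtering and TMM (`norm`)

Taxa are removed when their across-sample variance is below half the median
taxon variance or their prevalence is below 10%.  Both rules are evaluated
against the original matrix in one pass; the median is not recomputed after
removals, so the filter is not idempotent under re-application.  The
prevalence rule is deliberately read as "absent in ≥90% of samples are
removed": the inverted reading (remove taxa *present* in ≥90%) would delete
the core community and contradicts standard practice.  Filtering precedes
factor estimation.

TMM factors follow the reference formulation: the reference sample is the
column whose upper-quartile count fraction is closest to the mean of those
fractions; M (log2 ratio) and A (mean log2 abundance) values are computed
over taxa positive in both sample and reference; 30% of M values and 5% of
A values are trimmed from each tail; the factor is 2 raised to the
inverse-variance-weighted mean of the surviving M values, and factors are
rescaled to geometric mean 1.  Normalized abundance is counts-per-million
on the effective library, count / (library × factor) × 10⁶ — the unit is a
package choice, as normalization alone does not fix one.  Because the
precision weights see absolute counts, scaling one column changes the other
factors at the 1e-3 level; the package treats TMM scale-invariance as
approximate.

### Diversity and disease models (`diversity`)

Shannon H = −Σ pᵢ ln pᵢ (nats) over positive entries; Heip evenness
(e^H − 1)/(S − 1), defined as 0 when S = 1 (a one-taxon sample carries no
evenness information); Chao1 = S + f₁²/(2 f₂), with the bias-corrected form
S + f₁(f₁ − 1)/(2(f₂ + 1)) when no doubletons exist.  Chao1 requires
integer counts, so diversity is computed on raw counts by default; Shannon
and Heip are scale-invariant and accept normalized input.  The per-study
group comparison is a two-tailed Wilcoxon rank-sum test (exact enumeration
for combined n ≤ 12 without ties, otherwise the tie-corrected normal
approximation), BH-adjusted across studies.  Linear models use
Y = ln(diversity + 1e-6) — the additive guard keeps zero-diversity samples
— with disease coded 1 for CRC, and optionally age, 0/1 gender and BMI as
covariates; no interactions.  The disease coefficient and its two-sided
t-test are reported.

### Random-effects pooling (`meta`)

Per-study effects are Hedges' g (small-sample corrected standardized mean
difference; the correction is a switch) with the usual large-sample
variance.  Pooling uses the DerSimonian–Laird method-of-moments τ², normal
test of μ = 0, and I² = max(0, (Q − df)/Q)·100 — matching the defaults of
the standard meta-analysis tooling; REML and Knapp–Hartung adjustments are
out of scope.  Correlations are pooled on the Fisher-z scale
(y = atanh r, v = 1/(n − 3)) and back-transformed with tanh.  BH adjustment
is the step-up procedure with monotonicity enforced.

### Ordination (`ordination`)

Bray–Curtis d(x,y) = Σ|xₜ − yₜ| / Σ(xₜ + yₜ).  PCoA double-centers
B = −½ J D² J and keeps the top-k positive eigenpairs; explained variance
is relative to the positive eigenvalue sum (Bray–Curtis is non-Euclidean
and can produce negative eigenvalues, which are dropped; no Cailliez
correction).  Axis signs are fixed so each axis's largest-magnitude
coordinate is positive.  PERMANOVA partitions squared distances
(SS_total = Σ_{i<j} d²ᵢⱼ/n; within-group analogues per group) and assesses
pseudo-F by free (unstratified) label permutation with the add-one
estimator p = (1 + #{F* ≥ F})/(1 + n_perm); 999 permutations by default.
An exhaustive mode enumerates all labelings for small n.  The combined-data
disease test is run unadjusted for study, alongside the study test, rather
than stratified — both quantities are reported separately.

### Differential abundance (`diffabund`)

A deliberately transparent stand-in for RNA-seq-style count testing, used
qualitatively (ranked lists, q < 0.05 sets): median-of-ratios size factors
over taxa positive in every sample; per-taxon method-of-moments NB
dispersion (variance = m + αm², floored at 1e-8); and a hybrid test — for
taxa whose scaled total is ≤ 1000, an exact conditional NB test on the two
group sums given their total (summing, over all splits, the probabilities
no larger than the observed split's; the Poisson limit of this conditional
law is binomial, used when α̂ < 1e-4), otherwise a Wald test of the
log-mean difference with delta-method variance against a t reference with
n₁+n₂−2 degrees of freedom, which guards the small-sample anticonservatism
of a plug-in dispersion.  log2 fold changes use a 0.5 pseudo-count.

One non-obvious step: group-balance recentering.  When planted (or real)
effects are one-directional, the median-of-ratios factors absorb a small
systematic shift that leaks into every null taxon (observed as a ~0.06
median log2FC across nulls, enough to triple false discoveries).  Under
the usual assumption that most taxa are not differential, the median
per-taxon log-ratio of group means is constrained to zero by scaling the
case samples down and control samples up by equal halves of the median —
the symmetric split makes the adjusted matrix identical under a label swap,
so log2FC negates and p-values are preserved exactly.  No dispersion
shrinkage toward a trend is applied: at the cohort sizes involved,
per-taxon moments are adequate and transparent.

Per-study result tables are intersected by counting, per taxon, the number
of studies where q < 0.05.

### Interkingdom correlations (`interkingdom`)

Spearman correlation is the Pearson correlation of midranks (average ranks
on ties); constant vectors are errors, and grid cells with fewer than 4
shared samples or a constant taxon are missing rather than zero.  Grids
are computed within one disease group at a time — the control and CRC
association structures are the objects of interest — then pooled per cell
across studies by Fisher-z random effects.  BH runs across tested
(non-missing, ≥2-study) cells only, and cells at q ≥ 0.05 are masked.

### Prediction harness (`predict`)

AUROC is the midrank (Mann–Whitney) construction: the probability a random
positive outranks a random negative, ties counted ½.  The classifier is a
contract (fit / predict_proba); the default is a random forest with 1000
trees, the field's standard for microbial abundance profiles — the harness,
not the forest, is the contribution.  Within-study evaluation uses
stratified 10-fold CV (stratification prevents single-class folds at
cohort sizes near 80) reshuffled over 20 repeats, reporting the mean of the
200 fold-level AUROCs rather than a pooled-prediction AUROC.  Cross-study
evaluation fits on one full study and scores another; LODO pools all
remaining studies.  Feature spaces are intersected across datasets (the
conservative choice; a union-with-zeros variant was considered and
rejected as it lets the classifier key on presence/absence of whole
feature blocks).  The harness is granularity-agnostic: genome-, species-,
genus- or family-level tables all work, and bacterial + viral tables can
be column-concatenated.

## Synthetic data model (`synth`)

Counts are negative binomial around a latent log-mean per taxon and sample:

    l_ts = center + (b_t + o_t − center)·exp(−ε_s)   evenness dial
           + [case]·lfc_t·ln 2                        planted DA taxa
           + σ_c·z_cs                                 copula factors

with base abundances b_t ~ Normal(2, 1.5) shared across studies (the
common biology cross-study classifiers exploit), per-study batch offsets
o_t ~ Normal(0, batch_shift_sd = 0.5), relative profiles softmax(l) scaled
to a per-sample depth (log-normal around `depth_mean`, log-sd 0.15), and
NB dispersion α (default 0.3; variance m + αm²).

**Diversity effect.**  Per-study true effects θᵢ ~ Normal(μ, τ²).  The
case group's evenness dial ε compresses the spread of latent log-means,
raising Shannon diversity.  Every sample additionally receives its own
dial jitter (sd 0.25, both groups): subjects differ in community evenness
far beyond sequencing noise, and without this the planted group shift
would be a deterministic coordinated displacement of every taxon that a
multivariate classifier detects essentially perfectly.  The dial value
realizing a count-level Shannon SMD of θᵢ is solved per study: a
deterministic root on expected profiles gives a first guess, then an
affine correction (two pilot simulations of 600 samples, at dial 0 and a
wide probe) maps the profile-level response onto the count level, which is
biased relative to profiles by finite depth and undetected rare taxa.
Calibration noise adds about ±0.09 to each realized θᵢ; a planted zero
effect with no DA taxa bypasses calibration entirely so the null is exact.

**Differential taxa.**  Case log-means shift by lfc·ln 2 for listed taxa.
**Correlations.**  A planted (viral family, bacterial species, ρ) triple
adds shared standard-normal factors, scaled by σ_c = 0.8, to all member
taxa of the family and to the species, with latent correlation
2 sin(πρ/6) (the Gaussian-copula value whose Spearman correlation is ρ);
group-specific ρ values are supported.  NB sampling and compositional
normalization attenuate the realized Spearman below ρ — tests therefore
compare against a direct Monte-Carlo oracle of the same latent model, not
against ρ itself.  Planted taxa have their base log-mean floored at 3.0 so
recovery tests measure the statistics rather than rare-taxon detection
limits.  Metadata: age ~ Normal(60, 10), BMI ~ Normal(25, 4), gender
Bernoulli(0.5), with an optional confounding switch that shifts case age
and BMI to exercise the adjusted linear model.

**Seeding.**  One global seed expands via `SeedSequence(seed).spawn` into
a global-parameter stream, an effect-draw stream, and one stream per study
in listed order; identical inputs reproduce identical outputs.

### What the generator does not emulate

Read-level sequencing artifacts, compositional zero-inflation beyond the
NB, phylogenetic correlation between taxa, subject covariate effects on
the microbiome, and — most consequentially — the diffuse, weak, partially
inconsistent disease signatures of real cohorts.  Planted signatures here
are clean: a fold change of 2 on a handful of well-observed taxa plus a
coordinated evenness shift is far easier to classify than real CRC virome
data, so absolute AUROCs from the synthetic pipeline saturate near 1.0 and
should not be read as performance estimates for real data.  What the
prediction tests do establish is the harness's comparative structure:
shared signal transfers across studies and LODO pooling beats pairwise
transfer, while study-specific (batch-only) signal yields high within-study
but chance-level cross-study AUROC.

## Validation scale and numerical choices

The test suite and the acceptance script run at desk scale, chosen as the
package's own validation sizes: meta-analysis recovery uses 500 replicates
of 50 studies × 100 per arm; differential-abundance calibration uses 50
null and 20 planted simulations of 500 taxa × 50 per arm; the correlation
recovery uses 20 seeds of 7 cohorts × 40 per arm; the end-to-end
acceptance pipeline uses 7 cohorts totalling 449 controls and 462 cases at
a depth of 5×10⁴ reads-equivalent per sample, with the prediction protocol
scaled to 100 trees and 2–3 repeats.  Degenerate inputs are errors, not
silent results: all-zero abundance vectors, zero library sizes, constant
vectors in correlation, single-class labels in AUROC, collinear design
matrices.  Bit-score and plurality ties have documented deterministic
resolutions.  Monte-Carlo p-values use the add-one estimator and are
bounded below by 1/(n_perm + 1).

## Known limitations

- The NB test is a stand-in, not a re-implementation of any published
  tool; p-values should be consumed via ranked lists and q-thresholds.
- DL confidence intervals are known to undercover slightly at moderate k
  (the recovery test brackets coverage at 0.92–0.98 rather than 0.95).
- TMM factors depend weakly on absolute counts through the precision
  weights; exact scale invariance holds only in the unweighted limit.
- Heip evenness for S = 1 and the log-diversity guard (1e-6) are
  conventions; both are documented at the definition site.
- The synthetic acceptance run validates internal consistency and recovery
  of planted structure; it does not reproduce any real cohort's numbers.
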