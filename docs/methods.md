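# Methods

## Problem and data model

A microsatellite (SSR) genotype is a set of allele calls, each an exact
pair *(locus, fragment length in bp)*.  Single strains carry 0–2 alleles
per locus (0 = failed amplification, 1 = haploid or homozygous,
2 = heterozygous diploid; counts above 2 are flagged but kept).  A mixed
sample yields a *meta-profile*: the union of all alleles its strains
contribute, with no per-locus bound.  Allele identity is exact integer
equality — fragment binning and stutter-band resolution belong to the
upstream peak-scoring step and are deliberately out of scope here.
Failed loci contribute zeros in the encoding, not missing-data codes:
the deconvolution model treats an unamplified locus as evidence of
absence, which is the conservative choice for calling strains and is
exposed rather than hidden (it inflates GLMerror when a query locus
drops out entirely).

All model fits operate on the *allele universe*: the union of distinct
alleles over the reference collection **and** the query, sorted by
(locus name, length).  Query-only alleles are kept as rows no strain can
explain; they surface in the error statistic instead of being silently
dropped.  The fixed ordering makes every encoding, and hence every fit,
bit-reproducible.

## The deconvolution model

Rows of the design matrix are universe alleles, columns are reference
strains (0/1 = strain carries allele), and the response is the query's
presence vector.  The model is a binomial GLM with lasso penalty,
no intercept, and coefficients constrained non-negative:

    min over β ≥ 0:  (1/n) Σᵢ [log(1 + exp(xᵢᵀβ)) − yᵢ xᵢᵀβ] + λ Σⱼ βⱼ

Non-negativity encodes additivity of pooling; with no intercept, an
allele carried by no called strain gets probability 0.5 rather than
being absorbed into a baseline.  Coefficient magnitudes are *selection
scores*, not strain abundances, and are never interpreted
quantitatively.

### Solver

Penalized IRLS with cyclic coordinate descent, written for this package
and compiled with numba:

* Outer loop: weighted quadratic approximation at the current β
  (weights w = μ(1−μ) floored at 1e-5; linear predictor clipped at ±30
  before the logistic transform).
* Inner loop: cyclic coordinate descent on the weighted least-squares
  problem; because β ≥ 0 the L1 penalty is linear on the feasible set,
  so each update is a soft-threshold followed by projection onto
  [0, ∞).  Full sweeps alternate with sweeps over the active set only.
* Convergence: the largest *curvature-weighted* squared coefficient
  change of a sweep, maxⱼ denⱼ·Δβⱼ², must fall below `tol`
  (default 1e-7).  This is the convention of coordinate-descent GLM
  solvers; a raw coefficient-change criterion never triggers on
  separable fits, where coefficients creep logarithmically along
  directions of vanishing curvature.
* The design columns are scaled presence/absence vectors, so each
  column holds one repeated nonzero value; the kernel stores per-column
  nonzero row lists, making sweep cost proportional to the number of
  allele calls rather than rows × strains.

The solver is validated against two independent routes: scipy's
L-BFGS-B on the same objective with box constraints (the objective is
smooth on the non-negative orthant), and R glmnet fitting the identical
model (`family="binomial"`, `alpha=1`, `intercept=FALSE`,
`lower.limits=0`); both agree to ≤ 1e-4 on the test instances.

### Regularization path and λ selection

The path runs from λ_max — the smallest penalty at which all
coefficients are zero; under non-negativity only coordinates with
xⱼᵀ(y − ½)/n > 0 can ever activate, so λ_max is that maximum — down to
`lambda_min_ratio` (1e-4) times λ_max, log-spaced over
`lambda_path_size` (100) values, warm-started.

λ is chosen by K-fold cross-validation (default K = 10) over universe
rows: an unstratified seeded partition; each fold's model is fit on the
remaining rows over the full-data λ sequence and scored on held-out
rows by the MSE of predicted presence probabilities (binomial deviance
available via `cv_metric="deviance"`).  Ties resolve to the largest
(sparsest) λ.  Folds whose training rows are single-class still
contribute; if every fold degenerates, λ falls back to the full-path
deviance minimiser with a warning.  Column scales are computed once
from the full design and shared across folds, so the λ sequence means
the same thing in every fold.

Choices worth making explicit: folds are not stratified on the response
or on locus (nothing suggests stratification here, and unstratified
folds keep the procedure simplest to reproduce); no unpenalized refit
is performed after selection — the called set, not the coefficients, is
the result.  Strains with coefficient > `coef_epsilon` (1e-8) are
called present.  Predictor standardization (scale to unit variance, no
centering — the model has no intercept and centering would destroy the
0/1 structure) defaults on; coefficients are reported on the original
scale.

### Error statistic

GLMerror = 100 · |predicted △ query| / |predicted|, where *predicted*
is the union of the called strains' profiles.  "Alleles differing" is
the symmetric difference, penalising both missed and spurious alleles;
it is zero iff the prediction reproduces the query exactly.  An empty
call set makes the ratio undefined; 100.0 is returned with a degeneracy
flag so that batch benchmarks stay total.

## Evaluation metrics

With parental truth known, per locus:

* **D_a = S_sa / S_p** — pooled strains identifiable by at least one
  *strain-specific* allele (carried by exactly one parental) that is
  actually present in the observed pool profile; an allele lost to
  dropout cannot identify its carrier.  The alternative reading
  (specific-by-parentals regardless of observation) was considered and
  rejected as inconsistent with dropout accounting.
* **E_a = 100 · mean over pools of (|observed △ expected| / |expected|)**,
  both restricted to the locus; pools with no expected allele at the
  locus are excluded with a warning.

Per pool: TPR = 100·|called ∩ parental|/|parental| and the count of
false positives (called but not parental).

## Typing support

Strains are compared by the Cavalli-Sforza & Edwards chord distance.
A single strain has no observed allele frequencies, so per strain and
locus the frequencies are taken **uniform over the scored alleles**
(1.0, or 0.5/0.5) — this convention fixes the distance scale and is the
package's own choice, stated prominently.  Per locus

    d_l = (2/π) · sqrt(2 · (1 − Σₐ sqrt(f_p(a) · f_q(a))))

and the distance is the *mean* of d_l over loci typed in both strains
(loci failing in either strain are dropped pairwise, not imputed;
summing instead of averaging would only rescale, not reorder).  The
distance is bounded by (2/π)·√2 ≈ 0.9003.

Trees: neighbor joining on the chord-distance matrix (scikit-bio's
implementation; tie-breaking follows that library), negative branch
estimates clamped to zero with a warning, midpoint rooting (with an
explicit construction for 2-leaf trees, where the generic rooting
degenerates), Newick output at 6-decimal branch precision.

## Reference pruning

A collection can contain strains the model cannot tell apart — exact
duplicates, and haploid strains nested in a diploid relative's allele
set.  Pruning queries each strain's own profile against the current
collection and acts whenever the call set is not exactly the strain
itself:

* more than one strain called → keep one representative (the query
  strain if called, else the called strain with the largest
  coefficient, ties by input order), remove the others;
* a single *different* strain called with GLMerror 0 → an exact
  genotype equivalent; the called strain represents the query strain,
  which is removed.  (With coordinate descent, identical columns
  resolve to a single-strain call of whichever twin is swept first, so
  duplicates surface through this branch rather than as a >1 call.)
* a single different strain called with GLMerror > 0 → ambiguous but
  informative; both are kept.

Passes repeat until a full pass removes nothing (with a 100-round
guard).  Queries run against the shrinking collection as removals are
applied; the postcondition — every kept strain self-identifies uniquely
and exactly — is what the tests assert.  Haploid-subset strains are
*not* force-collapsed when the model distinguishes them cleanly: the
procedure is model-driven, and with this solver a haploid and its
diploid superset usually each self-identify.

## Synthetic data generator

The generator emulates the statistical structure of a real typing
collection, not any particular dataset:

* **Allele ladders**: per locus, `alleles_per_locus` (8) lengths spaced
  by `repeat_unit` (3 bp, a trinucleotide motif) from `base_length`
  (100 bp).  Real per-locus allele richness is unpublished; 8 is a
  plausible round number, exposed in the config.
* **Strains**: per locus, heterozygous with `het_prob` (0.5, two
  distinct ladder alleles) else one allele.
* **Clonal structure**: `n_clusters` founders with members derived by a
  stepwise mutation model (probability `within_cluster_mut_prob` per
  locus of stepping one repeat unit, bouncing off ladder edges).  The
  default config is unstructured (`n_clusters=0`);
  `SimulationConfig.clonal()` (one founder per ~2.8 strains, 5%
  step probability) is the preset that emulates a real collection's
  clonal expansions — it produces both exact re-isolates and surviving
  near-identical pairs, which are what make deconvolution hard.
* **Pools**: k strains sampled without replacement; expected = observed
  = union of parental alleles, noise applied separately.
* **Amplification noise**: each observed allele drops independently
  with its locus's dropout probability (`noisy_locus_presets` carries
  rates of the magnitude shown by the panel's weakest loci, C6 ≈ 0.09
  and C8 ≈ 0.046); stutter optionally adds an allele one repeat unit
  below a surviving true allele.  The expected (truth) profile is never
  corrupted.  With 10% dropout the realized E_a calibrates to 10%
  within binomial sampling error, by construction.
* **Seeding**: per-pool seeds derive from the master seed via a
  counter (`SeedSequence(master, spawn_key=(counter,))`), so any single
  pool of a grid is re-generable in isolation.

Not modelled: PCR kinetics, peak heights and competition between
templates (dropout in real pools is abundance-dependent, not i.i.d.),
allele-size calibration drift, and genuine population-genetic history
(the stepwise clonal model is a caricature that reproduces
near-identical pairs without a coalescent).  Passing benchmarks on this
generator therefore show that the *procedure* behaves as designed under
its stated error model — they do not certify performance on any real
collection, whose difficulty depends on its actual clonal structure and
amplification biases.

## Benchmark design and problem sizes

The recovery/false-positive benchmark mirrors the in-silico evaluation
design: pools of k = 2…6 strains, deconvolved against the full
collection, aggregated per k and locus set ("all.loci" = the 12-locus
panel; "sel.loci" = the 10 loci left after dropping the dropout-prone
C6 and C8).  The reference for benchmarking is generated with the
clonal preset and then pruned — the same pipeline a real collection
goes through — because an unstructured synthetic collection at these
allele richnesses is too easy: recovery saturates at 100% for every k
and no trend is visible.  On the pruned clonal reference the
characteristic behaviour appears: all-parental recovery declines
strictly with k, the fraction of pools with at least one false positive
rises strictly with k, and the 12-locus panel dominates the 10-locus
panel on mean recovery.

Default problem sizes — 50-strain collections (38 after pruning at the
fixed seed), 200 pools per k, 100-strain collections for the
self-identification audit, 100 instances for the exhaustive-search
comparison (≤ 8 strains, 5 loci, so the 255-subset enumeration is
exact), 1000 pools for the dropout calibration — were chosen so the
full suite and the acceptance script each complete in minutes on one
CPU while keeping binomial standard errors on the reported fractions
around or below 3 percentage points.

## Numerical and degenerate-input policy

* All-zero response (query shares no allele with the universe — cannot
  happen through `deconvolve`, which builds the universe over the
  query too): zero coefficients and a warning.
* Empty call set: GLMerror 100 with a degeneracy flag.
* Chord distance between strains with no shared typed locus: an error,
  not a guess.
* NJ on < 3 taxa: an error; 2-leaf midpoint rooting: explicit
  construction.
* All-zero branch lengths: arbitrary rooting with a warning.
* `n_folds` larger than the universe: an error instructing the caller.
* Pool with zero expected alleles at a locus: excluded from E_a with a
  warning.

## Known limitations

* Coefficients are not abundances; low-abundance strains are called or
  missed, never quantified.
* The model cannot distinguish strain sets whose allele unions
  coincide; pruning guarantees unique *self*-identification, not
  unique decomposition of every possible pool.
* CV over allele rows violates independence mildly (alleles of one
  locus are correlated through ploidy); the effect on λ selection is
  small but unquantified.
* The i.i.d. dropout model understates the structured, abundance-
  dependent allele loss of real pooled amplifications.
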