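# Methods

This note documents the models, parameters and design choices behind
`prosocontrast`, in the spirit of a statistical software vignette.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The measurement model: accentual-phrase boundary detection

The unit of analysis is one elicited noun token, described by four
scalars: the duration of its first and last full syllables (S1, S2, in
seconds) and the f0 at two hand-placeable landmarks, the "early L"
minimum and the H maximum associated with S2 (in Hz).  The right edge of
a French Accentual Phrase is cued on the phrase-final full syllable by a
rising pitch accent and by pre-boundary lengthening, so the classifier
labels a token `TWO_AP` (noun phrased separately from its adjective)
exactly when **both** criteria hold:

* pitch accent: `f0_h >= (1 + θ_p) · f0_l`,
* lengthening: `dur_s2 >= (1 + θ_d) · dur_s1`,

with both thresholds θ defaulting to 0.10 ("at least 10%") and exposed
as parameters for sensitivity analyses.  Decisions taken here:

* **Conjunction, not disjunction.**  The two cues are treated as jointly
  necessary for an AP right boundary.  A disjunctive rule would label a
  lengthened but unaccented syllable as a boundary, which contradicts
  the definition of the AP-final rise.
* **Inclusive thresholds.**  A ratio of exactly 1.10 counts as
  criterion-met.  The comparison carries a 1e-12 relative slack so that
  an exact 10% excess is not lost to the float rounding of
  `1.1 × value`; the slack is ~7 orders of magnitude below any plausible
  acoustic measurement precision.
* **Raw Hz and raw seconds.**  Ratios are computed on linear scales (no
  semitone conversion); the two criteria are scale-invariant by
  construction, which the property tests verify.
* **Missing or non-positive values are rejected, never classified.**
  An unvoiced stretch yields no f0 landmark; such tokens must be flagged
  upstream, not silently scored.

Tokens flagged as disfluent or as labeling errors are removed before
classification, and the filter report accounts for every input token
(the retained percentage is exact, not rounded).

## Scoring

A participant's prosodic phrasing score is

`score = 20 · (matches) / (tokens)`,

where a match is `ONE_AP` under the given condition or `TWO_AP` under
the contrastive condition, pooled over both conditions.  Pooling (rather
than averaging two per-condition proportions) follows the worked
arithmetic of the score's source: 3/9 + 6/9 → 9/18 → 10/20.  With equal
condition counts the two definitions coincide; with unequal counts
pooling weights each token equally.  The score is kept at full float
precision — the 0–20 scale exists only for comparability with the
20-point hinting (theory-of-mind) task.  A participant with zero
analyzable tokens has an *undefined* score and is omitted with a log
message; an absent score is not a zero.

## The mixed-effects logistic regression

The phrasing outcome is modelled as

`y_ij ~ Bernoulli(logit⁻¹(x_ij'β + u_p(ij) + v_i(ij)))`,
`u_p ~ N(0, σ²_p)`, `v_i ~ N(0, σ²_i)`,

with treatment-coded fixed effects for discourse status (reference:
given), group (reference: HC) and their interaction, and crossed random
intercepts for participant and item.  **Outcome coding is TWO_AP = 1**,
so a positive discourse-status coefficient means more separate-AP
phrasings for contrastive nouns; the coding is configurable at the data
frame level (the outcome column is plain 0/1).

Estimation is maximum likelihood under the Laplace approximation,
implemented in `prosocontrast.glmm`:

* inner problem — the joint posterior mode of the random effects by
  penalised Newton iteration with step halving (gradient tolerance
  1e-10, ≤ 60 iterations), with the mode warm-started across outer
  iterations;
* outer problem — L-BFGS-B over (β, log σ²) with finite-difference
  gradients (relative tolerance ~1e-10, 200 iterations by default);
  variances are optimised on the log scale and bounded in
  [1e-8, 100], so a degenerate component surfaces as ~0 rather than an
  error;
* standard errors — from the finite-difference Hessian of the Laplace
  deviance at the optimum (central differences, step 1e-4 relative);
  Wald z and two-sided normal p-values per fixed effect;
* AIC = −2ℓ + 2k with k = (fixed effects) + (variance components).

statsmodels offers no crossed-random-effects logistic GLMM with an ML
log-likelihood, which is why this component is implemented in-package.
The test suite cross-checks one fit against `lme4::glmer` (run via
Rscript): estimates and standard errors agree to ±0.02, variance
components to ±0.05 and AIC to 0.1 on a 400-observation dataset.
Non-convergence is reported through `ModelFit.converged` plus the
optimizer message, never masked.  A constant outcome raises a separation
error before any optimisation.  Single-group data automatically drop the
group and interaction terms (used for the separate per-group fits).

## Linear mixed models on log acoustics

To check that the classifier's two cues behave like graded acoustic
variables, S2 duration and H f0 are modelled on the natural-log scale
with the same fixed/random structure, via statsmodels `MixedLM`
(crossed intercepts through variance components on a single spanning
group; ML, not REML, so AICs are comparable across fixed-effect
specifications).  If L-BFGS stalls at a variance boundary the fit is
retried with Powell's method before the non-convergence flag is set.

p-values for LMM t statistics are approximate by nature.  The package
offers `normal` (Wald, default) and `containment` (t distribution with
df = n − rank(X) − number of random levels, a conservative containment
heuristic).  Sampling-based p-values (MCMC or parametric bootstrap) are
deliberately out of scope; with 323-observation designs the normal and
containment p-values differ only in the third decimal.

## Two-sample tests, correlation, AIC

* Group comparisons are pooled-variance unpaired t-tests
  (df = n₁ + n₂ − 2), computable from raw vectors or from printed
  summaries (mean, SD, n per group); the two routes agree to float
  precision and the raw route is a thin wrapper over the summary route.
  A Welch option exists but is not the default, matching the df = 18
  convention for 10 + 10 designs.
* Spearman correlation uses average ranks for ties and the t
  approximation with df = n − 2 (scipy).  `method="permutation"`
  enumerates all n! permutations exactly for n ≤ 8 and uses a seeded
  100 000-draw Monte Carlo permutation test above that — exact
  enumeration at n = 10 costs 3.6 M permutations for no inferential
  gain at the package's precision.
* AIC comparison requires both fits to be converged and on the same
  number of observations; ties prefer the first argument by convention
  and the signed difference is antisymmetric under swapping.

## The synthetic-data generator

The generator is the analysis model read forwards, plus an acoustic
realisation layer.  Defaults define the package's reference study
conditions and are not tuned per run:

| Parameter | Default | Meaning |
| --- | --- | --- |
| `n_participants_per_group` | 10 | per-group directors (HC, SZ) |
| `n_items` | 20 | critical landmark pairs, condition fixed per item, 10/10 balanced |
| `true_coefficients` | (−1.2384, 2.5982, 0.5948, −2.0395) | intercept, contrastive, SZ, interaction on the log-odds of TWO_AP |
| `var_participant`, `var_item` | 0.79490, 0.35673 | crossed random-intercept variances |
| `base_dur_s1` | 0.14 s | median S1 duration (lognormal, σ = 0.15) |
| `base_f0_l` | 120 Hz | median early-L f0 (lognormal, σ = 0.08) |
| `ratio_ranges` | TWO_AP: U[1.12, 1.40] (dur), U[1.12, 1.45] (f0); ONE_AP: U[0.90, 1.08] (both) | S2/S1 and H/L ratios per latent label |
| `criterion_noise` | 0.0 | probability of realising acoustics inconsistent with the latent label |
| `dropout_prob` | 0.1925 | disfluency/labeling-error flag rate (≈ 80.75% retention) |
| `hinting_link` | HC 17.9, SZ 14.9, sd 1.8, weight 15 | hinting score ≈ N(group mean + weight·(match proportion − group mean proportion), sd), rounded, clamped to [0, 20] |

The fixed and random coefficients are the published crossed-intercept
fit for the original 10 + 10 case-control study; the acoustic bases and
lognormal spreads are chosen once as typical adult French values whose
log-scale magnitudes are consistent with the published log-duration and
log-f0 intercepts.  The TWO_AP/ONE_AP ratio ranges straddle the 1.10
threshold by construction — a config invariant enforces that the TWO_AP
ranges start at or above 1.10 and the ONE_AP ranges end strictly below
it, so with `criterion_noise = 0` the classifier reconstructs every
latent label exactly (tested).  Narrower, boundary-crossing ranges can
be configured to stress the classifier.

All draws come from one seeded `numpy` Generator; the same seed yields
a byte-identical dataset.  A separate metadata-only fixture draws
hinting scores, total task time and speaking-turn counts from group
normals (defaults: the study's printed group summaries) for exercising
the t-test stage alone.

**What the generator does not emulate** — and hence what passing tests
do not show about real recordings: within-participant drift and
speaking-rate trends, f0 declination and octave errors, correlation
between duration and f0 realisations beyond the shared label,
item-specific segmental effects on duration, missing-at-random
annotation gaps (dropout is i.i.d.), and any dialogue dynamics.
Parameter-recovery results therefore validate the estimation machinery,
not the field validity of the acoustic criteria.

## Praat ingestion

TextGrid and PitchTier files are parsed in both of Praat's text
serialisations (verbose "long" and terse "short"), in UTF-8 or UTF-16.
The token convention is an interval tier (default name `syllables`)
where each noun contributes an adjacent S1/S2 interval pair, and a point
tier (`tones`) with exactly one L and one H point inside each token's
span (S1 onset to S2 offset).  f0 at a point time is linearly
interpolated between the bracketing PitchTier samples, which is Praat's
own PitchTier semantics.  An H point beyond the S2 offset, a stray L/H
point outside every token span, an S1 without a following S2, or a
point time outside the PitchTier's sampled range each raise a specific
error — ambiguous files are rejected, not repaired.

## Pipeline and reproducibility

`run_pipeline` executes ingest → filter → classify → score → fit,
writing every intermediate table; any stage error is re-raised with the
stage name and partial outputs are kept.  Group t-tests or correlations
whose inputs are insufficient (missing metadata, fewer than three scored
participants, constant scores) are recorded as skipped with a reason
rather than failing the run, since participant metadata is optional by
contract.  The JSON report embeds the fully resolved configuration and
package version; it deliberately contains **no wall-clock timestamps**,
so identical configuration + seed produces byte-identical reports — a
tested invariant.

## Problem sizes in the default suite

The simulation-based checks use 20 replicates at 40 participants/group
× 20 items for parameter recovery, 20 replicates at the study's own
10/group size for the per-group significance pattern, and 50 replicates
for the null-calibration checks; these sizes give stable pass/fail
behaviour at seeded randomness while keeping the default test run fast.

## Known limitations

* The mixed logit uses the Laplace approximation; with very small
  cluster counts (< ~5 items) adaptive quadrature would be more
  accurate.  Random slopes are not implemented — the retained models in
  the motivating analysis are intercept-only — though the model frame
  accepts any 0/1 outcome column for reanalysis.
* LMM p-values are approximations (see above); confidence intervals for
  variance components are not reported.
* The scorer presumes the 1AP-given / 2AP-contrastive expectation of
  French; other languages' phrasing conventions would need a different
  expectation map.
* The importer requires exactly one L and one H per token span and does
  not attempt to resolve competing points.
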