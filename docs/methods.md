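# Methods

This note documents the statistical model behind `befpartition`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The partition

For a mixture community of `Q` species, species `i` contributes
monoculture biomass `M_i` and mixture biomass `Y_i` (dry mass per unit
area; g/m² by convention, but every statistic is unit-covariant). With a
proportional-sowing null expectation of `M_i/Q` for mixture yield, the
deviation in relative yield is

    dRY_i = Y_i / M_i - 1/Q,

and the net biodiversity effect decomposes additively:

    dY = sum_i (Y_i - M_i/Q)
       = N * mean(dRY) * mean(M)   +   N * cov(dRY, M)
       =            CE            +            SE

The identity follows from `E[XZ] = E[X]E[Z] + cov(X, Z)` and is exact for
any community — **provided the covariance uses the count denominator N**.
The package therefore exposes two named conventions rather than silently
choosing one:

* `partition` — denominator `N`; `CE + SE = dY` holds to float precision.
* `estimator` — denominator `N − 1` (Bessel); this is the form the
  incomplete-sampling corrections require, and equals the partition form
  times `N/(N−1)` exactly.

Every result object records which convention produced it.

An optional per-species expected-relative-yield vector is *not* shipped:
the proportional null `M_i/Q` is fixed. The derivations hold for other
null expectations, so the hook is a possible extension, but no alternative
null model is provided.

### Species with M = 0 or missing M

`dRY` is undefined at `M = 0`. Records with a *measured* zero monoculture
are kept in the pool count `Q` but excluded from the participating `N`
(they are held on the sample object for bookkeeping). Species never grown
in monoculture at all ("pool-only") likewise count toward `Q` only.
Species with `M > 0` but `Y = 0` — present in the pool, absent from the
harvested mixture — are fully included with `dRY = −1/Q`. The error path
(`M = 0` with `Y > 0` submitted as a participating record) names the
offending species.

### OLS form

Regressing `dRY` on `M` by ordinary least squares (point-slope form,
slope `b1 = cov/var`, intercept `b0`) gives the algebraically identical
reformulation

    CE = N * mean(M) * (b0 + b1 * mean(M)),     SE = N * b1 * Var(M),

with `Var` under the same denominator convention as the chosen covariance.
`partition_via_ols` fits the regression with `statsmodels.OLS`, which
keeps it an independent computational route from the moment form — the
equivalence is asserted in tests at 1e−9 relative tolerance. Constant `M`
is rejected there (undefined slope) with a pointer to `partition()`,
where `SE` is exactly zero in that case.

## Estimating population effects from an incomplete sample

Superscript `P` marks population-level statistics (all `Q` species), `S`
sample-level ones (`N` species drawn from the pool). Two properties make
the corrections work, both under simple random sampling without
replacement (SRSWOR):

1. the Bessel sample covariance is unbiased for the Bessel-form
   population covariance `S_xz` (denominator `Q − 1`), and
2. the covariance of the two sample means is `((Q−N)/Q) · S_xz / N`.

Hence, with `SE^S` always Bessel-corrected:

    SE^P/Q  ~=  SE^S/N                                   (unbiased as-is)
    CE^P/Q  ~=  (CE^S - SE^S/N) / N                      (large-Q form)
    CE^P/Q  ~=  (CE^S - ((Q-N)/Q) * SE^S/N) / N          (finite-Q form)

The finite-Q form is the default: it is *exactly* unbiased for any `Q`
(verified by exhaustive enumeration over all `C(Q, N)` subsets in the
acceptance suite) and collapses to the sample statistic at `N = Q`. The
large-Q form undershoots the population CE by exactly `S_xz`,
independent of `N` — also asserted exactly by enumeration.

Two bookkeeping rules are easy to get wrong and are enforced throughout:

* the `1/Q` inside `dRY` always uses the **pool** size, even when only
  `N` species are observed — this is what keeps subsample statistics
  commensurate with the full community's; and
* `Q` must be supplied by the caller (sown richness or a survey-derived
  pool size). It is never inferred from the table's row count, because
  rows cover only sampled species; the `"infer_with_warning"` sentinel
  exists for fully observed tables and warns.

The expected value of the corrected SE is `Q · S_xz`, i.e. `Q/(Q−1)`
times the count-denominator population SE. Which of the two the "true"
population SE should be is a convention question the data cannot settle;
both are computed and labelled (`BiasCurve.se_pop` vs
`.se_pop_bessel`), and the bias experiments measure the corrected SE
against its own expectation `Q · S_xz`.

The corrections apply to **randomly** chosen subsets only. Corrections
for biased subsampling (e.g. monocultures kept only for species that grow
well) are out of scope.

## Subsampling experiments

`subsampling_experiment` treats a fully observed community as a finite
population and, per subset size `N`, evaluates four estimator variants per
draw:

| variant | per-draw value | reported bias against | scale |
|---|---|---|---|
| `ce_uncorrected` | `CE^S/N` | `CE^P/Q` | per-species |
| `se_uncorrected` | `SE^S/N` | `S_xz` | per-species |
| `ce_corrected` | finite-Q `CE` estimate | `CE^P` | population |
| `se_corrected` | `Q·SE^S/N` | `Q·S_xz` | population |

The uncorrected variants live on the per-species (`/Q`) scale because
that is where the analytic bias prediction

    E[CE^S/N - CE^P/Q] = ((Q-N)/Q) * S_xz / N

is defined (`predicted_bias`); the corrected variants are on the
population scale. The tidy output table records, per `(N, variant,
n_het)`: mean bias, SD, Monte-Carlo standard error, the analytic
prediction, draw count, and whether enumeration was exhaustive.

Numerical/design choices:

* **Draws** are uniform species combinations — without replacement within
  a draw, independent across draws, duplicates across draws allowed.
  Reference scale is 20,000 draws per `N`; tests and the acceptance suite
  run 2,000 (stated where it happens).
* **Exhaustive mode** auto-activates when `C(Q, N)` is at most the
  design's threshold (default 10⁵), making unbiasedness checks exact
  rather than stochastic. Exhaustive enumeration is also the oracle the
  Monte-Carlo path is converged against in tests.
* **Heterogeneous replication** (`n` independent random species draws,
  as opposed to `m` repeated measurements of one community): the draw
  sequence is cut into consecutive disjoint blocks of `n` and the SD of
  block means is reported. Exhaustively enumerated results are shuffled
  (seeded) before blocking, since enumeration order is not exchangeable.
* **RNG**: one `SeedSequence` per experiment, with one spawned substream
  per grid entry, so results for one `N` do not depend on the rest of
  the grid.
* **Degenerate cases**: SD is reported as 0 whenever all draw values are
  identical (in particular at `N = Q`), and as missing when there are
  fewer than two blocks of genuinely varying values.

## Sampling-error intervals

For an empirical sample (`N` observed of `Q`), the SD of the corrected
estimates attributable to incomplete sampling is approximated by
sub-subsampling: draw `n' < N` species from the observed `N` (default
`n' = max(2, N//2)`), apply the finite-Q correction to each draw, and
rescale the dispersion by the square root of the ratio of SRSWOR
design factors `g(n, pool) = (pool − n)/(pool·n)`:

    SD_hat(N from Q) = SD_observed(n' from N) * sqrt(g(N,Q) / g(n',N)).

`g` is exact for the variance of a sample mean under SRSWOR; the corrected
estimators are smooth functions of two sample means and a sample
covariance, for which it is a first-order approximation. The sub-sample
size is therefore an exposed parameter, and the procedure is documented
as an approximation rather than asserted to match any specific reference
recipe. At `N = Q` the interval is exactly zero.

## Synthetic communities

No external dataset ships with the package; `generate_community` builds
fully observed communities with controllable true effects:

* `M_i ~ lognormal(m_log_mean, m_log_sd)` — strictly positive with
  realistic right skew. Defaults `5.0 / 0.5` put the median near
  150 g/m² with ~1.7-fold multiplicative spread, in the range of
  temperate grassland monocultures.
* `dRY_i = a + b·(M_i − mean(M)) + eps_i`, `eps ~ N(0, resid_sd)`.
  Centring the slope on `mean(M)` decouples the knobs: noiseless, the
  community has `SE = Q·b·Var(M)` and `CE = Q·a·mean(M)` exactly.
  Defaults `a = 0.05`, `b = 0.002`, `resid_sd = 0.1` give, at `Q = 100`,
  a strong selection effect (comparable to or exceeding CE).
* `Y_i = M_i·(dRY_i + 1/Q)`, truncated at 0. Truncation (roughly a third
  of species at the `Q = 100` defaults) emulates poor performers driven
  to zero mixture biomass — a real feature of diverse mixtures — and is
  counted and surfaced. Truncation was chosen over resampling because
  resampling would silently distort the `M`–`dRY` law. The "true"
  CE/SE/dY attached to a generated community are always **recomputed from
  the post-truncation data**, so every unbiasedness property is exact
  regardless of truncation.

What the generator does **not** emulate: any particular species list or
biomass distribution from a real experiment, spatial structure,
year-to-year variation, or non-random subsample selection. A green test
against synthetic data establishes the statistical properties of the
estimators under SRSWOR; it says nothing about whether a particular field
sample of species was random.

## Observation error

Measurement noise is multiplicative, mean-one lognormal per biomass value
(`sigma² = ln(1 + cv²)`, `mu = −sigma²/2`): biomass is positive and
replicate spread scales with the mean, whereas additive noise could go
negative. The exact distribution family of real harvest error is not
identifiable from the data the method consumes, so the lognormal law is a
documented stand-in; its single knob `cv` is calibrated from replicate
harvests by `calibrate_cv` (per-species SD/mean, pooled by root mean
square over species). `m_reps` homogeneous replicates are averaged per
species, suppressing the noise SD by `1/sqrt(m_reps)`; `cv = 0` is
bit-exact identity by construction.

The replication study (`observation_error_experiment`) defaults to
subsampling at `N = Q`, which isolates the observation-error component:
at small `N` the sampling error can mask the effect of `m_reps`. Its
qualitative robustness claim — that for `N > Q/2` corrected-estimate
spread under noise is within a small factor of the fully observed noisy
community's — is reproducible as a simulation report, not asserted as a
hard threshold.

## Tolerances and limitations

* Algebraic identities (additivity, OLS equivalence, exhaustive
  unbiasedness): 1e−9 relative, with an absolute fallback near zero.
* Monte-Carlo checks: 4 MC standard errors for means; monotonicity over a
  grid is tested by rank correlation, not pairwise, to allow sampling
  noise.
* The estimators can return negative CE or SE estimates from a single
  draw even when the truth is positive; only their distribution over
  random draws is guaranteed.
* Sampling-error intervals are design-factor approximations (above), not
  exact variances; doubling the resample count should move them by less
  than their own Monte-Carlo error, which is tested.
* `N ≥ 2` is required everywhere a covariance appears; `N ≥ 3` for
  sampling-error intervals (the sub-subsample needs room).
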