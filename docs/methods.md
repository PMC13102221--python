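# Methods

## Thermal time

Daily development is the area of a single sine cycle through (tmin, tmax)
between the developmental thresholds, normalized per day:

    DD = (1/2π) ∫ max(0, min(T(θ), U) − L) dθ,   T(θ) = m + A·sin θ,

with m the daily mean and A the half-range. The defaults are L = 8.1 °C and
U = 32.2 °C; the upper threshold uses a horizontal cutoff (temperatures
above U count as U). The closed form is evaluated through the identity
max(0, min(T,U)−L) = max(0,T−L) − max(0,T−U), so one two-case helper covers
all six configurations of tmin/tmax relative to the thresholds; tests
compare it against direct numerical integration of the clipped sine at
10⁵ steps to 10⁻⁶ DD. The cutoff variant is stored on the threshold object
because earlier rules used other conventions; legacy "no upper threshold"
comparisons set U = +∞, which reduces exactly to the classic two-case
single sine.

Accumulation starts January 1 (biofix). Missing days are a hard error — a
gap error naming the first missing date — never imputed, because silent
imputation biases cumulative degree-days in whichever direction the
imputation errs. CDD→date inversion returns the first calendar day whose
end-of-day cumulative reaches the target, with no within-day interpolation:
both the temperature inputs and the trap reads are daily, so sub-day
precision would be spurious. Julian day is day of year with January 1 = 1;
leap years follow the calendar.

## The occurrence curve

The first component is a log-logistic in x with negative exponent γ₁
(its value at x = 0 is defined as the analytic limit, 0, so curves can be
drawn from the origin); components 2–4 are logistics centred at
μₖ = β₁ + ΣΔβ. Exponents are clamped at ±700 before exponentiation, which
prevents overflow while leaving every result unchanged to machine
precision.

Two readings of the logistic steepness are implemented. The printed
γ₂..γ₄ ≈ 0.06 produce transitions of ~0.2 DD when read as scale parameters
(z = (x−μ)/γ) — a near step function, inconsistent with the smooth fitted
seasonal curve — but transitions of ~70 DD when read as rate constants
(z = γ·(x−μ)). The rate reading is therefore the default; the scale mode
is retained behind a flag, and every quantity derived from medians or
shares (peak CDDs, peak dates, catch shares) is identical under either.
Likewise the first term is applied literally as (x/β₁)^γ₁ with the
published γ₁.

## Fitting

Site-year series are standardized (cumulative catch over site-year total;
dates to CDD) and pooled with equal point weight into one global fit —
one curve for all sites, no site-level random effects. Leading zero reads
are retained; they pin the left tail at zero. The objective is ordinary
least squares on the cumulative proportions over the 11 free parameters
(α₁..₃ with α₄ completed from the unit sum; β₁; Δβ₁..₃; γ₁..₄).

Constraints are enforced by reparameterization rather than by an inequality
solver: a multinomial-logit transform keeps (α₁..α₄) strictly inside the
simplex, and log transforms keep β₁, the Δβ and ±γ in their half-lines. The
transformed problem is smooth and unconstrained and is minimized with a
trust-region least-squares routine (SSE-change tolerance 10⁻¹⁰, iteration
budget equivalent to ~2,000 iterations; both configurable). Standard errors
are asymptotic: the diagonal of (JᵀJ)⁻¹·MSE with J the central-difference
Jacobian with respect to the original free parameters at the optimum.
r² = 1 − SSE/SStot and F = (SSmodel/11)/(SSE/df_error) use the corrected
(mean-centred) total sum of squares with df_error = n − 12; r² is clamped
at zero from below. Non-convergence and zero-signal inputs (constant
proportions) are flagged on the result object, not raised; mixing
proportions driven below 10⁻⁶ are reported as boundary-pinned.

Automatic initialization aggregates the pooled points into an equal-count
binned, monotonized empirical curve, then alternates two steps three times:
peak medians read off the curve at the mid-mass level of each component's
current share, and shares recomputed from the mass between adjacent median
midpoints. Steepness starts at field-typical values (γ₁ = −8, γ = 0.06 in
rate mode, 17 in scale mode). When the four medians crowd into under a
quarter of the observed thermal-time range, or any spacing collapses below
2% of it, the data do not support four peaks and a degenerate-data warning
is emitted (spacings floored to keep the parameter set valid).

## Validation

A peak is a maximal non-decreasing run of counts followed by a maximal
non-increasing run; it ends at the local minimum terminating the decrease.
Ties continue the current phase — with 15-day sampling, demanding strict
monotonicity would split peaks on every repeated count. Leading and
trailing zero reads are trimmed. More than four candidates are merged
smallest-total-first into the larger neighbour (totals are preserved;
segment totals always partition the trimmed series); fewer than four set a
shortfall flag, and shortfall series are excluded from summaries by
default.

The observed 50%-occurrence point of a peak uses the within-peak (not
season-wide) cumulative proportion, interpolated linearly between the two
observations bracketing the 0.5 level, on the Julian-day axis for
day-deviation summaries or the CDD axis otherwise. Two conventions cover
the edges: if the first observation already exceeds half the peak's catch
the first observation's value is returned with an edge flag; if the
cumulative proportion lands on 0.5 exactly at an observation that is not
the last, the crossing is ambiguous anywhere up to the next observation
and the midpoint of that span is returned as the tie-break.

Model deviations (|predicted − observed| days, pooled over peaks and
site-years) are compared across models by one-way ANOVA with Tukey HSD
letters at α = 0.05. The sum-of-squares decomposition is computed directly
so that identical groups yield F = 0 rather than 0/0; letters follow the
standard convention — groups sharing a letter are connected through
mutually non-significant pairs (maximal cliques of the non-significant
graph, lettered in order of group means).

## Projection

Scenario projection reuses the prediction path unchanged: accumulate CDD
under the scenario's daily temperatures with the 8.1/32.2 °C thresholds and
invert the four fitted peak CDDs to dates. Because degree-days are monotone
in temperature, a pointwise-warmer year can never delay a peak; and because
of the horizontal cutoff, added heat above 32.2 °C contributes nothing, so
peaks sitting in the hottest part of the season shift less than shoulder-
season peaks. No ordering of shifts across peaks is imposed by the code —
any asymmetry is an emergent property of the temperature trajectory.
Multi-year scenario periods are handled by projecting each year and
averaging the projected days (simple arithmetic mean across sites and
years), never by averaging temperatures first, which would smear the
nonlinearity of threshold crossing. Gridded climate rasters, spatial
interpolation and map rendering are out of scope; scenarios enter as
per-site daily series, and the synthetic generator's uniform warming
offset stands in for them in tests.

## Synthetic data

The climate generator draws daily means from an annual sine plus Gaussian
day-to-day noise and splits them into tmin/tmax by a fixed diurnal range
(the same noise draw perturbs both, so tmin ≤ tmax by construction).
Defaults — annual mean 12 °C, seasonal amplitude 13 °C, warmest day around
day 208, diurnal range 9 °C, noise SD 1.5 °C — describe a temperate
apple-growing climatology and accumulate ≈2,300 DD (8.1/32.2 °C) per year,
inside the 1,900–2,400 DD band that places the fourth flight peak in late
summer.

Trap counts are tied to thermal time, not the calendar: the expected catch
of each read is the occurrence curve's increment over the preceding
interval (the window opens one interval before the first read, March 1 by
default, and closes October 31), renormalized over the window and drawn
multinomially so a season's counts sum exactly to the site total. Positive
overdispersion switches to a Dirichlet-multinomial (interval probabilities
drawn from Dirichlet(pᵢ/ρ)), the one-parameter way to mimic the
overdispersion of field trap counts. Multi-site studies jitter each site's
annual mean (SD 1 °C) and amplitude (SD 0.5 °C), with per-site streams
spawned deterministically from the master seed.

What the generator does not emulate: spatially correlated weather between
sites, lure aging and trap-efficiency drift, observer error, pesticide-
induced suppression of catches, and diapause/photoperiod control of the
overwintered flight. Passing the closed-loop tests therefore shows that
the estimator recovers the curve when the model's structural assumption —
catch follows thermal time through this curve — holds, not that field data
satisfy that assumption.

## Problem sizes and tolerances in the test suite

The closed-loop recovery experiment uses 20 replicates of 30 sites × 500
moths at 15-day reads (≈510 pooled points per fit), scoring β₁ and the
three Δβ at a 5% mean-relative-error bar; the noiseless self-consistency
check uses 400 exact curve samples and a ±10% perturbed start at 10⁻³
relative error and SSE < 10⁻¹⁰. The validation loop uses 5-day reads and
10⁵ moths, requiring each observed peak median to land within one
observation interval (in CDD) of the generating median. The degree-day
closed form is checked on a 50×50 (tmin, tmax) grid spanning all six
threshold cases against 10⁵-step trapezoid integration at 10⁻⁶ DD.

## Known limitations

- The fitted curve describes the pooled, standardized pattern; per-site
  heterogeneity enters only through the pooling, and the published
  parameter table itself reports standard errors exceeding several
  estimates from the second peak on. Site-specific recalibration is
  advisable before operational use.
- Peak segmentation assumes the four-peak structure; seasons with merged
  or missing flights are flagged and excluded rather than modelled.
- Emergence of the overwintered generation is photoperiod-gated in
  reality; projecting it with thermal time alone overstates advancement
  under warming.
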