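# Methods

## Model

The exponentiated inverted Weibull (EIW) law has CDF
F(x; θ, β) = exp(−θ x^−β) on x > 0, density
f(x) = θβ x^−(β+1) exp(−θ x^−β). θ > 0 is the exponentiation
("scale-type") parameter and β > 0 the shape; θ = 1 recovers the inverted
Weibull and β = 1 the exponentiated inverted exponential. A useful
transformation fact, used both for sampling checks and for intuition:
T = X^−β is exponential with rate θ.

The stress-strength model assumes strength X ~ EIW(θ₁, β) and stress
Y ~ EIW(θ₂, β), independent, with a **common shape**. Then

R = P(Y < X) = ∫ F_Y(x) dF_X(x) = θ₁ / (θ₁ + θ₂).

The common-β assumption is what buys the closed form; if the two samples
clearly need different shapes (as a single-sample fit of each would reveal),
the ratio formula no longer holds and this package's joint fits are the
wrong tool.

All quantile/random-variate work uses the algebraic inverse of the CDF,
x = (−ln q / θ)^(−1/β), by inverse-transform sampling. CDF and density are
evaluated in log space so that extreme x or large β do not underflow; the
support is enforced strictly (x ≤ 0 is a domain error, not F = 0).

## Estimation

**Maximum likelihood.** At fixed β the likelihood is maximised by
θ_j(β) = n_j / Σ x_i^−β. Substituting gives a 1-D profile log-likelihood
whose derivative is solved by bracketed root-finding (Brent) on
β ∈ [10⁻³, 10³], the bracket expanding geometrically if needed; the weighted
means Σ x^−β log x / Σ x^−β inside the score are computed with a softmax
shift so that large β cannot underflow to 0/0. Standard errors come from
the inverse observed information (central-difference Hessian with steps
scaled to parameter magnitude, eps^(1/4) relative); a non-positive-definite
information matrix produces a warning and NaN SEs rather than a crash.

**Spacing and minimum-distance estimators.** With x₍₁₎ ≤ … ≤ x₍ₙ₎ and
spacings Δᵢ = F(x₍ᵢ₎) − F(x₍ᵢ₋₁₎) (boundary conventions F(x₍₀₎) = 0,
F(x₍ₙ₊₁₎) = 1):

* MPSE maximises (1/(n+1)) Σ log Δ₁ᵢ + (1/(k+1)) Σ log Δ₂ⱼ;
* MSADE minimises Σ|Δᵢ − 1/(n+1)| (both samples), MSALDE the same on logs;
* LSE/WLSE minimise (weighted) squared distance of F(x₍ᵢ₎) from i/(n+1),
  with WLSE weights (n+1)²(n+2)/(i(n−i+1)) — the inverse asymptotic variance
  of the uniform order statistic;
* CME minimises 1/(12n) + Σ (F(x₍ᵢ₎) − (2i−1)/(2n))² summed over both
  samples (the constant is kept in the reported objective but cannot move
  the argmin);
* ADE minimises the sum of the two samples' Anderson–Darling statistics
  A² = −n − (1/n) Σ (2i−1)[ln F(x₍ᵢ₎) + ln(1 − F(x₍ₙ₊₁₋ᵢ₎))].

Numerical guards: spacings are floored at 1e−10 inside logarithmic
objectives (ties would otherwise give −∞; the estimators are undefined under
exact ties and the floor simply keeps the objective finite), and CDF values
are clamped to [1e−12, 1 − 1e−12] inside the Anderson–Darling logs.

**Optimisation strategy.** Every one of these objectives separates as an
x-term in (θ₁, β) plus a y-term in (θ₂, β). The fitter exploits this: a
geometric grid of 25 β values spanning ×0.16–×6.3 around the MLE shape, with
an independent 1-D bounded Brent minimisation in log θ for each sample at
each grid point, locates the global basin; a Nelder–Mead polish on
(log θ₁, log θ₂, log β) plus four multiplicative-jitter restarts
(log-normal, σ = 0.25, fixed sub-seed so fits are deterministic) refines it.
Log-parameterisation enforces positivity without constraints. Nelder–Mead is
used for the polish of all objectives — the MSADE/MSALDE objectives are
nonsmooth and the smooth surfaces are cheap enough that derivative-free
polishing costs little. The profile-grid stage is the design choice that
matters: the WLSE and CME surfaces on real data are genuinely multimodal,
and 3-D descent from a single start point is exactly how one lands on — and
publishes — a dominated local point (see "Reference-value discrepancies").
Restart count and the achieved objective are recorded on every fit.

Tolerances: profile-score root to xtol 1e−10; inner Brent xatol 1e−6 (in
log θ, only needs to land in the basin); Nelder–Mead xatol 1e−8 / fatol
1e−11. With these settings the exhaustive-grid oracle tests agree with the
optimizer on toy data to well below grid resolution.

**Conventions.** The stress-sample size is called k throughout (configs may
write `m`; it is mapped). The CME plotting positions default to the standard
(2i−1)/(2n); a reversed variant `as_printed` = (2(n−i)+1)/(2n), which pairs
the smallest order statistic with the largest probability, is kept behind a
switch for documentation — on the jute data it drives the fit to the
degenerate uniform point (β → 0) and should not be used.

## Bootstrap intervals

Parametric only: replicates are drawn from the fitted EIW laws (sizes n and
k), refit with the same estimator, and R recorded; failed refits are redrawn
(max 10 per replicate, counts logged). Per-replicate generators are spawned
from the master seed (`numpy` SeedSequence), so results are reproducible and
independent of execution order.

* Boot-P at level 1−γ: replicate order statistics at ranks ⌈Bγ/2⌉ and
  ⌈B(1−γ/2)⌉, ranks clamped to [1, B].
* Boot-BCP: z₀ = Φ⁻¹(fraction of replicates below the original estimate),
  ranks shifted to ⌈B·Φ(2z₀ + z_{γ/2})⌉ and ⌈B·Φ(2z₀ + z_{1−γ/2})⌉. Ties
  with the point estimate count ½; the fraction is clamped to
  [1/(2B), 1 − 1/(2B)] so z₀ stays finite when all replicates fall on one
  side. No acceleration constant (BC, not BCa).

Default B = 1000 for data analyses, 500 inside simulation CI-length tables
(lengths are insensitive to B beyond a few hundred).

## Goodness of fit

Single-sample fits (each sample with its own shape — the case-study
workflow) are checked with the one-sample KS statistic over order
statistics. The default p-value evaluates the asymptotic Kolmogorov
distribution at √n·D and ignores the estimated-parameter effect; it is
therefore conservative-to-liberal in the usual plug-in way and is reported
as a descriptive index, not a calibrated test. An exact finite-n mode
(`mode="exact"`) is available. P-P pairs (i/(n+1), F(x₍ᵢ₎)) and CDF overlay
series are exposed as arrays; no figures are rendered.

## Monte Carlo harness

`run_study` draws each replicate's two samples by inverse transform with
per-replicate spawned seeds, fits every requested method to the *same*
data, and accumulates per-parameter means and MSEs plus optional bootstrap
interval lengths. Failed fits are excluded (not redrawn) and counted, so all
methods see identical streams. The bundled study grid follows the stated
simulation design — sizes (30,40), (35,45), (50,60), (70,80) — and the
default acceptance-scale replicate count is 2000 (full 10000 by config);
the test suite scales further down (120–600 replicates) with tolerances of
3 Monte Carlo standard errors of the run actually performed.

What the generator emulates: independent, complete (uncensored), exactly
EIW-distributed samples with a genuinely common shape. Real
breaking-strength data violate all of these gently (measurement rounding,
possible shape heterogeneity between gauge lengths, occasional censoring),
so passing recovery tests demonstrates correctness of the estimators under
the model, not robustness to model failure.

## Reference-value discrepancies (jute data)

The carbon-fibre fits reproduce previously reported values to four decimals
(joint MLE θ̂₁ = 103.93, β̂ = 4.574, R̂ = 0.7722; single-sample fits
likewise, noting the reference table transposes its two columns — the KS
row, which is not transposed, pins the correct pairing). The jute-fibre
reference values, however, are **not** optima of their stated objectives:

* the reference joint-MLE point has lower log-likelihood than the exact
  profile root (−416.667 vs −416.635) and does not satisfy
  θ_j = n / Σ x^−β at its own β̂;
* for every minimum-distance method checked, the exact optimum found here
  strictly dominates the reference point under that method's own objective
  (e.g. MPSE mean-log-spacing 8.0593 vs 8.0892).

The jute objectives are flat near their optima, and the reference values
behave like early-terminated optimizer output; with the same code the
sharper carbon surfaces reproduce exactly. This package reports the exact
optima (joint MLE β̂ = 1.1332, R̂ = 0.5752; MPSE R̂ = 0.5683) and keeps the
comparison tests against the jute reference cells in the suite, where they
fail visibly rather than being silently relaxed. Simulation cross-checks
tell the same story: mean estimates for MLE/LSE/WLSE/CME match the reported
large-replicate study within Monte Carlo error, while the corrected
Anderson–Darling objective is far less biased than the reported ADE rows
(whose printed objective is garbled), and the spacing methods differ
slightly in bias direction.

## Known limitations

* No censoring, no Bayesian machinery, no BCa intervals, no
  different-shape (β₁ ≠ β₂) stress-strength model.
* Observed-information SEs are provided for the MLE only; for the other
  estimators a clearly-labelled parametric-bootstrap SE is offered instead
  (their sampling variances have no closed form here).
* The KS p-value ignores parameter estimation; treat it descriptively.
* Exact ties in the data make spacing-based objectives degenerate; the
  1e−10 floor keeps them finite but heavily tied data deserve a different
  estimator.
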