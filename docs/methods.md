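# Methods

## The model

`delmm` fits regression models for a *single subject's* discrete
longitudinal outcome: values y_t drawn from a finite ordered support
v_0 < ... < v_K (e.g. daily pain ratings 1-9), observed at N distinct
integer times t(i) inside some window, with arbitrary gaps.  Three
probability models map a J-column predictor row x_t to the category
probabilities p_{t,u}:

* **multinomial** — generalized logits against the reference category
  v_0, one slope vector per non-reference category
  (K·J probability parameters);
* **ordinal** — cumulative logits (proportional odds): K category
  intercepts plus J shared slopes (K + J parameters);
* **censored Poisson** — log λ_t = x_t'β on the *category index*
  u = 0..K−1, with the top category absorbing P(Poisson ≥ K)
  (J parameters).  The index entering the Poisson mass is the category
  position, not the support value, so any ordered numeric support works.

From the probabilities come the mean μ_t = Σ v_u p_{t,u} and variance
Var_t = Σ v_u² p_{t,u} − μ_t².  Dispersions inflate or deflate the
variance multiplicatively on the log scale, log φ_t = x′_t'β′, giving
extended standard deviations σ_t = (φ_t Var_t)^{1/2} and standardized
residuals stde_t = (y_t − μ_t)/σ_t.  Serial dependence uses the
*spatial* AR(1) working correlation r = ρ^{|Δt|}, which respects gaps
between observation days (index-based AR(1) does not).

All parameters θ = (β, β′, ρ) are estimated at once by maximizing the
**likelihood-like objective**: the multivariate normal log-density of
the residual vector with covariance DIAG(σ)·R(ρ)·DIAG(σ).  This is a
pseudo-likelihood — the outcome is discrete, not normal — but it yields
estimating equations for every parameter jointly (unlike GEE, which
fixes covariances when estimating mean parameters), a parameter
covariance −H^{-1}, and a cross-validation score with a likelihood
interpretation.

## Derivatives

The gradient and Hessian are assembled generically from per-time moment
derivatives supplied by each engine (∂μ/∂β, ∂Var/∂β and their second
derivatives), chained through

    ∂stde/∂β_a  = −(∂μ/∂β_a)/σ − stde·W_a/2,   W_a = (∂Var/∂β_a)/Var
    ∂stde/∂β′_j = −stde·x′_j/2

plus the AR(1) identities ∂R⁻¹/∂ρ = −R⁻¹(∂R/∂ρ)R⁻¹ and
∂log|R|/∂ρ = tr(R⁻¹ ∂R/∂ρ).  All chain rules were derived from the
link functions directly and are validated coordinate-by-coordinate
against central finite differences (the test-suite and the acceptance
script both re-run this check on randomized instances for all three
engines).  The ρ blocks avoid forming ∂R⁻¹/∂ρ explicitly: with
A = R⁻¹∂R/∂ρ and q = R⁻¹stde, every needed quantity is a
matrix-vector product given the single O(N³) product A.

## Estimation

Newton iteration θ ← θ − H⁻¹g with safeguards, since the paper-style
unconstrained treatment meets several numerical hazards in practice:

* **ridge fallback** H − τI when the Newton direction is not an ascent
  direction, plus an ∞-norm step cap of 50 against near-singular H;
* **step halving** (up to 30, abandoning scales below `step_tol`)
  accepting only non-decreasing objective values;
* **staging**: (β, β′) are fit first with ρ = 0, then ρ is released;
* **ρ projection** into [−0.99, 0.99] after every step;
* **convergence** when max|g| < 1e−6 *or* the Newton decrement
  g'(−H)⁻¹g — the predicted gain of the next step, a scale-invariant
  criterion — falls below 1e−9.  The raw gradient tolerance alone
  misbehaves when curvature is of order 1e6 and machine-precision
  optima keep max|g| ≈ 1e−3.

Starting values come from the marginal outcome distribution (log mean
category index for the censored Poisson, smoothed empirical log-odds or
cumulative logits for the other engines), slopes and dispersion
coefficients zero.

**Ordinal boundary ties.**  With freely parameterized cumulative-logit
intercepts (no monotonicity constraint), the objective is *boundary
attracted*: emptying a category (p_u → 0) shrinks the variance and can
raise the objective, so optima often tie adjacent intercepts, and the
unconstrained gradient then points across the validity boundary at
every step scale.  The solver treats near-ties (gap < 1e−4) as active
equality constraints: Newton steps are solved in a merged basis where
tied intercepts move jointly, near-ties are snapped exactly equal (so
the emptied category's probability is exactly zero at every predictor
value, including held-out ones), and a KKT check at each constrained
optimum releases any tie whose separation in the valid direction would
increase the objective.  Mildly negative category probabilities
(≥ −1e−8) arising from roundoff at these boundaries are tolerated; the
objective touches probabilities only through μ and Var.

**Degenerate variances.**  The per-time variance enters logs and square
roots as Var + 1e−10 (additive smoothing, not a hard clamp), keeping
the objective differentiable everywhere while capping the density spike
that a collapsing variance with a near-zero residual would otherwise
produce.  The censored-Poisson rate predictor is clamped to ±30 before
exponentiation (λ² appears in second-derivative formulas); other linear
predictors are clamped at ±700.

## Likelihood-like cross-validation (LCV)

Observations are dealt into k folds by a seeded shuffle followed by
round-robin assignment (sizes differ by at most one; deterministic
given the seed — the same seed must be used for every model being
compared).  With T+(f) the union of folds 1..f and θ(T∖T(f)) the
estimate fit without fold f,

    LCV_f = L(T+(f); θ(T∖T(f))) / L(T+(f−1); θ(T∖T(f))),
    LCV = (Π_f LCV_f)^{1/N},  larger is better.

Fold subsets keep their actual observation times, so AR(1) submatrices
reflect true gaps.  Substituting one fixed θ for every deleted estimate
telescopes the product to L(T;θ) exactly; the tests use this identity
as an oracle.  Scores are computed in log space.

## Adaptive model search

A two-phase heuristic steered by LCV over fractional-polynomial terms:
power transforms x^p of nonnegative predictors and *geometric
combinations* (x1^p1 · x2^p2)^p — products of power transforms that
generalize interactions to nonlinear moderation.  Every transformed
value is capped at 1e12 (applied to the inner product and again after
the outer power) with 0^0 := 1 and 0^negative := the cap, so models
with negative powers remain evaluable at covariate value 0.

* **Expansion**: repeatedly, over candidate terms (each base predictor;
  plus pairwise products of in-model bases when geometric search is
  on), run a 1-D power search — candidate offsets
  {±0.5, ±1, ±2, ±3, ±5} around the current power, then step halving to
  resolution 0.01 — and add the best term, first to the probability
  design, then to the dispersion design; stop when the best relative
  LCV gain is below `tol_expand` (default 0.1%).
* **Contraction**: repeatedly remove the term or intercept whose
  removal costs the least relative LCV, accepting while the loss is
  below `tol_contract` (default 0.1%), optionally re-refining remaining
  powers after each removal.  Intercepts are removable, so
  zero-intercept models can be selected.

The best-scoring specification encountered anywhere in the search is
returned, with the full trace.  Scores are cached per specification;
candidate fits that fail are skipped with a warning.  The search is
deterministic given (data, options, seeds).

## Synthetic data

The generator uses a Gaussian copula (NORTA): a latent normal vector
with correlation ρ_latent^{|Δt|} at the observed times is pushed
through Φ and then the inverse CDF of the per-time marginal category
distribution implied by a chosen engine and true parameters.  Marginals
are exact by construction; the outcome-scale serial correlation is an
attenuated, monotone image of ρ_latent.  Consequently recovery tests
target coefficients and fitted curves, and check only sign/ordering of
the estimated autocorrelation.  The working model's dispersion is not
part of the generative law (the copula needs only marginals), so
simulated data correspond to constant-dispersion truth.

`patient_fixture` emulates a single-subject daily pain study: 86 of 97
days observed, ratings 1–9, censored-Poisson marginals with
log λ = 0.76·t^0.2 + 1.16/t + 0.08·flares (rate ≈ 6.8 at day 1,
dipping below 4 within the first week, recovering toward 7 by day 97),
daily flare counts 0–4 from a reflected lazy random walk (serially
persistent), and ρ_latent = 0.4.  It is a qualitative emulation, not a
reconstruction of any real patient; magnitudes were chosen once to
match the published qualitative description of such data.

What passing tests on this generator do *not* show: real pain-rating
data need not follow a censored-Poisson marginal, its serial dependence
need not be AR(1) on any scale, and informative missingness (the
dropped days are missing completely at random here) is not emulated.

## Validation studies and problem sizes

`scripts/acceptance.py --seed S --out results/acceptance.json` re-runs
every study from scratch (about two minutes on one CPU):

* derivative accuracy: 100 randomized instances per engine (N ≤ 12,
  ρ ∈ (−0.8, 0.8)); worst scaled deviation |analytic−FD|/(1+|FD|).
  Draws with a per-time variance below 1e−4 are redrawn because the
  finite-difference oracle itself loses the compared digits there.
* optimizer agreement: Newton vs restarted Powell on N = 25, plus a
  random-perturbation check that nothing improves the objective.
* exact identities: multivariate-normal equality, ρ = 0 per-observation
  decomposition, and the consecutive-times closed form
  log|R| = (N−1)log(1−ρ²).
* LCV telescoping at a fixed θ (exact to roundoff).
* recovery: 100 replicates of N = 500 copula-simulated
  censored-Poisson data with the true design supplied; reports the mean
  absolute error of the fitted mean curve against the generating truth
  and the ratio of the empirical SD of each coefficient to the mean
  model-based SE.
* discrimination: 25 replicates of N = 300.  The nonlinear truth is a
  smooth quadratic-in-time log-rate dipping mid-window (rate spanning
  about 3–7 on a 1–9 support, so no category saturates), scored
  true-form (intercept, t, t²) against intercept + t; the moderation
  truth contains a flare-by-time product, scored with and without the
  geometric combination.  Reported as win percentages.
* parameter accounting for the two reference model shapes
  (zero-intercept censored Poisson with 2+1 transforms → 3; the
  K = 8 multinomial analogue with 1+1 transforms → 9).

The test-suite runs the same studies at the same sizes, except the
adaptive-search recovery checks, which run scaled down (8 replicates,
N = 300, 3 folds, power resolution 0.1) with a correspondingly reduced
hit threshold.

## Known limitations

* The pseudo-likelihood can possess spurious local maxima where a
  flexible term (e.g. t^−1, which is active only at the first few
  days) drives early-time fitted variances toward zero; the additive
  variance smoothing caps the objective gain but does not remove the
  attractor.  Cross-validation usually punishes such fits, and they
  surface as non-convergent or poorly scoring deleted estimates.
* Model-based SEs and z-values are reported only for converged fits
  with a negative-definite Hessian, and are unreliable for adaptively
  selected models (selection inflates apparent significance); reports
  flag this.
* Single-subject only: no pooling across subjects, no non-integer
  times, no missing-data machinery beyond absent rows.
* The multinomial engine's parameter count grows as K·J; on short
  series (N below a few times K·J) fits are frequently ill-conditioned
  and the covariance is withheld.
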