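# Methods

## Model structure

The stochastic system tracks initiated-cell counts along two independent
multistage pathways: CIN with stages I₁, I₂, I₃ (4 rate-limiting events
to cancer) and MSI with stages J₁…J₄ (5 events). Time is discrete with
Δt = 1 model unit = `dt_months` (default 3) calendar months; all rates
are per cell per unit. Over one step, conditionally on the current
counts:

* initiations into stage 1 are Poisson with means λ_I Δt and λ_J Δt
  (λ = N·α₀ with the stem-cell pool N folded in; default N = 10⁸ cells,
  so the published per-cell initiation rates 1.4×10⁻⁶ and 8.3×10⁻⁷ map
  to λ_I = 140, λ_J = 83 per unit);
* births and deaths of each stage are a multinomial draw over
  (divide, die, neither) with probabilities (bΔt, dΔt, 1−(b+d)Δt);
* mutations to the next stage are Poisson with mean (count)·αΔt,
  independent of the birth/death draw — mutation is asymmetric (one
  daughter mutates at division) and does not deplete the current stage.

Counts update by the exact accounting identity, so every trajectory
conserves cells step by step. The expected numbers obey the linear chain
du_l/dt = inflow + γ_l(t)u_l with γ = b − d; for time-homogeneous rates
the solution is evaluated in closed form as λ·(∏α)·divided difference of
exp(·t) over the net proliferation rates (computed confluently via the
Opitz bidiagonal matrix exponential, exact also for repeated or zero
rates — the MSI pathway always has γ_{J1} = γ_{J2} = 0, so the classical
pairwise-distinct partial-fraction form, also provided, never applies to
it). Time-varying (growth-limited) rates integrate numerically
(DOP853, rtol 10⁻¹¹).

A deliberate consequence of the discrete-time formulation: the exact
mean of the stochastic system follows the one-step Euler recursion of
the conditional means and differs from the continuum ODE solution by
O(Δt) (about 4% in the last stages at 30 years with Δt = 1). Simulator
tests therefore compare Monte-Carlo moments against the discrete
recursion (the law actually sampled) and verify first-order convergence
to the ODE as Δt shrinks, rather than conflating the two.

## Growth limitation of the polyp stages

The growth-limiting mechanism is implemented as exponential decay of the
polyp-stage birth rate, b(t) = b·exp(−δt), with the death rate constant
— the simplest one-parameter form consistent with adenomas growing to a
maximum size, and pluggable should a logistic variant be preferred. At
the default estimates the decay constants are δ₁ = 8.3×10⁻⁵ (I₂) and
δ₂ = 1.6×10⁻³ (J₃) per unit.

## Tumor onset and the observation model

A newly transformed malignant cell needs at least one model unit to
grow into a detectable tumor (`p_detect_lag`, default 1 unit), so the
pathway onset intensities are ω₁(t) = α₃∫₀^{t−1}E[I₃] and
ω₂(t) = β₄∫₀^{t−1}E[J₄]. First-onset probabilities per age group use
the nonhomogeneous-Poisson survivor form Q_i(j) = e^{−ω_i(t_{j−1})} −
e^{−ω_i(t_j)} (nonnegative by monotonicity of ω, and reproducing the
additive small-probability approximation Q_T ≈ Q₁ + Q₂), combined across
pathways by inclusion–exclusion. Age-interval boundaries are half-open
(t_{j−1}, t_j] with t₀ = 0 at birth; the packaged SEER table encodes its
first two rows as [0,1) and [1,5) years.

Validity caveat: Q computed from *expected* cell numbers is a
first-order approximation in the last-stage transformation rates. When
the per-person cumulative intensity is O(1) — as at the published
point estimates evaluated per person — E[e^{−ω_path}] exceeds
e^{−E[ω]} appreciably (Jensen), and the expected-number Q_T overstates
the per-person first-onset fraction by several percent absolute. The
Monte-Carlo cross-check of Q_T is therefore run in the small-intensity
regime (last-stage rates scaled down ×0.02) where the approximation's
own premise holds. Fitted parameters put per-person lifetime risk at
the percent scale, well inside that regime.

## At-risk convention

The packaged table carries the census at-risk counts n_j ~ 10⁷. The
published analysis states that fitting used the lifetime-eligible
population m_j ~ 10⁵ instead. A direct check makes the difference
structural: with n_j the fitted Q_T ~ 10⁻³ leaves the survivor factors
≈ 1 and no parameter set can reproduce the downturn of incidence after
age 75, whereas at the 10⁻² scale the depletion of susceptibles does so
naturally. Fits therefore expose an `n_scale` factor (default 1,
honoring the printed table; 10⁻² — the stated order of m_j/n_j — for
reproducing the published analysis, and the setting used by
`scripts/acceptance.py`).

## Prior

The prior is box-uniform ("partially informative"): constant inside an
open box, zero outside, with boundary values counted as outside. The
published bounds for the initiation intensities (1, 1000), polyp-stage
net proliferation (10⁻⁴, 2×10⁻²), growth limitation (10⁻⁵, 5×10⁻³) and
last-stage net proliferation (10⁻², 0.5) are used verbatim. The printed
mutation-rate bounds exclude the published point estimates themselves
(e.g. an upper bound of 10⁻⁴ against an estimate of 3.2×10⁻³) and so
cannot be meant literally; the default box instead brackets each
mutation rate by roughly one decade around its published magnitude:
α₁, β₁ ∈ (10⁻⁶, 10⁻³), α₂, β₂ ∈ (10⁻⁵, 10⁻²), β₃ ∈ (10⁻⁴, 10⁻¹),
α₃, β₄ ∈ (10⁻⁸, 10⁻⁴). Any prior can be supplied as YAML.

## Fitting

τ_j depends on the parameters only through the expected cell numbers
plus (α₃, β₄), so the observed-data posterior over the 15 identifiable
parameters (λ_I, λ_J, α₁..α₃, β₁..β₄, b_I₂, δ₁, γ_I₃, b_J₃, δ₂, γ_J₄;
death rates of the proliferating stages held at reference values since
the incidence surface sees only b − d for the constant-rate stages) is
computable without augmentation. `gibbs_fit` therefore begins with a
seeded bounded global optimization of that posterior in log₁₀ space —
differential evolution with Sobol initialization, a deep Nelder–Mead
polish along the likelihood ridges, and an L-BFGS-B finish, with
independent restarts — and starts the Gibbs recycles at the mode. The
box-midpoint initialization is available (`init="midpoint"`) but from
there the recycles alone cannot reach the data basin in a practical
number of iterations: the conditional updates regenerate parameters
consistent with paths simulated at the *current* parameters, so their
data-driven drift per recycle is tiny.

Each recycle then follows the multi-level scheme:

1. **Augmentation.** K candidate latent paths are simulated from the
   system model at cohort scale (default 10⁵ persons superposed:
   initiation intensity scaled by the cohort, per-cell rates unchanged),
   weighted by the Poisson observation likelihood of the incidence each
   path implies, and resampled by weighted bootstrap. For age groups
   whose realized path carries no last-stage cell time (the infant
   groups), the expected-number τ stands in — a candidate-independent
   factor that keeps the weights finite. The effective sample size of
   the weights is reported; with population-scale counts the likelihood
   is extremely peaked and ESS ≈ 1 is the norm (selection approaches
   argmax), a known property of importance resampling against
   high-information data.
2. **Conditional updates.** Poisson-count parameters take their
   events/exposure conditional mode; last-stage birth and death rates
   take the multinomial proportion mode; the growth-limited stages take
   the profile mode of (b, δ) with b(δ) closed-form and δ maximized on
   its bracket; all projected into the open prior box. The last-stage
   transformation rates (α₃, β₄) are updated by bounded 2-D maximization
   of the incidence likelihood given the selected path (ω is linear in
   each rate, so the path enters only through its cumulative last-stage
   integrals).
3. **Recycling.** Draws are collected across chains (default 2, seeds
   spawned from the master seed); estimates are the sample means of the
   post-burn-in draws. Convergence is monitored as stabilization of the
   running posterior-mean vector (relative change < 10⁻³ per recycle
   over 5 consecutive recycles) — the per-recycle conditional modes
   themselves jiggle at the latent-sampling noise floor and never meet a
   componentwise tolerance. Split-R̂ per parameter (via arviz) is
   attached when at least two chains run.

Because the conditional updates have no restoring force along the
likelihood ridges, long recycle runs random-walk the estimates away from
the mode; the default configurations therefore use short recycle counts
after the MAP stage, and the posterior spread reported by the draws
reflects the latent-sampling noise rather than full data curvature.
This mirrors the character of the original scheme, which likewise has
no accept/reject correction.

AIC and BIC are reported as Dev + 2p and Dev + p·log n with p = 15 and
n = 18 stated explicitly in every report, so alternative conventions
can be recomputed from the deviance.

## Identifiability

Shifting last-stage birth and death rates by a common constant leaves
every τ_j unchanged (verified to 10⁻¹⁰ relative): incidence identifies
net proliferation only. Beyond that, the two pathway slopes trade off
along a nearly flat likelihood ridge of the incidence curve: on
synthetic data generated at the published rates with the SEER at-risk
counts, the maximum-likelihood estimate of γ_I₃ scatters ±25–35% across
replicates even though the optimizer provably reaches the global mode
(log-likelihood above the truth by ≈ χ²₁₅/2) and a noise-free fit
recovers both γ's within 6%. Posterior means coincide with the mode to
≈1%, so this spread is a property of the model-data combination, not of
the estimator.

## Synthetic data

`simulate_incidence` draws y_j ~ Binomial(n_j, Q_T(j)) independently
across groups at the expected-number Q_T — the observation model's own
law — with full provenance (parameters, seed) attached. It emulates the
sampling noise of an age-grouped registry table; it does not emulate
person-level path heterogeneity in Q (relevant only at O(1) per-person
intensities, see above), secular trends across birth cohorts, or
registry artifacts such as age heaping. Passing recovery tests on this
generator therefore demonstrate correctness of the fitting machinery
under the model's own assumptions, not robustness to real-data
misspecification.

## Numerical choices

* Fast path: the expected-number chain integrates by fixed-step RK4
  (h = 0.5 unit; relative error ~10⁻⁸ at fitted rates, checked against
  the DOP853 route), numba-compiled when available, vectorized across
  parameter draws for the global optimizer.
* Reference path: DOP853 with rtol 10⁻¹¹ for all reported quantities.
* Deviance at y_j = 0 uses the continuity limit 2τ_j; τ_j = 0 against
  y_j > 0 yields −∞ likelihood and is flagged.
* Degenerate (tied) net-proliferation rates: the confluent closed form
  handles them exactly; the strict distinct-rate form raises a
  dedicated error directing to the ODE path.
* RNG: one seeded generator per trajectory with a documented stream
  order (initiations, per-stage multinomials low→high, per-stage
  mutations), so identical seeds reproduce trajectories bit for bit;
  chain seeds are spawned from the master seed via `SeedSequence`.

## Problem sizes used in the shipped checks

Expected-number oracles run 20 random prior-box draws; Monte-Carlo
moment checks use 10⁴ trajectories (horizon capped so counts stay
simulable for explosive draws) and 10⁵ one-step replicates; the SEER
refit and the acceptance script use K = 50 candidate paths, 10 recycles
on 2 chains after a 3-restart global-optimization stage; parameter
recovery runs 10 replicate fits at a reduced optimizer budget.

## Known limitations

* The printed AIC/BIC pair of the original analysis (55.96 / 81.30) is
  not reproducible from its own printed predictions (which imply a
  deviance ≈ 628) under any (p, n) convention; this package reports its
  own deviance with the convention stated.
* The posterior spread from the recycles underestimates parameter
  uncertainty (see Fitting); treat the reported SDs as stability
  diagnostics, not credible intervals.
* Person-level risk heterogeneity, screening effects and cohort trends
  are out of scope; the at-risk adjustment is a single scalar, whereas
  the true lifetime-eligible counts vary by age group.
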