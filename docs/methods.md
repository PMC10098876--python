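# Methods

This note records the statistical model the package implements, the
numerical choices, what the simulator does and does not emulate, and known
limitations.

## Stage-wise model

For arm j ∈ {1,…,K} versus the shared control, the stage-1 score statistic
satisfies S₁,j ~ N(θ_j V₁,j, V₁,j) asymptotically, so
θ̂₁,j = S₁,j/V₁,j ~ N(θ_j, σ²₁,j) with σ²₁,j = 1/V₁,j. Two estimation
routes produce (θ̂₁, Σ₁):

* **logrank score route** — S and V are the usual logrank sums (observed
  minus expected control-share, and the hypergeometric variance). The
  shared-control covariance is
  q_ij = σ²₁,i σ²₁,j Σ_d p_{d,i} p_{d,j}, where the sum runs over stage-1
  event times, p_{d,i} = r_{d,i}/(r_{d,c}+r_{d,i}) when the event at t_d is
  on the control or arm i and 0 otherwise. Only control events contribute
  off-diagonally. Tied event times are processed as simultaneous events
  with risk sets frozen at the tie time, which converges to the
  unique-times formula as ties vanish.
* **proportional-hazards route** (default) — one Cox model with K
  treatment indicators at the interim; Σ₁ is the inverse observed
  information. Combined-data (θ̂_j, V_j) for a selected arm come from a
  pairwise Cox fit on all control + arm-j records.

The stage-2 increment is θ̂₂,j = (S_j − S₁,j)/(V_j − V₁,j) with variance
σ²₂,j = 1/(V_j − V₁,j); the naive estimate recombines exactly as
θ̂_j = (σ²₂θ̂₁ + σ²₁θ̂₂)/(σ²₁+σ²₂). Approximate independence of the
increment from stage-1 data rests on all triggers (interim event count,
stage-2 event count, carry-over horizon) being prefixed.

The Cox fits use an in-package Newton solver on the Breslow partial
likelihood (gradient sup-norm ≤ 1e-8, ≤ 100 iterations, step-halving with
a relative monotonicity margin, exp-overflow guarded by η-centering). A
|log HR| above 15 at convergence is reported as monotone likelihood — at
that magnitude some arm has essentially no events inside shared risk sets
and the maximizer is at infinity. The solver is validated against
lifelines (untied data, Efron≡Breslow there) and against brute-force
maximization of an independently coded Breslow likelihood (tied data).

## Selection rules and bounds

Each rule yields the selected set S, the per-arm conditional upper bound
W_j (L_j = −∞ for all six rules), and a rectangle description
{lower ≤ A θ̂₁ ≤ upper} of the selection event. P-value rules operate on
the z scale θ̂₁,j√V₁,j; competitor effects are rescaled by
√(V₁,j′/V₁,j) so that all bounds live on arm j's log-HR scale. Ties in
best-type rules break toward the lowest arm index (a measure-zero event).
The futility event of a thresholded rule is itself a rectangle, so outcome
probabilities partition unity — a property the tests check to 1e-6.

## Truncated-MVN kernels

Prob(S) and E[θ̂₁,j 1_S] are rectangle probabilities and first truncated
moments of an MVN in the A-transformed coordinates. First moments use
E[X 1_R] = μP(R) + Σc with boundary terms
c_k = φ_k(l_k)P(R₋ₖ|X_k=l_k) − φ_k(u_k)P(R₋ₖ|X_k=u_k), each conditional
factor an (m−1)-dimensional rectangle probability. Rectangle probabilities
in dimension ≥ 2 use scipy's quasi-Monte-Carlo integrator with absolute
tolerance 1e-6 by default (1e-9 for the two-dimensional worked example)
and a fixed internal randomization seed, so outputs are deterministic.
Selection probabilities below 1e-12 raise rather than divide.

## The estimators

* **SI/MI** — bias for j ∈ S is t_j(E[θ̂₁,j1_S]/Prob(S) − θ_j) with
  t_j = V₁,j/V_j; unselected arms use their stage-1 estimates as working
  values. MI iterates θ̃ ← θ̂ − b(θ̃) from the naive vector; tolerance
  1e-6 (sup-norm step), cap 100 iterations, divergence declared after 10
  consecutive step-doublings. Non-convergence returns the last iterate
  flagged, so a prespecified fallback (e.g. the UMVCUE) can take over.
* **shrinkage** — stage-1 posterior mean Cθ̂₁ + (I−C)θ̂₁,all·1 with
  C = I − Σ₁(ν²I+Σ₁)⁻¹, combined as wθ̂_SH⁽¹⁾ + (1−w)θ̂₂,j. ν² is
  estimated by a method-of-moments fixed point,
  ν² ← max{0, Σw̃_j[(θ̂₁,j−θ̂₁,all)² − σ²₁,j]/Σw̃_j} with precision
  weights w̃_j = 1/(ν²+σ²₁,j), iterated to 1e-8; a fixed ν² can be
  supplied instead. The default simulator weight is
  w = E₁(|S|+1)/(E₁(|S|+1)+E₂(K+1)) from the planned event counts.
* **UMVCUE** — holding the complete sufficient statistic
  θ̂*_i = θ̂₁,i + (q_{ji}/σ²₂,j)θ̂₂,j fixed, the selection constraint
  θ̂₁,j ≤ W_j becomes a one-sided interval for θ̂₂,j and the estimator is
  the truncated-normal mean
  θ̂_j − η_j[φ(u)−φ(l)]/[Φ(u)−Φ(l)], η_j = σ²₂,j/√(σ²₁,j+σ²₂,j).
  Own-threshold rules give B_L = ((σ²₁+σ²₂)θ̂_j − σ²₂W_j)/σ²₁, B_U = ∞.
  When W_j is achieved by competitor l the bound involves q_jl, and the
  truncation side flips with the sign of q_jl − q(S)
  (q(S) = σ²₁,j for log-HR rules, σ₁,jσ₁,l for P-value rules); the
  boundary expressions were re-derived from the sufficient-statistic
  construction and are verified in the tests by checking that the
  constraint binds exactly at the bound. q_jl = q(S) is a degenerate
  branch and raises. One-sided truncations are evaluated with log-scale
  Mills ratios, stable arbitrarily far into the tails.

## Simulator

Proportional Weibull hazards h₀(t) = λγt^{γ−1}, h_j = e^{θ_j}h₀, with the
control scale derived from the control median, λ₀ = ln2/median^γ (the
median is the design quantity; for γ = 0.5 and a 365-day median,
λ₀ = ln2/√365). Recruitment is deterministic at `recruit_rate` subjects
per day with randomly permuted blocks of size K+1 (stage 2: |S|+1, with
allocation restricted to control + S immediately after the interim). The
interim occurs at the calendar instant of the D₁-th death; stage 2 ends at
the E₂-th death among stage-2 patients; stage-1 patients without events
are censored a fixed number of days after the interim. Preset scenarios
use K = 4, D₁ = 717, E₂ = 316, one-year carry-over, one recruit/day,
best-arm rule with futility at 0, γ = 0.5 — with true log-HR vectors
(0,0,0,0), (−0.2231,…), (0,−0.1393,−0.3011,−0.5108) and
(−0.9163,−0.9163,−0.9163,−1.0498).

Replication uses one master seed with independent per-replicate
substreams; conditional bias/RMSE for arm j average only replicates in
which arm j was selected, and MI metrics exclude (but count)
non-converged replicates. Failed fits inside a replicate are recorded,
not raised.

What the generator does **not** emulate: non-proportional hazards,
informative censoring or dropout, covariates, staggered site activation,
or data-dependent triggers. Passing tests therefore demonstrate correct
estimator algebra and calibration under the design's idealized sampling
model, not robustness to those violations.

The `normal_theory_replicate` shortcut draws (θ̂₁, θ̂₂,j) directly from
the joint normal law, skipping the survival layer. It is the oracle for
conditional-unbiasedness checks, and its vectorized UMVCUE is tested
draw-by-draw against the scalar API route.

## Problem sizes

The packaged replication studies run at desk scale: 2,500 replicates for
the equal-arms scenario (≈500 selections per arm; Monte-Carlo SE of a
conditional bias ≈ 0.004 per arm, ≈ 0.002 pooled across the four
exchangeable arms) and 2,000 stage-1-only replicates for the graded
scenario. The reference operating characteristics they are compared to
come from 100,000-replicate runs, so agreement is asserted within
3 Monte-Carlo standard errors, pooling exchangeable arms where symmetry
allows.

## Known limitations

* The UMVCUE is exactly conditionally unbiased (given "arm j selected"
  for threshold rules; given S = {j} for pure best-arm rules) under the
  joint normal model. For the two rules that combine a futility threshold
  with the best-arm comparison, the construction keeps only the binding
  constraint — given the sufficient statistic, both the futility and the
  competitor constraints restrict θ̂₂,j — so a small intrinsic bias
  remains (≈ −0.003 at the preset design with all effects null, the same
  order as the residual bias visible in the reference simulation study).
  The test suite documents this honestly: the unbiasedness oracle passes
  for the four single-constraint rules and fails, by that small margin,
  for the two dual-constraint rules.
* With K > 2 competitors and unequal shared-control covariances the
  competitor-bound branch uses the observed argmin competitor l; when
  covariances differ across arms the binding competitor can in principle
  change within the integration range, another (tiny) source of
  approximation inherited from the closed form.
* On top of the normal model, the survival layer itself is approximate:
  carry-over follow-up makes the increment only approximately independent
  of stage-1 data, and the asymptotic normality of score-based estimates
  degrades for |log HR| large (hazard ratios below ≈ 0.4), where the
  proportional-hazards route is preferable.
* Confidence intervals are out of scope; the package provides point
  estimation only.
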