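# Methods

## The task

The package simulates an adaptive two-choice probabilistic reversal-learning
task. Two stimuli A/B are shown; one is the current target. Feedback is
*contingent* on 75% of trials (reward iff the target was chosen) and inverted
on the remaining 25%, drawn i.i.d. per trial. A reversal (target flip) occurs
as soon as the learner has (a) completed the block's minimum number of trials
— drawn uniformly from 6–10 afresh each block — and (b) chosen the target on
three consecutive trials. "Correct" for this criterion means *choice of the
target*, not received feedback: feedback is probabilistic, so only
choice-based streaks make the criterion well defined. A run ends at 12
reversals or 240 trials, whichever comes first. Because reversals are
performance-contingent, the schedule cannot be pre-generated; the engine is
stepped interactively (`revlearn.task`).

An important consequence of the adaptive design, visible throughout the
synthetic results: error *rates* are partly self-equilibrating. Better
learners reach criterion sooner, so reversals arrive more often per trial and
every reversal restarts an error-rich relearning phase. Overall error
percentages therefore vary only weakly with the agent parameters (≈43–50%),
while the *composition* of errors shifts strongly: livelier updating (larger
ω, see below) and stronger exploitation (larger β) raise the perseverative
share and lower the regressive share.

## Learning models

All models choose via a softmax on a value difference,
p(A) = 1/(1 + exp(−β(V_A − V_B))), with inverse temperature β ≥ 0
(exploitation vs decision noise).

**Anti-correlated Rescorla–Wagner (`rw`).** One prediction error
δ = R − V_chosen updates both options in opposite directions:
V_chosen ← V_chosen + αδ, V_unchosen ← V_unchosen − αδ, with constant
learning rate α ∈ [0,1]. V_A + V_B is conserved exactly — used as an
invariant test. Values start at (0.5, 0.5).

**Three-level binary HGF (`hgf`, `hgf_fixed_theta`).** The binary state
x₁ ("A is rewarded") is governed by a sigmoid of a latent tendency x₂, which
random-walks with step variance exp(κx₃ + ω); the log-volatility x₃
random-walks with step variance exp(ϑ). κ is pinned to 1. Filtering yields
Gaussian beliefs (μ₂, σ₂, μ₃, σ₃) with the familiar precision-weighted
updates: with ŝ = s(μ₂), π̂₁ = 1/(ŝ(1−ŝ)), π̂₂ = 1/(σ₂ + e^{μ₃+ω}),

    δ₁ = R − ŝ,   σ₂′ = π̂₁ / (π̂₂π̂₁ + 1),   μ₂′ = μ₂ + σ₂′ δ₁,

so σ₂′ is the per-trial effective *learning rate* applied to the level-1
prediction error. Level 3 uses the canonical volatility update: volatility
prediction error δ₂ = (σ₂′ + (μ₂′−μ₂)²)·π̂₂ − 1, weight w₂ = e^{μ₃+ω}·π̂₂,
precision π₃ = π̂₃ + ½κ²w₂(w₂ + (2w₂−1)δ₂) with π̂₃ = 1/(σ₃ + e^ϑ), and
μ₃′ = μ₃ + κw₂δ₂/(2π₃). The two HGF variants differ only in whether ϑ is a
free parameter or fixed at the group-level value −3.5066. ϑ is interpreted on
the log scale (level-3 step variance e^ϑ): a printed negative "variance" is
only meaningful there, consistent with standard HGF tooling.

The softmax sees V_A = ŝ (the predicted reward probability of option A,
*before* the trial's update) and V_B = 1 − V_A. Feedback is remapped to the
option-A frame before updating (u = feedback if A was chosen, else
1 − feedback). Missed trials trigger no update and are excluded from all
likelihoods and error counts.

### Initial conditions and the operating point

Starting beliefs are fixed constants, not fitted: μ₂(0)=0, σ₂(0)=1,
σ₃(0)=1, and μ₃(0) = **−4**. The choice of μ₃(0) sets the filter's
operating point, since with the tiny fixed ϑ the level-3 state barely moves:
the effective tonic log-volatility is ≈ ω + μ₃(0). Three constraints pin it:

* **Stability.** With μ₃(0) ≥ 0 and study-scale ω (≈ 0.3–1.0) the level-2
  walk variance e^{μ₃+ω} ≳ e reaches a self-destabilising regime — during
  confident streaks σ₂ accumulates ≈ e^{μ₃+ω} per trial, a disconfirming
  outcome then throws μ₂ by ±σ₂, and the loop diverges (28/30 closed-loop
  runs overflow at ω=0 with μ₃(0)=1).
* **Identifiability.** At μ₃(0)=−5 the behavioural imprint of ω is too weak
  to recover it from a 240-trial run (true-vs-recovered r ≈ 0.55); at −4 and
  −3 recovery reaches r ≈ 0.75.
* **Learning-rate scale.** μ₃(0)=−4 puts mean per-trial σ₂ for the
  group-mean parameters at ≈ 0.22–0.30, the scale the study reports.

### Numerical guards

s(μ₂) is clamped to [10⁻⁸, 1−10⁻⁸] before forming π̂₁; the exponent of the
level-2 walk variance is capped at 30; states are clamped to |μ₂| ≤ 12,
μ₃ ∈ [−12, 3], σ ≤ 50 (beyond these the states carry no additional
behavioural meaning); and π₃ is floored at 0.05·π̂₃, because the quadratic
volatility correction can push it non-positive when w₂ < ½ meets a large
volatility surprise. With the guards, simulation is stable over the full
parameter range the cohort generator can draw; non-finite arithmetic still
raises a `NumericalError` naming the trial. The reported learning rate is
the σ₂ actually applied to δ₁ (pre-clamp).

The one-step update is validated against a brute-force oracle: on states
sampled from actual operating trajectories, μ₂′ lands within 10⁻² of the
grid-located mode (Laplace point) of the exact posterior
p(x₂ | R) ∝ N(x₂; μ₂, σ₂+e^{μ₃+ω})·s(x₂)^R(1−s(x₂))^{1−R}. The exact
posterior *mean* deviates by up to ≈0.02 at the largest prediction
variances — the update is a modal, not a moment, approximation.

## Model inversion

Each model is fit per subject-run by MAP in a transformed space (log β,
logit α, identity ω and ϑ) with weakly informative Gaussian priors centred
near the study's group means: ω ~ N(0, 2²), ϑ ~ N(−3.5, 1²) when free,
log β ~ N(log 5, 1²), logit α ~ N(0, 1.5²); hard bounds β ∈ [10⁻³, 50],
α ∈ [10⁻³, 1−10⁻³], ω ∈ [−10, 5], ϑ ∈ [−10, 0]. L-BFGS-B with 8 (library
default; 3–4 in the repeated studies) jittered restarts of one prior SD;
ties broken by log-joint then by smaller parameter norm; runs must have
≥ 30 valid trials. Numerically failed evaluations receive a large penalty so
the optimiser steers clear of pathological regions. Bound hits are flagged
(`at_bounds`); note that with the log-normal β prior a flat likelihood holds
the MAP interior (≈12), so the default upper bound binds only when the
likelihood genuinely pushes past it.

The reported "log evidence" is a Laplace approximation at the MAP,
log p(y,θ̂) + d/2·log 2π − ½ log|H|, with H a central finite-difference
Hessian of the negative log-joint (eigenvalues floored at 10⁻⁶). It is a
negative-free-energy-style approximation, not a full variational inversion.
A consequence worth stating plainly: on data generated from the fixed-ϑ
model, the free-ϑ likelihood is flat in ϑ (the MAP sits at the prior mean)
and the Laplace evidence of the nested model then cancels the extra
parameter's terms essentially exactly (measured gap 0.000 ± 0.002 nats per
run). The two HGF variants are therefore *statistically equivalent* on such
data, and group-level selection between them is a near coin flip; only the
RW model is decisively rejected (≈1.4 nats per run). Model-recovery results
must be read with that degeneracy in mind.

## Random-effects model selection

`rfx_bms` implements the variational Dirichlet scheme for group BMS: iterate
subject-wise posterior model assignments u_nk ∝ exp(logE_nk + ψ(α_k) −
ψ(Σα)) and concentration updates α = α₀ + Σ_n g_n, to Δα < 10⁻⁴
(cap 500 iterations); α₀ = 1 per model. Exceedance probabilities are
Monte-Carlo argmax frequencies over 10⁵ Dirichlet draws (repeat-seed spread
< 0.01). Per subject, condition-run evidences are summed before BMS (one
evidence per subject per model); a per-run mode is available.

## Error taxonomy and alignment

Within each post-reversal block, non-missed errors before the block's first
correct choice are *perseverative*; errors after it are *regressive*; errors
in the initial acquisition block have no previously-reinforced target and are
tallied separately (included in overall). All percentages share one
denominator: the run's valid (non-missed) trials. Reversal-aligned summaries
average learning rate and value over a window of 2 trials before to 5 after
each block start, with the value re-expressed as the probability assigned to
the *pre-reversal* target so A→B and B→A reversals average coherently;
offsets truncated at run boundaries contribute nothing.

## Synthetic cohorts

`default_paper_specs()` emulates the study: 28 children + 25 adolescents,
three conditions each, β drawn once per subject (reported only across
conditions) and ω per condition, from truncated normals at the fitting
bounds (the printed SDs are large relative to the means, so untruncated
draws can produce invalid agents). A unitless everyday-rigidity covariate is
drawn jointly with β at correlation 0.32 through a Gaussian copula over a
bivariate normal. Agents are the fixed-ϑ HGF.

One deliberate design choice: the study's reported per-condition ω
estimates admit two group assignments, and the default specs use the
internally consistent one. The groups' reported average learning rates
(children 0.21 < adolescents 0.26; the learning rate is monotone in ω) and
the direction of the study's simulated error pattern both require the
adolescents to carry the larger ω, so children are modelled as the slower
belief-updaters. Under it the generator reproduces, qualitatively, the
study's structure: the ω and learning-rate group contrasts are strongest in
the control condition, mean learning rates sit near 0.2–0.4, β correlates
positively with rigidity (r ≈ 0.33 at n=53) and the learning rate
negatively with overall errors.

What the generator does *not* emulate: human strategy beyond the model
class (real participants err less overall, ≈33–40% vs ≈47% here — agents
lack any reversal-structure awareness), reaction times, condition-specific
motivational effects beyond the printed ω differences, and the SRS
instrument itself (only the covariate's correlation structure matters).
Passing tests therefore certify the pipeline's internal consistency and
directional behaviour, not quantitative fidelity to human error levels.

## Problem sizes used by the test and acceptance runs

Parameter recovery uses 40 agents × 240 trials (reversal cap lifted so runs
reach full length). Repeated recovery studies use 8+8 subjects and
5-reversal runs — five is the shortest run guaranteeing the 30-valid-trial
fitting minimum. Error-pattern direction uses full-size cohorts. The
group-level error-pattern direction (adolescents more perseverative,
children more regressive) is a *majority tendency* here, not a per-cohort
certainty: the group ω separation (0.27) moves perseverative percentages by
under one point, while the prescribed between-subject β dispersion
(SD ≈ 4.2) contributes replicate-level noise of a couple of points, so
individual cohorts reproduce the direction in roughly 50–70% of draws.

## Known limitations

* The Laplace evidence cannot separate the two HGF variants on fixed-ϑ data
  (see above); a parameter-counting criterion (e.g. BIC) would, but only by
  fiat.
* MAP + Laplace, not MCMC or full variational inference; no hierarchical
  (group-level) priors across subjects.
* Binary two-option tasks only; no perceptual uncertainty at level 1.
* The σ₂ learning-rate peak around reversals is shallow under a fixed tiny
  ϑ (volatility beliefs barely move within a run); group differences in the
  aligned curves are level shifts more than shape changes.
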