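# Methods

## Task model

Each trial k carries a stimulus category c_k ∈ {−1, +1} (left/right
rewarded side) generated by a two-state Markov chain: the category
repeats the previous one with probability P_rep and flips otherwise,
so the marginal over categories is 0.5 for any P_rep ∈ (0, 1).  P_rep
switches between 0.7 ("repeating") and 0.2 ("alternating") in blocks of
200 trials; the first block type and the initial category are
configurable (defaults: repeating, +1).

Stimulus strength s_k is drawn uniformly from {0, 0.23, 0.48, 1},
independently of the category (the marginal over strengths is not
dictated by the task design; uniform is the package default and is
configurable).  Signed stimulus evidence is e_k = c_k · s_k.  Each
trial has n_frames = 8 evidence frames, one per cycle of the 20 Hz
amplitude modulation (50 ms frames, 400 ms of stimulus).  The
instantaneous evidence S_{k,f} of each frame is i.i.d. from a
*stretched beta* on [−1, 1] with mean e_k and variance 0.06: x is
mapped to u = (x+1)/2, the Beta(α, β) shapes are solved from the mapped
mean m = (e+1)/2 and variance v = 0.06/4, and the draw is mapped back.
The mapping is infeasible when v ≥ m(1−m); with the default variance
this never occurs for |e| ≤ 0.48, and |e| = 1 is handled as a point
mass (every frame equals the category).  Frame evidence sets the
per-frame envelope amplitude weights a^L = (1 + S)/2 and
a^R = (1 − S)/2, computed as 0.5 ± 0.5·S so that their sum is
bit-exactly 1 at every sample in floating point.  The common AM factor
is 1 + sin(2π f_AM t + φ) with φ = 3π/2, zero at stimulus onset; f_AM
is interpreted as a cyclic frequency so that 20 Hz gives the 50 ms
cycle.  Frame f (1-based) spans the half-open interval
[(f−1)/f_AM, f/f_AM).

All randomness in a session derives from one generator stream seeded
by a single integer, making generated tables byte-reproducible.

## Generative agent

Three latents evolve across trials (reset to z^L = z^T = 0, c^T = 1 at
each session start):

    z^L ← (1 − λ_L^q) z^L + Δ_L^q r_t                 (lateral evidence)
    z^T ← (1 − λ_T^q) z^T + Δ_T^{o,q} T_t             (transition evidence)
    c^T ← clip(c^T + Δ_C^q, 0, 1)                     (gating signal)

where r_t ∈ {−1, +1} is the response and T_t = r_{t−1}·r_t the
transition (+1 repetition, −1 alternation).  Superscript q is the
current trial's outcome (so leaks and the gate update are driven by
the trial just completed; λ = 1 means the accumulator is fully cleared
by that outcome) and o is the outcome of the preceding trial, which
together with q selects the transition update Δ_T^{o,q}.  The first trial of a session has no transition, so only the
lateral and gating updates apply there.  The pre-choice decision
variable is

    y_t = w_stim · x_t + γ^L_t + γ^T_t + B,
    γ^L = z^L,    γ^T = c^T · z^T · r_{t−1},

with x_t the summed frame evidence of the trial (a single stimulus
weight; per-frame weights belong to the GLM, not to this model), and
the choice is Bernoulli with p(right) = π_R + (1 − π_R − π_L) Φ(y_t).

The gate update is an additive increment hard-clipped to [0, 1]:
Δ_C^− = −1 extinguishes the gate after a single error (full blockade of
the transition bias), Δ_C^+ = +1 restores it fully after any correct
response.  Setting λ_T^− = 1 with Δ_C ≡ 0 (gate frozen at 1) instead
yields the rival *complete reset* dynamics in which the evidence
itself, not just its influence, is erased by errors.  A lapse term is
included (bounded in [0, 0.5]); it may fit to ≈ 0.

### Default parameters (the simulated study conditions)

| parameter | default | rationale |
|---|---|---|
| Δ_L^+ / Δ_L^− | +0.03 / −0.03 | win-stay-lose-switch lateral updates, an order of magnitude below the transition scale |
| λ_L^± | 0.4 | fast lateral discounting |
| Δ_T^{++} | 0.2 | only ++ transitions drive the transition estimate |
| Δ_T^{+−,−+,−−} | 0 | transitions involving an error are ineffective |
| λ_T^± | 0.3 | kernel decay over ≈ 5 trials; identical after correct and error (the evidence survives errors) |
| Δ_C^+ / Δ_C^− | +1 / −1 | full gate recovery after rewards, extinction after errors |
| w_stim | 0.3 (per summed-frame unit, ≈ 2.4 per unit e) | ≈ 0.78 accuracy; stimulus impact an order of magnitude above the transition bias |
| B, π_R, π_L | 0 | no fixed side bias or lapses in the reference agent |

With these values the simulated conditioned repeating bias saturates
near b ≈ 0.7 after five correct repetitions and resets below 0.05
after one error, and after-correct accuracy exceeds after-error
accuracy by ≈ 0.03 — the qualitative regime of trained rats in this
kind of task.

### Fitting

Latents are deterministic given parameters and history, so the
sequential likelihood is exact (no filtering).  Fitting maximizes the
log posterior: weak Gaussian priors (sd 10) on unbounded parameters
(Δ's, w_stim, B) and uniform priors on bounded ones (leaks, Δ_C,
lapses).  Optimization is bound-constrained L-BFGS-B with 10 starting
points (a neutral init plus random restarts), convergence tolerance
1e−6 on the objective; the best iterate is returned with a convergence
flag.  The sequential recursion is JIT-compiled (numba), making a
10^4-trial fit a matter of seconds.

Identifiability caveat: the gate updates Δ_C^± and the after-error
leak λ_T^− are informed only by post-error and rebound trials (roughly
a fifth of the data) and the likelihood surface has shallow rival
modes in which a partially open post-error gate trades off against a
partial recovery.  At 10^4 trials the MAP can land in such a mode with
Δ_C errors of several tenths; Δ_T^{++}, λ_T^+, w_stim and the lateral
parameters recover tightly.  The parameter-recovery harness
(`recover_parameters`, CLI `recover`) quantifies this per seed.

## Psychometrics

Rightward curve P(right) = Φ(β e + B) and repeating curve
P(repeat) = Φ(β′ ê + b) with ê_t = r_{t−1} e_t; B is the fixed side
bias, b the repeating bias (b > 0: tendency to repeat).  Both are
lapse-free two-parameter probits fitted by Bernoulli maximum
likelihood (statsmodels `Probit`), not least squares on proportions.
Uncertainty is a nonparametric bootstrap over trials (1000 resamples
when requested); fits with any evidence level under 10 trials are
flagged unstable.  Trials without a previous response
(session-initial, post-invalid) are excluded from repeating fits.

Conditioning uses a small history-pattern language (tokens per trial,
anchored to end at t−1): `c`/`e` constrain the outcome, `r±`/`a±`
additionally constrain the transition into the trial, `.` matches
anything.  "n correct repetitions" is `c` followed by n `r+` tokens
(n+1 correct trials); appending `e` gives the error-terminated runs.
Matching is end-anchored and requires at least the pattern (longer
conforming histories also match).

## History GLM

Probit-with-lapses model of choice (see module docstring for the
decision variable).  Regressors per trial: 8 stimulus frames; summed
past stimulus evidence (sensory after-effect) at lags 1–5 plus a
pooled lag-6 term covering lags 6–10 (the pooled regressor is the sum
of its constituent lag regressors, sharing one weight); lateral
kernels r^+/r^− (−1/0/+1 coding by outcome) with the same lag layout;
and transition kernels T^{o,q}_{t−k} = r^o_{t−k−1} r^q_{t−k} for the
four outcome pairs, multiplied by r_{t−1} to project them into choice
space.  History never crosses session boundaries.

Fitting is penalized MLE (L2 strength 1e−4, configurable) with
analytic gradients under L-BFGS-B; lapses are bounded in [0, 0.5].
Conditioning on the previous outcome makes some lag-1/2 regressors
exactly collinear (e.g. after a correct trial, T^{++}_{t−1}·r_{t−1}
equals the lag-2 correct-response regressor); collinear and
identically-zero columns are detected by a greedy orthogonalization in
a fixed priority order — intercept, stimulus, transition, lateral,
after-effect — so the transition kernel, the quantity of interest, is
always reported, and the dropped columns are listed in the fit result.
The reported lag-1 after-correct transition weight therefore absorbs
the collinear lateral contribution.  Standard errors come from the
observed information of the weight block at the optimum; bootstrap
over sessions is available through refitting resampled tables.
Trials following an invalid trial are excluded from all conditions.
Model comparison (`compare_models`) reports BIC and held-out
log-likelihood; on gating-agent data the outcome-split model beats the
pooled model on held-out likelihood, while BIC can prefer the pooled
model because the split doubles the parameter count for a likelihood
gain concentrated in a few transition weights.

## Transfer coefficients

For lag k and an outcome pattern over trials t..t+k−1, the transfer
coefficient is the probit-regression weight of the repeat-axis
transition bias at t (γ^T_t · r_{t−1} = c^T_t z^T_t) in predicting the
repeat-coded choice at t+k (1 if r_{t+k} = r_{t+k−1}), with the
repeating stimulus evidence ê_{t+k} as covariate (covariate inclusion
is configurable).  Wald standard errors by default; a bootstrap
(over sessions when several are present, else over trials) gives
percentile CIs.  Under gating dynamics the (error, correct) lag-2
coefficient is large and positive (rebound); under complete reset it
is null.  Because z^T is strongly autocorrelated and keeps receiving
block-consistent updates between t and t+k, the coefficient measures
*predictability* and decays with k more slowly than the raw
discounting factor (1 − λ_T)^k; the decay is monotone but the per-lag
decrement is small relative to estimator noise below ~10^5 trials.

## What the synthetic data does and does not emulate

The generator reproduces the block-structured Markov sequence, the
strength/evidence/frame hierarchy and the envelope arithmetic of the
task, and the agent reproduces the build-up/reset/rebound phenomenology
of trained animals.  It does not model reaction times or within-trial
accumulation, intertrial-interval effects, session-to-session learning
or drift, invalid trials (withheld responses), or differences between
frequency- and level-discrimination acoustics.  Passing tests therefore
validate the analysis machinery and its discriminating power on data
from a known generative process, not any claim about a particular
animal dataset; analyses of real sessions enter through the canonical
CSV format (an adapter for the public data deposit is left as an
extension point).

## Numerical and problem-size choices

Monte-Carlo checks of the task statistics use 10^5 draws (standard
errors well below the asserted tolerances).  GLM signature checks use
5 seeds × 50,000 trials; transfer discrimination uses 20,000-trial
sessions with 200 bootstrap resamples; parameter recovery uses
20 sessions × 500 trials; the repeating-bias build-up/reset curves use
a 5×10^5-trial simulation — the scale of a pooled multi-animal
dataset — because the error-terminated n = 5 cell holds only ~0.6% of
trials.  Probabilities are clipped at 1e−10 (GLM) / 1e−12 (agent)
inside log-likelihoods; probit fits flag |estimates| > 10^3 as
separation.  Ties in the gate clip are exact (0 and 1 are reachable and
absorbing until the opposite outcome).
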