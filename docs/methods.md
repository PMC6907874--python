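# Methods

## The task and the ideal observer

On each trial an observer may draw up to 20 beads, with replacement, from a
hidden jar whose dominant-color proportion is `q ∈ {0.6, 0.8}`, paying
`c ∈ {0, 0.1, 0.4}` points per bead, and then judges the jar's identity for
a 10-point reward. An ideal observer judges by majority color and splits
ties with a fair coin, so the probability of a correct judgment after `n`
beads is a binomial tail sum

    p(n | q) = P(K > n/2) + P(K = n/2)/2,   K ~ Binomial(n, q),

with `p(0 | q) = 1/2`, and the expected gain is
`E[Gain | n, q, c] = (10 − n c) · p(n | q)`. The optimal sample size
`n_opt` maximizes the gain curve over `n = 0..20`.

Because an even draw adds no information under majority-with-coin-tie
(`p(2k | q) = p(2k−1 | q)` exactly), the gain curve is flat on `(19, 20)`
when `c = 0`. Argmax ties are therefore broken toward the **largest**
maximizing `n` (tolerance `1e-9` on the gain): at zero cost the optimum is
read as "sample as much as possible", `n_opt = 20`. With `c > 0` exact
ties do not occur.

Behavioral optimality measures, per participant and condition:

- **efficiency** — mean expected gain of the observed sample sizes divided
  by the maximum of the gain curve (linear, so the order of averaging does
  not matter); in `(0, 1]`.
- **sampling bias** — mean observed sample size minus `n_opt`.
- **sampling variability** — sample SD (ddof = 1) of the sample sizes.
- **noncompliance flags** — boxplot rule (`1.5 × IQR` beyond the
  quartiles, linear-interpolation type-7 quantiles) on per-participant
  values within a condition.

## Choice models

Each stop/continue decision is Bernoulli with stop probability
`σ(X)`, `X = Σ β_k DV_k`. Two decision-variable sets:

- **cost set** (5 weights): indicators of the three cost levels (no
  global intercept — the indicators span it), beads drawn `j`, and total
  cost `j·c`;
- **evidence set** (6 weights): intercept, unit log evidence
  `ln(q/(1−q))`, `|CI|`, total log evidence `ln(q/(1−q))·|CI|`,
  previous-trial correctness (0/1; 0.5 on the first trial of a session),
  and previous-trial sample count.

`CI` is the pink-minus-blue count with exponential decay
`CI ← α·CI ± 1`, `α ∈ [0, 1]`; models "without decay" run the same
recursion with `α = 1`. When both sets share one stage (combined
one-stage models) the evidence intercept is dropped (10 weights).

Two-stage models assign the cost set to one stage and the evidence set to
the other (2 orders), let either a first-stage *continue* or a first-stage
*stop* recruit an optional second stage (2 triggers), and set the
second-thought probability `p_sec` by the cost condition (3 parameters),
the evidence condition (2), or a flexible logit-linear function of the
first-stage stop probability, `logit(p_sec) = γ·logit(p1) + φ` (2).
Overall stop probabilities:

    continue-triggered:  p = p1 + (1 − p1) · p_sec · p2
    stop-triggered:      p = p1 (1 − p_sec) + p1 · p_sec · p2

The registry holds 4 one-stage + 2×2×3 = 12 two-stage models. The
best-supported architecture (cost first, continue-triggered, cost-set
second-thought rule) carries 5 + 6 = 11 stage weights, 3 second-thought
probabilities, and 1 decay rate. Forced stops at the 20-bead cap are not
choices and never enter the likelihood. Degenerate probabilities are
clamped at `1e-12` (and logged); "unbounded" weights are clipped to
`[−50, 50]` as an implementation bound.

## Decision times

Only continue-choice DTs are modeled (stopping uses a different key).
Expected first-stage DTs are exponential-linear in the stage's stop
probability:

    Y_cont1 = exp(b0 + b1 (1 − p1) + b2 p1 (1 − p1))
    Y_stop1 = exp(b0 + b1 p1 + b2 p1 (1 − p1))

and a second-stage decision adds `exp(b0' + b1'(1 − p2) + b2' p2(1 − p2))`
on top of `Y_cont1` (continue-triggered) or `Y_stop1` (stop-triggered).
Observed DTs are lognormal about the path's expected DT (`σ` per stage),
so a two-stage model predicts a two-component lognormal mixture whose
weights are the stage posteriors given a continue choice:

    continue-triggered:  P(S1|cont) = (1−p_sec) / ((1−p_sec) + p_sec(1−p2))
    stop-triggered:      P(S1|cont) = (1−p1) / ((1−p1) + p1·p_sec·(1−p2))

No separate non-decision constant is added; `b0` absorbs it. `b0` and `σ`
are positive (bounded `[1e-6, 10]` and `[1e-3, 10]`); `b1`, `b2` are free
in `[−50, 50]`. The joint likelihood of a choice and its DT factorizes
exactly into the Bernoulli choice term and the conditional DT mixture, so
the joint log likelihood is the sum of the two parts (verified numerically
in the tests).

## Fitting

Per participant and model, estimation is two-step: the choice parameters
are fit to the stop/continue sequence by bounded L-BFGS-B (analytic
gradients, including the decayed-CI recursion derivative), then the DT
parameters are fit with all choice-derived stage quantities frozen — DTs
never move a choice parameter away from a choice optimum.

The choice surface has a nearly flat ridge in the second-thought
probabilities: a strong first stage can absorb second-stage stopping, so
well-separated parameter vectors can attain almost the same choice
likelihood while implying very different DT mixtures. Three measures make
the search reliable and are part of the package's estimation procedure:

- **structured starts** — one-stage prefits of each DV set anchor the
  stage weights (scaled down at random, since a lone stage overestimates
  its own hazard); `p_sec` is started on a coarse grid and at the
  slow-component share of a 2-component Gaussian mixture of the log DTs
  (a moment-matching start only — the objective is unchanged);
- **nested floor** — the stage-1 prefit with `p_sec = 0` is always kept
  as a candidate, so a two-stage fit can never end up worse than its own
  first-stage restriction;
- **joint tie-breaking** — distinct choice optima within 10 log-units of
  the best restart are treated as a near-tie band and the joint
  (choice + DT) likelihood selects among them. Reported choice parameters
  therefore always lie on or near the top of the choice-likelihood
  surface, while the band resolves the `p_sec` ridge with the information
  the DT mixture carries.

Restart seeds derive deterministically from (seed, participant, model), so
refits reproduce exactly and results are independent of execution order.
Convergence tolerance is `1e-6` on the objective; the default is 10
restarts.

## Model comparison

AICc (`AIC + 2k(k+1)/(n−k−1)`) and BIC use the number of modeled DTs as
`n` and the total choice + DT parameter count as `k`. Fixed-effects
summaries report per-participant ΔAICc against each participant's best
model. Random-effects group BMS treats the model identity as a random
effect: with per-participant log model evidence approximated as `−AICc/2`
(the standard surrogate; the bridge is a package decision), a variational
Dirichlet posterior over model frequencies (uniform prior `α₀ = 1`,
tolerance `1e-6`) yields expected frequencies; exceedance probabilities
come from Dirichlet Monte Carlo (default 10⁶ draws, seeded); the Bayesian
omnibus risk compares the free energy of the random-effects model with the
uniform-frequency null, and the protected exceedance probability is
`EP·(1−BOR) + BOR/K`.

The **cost-evidence strategy index** is the mean AICc of the 6 cost-first
two-stage models minus the mean of the 6 evidence-first models; negative
values indicate a cost-first preference. Analogous contrasts on the
trigger and second-thought dimensions are exposed (flexible-rule models
belong to neither rule family and are excluded from that contrast). The
index is a noisy family contrast: single-model fit differences of hundreds
of log-units propagate into it, so at small samples its magnitude is
unstable even when its sign is systematic.

## Behavioral statistics

- **DT preprocessing** — log-transform, then boxplot-rule exclusion with
  fences computed on the pooled (all-participant) log-DT distribution;
  per-participant fences are available but off by default.
- **log-DT mixture** — 2-component Gaussian EM (components ordered by
  mean) with the 1-component BIC alongside.
- **dip test** — Hartigan's dip statistic, computed by the classical
  GCM/LCM iteration (validated in the tests against an LP brute force
  that finds the closest unimodal cdf directly); p-values by bootstrap
  from the uniform null. Ties in the data are handled only approximately;
  DT data are continuous.
- **Spearman + FDR** — `scipy` Spearman correlations with
  Benjamini-Hochberg adjustment within the stated comparison family.
- **cluster-based permutation test** — participants ranked ascending by
  strategy index; running Spearman correlation with AQ over the first
  `k = 10..n` participants; pointwise significance at uncorrected .05 by
  the t approximation against zero, or by Monte-Carlo bands from
  inclusion-order shuffling against the overall correlation; contiguous
  same-signed significant points form clusters sized by `|Σ atanh(r)|`
  (for the overall reference, `atanh(r) − atanh(r_overall)`); cluster
  p-values from the permutation distribution of the maximum cluster size
  (index/AQ re-pairing, or inclusion-order shuffling). Fewer than 100
  permutations are refused.

## Synthetic populations

The schedule generator reproduces the study design exactly: 3 cost blocks
(order by a 1..6 permutation id) × 96 trials, evidence levels randomly
mixed within block, 48 trials per cell, the pink-dominant jar preselected
on half the trials of each cell, left/right counterbalanced.

Agents generate choices by forward draws through the two-stage decision
tree (so empirical stop frequencies match the closed forms by
construction) and DTs from the finalization path's lognormal. Strategic
diversity is per-trial mixing: each trial runs a cost-first process with
probability `π` and a mirrored evidence-first process otherwise. In
populations, AQ ~ Normal(69.97, 10.48) (rounded, clipped to 0–150) and
`π = σ(a + b·zAQ)` with default `(a, b) = (1.0, 1.2)`.

Generative defaults (in `simulate.py`) were chosen so that mean sample
sizes fall in plausible ranges per condition (≈15/11 beads at zero cost —
undersampling against the cap; ≈6/5 at low cost; ≈2 at high cost —
low-evidence above high-evidence throughout), the pooled log-DT
distribution is clearly bimodal (fast component ≈ 0.3 s, slow ≈ 2 s), and
second thoughts increase with cost (`p_sec = 0.15/0.45/0.65`). The
evidence stage is deliberately threshold-like (steep `|CI|` weight):
shallow evidence stages leave the second-thought probability essentially
unidentifiable from choices, which would contradict the decisive
model-comparison regime the generator is meant to emulate. Across-agent
variation uses Gaussian jitter on weights and Beta jitter on
probabilities; the Beta concentration for `p_sec` (`psec_kappa`) is 8 by
default (spread needed by recovery studies) and should be set high (e.g.
60) for strategy-diversity studies, where stage order — not the stages —
is meant to be the dominant individual difference.

What the generator does **not** emulate: learning or fatigue across
blocks, lapses and attention failures, left/right response biases,
questionnaire item structure, or any within-trial evidence accumulation
producing DT autocorrelation. Passing tests therefore show that the
pipeline recovers what this generative family encodes at the study's
scale, not that real data are free of these complications.

## Problem sizes and numerical choices

Simulation-based checks run at deliberately modest sizes chosen as a
package decision: parameter recovery at 20 agents × 288 trials,
model recovery at 10 agents for each of 4 representative generators with
the 4-model candidate set, strategy-diversity checks at 10–12 agents,
permutation-test calibration at 1000 null replicates × 150 permutations,
bootstrap dip tests at 200–1000 resamples. The Monte-Carlo oracle for the
ideal observer uses 10⁶ draws per (n, q) with a Bonferroni-style 4-SE
band across the 40 simultaneous comparisons.

Known limitations: the second-thought probabilities are weakly identified
from choices alone (the tie-break band documents exactly how DT
information is allowed to resolve this); `α` is unidentified whenever the
evidence stage is effectively silent and then drifts to a bound (flagged);
one-component DT data leave stage-2 DT parameters unidentifiable
(flagged, not fatal); the strategy index's magnitude is unstable at small
n; and the dip implementation treats tied observations approximately.
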