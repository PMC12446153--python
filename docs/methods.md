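# Methods

## What is simulated

The package simulates 2×2 within-participant interference experiments in
which the congruency sequence effect (CSE) — the modulation of the current
congruency effect by previous-trial congruency — either exists with a known
magnitude or is absent. Both factors are dummy-coded 0/1 (congruent = 0,
incongruent = 1), so a CSE is a negative previous×current interaction and
the classic raw score (cI − cC) − (iI − iC) equals minus the interaction
coefficient. Decision pathways (outlier filter × hypothesis test) are then
scored by how often they accept the CSE on data that contains it (TPR) and
on data that does not (FPR).

## Generative pipeline

**Stage 1 (cohort).** For each participant, random effects
(intercept, congruency slope) are drawn from MVN(0, Σ) and an accuracy
intercept from N(0, σ_acc²). Trial RTs in each of the four cells are
Gaussian around the linear predictor with residual SD σ; accuracy counts are
binomial with logistic probabilities from a parallel accuracy model. Only
per-cell summaries (mean RT, RT variance with ddof = 1, accuracy proportion)
flow forward; a separate entry point (`simulate_stage1_trials`) retains the
Gaussian trials for parameter-recovery checks.

**Stage 2 (diffusion).** Each cell summary is converted by the EZ closed
forms into drift rate v, boundary separation a and non-decision time Ter of
an unbiased Wiener process with scaling s = 0.1 (the conventional value;
configurable). Accuracies of exactly 0 or 1 are edge-corrected to 1/(2n)
and 1 − 1/(2n). A cell at exactly 50% accuracy has undefined drift; rather
than jittering it, the whole dataset replicate is regenerated from a shifted
sub-seed and the event is logged. Accuracies below 0.5 are handled by the
sign term of the EZ formula (negative drift). Ter values that would be
negative are floored at 0 (possible only for extreme summaries).

Trial RTs and correctness are then sampled from the *exact* first-passage
distribution of the Wiener process. For an unbiased start z = a/2 the
decision-time distribution is identical at both boundaries, and in scaled
time τ = t·s²/a² it is a one-parameter family in μ = va/s²:
f(τ) ∝ exp(−μ²τ/2)·S(τ) with S the alternating boundary series. S is
precomputed once on a fixed 8193-point grid over τ ∈ [0, 6] (residual tail
mass < 2e−13); per cell, sampling is a single inverse-CDF pass, and the
correct/error choice is an exact Bernoulli with P = 1/(1 + e^(−μ)). An
Euler–Maruyama simulation was deliberately not used: its O(√dt)
boundary-overshoot bias is visible at the precision of the moment oracle
(sampler vs closed forms within 3 SEs at 10⁵ trials), which the series
sampler passes with ~0.1 SE to spare.

**Contaminants.** Exactly round(rate·n) trials per participant × cell
(default 5% of 100) are replaced by RT ~ Uniform(0, 3.09 s) with fair-coin
correctness, emulating inattention/lapses that do not depend on the decision
process. Contaminants are injected after trial generation and are invisible
to the filters, as in real data.

## Parameter profiles and defaults

The interaction coefficients of the two true-effect profiles are empirical
estimates: −20.86 ms (prime-probe, "large") and −14.62 ms (flanker,
"small"). Null profiles zero the interaction and keep everything else,
including the accuracy model — nullification by construction rather than by
permutation of empirical data, which requires the original raw datasets.

All other generative components are not published at full precision and are
shipped as named defaults flagged `is_default_guess` (cleared per field when
a config override is supplied):

| component | prime-probe | flanker | rationale |
|---|---|---|---|
| intercept β₀ | 650 ms | 600 ms | typical online interference-task RTs |
| congruency β_C | 80 ms | 65 ms | typical congruency effects |
| previous β_c | 5 ms | 5 ms | small main effect of previous trial |
| intercept SD | 80 ms | 75 ms | between-participant spread |
| slope SD | 25 ms | 20 ms | individual differences in congruency effect |
| intercept–slope r | 0.3 | 0.3 | slower participants show larger effects |
| residual σ | 150 ms | 140 ms | within-cell trial noise |
| accuracy logits | 2.9/−0.6/−0.1/0.25 | 3.0/−0.5/−0.1/0.2 | ≈91–95% cell accuracy |
| accuracy RE SD | 0.5 | 0.5 | moderate participant accuracy spread |

These produce mean correct RTs around 600–750 ms, accuracies ~0.90–0.95,
and EZ parameters in conventional ranges (v ≈ 0.2–0.3, a ≈ 0.11–0.13,
Ter ≈ 0.35–0.45 s). They were chosen once for realism; rate results at
these settings characterize *this* data-generating process, and headline
TPR/FPR magnitudes shift with Σ and σ even though pathway *orderings* are
robust in our diagnostics.

## Filters

SD and MAD trims center on the participant × condition cell (the natural
reading of "conditional" z-scores in within-subject RT work); a pooled
across-participant mode exists behind `center="condition"` for sensitivity
checks. MAD uses the 1.4826 normal-consistency scale. All intervals are
closed; cells with zero spread are kept whole. Filter statistics are
computed after error-trial exclusion and *including* contaminants, mirroring
what an analyst can actually condition on.

## Hypothesis tests and the decision rule

The ANOVA route aggregates to cell means and tests the 2×2 within-subject
interaction (statsmodels `AnovaRM`); its F equals the squared paired t on
per-participant CSE contrasts, an identity the tests verify to 1e−10.
Mixed models (statsmodels `MixedLM`) are fit by **maximum likelihood**, not
REML, because the null/alternative comparison differs in fixed effects.
Significance of the interaction uses its Wald z test (mixed-model df
conventions vary; Wald is the scale-invariant common denominator). ΔAIC and
ΔBIC are computed from the ML log-likelihoods with an explicit shared
parameter count, which guarantees ΔAIC = LRT statistic − 2 for the 1-df
difference. Raw-RT models are fit in seconds with estimates reported in ms;
log models in log-seconds (shift-invariant for every test statistic).

Convergence policy: optimizer non-success, singular random-effect
covariance, Hessian warnings, non-finite estimates, or a random-effect
variance below 1e−4 of the residual variance mark a run non-converged; such
runs are excluded from rate denominators rather than counted as rejections.
statsmodels' own "MLE may be on the boundary" heuristic compares RE
variances to an absolute 0.01 and therefore fires on every healthy
second-scale fit; it is replaced by the relative criterion above.

No multiplicity correction is applied across pathways: the multiplicity of
analyst choices is the object of study.

## Engine, seeding and summaries

Each dataset's generator stream is `SeedSequence([master, effect index,
sample size, replicate, attempt])`, so all 50 pathways see bit-identical
data, any grid subset is reproducible in isolation, and regeneration after
an EZ-degenerate cell advances only the attempt counter. Rates are pooled
by summing decision and convergence counts (never by averaging rates) with
Wilson score 95% intervals on the pooled counts; a normal-approximation
interval is available through `wilson_interval`'s statsmodels backend if
needed.

The reference design is 4 effect types × {25, 50, 100, 200, 400}
participants × 1000 replicates × 50 pathways (10⁶ mixed-model-heavy
analyses) — a cluster-scale job. Desk-scale runs are first-class: the test
suite and the reproduction script use 20–400 replicates with reduced test
lists, sized so Monte-Carlo envelopes (binomial SEs on pooled counts) still
separate the qualitative orderings of interest: TPR growing with sample
size, MAD-2 maximal / no-filter minimal pooled TPR and FPR, and log-LMM
null FPR above the ANOVA's.

## What the generator does not emulate

Trials within a cell are exchangeable: no sequential dependencies, feature
transitions, learning/fatigue drifts or block structure. Contaminants are
uniform and evenly spread across cells, an intentionally exaggerated noise
model. The diffusion layer is the three-parameter EZ form — no
starting-point bias, no across-trial variability in drift or start point.
Accuracy random effects are intercept-only and independent of RT random
effects. Consequently, passing tests validate the engine and the relative
behavior of analysis pathways under this process; they do not certify
absolute TPR/FPR levels for any particular empirical paradigm.

## Numerical notes

- EZ round trip (forward∘inverse) is exact to ≤1e−8 over the tested grid.
- The sampler grid (8193 points, τ ≤ 6, series truncated at term k once
  k²π²τ₁/2 > 45) keeps quadrature bias well under Monte-Carlo noise at 10⁵
  trials; truncation negatives (~1e−15) are clipped.
- `round()` on contaminant counts uses banker's rounding (numpy `rint`),
  relevant only for odd cell sizes at 5%.
- Degenerate ANOVA inputs (zero contrast variance) are mapped to p = 1,
  i.e. no rejection, instead of NaN propagation.
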