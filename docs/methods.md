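# Methods

## Generative model of the task

A session consists of 5 runs of 72 trials. Trials come in 8-trial blocks
containing exactly 6 *expected*, 1 *unexpected* and 1 *ambiguous* trial in
pseudo-random order, so unambiguous trials follow the hidden tone→rotation
contingency with probability 0.75 within every block. The hidden
contingency starts in a uniformly drawn state (c1: high tone → CW, low →
CCW; c2 reversed) and reverses after segments of 16, 24 or 32 trials,
drawn uniformly among the lengths that still fit inside the run; trials
after the last reversal keep the final contingency. Tones are drawn
uniformly per trial. All of this is deterministic given a seed, and every
generated run satisfies the block-composition and reversal-spacing
invariants exactly (they are checked exhaustively in the tests).

Ambiguous trials present no rotation. They are the probe for prior bias:
the fraction of ambiguous trials perceived according to the current
contingency ("congruency") is the behavioral signature of interest.

## Contingency model: three-level binary HGF

The filter's input on trial *t* is u(t) = 1 iff the tone-rotation pair is
congruent with the reference coding c1, so the level-2 state is the
log-odds belief about the *association*, not about raw rotation direction.
Ambiguous trials provide no objective pairing and enter as missing inputs
by default (posterior = prediction, zero prediction errors); a
configuration switch (`schedule_inputs` / `InversionOptions.ambiguous_input`)
is reserved for updating on the reported percept instead.

Prediction step (before the input), from the previous posterior
(μ₂, σ₂, μ₃, σ₃):

    μ̂₂ = μ₂            σ̂₂ = σ₂ + exp(κμ₃ + ω₂)
    μ̂₃ = μ₃            σ̂₃ = σ₃ + exp(ω₃)
    μ̂₁ = σ(μ̂₂)                      (logistic; clamped to (0,1) at 1e-8)

Update on an observed input:

    δ₁ = u − μ̂₁
    π₂ = 1/σ̂₂ + μ̂₁(1 − μ̂₁)         μ₂ ← μ̂₂ + δ₁/π₂        (ε₂ = δ₁/π₂)
    w₂ = exp(κμ₃ + ω₂)/σ̂₂
    δ₂ = (σ₂ + (μ₂ − μ̂₂)²)/σ̂₂ − 1
    π₃ = 1/σ̂₃ + (κ²/2)·w₂(w₂ + (2w₂ − 1)δ₂)
    μ₃ ← μ̂₃ + (κ/2)(w₂/π₃)δ₂                               (ε₃ = that step)

ε₂ and ε₃ — the precision-weighted prediction errors — are defined as the
belief-update steps at levels 2 and 3. A non-positive π₃ (possible in this
update scheme when a confident level-1 prediction is violated under high
volatility) raises an explicit model-instability error identifying the
trial and parameters; the inversion uses it to reject parameter proposals,
and nothing downstream ever sees NaN/Inf. An equivalence test checks the
filter against an independent literal transcription of these equations at
1e-8 on random parameter/input draws.

The conditional rotation probability given the tone is
μ_a = σ(μ̂₂) for the high tone and 1 − σ(μ̂₂) for the low tone.

**Defaults.** κ = 1 (fixed, not estimated, the common three-level
practice), μ₂₀ = 0, σ₂₀ = 0.1, μ₃₀ = 0, σ₃₀ = 1. The initial volatility
state is centred at 0 so that the tonic level-2 step variance is exp(ω₂);
a positive μ₃₀ inflates early step variances and pushes the standard
precision update into its instability region for fast learners (ω₂ around
−0.7), which is why 0 is the package default.

## Response models

Eight variants {0, A, P, S, AP, AS, PS, APS} toggle three influences on
the percept. The posterior percept probability is additive in log-odds:

    logit P(θ₁) = stimulus + [A] π_a·logit(μ_a) + [P] w_p·y(t−1)
                  + [S] w_s·y(last ambiguous)   (S term on ambiguous trials only)

where y(·) = ±1 codes the CW/CCW percept (0 when absent — first trials
contribute no bias). The stimulus term is ±logit(1 − 1e-4) on unambiguous
trials (a small fixed report-error floor rather than exact determinism)
and 0 on ambiguous trials. Additivity in log-odds keeps each weight
interpretable and gives exact nesting: with π_a = w_p = w_s = 0 all eight
variants reduce to model 0 (asserted in the tests). Sensory memory is
implemented strictly as ambiguous→ambiguous influence, the narrow reading
of the component; it does not decay over intervening unambiguous trials.

The prediction report follows a noisy decision rule on μ_a:
P(predict CW) = σ(logit(μ_a)/ζ) with decision noise ζ > 0 (ζ → 0
deterministic, ζ → ∞ indifferent). μ_a drives both reports; ζ applies to
predictions only. The perception report is sampled from (and scored
against) P(θ₁) itself. The low-level perceptual prediction error is
δ_q = P(θ₁) − y_perception with y ∈ {0, 1}.

## Inversion and model evidence

Each run of each subject is fitted separately. Free parameters — ω₂, ω₃,
ζ (log-space), plus π_a (log-space), w_p, w_s as the variant requires —
are estimated by BFGS on the negative log-joint in estimation space, with
one start at the prior mean plus seeded prior draws (library default 8
restarts; the bulk simulation studies in the tests and the acceptance
script use 2, which the recovery results show is sufficient at this
problem size). The log model evidence is the Laplace approximation
ln p(y|θ*) + ln p(θ*) + (d/2)ln 2π − ½ ln det H, with H the numerical
Hessian at the MAP (central differences, eigenvalues floored at 1e-8).
Per-subject evidence is the sum over runs (independent-runs assumption,
matching per-run inversion followed by subject-level model comparison).
Because the percept history entering priming/sensory memory is the
*observed* response sequence, the per-trial report terms are precomputed
and the likelihood is vectorized; a test asserts its equality with the
readable reference implementation.

Priors (estimation space): ω₂ ~ N(−3, 4), ω₃ ~ N(−6, 4),
ln ζ ~ N(ln 0.1, 1), ln π_a ~ N(0, 1), w_p, w_s ~ N(0, 1). The ω₃ prior is
centred where the volatility walk is slow because level 3 is weakly
identified by 72-trial runs; group-mean ω₃ estimates consequently stay
near −6. A zero prior variance fixes a parameter at its prior mean, in
which case the evidence reduces exactly to the log-likelihood there.

## Group-level model selection and averaging

Random-effects BMS treats each subject's generating model as a draw from
Dirichlet-distributed population frequencies (α₀ = 1 per model).
Variational updates (converged at |Δα| < 1e-6) give expected frequencies
and per-subject posterior model probabilities; exceedance probabilities
are Monte-Carlo estimates over the Dirichlet posterior (default 10⁶
seeded samples; bit-reproducible). The Bayes omnibus risk compares the
random-effects free energy against the equal-frequency null,
BOR = 1/(1 + exp(F₁ − F₀)), and PXP_k = EP_k(1 − BOR) + BOR/K.

Two properties of this scheme are worth knowing. First, the Monte-Carlo
exceedance computation is exact up to sampling error (checked against the
closed-form Dirichlet tail for two models). Second, the variational
posterior itself is overconfident relative to the exact random-effects
posterior when subjects are few: at 3 subjects the exceedance
probabilities can differ from exact-posterior sampling by ~0.1 (the
ranking agrees). This is a property of the standard variational scheme,
not of this implementation, and it disappears as subjects accumulate.

BMA averages each subject's per-model MAP estimates (mean across runs)
weighted by that subject's posterior model probabilities (a "group"
weighting switch uses expected frequencies instead). A parameter absent
from a variant contributes that variant's — or, where the variant never
defines it, the shared default — prior mean; subjects' unfittable cells
are dropped with renormalized weights.

## Behavioral scoring and statistics

Prediction correctness is scored against the presented rotation on
unambiguous trials and against the contingency-implied rotation on
ambiguous ones (no rotation is presented there); a convention switch
scores all trials against the contingency. Congruency is computed over
ambiguous trials only and reported as missing when none exist. Confidence
ratings 1 (very sure) … 4 (very unsure) map affinely to certainty
percent: (4 − r)·100/3. One- and two-sample t tests are two-tailed with
Cohen's d (pooled SD for two samples); the ambiguity × group certainty
design uses a mixed ANOVA; Pearson correlations are corrected within
their declared family by Benjamini–Hochberg FDR (checked against a
literal step-up oracle).

## Synthetic cohorts and what passing tests show

`simulate_cohort` draws per-subject parameters from truncated normals
whose defaults are the study conditions this package models: model A with
π_a ~ 1.37 (SD 0.28), ω₂ ~ −0.72 (SD 0.86), ω₃ ~ −6.23 (SD 0.09),
ζ = 0.1, no lapses. Draws that destabilize the filter on the subject's
schedule are rejected and redrawn (the generative model is only defined on
the filter's stable domain). At these conditions a 26-agent cohort yields
group prediction accuracy ≈ 0.75, unambiguous perception accuracy ≈ 1.0,
and ambiguous congruency ≈ 0.73–0.79 depending on the cohort draw.

The generator emulates the task's statistical structure and the fitted
model family — not everything about real participants. It has no lapses
or attention drift by default, its reports are sampled from the exact
model likelihood, and its between-subject spread comes from point
estimates of group variability; real cohorts are noisier (e.g. their
congruency is somewhat lower and more dispersed than model-A agents at
the same group-mean parameters produce, and their empirical unambiguous
accuracy of ~99% exceeds the 1e-4 report-error floor). Passing tests
therefore demonstrate internal consistency of simulation, inversion and
selection — parameters and models are recovered from data the model
generated — not that the model captures every source of human variance.

## Problem sizes and numerical choices

The recovery study fits 8 variants × 5 runs × 20 subjects (π_a grid
{0.8, 1.2, 1.6}); the cohort pipeline uses 26 subjects. Probabilities are
clamped to [1e-8, 1 − 1e-8]; precisions are floored at 1e-8 before the
instability rejection; BFGS uses gtol 1e-5 with a 1e-6 restart-improvement
tolerance; Hessian steps are 1e-4. Exceedance Monte-Carlo uses 10⁵–10⁶
samples depending on the stage. All stages are deterministic given their
seeds, including byte-identical schedule files.

## Known limitations

* The level-3 precision update of the standard binary HGF can reject
  plausible fast-learning parameter regions on some input sequences;
  rejection is explicit, but fitted ω₂ can be mildly shrunk toward the
  prior as a result.
* Exact response-model parametrizations in the literature vary (e.g.
  whether decision noise also applies to the percept report, or whether
  sensory memory decays); the choices above are documented defaults, not
  the only defensible ones.
* The reader for the original study's deposited behavioral data is an
  explicit stub: the deposit's column layout is undocumented, and the
  adapter must be completed against the actual files before benchmark
  numbers can be recomputed from them.
* Confidence ratings are only descriptively rescaled; no generative model
  of confidence is provided.
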