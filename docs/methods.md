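# Methods

## Task and generative model

One trial has four observation epochs. At τ=1 an auditory cue (brown or
blue noise) maps one-to-one onto the attentional rule. At τ=2 every
modality emits its null level: the delay carries no information, so
whatever the agent knows about the rule must be carried by its own
dynamics. At τ=3 visual and auditory stimuli appear together; under the
rule "attend vision" the visual stimulus is a deterministic image of the
target and the auditory stimulus is uniform noise over {blue, green}, and
vice versa under "attend audition". At τ=4 feedback is *correct* iff the
committed choice matches the target; not choosing counts as incorrect.

Hidden states factorize into rule (2), target (2), and choice (3); the
joint state indexes the likelihood arrays. Transitions are identity
matrices for rule and target — a maximally precise belief that these do
not change within a trial, which is exactly what sustains delay-period
activity — and action-dependent for choice ({stay, pick-blue, pick-green};
picked states are absorbing). Time dependence of the likelihood is stored
as one array per time step rather than through an explicit clock factor;
the two parameterizations have identical marginals because the clock
advances deterministically, and the per-step layout keeps the joint state
small.

Preferences are log-weights over outcomes, all zero except feedback at the
final step: +c for correct, −c for incorrect, 0 for null, with c = 3 nats
by default. c is not dictated by the task; 3 nats makes the correct-choice
policy dominate the posterior at odds e^6 : 1 (posterior ≈ 0.995) while
keeping the softmax well away from saturation, and it is exposed for
sensitivity analyses. The policy space defaults to the three
terminal-choice sequences (stay, stay, {stay | pick-blue | pick-green});
the full 27-policy tree is available for studying premature responding.

## Inference

Beliefs are mean-field: per policy, per factor, per represented time step.
Each update sweep (Gauss–Seidel over time steps and factors) computes a
prediction error

```
ε = w·(ln(B s_prev) + ln(Bᵀ s_next)) + likelihood − v,   v ← v + κ ε,   s = softmax(v)
```

where the likelihood message contracts the observed outcome's
log-likelihood with the concurrent beliefs about every other factor (this
contraction is attentional gain control: a concentrated rule belief
switches which stimulus modality drives the target units), and logs are
floored as `ln(p + e⁻¹⁶)`. Messages from unobserved epochs are omitted.
Beliefs persist across epochs (warm start), so the sweep-resolved traces
concatenate into one within-trial time series.

Defaults: 16 sweeps per epoch, step size κ = 1/3, full-sum message weight
w = 1, policy precision γ = 1. These are declared conventions, chosen
once against three validation targets measured jointly: (i) deterministic
chains must be recovered exactly against an enumeration oracle (full-sum
passes at ≤ 2·10⁻⁷; the half-averaged w = ½ variant, also provided, does
not reach that tolerance because halving also halves the log-floor
penalties); (ii) the delay-period LFP must be quiet relative to the cue
response — at κ = 0.25 the depolarizations have only relaxed to ~1% of
their 16-nat span within an epoch, leaving a spurious delay deflection at
16% of the cue peak, whereas κ = 1/3 leaves 2.7%; (iii) behavioral and CVA
outcomes must be unchanged across the κ grid {0.25, 1/3, 0.4, 0.5}, which
they are.

Per-policy free energy is evaluated at the post-update fixed point as
complexity (divergence of beliefs from their forward message) minus
accuracy (expected log-likelihood of observed outcomes). Expected free
energy over future steps is risk — divergence of predicted outcomes from
the log-preferences — plus ambiguity, the expected entropy of the
likelihood mapping. The policy posterior is `softmax(−γ(F + G))` (a
`prior`-only mode using −G alone is available); the executed action is the
posterior-mass argmax over next moves, with exact ties resolved to the
lowest action index — a documented determinism that matters for lesioned
agents whose values tie exactly.

### Known limitations of the scheme

Two properties one might expect of an idealized variational scheme fail by
construction, and the package reports rather than hides them:

* **Strict within-epoch descent of F.** When decisive evidence arrives
  (epoch 3), the policy-averaged F falls below its fixed-point value
  mid-trajectory and then rises to it (measured: 2.79 → 1.80 → 2.08).
  This is independent of step size — any path ending at the fixed point
  must climb back — and reflects that F with log-of-marginal forward
  messages is not a Lyapunov function of the full-sum updates. Violations
  are recorded in `BeliefState.descent_violations`.
* **Exact equality with smoothed posteriors.** The fixed point
  double-counts evidence through the forward and backward use of
  neighboring marginals, so converged beliefs are slightly overconfident
  relative to exhaustive-enumeration smoothing on stochastic models
  (median worst-KL ≈ 0.002 over random 2-level chains, but a ~10% tail of
  models exceeds 0.05). Deterministic models are recovered exactly. For
  the same reason F can undershoot the exact mean-field evidence bound by
  up to ~0.03 nats on stochastic models (Jensen gap of `ln(B s)`); the
  bound is tight for deterministic models.

For the attention task itself — deterministic mappings throughout — both
issues are immaterial: beliefs converge to the exact posteriors.

## Environment

The generative process mirrors the agent's model, with one deliberate
choice: the unattended (distractor) stimulus defaults to **incongruent** —
it always names the other target, so the two modalities conflict on every
trial and the task cannot be solved without the rule. Independent (uniform,
matching the agent's likelihood exactly) and congruent modes are provided;
the process-equals-model identity is exact in independent mode and is
tested there. Under an independent distractor a rule-lesioned agent would
still solve the ~50% of congruent trials through the rule-averaged
likelihood, putting its error rate near 25% rather than the ~50% that a
complete delay failure produces; the incongruent default is what makes
"no working memory → chance performance" true.

One master seed spawns independent substreams for trial conditions and for
each trial's stimulus noise, so any component can be regenerated alone.

## Electrophysiology

A unit is one (factor, level, represented time) triple. Its firing rate is
the Bayesian-model-average belief — per-policy expectations weighted by the
policy posterior implied by that sweep's F and G, so commitment to a choice
develops continuously rather than jumping at epoch boundaries — and its
LFP is the first difference of the summed policy-averaged depolarization
per factor, optionally smoothed with a centered moving average (off by
default; no band-pass filtering is applied). Rasters render rates as a
density image by default; a seeded Bernoulli point process is the
stochastic alternative. With 16 sweeps per epoch a trial yields 64 bins
per unit.

## Lesions

Lesions are convex mixtures of the relevant arrays toward uniform,
`(1−severity)·array + severity·uniform`, giving a graded severity axis
whose endpoints are the canonical manipulations: lateral = rule
transitions, medial = feedback likelihood (flattened at all time steps;
only the final step matters functionally since earlier feedback is
null-deterministic), extrinsic-rule-cue = the τ=1 cue likelihood, and
flat-preferences = scaling feedback preferences toward zero. All lesioned
models remain valid probability models at every severity. Delay-period
rule concentration is non-increasing in lateral severity.

## Canonical variates analysis

The design matrix has one column per factor: the policy-averaged belief in
the eventually-inferred level (argmax of the final-bin belief about the
last represented step), averaged across represented time steps — 64 rows
for a default trial. Synthetic data are `Y = X M + E` with `M` a standard
normal 3×k mixing matrix (k = 10 by default; the data-matrix width is a
free choice) and noise sd `rms(XM − mean)/snr`. SNR is defined against the
*centered* signal: the analysis centers both matrices, so column means
carry no information, and an SNR measured against the raw signal would
understate the effective noise roughly threefold for these step-like
regressors.

CVA whitens each centered matrix by its SVD and takes the SVD of the
whitened cross-covariance; successive canonical correlations are tested by
Bartlett's χ² approximation to Wilks' Λ (`−(n−1−(p+q+1)/2)·Σ ln(1−r²)`),
counting significant variates as the run of consecutive rejections from
the first. A row-permutation test is available as an assumption-free
alternative. The implementation is cross-checked in the test suite against
an independent generalized-eigenvalue formulation and against
statsmodels' canonical correlations.

## Problem sizes

Default analyses use 64 intact trials, 200 lateral-lesion trials, 50
trials per lesion-battery arm, 100 noise seeds for the CVA recovery, and
200 for its type-I calibration; the enumeration oracle runs on chains with
at most two factors, three levels, and three time steps, where exhaustive
enumeration is exact and fast.
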