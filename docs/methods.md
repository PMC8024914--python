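# Methods

## Task model

A session is defined by its stimulus-introduction plan. Three initial
stimuli occupy the three slots on trial 0; every stimulus lives for a
number of consecutive trials drawn uniformly from {5, …, 9}; when a
stimulus expires the next queued novel stimulus replaces it (simultaneous
expiries are served lowest-id first), and a default session introduces 40
novel stimuli, labelled as two runs split at the 21st introduction. Each
stimulus draws an independent payoff probability p ~ Uniform(0, 1) and
pays $0.30 with probability p, so expected payoffs are uniform on
$0.00–$0.30. The trial count is emergent (≈100 trials by conservation:
3 × trials = Σ lifetimes).

**End-of-session alignment.** Independent lifetimes leave the three slot
streams ragged when the novel queue is exhausted. The generator sets the
session length to the median stream span and adjusts the trailing
lifetimes of the other two streams toward it (latest stimulus first,
clamped to [5, 9]). The two adjustments have opposite signs, so they are
mean-zero across seeds; interior lifetimes remain exactly iid uniform, and
a χ² test over 1,000 sessions confirms uniformity on the non-trailing
lifetimes. The cost is that the last stimulus of each slot may deviate
from its drawn lifetime by a few trials. With a degenerate lifetime range
(min = max) alignment is only possible when the stimulus count divides
evenly across slots; otherwise the generator raises.

Stimulus screen positions are randomized metadata; value learning is
position-independent. The simulator always responds; the data model
carries a `responded` flag because observed data contain omissions, which
are modelled as separate unmodulated regressors downstream.

## Agent and estimation

The agent is the standard delta-rule/softmax pair: only the chosen
stimulus updates, RPE is computed against the pre-feedback EV, and the
softmax acts on the three offered EVs (β = 0 is the uniform policy; the
rule is translation-invariant in the EVs). Novel stimuli initialize at
EV₀ = $0.216 (the group novelty propensity, used as the novelty prior);
the three initial stimuli use the same prior by default. Replaced
stimuli's values are dropped.

Estimation is maximum likelihood. `fit_subject` runs multi-start bounded
L-BFGS-B over (α, β) with α ∈ (0.01, 1], β ∈ [0, 50], and flags
non-identifiability when the profiled likelihood is flat in α (as under
β = 0). `fit_pooled` implements the group-α workflow as a profile
likelihood: for each candidate shared α the trajectories are derived once
and β is concentrated out by 1-D bounded minimization, either one shared β
or one per subject. Trajectories depend only on α and the feedback
history; β enters the likelihood alone. Non-responded trials leave EVs
unchanged and are excluded from the likelihood. Log-sum-exp guards all
softmax evaluations.

Sampling properties worth knowing: in this 3-armed, binary-feedback
design a single ~100-trial session pins α down only to ±0.15 or so
(SD ≈ 0.1 at 500 trials; verified against a grid-search oracle), while
the pooled estimate over 200 sessions has SD ≈ 0.02.

## Novelty propensity and explore trials

A trial is *explore* when the chosen stimulus has lag 2 (second trial
since its introduction); lag counts offered trials, starting at 1. An
offered stimulus with lag ≤ 2 counts as novel; stimuli with lag ≥ 3 are
non-novel (configurable threshold). NP is estimated per subject by
logistic regression of "novel chosen" on the best non-novel EV over
trials that offer a lag-2 stimulus, at the fixed group α; the 50% point
−intercept/slope is reported only when the fit converges with a negative
slope, no separation, and a midpoint inside a plausibility window
([−0.15, 0.45], the EV support padded by half the reward magnitude) —
shallow logistics otherwise place the midpoint arbitrarily far outside
the observable range. A pooled cohort-level variant
(`estimate_np_pooled`) concatenates all subjects' lag-2 trials.

Reliability: at the task's ~30 lag-2 trials per subject, the per-subject
NP estimate has error SD ≈ $0.10, and the mapping from the generative
novelty prior to the logistic midpoint is compressive (slope ≈ 0.3), so
individual differences in NP are measured with low reliability. The
pooled estimator is monotone in the generating prior and is what the
monotone-link property tests use. This limitation propagates: analyses
moderated by estimated NP (e.g. CUDIT-by-NP interactions) are strongly
attenuated at these trial counts.

## fMRI design and GLM

Event timing follows the task structure (1.5 s cue, 1.5 s feedback,
1–2 s uniform jitters). Six event classes are modelled; cue classes carry
the chosen stimulus's pre-choice EV and feedback classes the trial RPE as
parametric modulators. Modulators are mean-centered per run before
convolution, which makes the modulated column orthogonal (in expectation)
to its unmodulated companion. The HRF is the canonical double-gamma
(positive gamma peaking near 6 s, undershoot near 16 s, ratio 1/6,
peak-normalized; parameters configurable), applied at 16× oversampling
and sampled at the TR (default 2 s). Per-run polynomial drift (default
linear) and six motion regressors complete the design; empty event
classes and all-zero columns are dropped with a record.

Censoring: per-volume displacement is the Euclidean norm of the backward
difference of the six motion parameters (rotations in mm-equivalent
units); volumes above 0.5 mm and their predecessors are censored. A
subject is excluded when more than 15% of volumes are censored (exactly
15% is retained). BOLD is converted to percent signal change around the
mean of uncensored volumes, and the GLM is OLS on censored-row-deleted
data; rank deficiency raises with the collinear columns named. The
RPE-modulated feedback betas (explore and non-explore), averaged over ROI
voxels, are the downstream quantities.

## Clinical statistics

- **Rankit**: Φ⁻¹((r − 0.5)/n) with tie-averaged ranks (Blom and Tukey
  offsets available); AUDIT is Rankit-transformed then z-scored, CUDIT
  only z-scored, matching their respective skewness.
- **Partial correlation** by double residualization; df = n − 2 − k.
- **Steiger's z** for dependent correlations sharing one variable, with
  the Dunn–Clark covariance correction.
- **VIF** per column against all others plus intercept.
- **Moderation**: OLS with interaction; Johnson–Neyman boundaries are the
  real roots of the quadratic where the simple-slope t equals the
  two-sided critical t; 0, 1 or 2 boundaries are reported with the
  significance pattern, or a whole-range statement when no real root
  exists.
- **Group ANCOVA**: the two-level (explore/non-explore) within factor is
  handled by the exact mean/difference decomposition — between-subject
  effects on the subject mean, Decision interactions on the difference —
  algebraically equivalent to the mixed-design ANCOVA for two levels.
  Each continuous term is 1 df, so F = t²; partial η² = F/(F + df_resid).
  Missing betas are excluded listwise with counts recorded. Sex is coded
  1 = male. Two-sided tests at α = .05, no multiple-testing correction at
  the ROI level (spatial cluster correction is out of scope).

## Synthetic cohort

The generator emulates the study conditions: n = 128 (78 male), AUDIT
right-skewed (target mean 3.4, SD 5.48, range 0–34), CUDIT mean 9.1, SD
9.37, range 0–32, AUDIT–CUDIT Pearson r ≈ 0.49, females higher on AUDIT
(r ≈ −0.25 against male coding). Scores are gamma-quantile transforms of
a latent bivariate normal (latent ρ = 0.59, mean-centered female shift of
0.6 latent SD — both calibrated once against these targets), rounded and
clipped. Smoking, diagnosis and medication flags are drawn at the study
base rates with mild symptom loadings.

Agent parameters: α is logit-normal around 0.692 with logit-SD 0.15
(between-subject SD ≈ 0.03 — modest by design, since the fixed-group-α
analysis workflow presupposes limited α variation; the pooled shared-α
estimate is a likelihood-weighted compromise that drifts below the mean
under wide heterogeneity). β is log-normal around 8 with a planted
negative AUDIT slope (−0.25 per AUDIT SD on log β), which produces the
behavioral performance deficit (AUDIT vs best-non-novel proportion
r ≈ −0.3 at the default settings). The generative novelty prior varies
with SD $0.08.

Neural RPE scaling is parameterized on the mean/difference scale so that
planted slopes are standardized against the matching noise SD: the
subject-mean γ carries an AUDIT slope of −0.3, and the explore-minus-
non-explore difference carries AUDIT and CUDIT×NP slopes of −0.3 (noise
SD 0.15 on both scales, baseline 0.5 in percent-signal-change units).
ROI BOLD is design × effects plus white noise over 4 voxels at baseline
100. Motion is a 6-parameter random walk with occasional spikes; ~8% of
subjects are "high movers" who tend to fail the 15% censoring rule.

What the generator does **not** emulate: scanner artifacts, physiological
or temporally autocorrelated noise, spatial structure, non-response
trials, session effects, or the diagnosis/medication frequency structure
beyond base rates. Passing tests therefore demonstrate internal
consistency of the pipeline under white-noise conditions, not performance
on real fMRI data.

## Problem sizes and calibration checks

Test and acceptance problem sizes are chosen to give stable Monte-Carlo
estimates at interactive runtimes: 200 agents for group-α recovery
(estimate SD ≈ 0.02 against the ±0.05 criterion), 1,000 statistical-layer
cohorts for the ANCOVA type-I calibration (MC SE ≈ 0.7 points), 50
cohorts for the 80%-power check, 100 GLM replicates for modulated-beta
recovery, and 6 full-chain cohorts (n = 128) combined by Fisher's method
for end-to-end detection of the planted AUDIT-by-Decision effect. The
power and calibration criteria run at the statistical layer (betas and
NP drawn directly) because the full chain adds measurement attenuation —
GLM noise, Rankit-vs-raw mismatch, and above all NP estimation noise —
that is reported here as a property of the method rather than hidden by
larger planted effects.

## Known limitations

- The pooled shared-α MLE is consistent only under homogeneous α; under
  heterogeneity it estimates a likelihood-weighted typical value.
- Per-subject NP is low-reliability at this task length; cohort-level NP
  is well-behaved. CUDIT-by-NP moderation through the full chain is
  essentially undetectable at planted standardized slopes of 0.3.
- The feedback scheme is Bernoulli at a fixed magnitude; graded feedback
  distributions are supported via the pluggable scheme interface but not
  exercised by the pipeline.
- The ANCOVA's mean/difference decomposition is exact only for a
  two-level within factor.
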