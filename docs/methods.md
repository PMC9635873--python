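# Methods

This note records the modeling and statistical choices behind `reachcond`,
in the spirit of a methods appendix: what is computed, under which
assumptions, and where the design was genuinely open.

## Task and coordinate conventions

All simulation and analysis happens in *adaptive-positive* coordinates:
positive heading angle points away from the clamped cursor, the direction
in which implicit adaptation drifts. Raw data files store unoriented angles
(CCW-positive screen coordinates); orientation (sign flip for
counterclockwise-clamp participants) is an analysis step and is never baked
into files. The error-bearing clamp is +15° after orientation; the 0° clamp
and no-feedback probe trials both carry US = 0 in the models and are
distinguished only in metadata. Angles are degrees, times milliseconds.

## Trial schedules

Differential designs interleave CS+ and CS− with exact 50/50 counts per
phase (balanced multiset, shuffled). Because participants must not predict
the next cue from the current one, candidate acquisition sequences are
rejection-sampled until the lag-1 autocorrelation of the ±1-coded CS series
is non-significant. "Non-significant" is operationalized as a two-sided
p > 0.05 from the standard product-moment test (`scipy.stats.pearsonr` of
the sequence against itself shifted by one); the construction (balanced
shuffle before the check) guarantees exact counts regardless of rejection.
The imperative-onset jitter (800–1200 ms) is recorded as schedule metadata
only — no analysis consumes it, and the timing manipulations that
distinguish the delay and simultaneous designs are represented as design
labels, not as a mechanistic time axis.

## Conditioning models

The Rescorla–Wagner implementation treats the movement plan as a CS present
on every trial, alongside the scheduled tone/light cue(s). The response on
trial n is the summed pre-update strength of the present cues (response
precedes learning); all present cues then update from the shared error
λ·US − V_total. Strengths start at zero. The state-space model is the
single-state linear learner x[n+1] = A·x[n] + B·e[n] with e = +15 on
error-clamp trials and 0 otherwise.

Default simulation parameters follow the published simulation settings:
λ = 15°, β = 0.12 (differential) or 0.02 (compound), α_plan = 0.99,
α_tone = α_light = 0.002 (differential) or 0.1 (compound); state space
A = 0.9, B = 0.12. All are overridable. Parameter validation enforces
α, β, A, B ∈ [0, 1] and the stability condition (Σα)·β < 2.

### Two estimators of the Pavlovian effect

The data analysis estimates the Pavlovian effect from Δθ cell means. For
model trajectories the package additionally provides a *counterfactual
contrast*: the mean difference in predicted heading had the current cue
been CS+ vs CS−, holding the learned state fixed. The two agree in
expectation, but only the contrast is exact on a single finite schedule:
for the state-space model Δ[n] = (A−1)x[n−1] + B·e[n−1] contains a
retention-fluctuation term whose subset means differ by O(n^−1/2) sampling
error, so the Δ-cell estimator returns values of order ±0.01–0.05° on a
600-trial schedule even though the model's response to the current cue is
identically zero. Parameter sweeps (`sweep_pavlovian`) therefore default to
the contrast estimator — which is exactly zero for every state-space
parameter combination and strictly positive for Rescorla–Wagner whenever
α_cs, β, λ > 0 — with the Δ-cell estimator available as an option and
averaged over eight participant-unique schedules, mirroring how the
behavioral analysis averages over participants.

## Synthetic participants

The generator wraps a model trajectory in the measurement process the
analyses assume: iid Gaussian motor noise on heading (default σ = 3.5°, a
typical reach-direction variability for planar reaches; the minimal noise
model consistent with the Δ-based analyses), sign-mapping per
counterbalanced clamp direction, outlier injection outside the platform's
screening bounds at the printed per-platform exclusion rates (lab 0.03%,
web 1.35%), truncated-Gaussian RT (293 ± 49 ms on [100, 400]) and MT
(103 ± 31.2 ms on [30, 300]), a configurable fraction of deliberately slow
trials exceeding the RT/MT exclusion thresholds (default 8%, between the
printed lab acquisition and probe rates), and a within-movement feedback
correction (heading at target radius minus heading at 50 ms) drawn as
Gaussian with mean −0.32° and sd 2.92°. Clamp direction alternates across
participants and the CS+ cue every two, so cohorts in multiples of four are
fully crossed; every participant receives a unique schedule seed derived
from the master seed.

What the generator does *not* emulate: baseline reach biases, slow motor
drift or autocorrelated noise, kinematic trajectories, savings or
spontaneous recovery, and any awareness-related heterogeneity. Passing
tests on synthetic cohorts therefore validate the pipeline's mechanics and
statistical identities, not the richness of human data.

## Preprocessing

Orientation, then subtraction of the first acquisition trial's heading
(the baseline reach). Outlier screening runs on the oriented series: lab,
|θ| > 100° or trial-to-trial change > 25°; web, θ outside (−50°, 70°) or
change > 20°. A change-based flag marks the later trial of the pair (the
earlier observation was already accepted). Slow trials (RT > 400 ms and/or
MT > 300 ms, strict inequalities) are excluded from Δ analyses only. Δθ is
valid only when both trials of the pair are unmasked and in the same phase;
the acquisition→probe boundary pair is never analyzed.

## Effect statistics

Per participant, valid Δθ are averaged (mean by default; median optionally,
used for compound probe data whose distributions are skewed) into the 2×2
(previous CS × current CS) table. The group-level two-way repeated-measures
ANOVA is computed from the full within-subject sums-of-squares
decomposition; with two levels per factor each F equals the squared paired
t of the corresponding contrast (asserted in tests, and cross-checked
against `pingouin.rm_anova` as an independent oracle). Partial η² is
SS_effect/(SS_effect + SS_error); contrast summaries report the group mean
difference, its 95% t-interval, and Cohen's d (mean/sd of differences).

Dynamics: acquisition is tiled into 50-trial bins; within each bin, valid
Δθ is regressed on centered codes (CS+ = +1, CS− = −1) for the previous
cue, the current cue, and their product, so main-effect weights read as
half-differences. Rank-deficient bins yield missing weights. Group
inference uses per-participant OLS slopes of each weight series across
bins — a one-sample t per effect and a paired t between the current- and
previous-cue slopes. This is a deliberately simple stand-in for a mixed
model with participant random effects; it matches the per-participant SEM
presentation of the binned weights.

Compound probe analysis: per-participant median Δθ for compound, tone-alone
and light-alone probe trials; Friedman test across the three conditions
(χ² set to 0 when all rows are fully tied), Kendall's W = χ²/(N(k−1)), and
pairwise Wilcoxon signed-rank tests with Bonferroni correction (×3, capped
at 1). Overshadowing is the Pearson correlation between per-participant
tone-alone and light-alone probe responses. The pooled singleton analysis
collapses the two single-cue conditions and reruns the 2×2 ANOVA on
(previous type) × (current type).

## Model fitting

Each model is fit per participant by minimizing the sum of squared
residuals over outlier-screened trials, with the model state propagated
through every trial (including masked ones — the participant experienced
them) and probe trials treated as US = 0 extinction. Bounds follow the
published fitting setup: all parameters in (0, 1) except λ ∈ (−30, 60);
k = 5 for RW and k = 2 for SS, counted as written even though only the
products α_i·β are identifiable. The optimizer is bounded L-BFGS-B
(ftol 1e−12, gtol 1e−9) restarted from 200 uniform random points within
the bounds; the inner simulation loops are numba-compiled, with the plain
reference simulators pinned equal in tests. AIC = n·ln(SSR/n) + 2k on the
residuals; SSR = 0 is treated as degenerate (SSR-only comparison).

Fits use the oriented series *without* baseline subtraction. Both models
pin the initial state at zero, so an additive offset is outside either
model class; subtracting the noisy first-trial heading would inject a
constant −ε₁ offset (sd = σ_m) that biases every fitted parameter. Δ-based
analyses are baseline-invariant, so this choice affects fitting only. A
`baselined=True` option restores the subtracted series for data whose
baseline bias is real rather than noise.

### Identifiability

A Cramér–Rao analysis of the product parameterization (numerical Jacobian,
σ = 3.5°, 800 trials) shows the plan-rate product α_plan·β is well
identified per participant (relative sd ~10–16%), but the cue products are
not: at the low-salience differential setting (α_cs = 0.002) the floor is
~67% relative error even before parameter correlations, and at the salient
setting (α_cs = 0.1) the tone/light products trade off at r ≈ −0.98,
leaving a ~63% floor. Per-participant recovery of α_cs·β to tight
tolerances is therefore not achievable at realistic noise in this design —
fits frequently sit on the α_cs = 0 boundary — and recovery claims in the
test suite are interpreted against this floor. Model *selection*, by
contrast, is reliable in the salient-cue regime: the model-recovery study
(20 replicate 6-participant cohorts per generator, 20 restarts) uses
α_tone = α_light = 0.1 with β = 0.12, where RW-generated cohorts yield
mean ΔAIC ≈ −10³ in favor of RW and state-space-generated cohorts a small
positive ΔAIC (the parameter-count penalty), because at α_cs = 0.002 the
cue component contributes less explainable signal (~27 deg²) than the AIC
penalty for three extra parameters — no selection procedure could prefer
the richer model there.

## Problem sizes and numerical choices

Simulations use the full published session lengths (600 + 200 or 600 + 300
trials). Cohort-level demonstrations use 16 participants (8–16 where only
the mechanics are exercised); the model-recovery study uses 20 cohorts of 6
with 20 restarts. Sweeps use 20×20 grids averaged over 8 schedules.
Degenerate inputs fail loudly: constant sequences in the lag-1 test, empty
Δ cells (named in the error), zero error variance in the ANOVA, SSR = 0 in
AIC, fewer than 10 valid observations in fitting. Diverging parameter
combinations inside the fit objective saturate at a large finite value so
the optimizer retreats rather than propagating non-finite costs.

## Known limitations

The Rescorla–Wagner implementation has no time axis: CS–US interval
effects are representable only as design labels. The generator's iid noise
understates the slow drifts of real reach data, which inflate human SSR
differences relative to synthetic ones. The group slope inference
approximates a mixed model. Reading the original study's raw files is not
supported — the CSV schema here is the package's own.
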