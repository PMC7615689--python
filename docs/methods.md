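# Methods

This note documents the models and procedures implemented in
`streetnav`, the choices that were genuinely open, and what the
synthetic cohort does and does not show.

## Task geometry

Streets are corridors of width 0.06 height units (1.0 = task-window
height). Training streets are straight, length 0.5, angled 0–90° in the
movement frame; width and length are not properties of the paradigm's
design and are package defaults chosen to give Figure-like geometry
with a realistic error range. Transfer streets are a fixed family of
six smooth curves — a diagonal chord plus two sinusoidal deflections
vanishing at the endpoints, with per-curve amplitude/phase constants
hard-wired in `geometry._CURVE_PARAMS` — because only their qualitative
shape is specified by the paradigm; any fixed family of "slightly
different" smooth curves serves, and a literal parameter table keeps
every run reproducible.

Angle grids: a task with minimum angular difference Δ uses the
arithmetic grid containing 0 and 90 with `round(90/Δ)` intervals. For
Δ = 6.425° (which does not divide 90) this yields 15 angles at 6.4286°
spacing; the printed 6.425 is treated as a rounded description of the
uniform 90/14 grid, consistent with the inclusive 0..90 enumeration the
other tasks use.

Coordinates are stored window-centred (origin at the window centre)
rather than bottom-left: the M and L transpositions are then pure sign
flips, which are bit-exact involutions in floating point (x → W − x is
not). `to_window_coords` converts for display/export.

## Scheduling

A session is 100 trials × 6 streets. The schedule must repeat every
street equally often and keep consecutive streets ≥ 22.5° apart — read
conservatively as applying across trial boundaries too. With 600 slots
over grids of 5–46 angles, "equally" means maximally balanced counts
(difference ≤ 1). The sampler builds the sequence from constrained
random permutations of the full grid ("rounds", retried locally on dead
ends, globally up to a bounded restart cap → `SchedulingInfeasibleError`
beyond it) and finally rotates the sequence by a seeded offset so that
round boundaries never align with trial boundaries; without the
rotation, tasks whose grid size equals the trial length would receive
identical six-angle trial compositions and trial difficulty would be
degenerate.

## Control law and simulator

Per frame and axis: velocity += 0.001 height units if the key is held,
−= 0.001 if released, clamped to [0, 0.3]; position moves by the
velocity along the signed axis direction (transposed for M/L).
"Potentiation" is read as linear per-frame accumulation, the simplest
law consistent with the stated constants. Collisions are tested as
distance-to-centreline > width/2 (equivalent to edge intersection for
corridor geometry and much cheaper); a collision resets position to the
street start **and zeroes velocity** — the zero-velocity choice is
ours; carrying velocity would immediately re-collide. Completion
requires the arc-length projection to enter the final 5% of street
length. A 3600-frame cap (60 s) guarantees termination; capped streets
are "aborted", excluded from scoring, and counted in the logs.

## Synthetic participants

The study measured humans; the package needs a generative stand-in.
Agents are closed-loop steering controllers: each frame they project
the cursor onto the centreline, aim at a look-ahead point 0.08 units
ahead, corrupt the ideal heading with zero-mean Gaussian angular noise,
and hold the key on any axis whose speed is below the desired axis
speed. Practice follows two exponentials in the trial index t:

    sigma(t) = motor_noise_sd * exp(-r (t-1)) + noise_floor   [degrees]
    skill(t) = min(1, baseline + gain * (1 - exp(-r (t-1))))

with preferred speed `skill(t) * 0.01` height units/frame — well below
the 0.3 cap, as real cursor speeds are (the cap almost never binds on a
0.5-length street). Population defaults: baseline 0.45 ± 0.10, learning
rate 0.030 ± 0.008 per trial, initial noise 12 ± 3° with a 2° floor;
chosen so that a 100-trial session spans most of the learning curve
(e^-3 ≈ 0.05 of the initial noise remains) and errors sit in the
sub-corridor-width range.

Two controller details matter:

- **Dead zone (0.15).** A key is not pressed when its desired heading
  component is negligible. Movement is one-way per axis, so on an
  axis-aligned street any noise-driven press of the other key would
  ratchet the cursor off the ideal line irrecoverably; humans simply do
  not feather the second key there.
- **Angle-dependent noise.** The steering-noise SD is scaled by a
  bimanual-demand factor: 0.2 at the single-key angles 0°/90°, rising
  along `sin²(2θ) − 0.7 sin⁴(2θ)` (normalised) to a peak near 29°/61°
  and slightly lower at 45°. This reproduces the observed difficulty
  ordering — axis streets easiest, the 10–40° and 50–80° bands hardest —
  which a uniform noise model inverts (see dead zone above).

A 1–3 competence covariate is drawn from a Gaussian copula with rank
correlation 0.4 to baseline skill (configurable; the default mirrors
the direction, not any particular magnitude, of the competence effect).
All group effects are configuration, never code: per-task learning-rate
scaling (default: the least variable task learns fastest), a noise
penalty of 12% per transposed axis on transfer streets, and a transfer
carry-over crediting 30% of the training trials as experience in the
post-transfer trials, discounted 25% per transposed axis.
`EffectConfig.null_world()` zeroes all of them, and the pipeline then
produces null statistics — the property the type-I calibration tests
check.

## Fidelity levels

The pipeline runs at two fidelities sharing the same agent model.
`"kinematic"` simulates every frame; it is exact but a full 450-agent ×
100-trial cohort is millions of street traversals. `"analytic"` (the
default for cohort-level statistics) draws street scores from
closed-form surrogates of the same policy:

    mt  = frames(length, skill) / 60 * exp(0.3 * sigma_eff) * lognormal(0.10)
    err = 0.02 * sigma_eff * lognormal(0.20)

with `sigma_eff` the radian steering noise including the angle factor.
The surrogate constants were calibrated once against the kinematic
simulator at the default policy constants and are fixed. Tests of
kinematic properties always run the frame-level simulator (at smaller
n); cohort-level statistical checks use analytic cohorts. Problem sizes
used by the test-suite: frame-level learning-rate recovery uses 50
agents × 100 trials; the end-to-end frame-level pipeline check uses a
2-agent mini-cohort; analytic checks use the full 450-agent design.

## Scoring

Movement time: (completion frame − onset frame)/60, onset being the
first frame with nonzero velocity. Error: RMS distance to the ideal
line over the movement epoch — including frames of failed attempts
before resets (a wall hit must not be error-free), excluding idle
frames before onset (aligns the error and time windows). Straight
streets use the triangle-area (Heron) construction; curved streets the
nearest neighbour on a 0.002-spaced arc-length resampling (tests verify
both agree to 1e-4 on a 1e-4-spaced line).

Constants a (mean error) and b (mean movement time) come from an
independent synthetic pilot: 5 agents per cell, 75 total, at a seed
derived from the master seed. The PI is computed from trial-level
(street-averaged) movement time and error, not averaged from per-street
PIs. The normalisation is implemented exactly as printed
(Pe = a/error, Pm = mt/b, PI = Pm·Pe); note Pm as printed *rewards*
slower movement, so PI improves with practice only because the error
term dominates. A `pm_inverted` switch (Pm = b/mt) is provided; every
conclusion the pipeline draws is stated in terms robust to this choice,
and all defaults keep the printed form.

## Denoising

Street difficulty is the per-angle grand mean of the dependent variable
(within and across subjects, per training task and variable); trial
difficulty is the mean over the trial's six streets (averaged over
subjects' individual schedules per trial index). The group-level trial
series is regressed on trial difficulty by OLS and the **mean-centred
fitted component** is subtracted from every subject's series. This
removes exactly the difficulty-attributable variation while preserving
the learning trend, loses no data, preserves between-subject variance
at every trial exactly, and is idempotent (the denoised group mean is
OLS-orthogonal to difficulty). The alternative literal reading —
subtracting the regression's raw residuals — would remove the learning
signal itself, contradicting the procedure's stated purpose; it is
available as `mode="residual"` for comparison. Constant difficulty
returns the input unchanged with a warning. Denoising is applied to
movement time and error separately, before PI computation; transfer
trials (one shared curved-street difficulty) are not denoised.

## Statistics

Fits are OLS (statsmodels) with Type-II sums of squares (identical to
the classical decomposition for the balanced synthetic designs, robust
for unbalanced user data). Partial η² = SS_effect/(SS_effect+SS_error);
Cohen's f = √(η²/(1−η²)); Cohen's d uses the pooled SD (two-sample) or
the SD of differences (paired). Post-hoc t-tests are
Bonferroni-adjusted with an **explicit family size** parameter,
defaulting to the number of pairwise comparisons (10 for five groups);
published follow-ups sometimes adjust for the number of levels instead,
which the parameter accommodates. ANCOVA mean-centres covariates before
fitting.

Design planning: the between-factors test of a k-group
repeated-measures ANOVA with m measurements correlating ρ has
noncentrality λ = N·m·f²/(1+(m−1)ρ), df = (k−1, N−k). The required-N
search walks multiples of k and returns the first N whose noncentral-F
power reaches the target. With the pilot η²p = 0.054 the conversion
gives f = 0.23892 — the standard planning workflow feeds the *unrounded*
f into the search (the rounded 0.24 would stop one step earlier, at a
power of 0.9502 vs the 0.95017→0.9566 boundary); the package follows
that workflow.

Bayesian model-averaged ANOVA (BF_exclusion) is deliberately out of
scope: "default priors" are software- and version-specific, so the
number is not reproducible from a specification; the frequentist
interaction test is emitted instead and the analysis dict is the
extension point.

## Known limitations

- Agents are a minimal generative model: no fatigue, no strategy
  shifts, no inter-trial pauses, no input-device latency; the analytic
  fidelity further replaces emergent resets with a lognormal
  movement-time inflation. Passing tests show the pipeline recovers the
  structure this model generates, not that the model captures human
  motor learning.
- The curved-street family is a stand-in with the paradigm's
  qualitative properties; real transfer-street shapes were only ever
  published graphically.
- Effect-size defaults (task learning-rate scaling, flip penalties,
  carry-over) set the *direction* of the published group effects; their
  magnitudes are not calibrated to human data, so simulated F/t/r
  values are not comparable to published ones.
- The ANCOVA follow-up t-tests are plain two-sample tests on
  covariate-adjusted values, not model-based contrasts with the model's
  residual df.
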