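# Methods

## Data model and time base

A stride is one full limb cycle bounded by two successive touchdowns of
a reference limb (default: left hindlimb, overridable per record). Video
frame numbers are the stored ground truth; times are always derived as
`frame / fps`, which avoids floating-point drift in interval arithmetic.
Each limb in a stride carries two touchdowns (TD) and two liftoffs (LO);
validation requires exactly one liftoff strictly inside the touchdown
bracket per limb (contact → swing → next contact). The stride window is
half-open, `[TD₁, TD₂)` of the reference limb: the closing touchdown
belongs to the next stride. Simultaneous events on different limbs are
legal and ordered LH < LF < RH < RF for reproducibility; ties do not
affect any interval metric.

## Spatiotemporal metrics

- **Relative stride length** `λ = L/h`: both distances are digitized in
  the *same* frame, so lens/parallax distortion cancels in the ratio.
- **Stride duration**: per limb `T_i = TD₂ − TD₁`; the stride value is
  the mean over the four limbs.
- **Relative speed** `v = λ / T̄`, in shoulder heights per second. (Field
  convention sometimes labels this "% shoulder height per second"; the
  values reported here are the plain fraction, e.g. 0.55, matching how
  such tables are printed.)
- **Limb phase**: for each ipsilateral pair,
  `((TD_fore − TD_hind) mod T_hind) / T_hind × 100`, using the first
  forelimb touchdown at or after the hindlimb touchdown. The stride's
  limb phase is the mean of the left and right pairs (symmetrical-gait
  assumption); the per-pair values are kept as diagnostics.
- **Duty factor**: `(LO − TD₁) / (TD₂ − TD₁)` with each limb's *own*
  period in the denominator, which keeps the value in (0, 1) even under
  digitization noise.
- **Mean NSL**: time-weighted average of the number of limbs in contact
  over the reference-limb window, computed exactly by an event-boundary
  sweep (no frame sampling). Where the window extends beyond a limb's
  digitized events its contact pattern is extended periodically with
  that limb's own period. When all limbs share one period this gives the
  identity mean NSL = Σ duty factors exactly; the support-time profile
  over 0–4 limbs is returned alongside. A 10⁴-point time-sampling oracle
  cross-checks the sweep in the test suite. (A frame-counting variant
  would differ only at quantization scale; the sweep is the default and
  the only implementation exposed.)
- **Ipsilateral DFAI**: `(L_df − R_df)/(½(L_df + R_df)) × 100` with
  `L_df`, `R_df` the side means of fore- and hindlimb duty factors; for
  animals with a snare-injured right limb the right side is taken first,
  so negative values always mean less contact time on the injured side.
  0 is perfect contralateral symmetry; the index is antisymmetric under
  left–right swap.

## Gait classification

Limb-phase bands are half-open and closed on the left: [0,25) LSLC,
[25,50) LSDC, [50,75) DSDC, [75,100) DSLC. (Prose definitions of the
form "between 25 and 50%" are ambiguous at the boundary; closed-left is
the package convention.) Named gaits — pace, lateral-sequence
singlefoot, trot, diagonal-sequence singlefoot — attach when the phase
is within a tolerance (default 2 percentage points, configurable) of the
anchors 0/25/50/75, with the 0% anchor also matched by wrap-around from
just below 100%. The `DD:PP` descriptor rounds mean duty factor and limb
phase to integer percentages.

## Neck angle

With `u` the back vector (tail base → withers) and `v` the neck vector
(withers → occiput), the angle reported is `180° − θ`, where θ is the
signed turn from `u` to `v` with dorsal (upward) deviation positive.
Collinear landmarks give 180°; dorsal extension lowers the angle,
ventral flexion raises it, placing walking giraffe in the ~177–196°
range. The sign is normalized by travel direction and by the image
y-axis convention (default: y-down pixel coordinates; a flag declares
y-up input), so the same posture yields the same angle whichever way the
animal crosses the frame. The angle is invariant to translation, uniform
scaling and in-plane rotation of all three landmarks.

Per stride, peak dorsal extension is the series minimum, peak ventral
flexion the maximum, and ROM their difference, taken over the
reference-limb stride window (the global extrema, not per half-cycle,
since one extension/flexion pair is reported per stride even though the
neck oscillates twice).

## Synthetic gait generator

The generator emulates 30-fps manual digitization of a lateral-sequence
lateral-couplet walk. Defaults are the healthy adult-giraffe walk:
stride duration 2.31 s, limb phase 13.10 %, duty factor 0.66 on all
limbs, relative stride length 1.26 (630 px over 500 px), neck angle
oscillating twice per stride around 188.45° with 7.45° amplitude, phased
so dorsal peaks fall at early forelimb stance.

Event algebra: reference hind TD at `t₀`; ipsilateral fore at
`t₀ + pT`; contralateral hind at `t₀ + T/2`; its fore at
`t₀ + (0.5 + p)T (mod T)`; liftoffs at `TD + dT`; second touchdowns one
period later. Independent Gaussian timing noise (default SD one frame,
1/30 s — the scale of manual frame picking) is added per event before
nearest-frame quantization; draws violating the stride invariants are
resampled, bounded at 100 attempts.

Per-frame neck angle noise defaults to 0.25°. This is deliberately
sub-degree: per-stride ROM is extracted as max − min over ~69 frames,
which is biased upward by frame noise (extreme-value effect; measured
+0.4° at 0.25° noise but +2.8° at 1° noise), and the generator is
calibrated so the *extracted* ROM matches the emulated ~14.9° scale with
amplitude 7.45°.

Cohorts: four condition groups, one clip per individual, 1–8 strides per
individual (uniform). Per-individual normal random intercepts (SDs:
relative stride length 0.07, stride duration 0.09 s, limb phase 0.9 pp,
neck mean 5°, neck amplitude 1.5°) plus per-stride residual SDs (0.05 /
0.05 s) were chosen so stride-level spreads match the observed scale of
healthy free-ranging data. Snare effects default to −0.18 relative
stride length, −1.3 pp limb phase and a 0.058 duty-factor reduction on
the injured limb (drawn LH:RH:RF = 8:1:4), which propagates to a
−4.5 %-scale DFAI; skin-disease deltas default to zero, matching the
finding that neck-lesion disease leaves limb kinematics unchanged. The
base gait is exactly left–right symmetric, so healthy DFAI is centred on
0; observed healthy populations can sit slightly off 0 (~−1 %), a
biological asymmetry the generator intentionally does not model. All
randomness flows from one integer seed; identical seeds give
byte-identical output files.

What the generator does *not* emulate: continuous locomotion (strides
are generated independently, no shared clock or serial correlation
beyond the individual intercept), speed–stride-length covariation,
perspective distortion, occlusion/missing limbs, or force-level
mechanics. Passing tests therefore demonstrate correctness of the
event-to-metric computations and calibration of the statistical stage
under a faithful idealization — not robustness to every artifact of real
field video.

## Statistical comparison

Per metric: linear mixed model with skin-disease and snare presence as
crossed binary fixed factors (additive, no interaction — condition-cell
mean patterns in this design are additive and the interaction is not
separately identifiable with few snared individuals), a random intercept
for individual-within-clip (the grouping used in the motivating field
protocol; an individual-only grouping is available via a switch), REML
estimation through statsmodels' MixedLM. Relative speed, grand-mean
centred, is a covariate for mean NSL and neck ROM, where speed is a
known confounder.

Satterthwaite denominator df are computed in-package: for a contrast
`L`, `f(θ) = L C(θ) Lᵀ` with `C` the GLS fixed-effect covariance and
`θ = (σ², τ²)`; `df = 2f²/(gᵀA g)` with `g = ∇f` (central differences)
and `A` the inverse Hessian of the profiled REML negative log-likelihood
(evaluated via the closed-form single-random-intercept likelihood). The
implementation agrees with the reference R stack (lme4 + lmerTest +
emmeans) to 3–4 significant figures on a fixed dataset frozen into the
test suite. When τ² is estimated at the boundary or the information
matrix is not positive definite, the model falls back to residual df
with a logged, clearly labelled note — never silently. If statsmodels'
optimizer fails (singular profiled-gradient step on small near-boundary
data), the same REML objective is minimized directly by Nelder–Mead in
log-variance space.

Marginal (Type III) F tests for the two 1-df factors are the squared
Satterthwaite t statistics. EMMs are reported per condition cell at the
covariate grand mean with per-contrast Satterthwaite df for the 95% CIs
(per-contrast rather than a common df, since the contrast variance
profiles differ). The six pairwise condition contrasts are adjusted by
Benjamini–Hochberg FDR. A constant response short-circuits to a
degenerate result (all EMMs equal, all contrasts zero) rather than an
optimizer failure.

Type-I error of the snare test under the null is verified by simulation
(200 cohorts of 16 individuals; the rejection count must fall inside the
99% binomial band around 5%).

## Problem sizes and numerical choices

The acceptance script and cohort-level tests use 10 individuals per
condition with 1–8 strides each (~170 strides), the scale of a
season-long field campaign; the type-I simulation uses 200 cohorts of 16
individuals with 2–4 strides. NSL sweep tolerance against the sampling
oracle is 8×10⁻⁴ (the oracle's own resolution bound at 10⁴ points);
the NSL–duty-factor identity is asserted to 10⁻⁹ on periodic strides.
Satterthwaite df are clipped to [1, n − p]. Named-gait tolerance
defaults to 2 pp. Degenerate inputs (zero-length windows, liftoff on a
touchdown frame, coincident landmarks, non-positive pixel distances)
raise typed validation errors naming the clip, stride and limb.

## Limitations

- Stride-level field data from the motivating study are not
  redistributable with the package, so the study-summary reproduction
  runs against the synthetic cohort's known ground truth (calibrated to
  the published healthy-walk summaries) rather than the original
  digitizations. The printed mean NSL of 2.72 in that study is mutually
  inconsistent with its mean duty factor of 0.66 (the exact identity
  gives 2.64, implying duty ≈ 0.68); the generator follows the duty
  factor, so its cohorts yield NSL ≈ 2.64.
- Only symmetrical walking gaits are modeled; gallop/canter and aerial
  phases are out of scope (NSL handles 0 supports, but the generator
  never produces them).
- The random-effects structure is a single intercept; no serial
  correlation between strides of one clip, and no random slopes.
- Neck analysis assumes near-perpendicular filming; out-of-plane
  rotation biases angular measures and is not corrected.
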