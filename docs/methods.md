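# Methods

## Response model

The analgesic response of one animal to one stimulation session is
modelled on the normalized scale as a product of two logistic functions,

    f(t) = I · S₁(t) · S₂(t),    S_k(t) = 1 / (1 + exp(−a_k (t − t_mid_k))),

with `a₁ > 0` (ramp-up) and `a₂ < 0` (wind-down) in the canonical
orientation.  The model assumes a single biphasic episode: thresholds
rise once after stimulation onset and fall once as the effect washes out.
It does not represent rebound, oscillation, or multiple episodes.

Two structural properties matter for implementation:

- **Exchange symmetry.**  `(I, a₁, a₂, t₁, t₂)` and `(I, a₂, a₁, t₂, t₁)`
  describe the identical curve.  After fitting, a solution that lands in
  the mirrored labeling (falling factor first) is relabeled canonically.
  This changes nothing about the fitted curve or its SSD.
- **Overlap degeneracy.**  When the two phases overlap, the plateau is
  `I·max(S₁S₂) < I` and `(I, t_mid1, t_mid2)` trade off along near-flat
  cost valleys extending to arbitrarily large `|I|`.  Left unchecked, a
  local optimizer can ride these valleys to solutions that fit the data
  but whose parameters no longer mean what the quality-control rules
  assume (see bounds below).

Slopes are evaluated from the analytic derivative
`f′(t) = I[a₁S₁(1−S₁)S₂ + a₂S₂(1−S₂)S₁]` at the fitted midpoints; with
well-separated phases they approach `I·a₁/4` and `I·a₂/4`.  The
normalized FWHM is taken operationally as `(t_mid2 − t_mid1)/T_stim`;
this equals "time above half maximum" only for well-separated phases and
is reported as defined (a negative value marks an inverted fit and is
preserved for quality control, not silently repaired).

## Normalization and fitting

Raw series are normalized as `f_target(t) = (PWT(t) − PWT(0))/PWT(0)`,
which removes baseline differences across animals and makes the target
unitless; `f_target(0) = 0` anchors the left tail.  The cost is the plain
summed squared deviation over the observation grid (t = 0, 15, …,
T_stim + 30; 7 points for the 60-min design, 9 for the 90-min design).

The default optimizer is deterministic trust-region-reflective least
squares started from the fixed initialization `I = 1, a₁ = 0.5,
a₂ = −0.5, t_mid1 = T_stim/4, t_mid2 = t_mid1 + T_stim`
(tolerances 1e−12, ≤10,000 evaluations), with box bounds

| parameter | bounds | rationale |
|---|---|---|
| I | [−2, 2] | normalized responses lie in (0, 2); beyond this, I stops meaning "reversal magnitude", which the exclusion rules rely on |
| a₁, a₂ | [−0.6, 0.6] 1/min | a transition steeper than ~0.6/min completes inside one 15-min sampling interval and its steepness is unidentified |
| t_mid1, t_mid2 | [−T/4, 2T] | midpoints far outside the recorded window are not interpretable |

The bounds keep every quality-control outcome reachable (negative I,
|I| < 0.1, Dev% > 50).  A fully unconstrained Levenberg–Marquardt fit
remains available (`OptimizerSettings(method="lm")`); on sparse noisy
grids it occasionally returns valley solutions with |I| of 10³–10⁶,
which is why it is not the default.  No ordering constraint is placed on
the midpoints.  The returned solution is never worse (in SSD) than the
initialization; optimizer failure is reported via `converged=False`, not
an exception.

Fit quality is `Dev% = 100·SSD/SSR` with `SSR = Σ f_target²`.  For an
identically-zero target the standalone `percent_deviation` raises
(undefined), while the fitting path records NaN/inf and defers to QC,
which catches the case through the small-scale rule.  Exclusion flags:
Dev% > 50; 0 ≤ I < 0.1; I < 0.  Thresholds are parameters of
`apply_exclusion` and the pipeline config.

## Synthetic studies

`simulate_study` emulates the crossover design: every animal receives all
five patterns in a uniformly random session order; per-animal baselines
are Normal(6.0, 0.8²) g truncated above 1 g; the forward model is
`PWT(t) = baseline + max_reversal · f_unit(t) + ε`, ε ~ Normal(0, 1 g²),
optionally snapped to a von Frey filament series
{0.4, 0.6, 1, 1.4, 2, 4, 6, 8, 10, 15} g with the 15 g ceiling.
Quantization is off by default: threshold estimates produced by a
staircase procedure are effectively continuous, and the staircase itself
is out of scope.  Each animal owns a random stream spawned from the
master seed, so enlarging a study never perturbs existing animals.

Default kinetics (per pattern: steepness a₁/a₂ in 1/min, midpoints as
fractions of T_stim, reversal in grams) encode the qualitative pattern
differences the analysis is meant to detect — tonic with the fastest
wash-in, steepest wash-out, earliest decay (half-decay inside a 90-min
stimulation window, reproducing efficacy loss under prolonged constant
stimulation) and smallest FWHM; the four dynamic patterns with gentler
ramps, shallower decays and larger FWHM.  Two deliberate constraints
shaped the defaults:

1. every generative transition spans at least two sampling intervals
   (|a| ≤ 0.4), otherwise fitted steepness — and hence the slope
   summaries — would be unidentified on the 15-min grid;
2. every decay midpoint lies inside the recorded window, otherwise
   t_mid2 is weakly identified and fits become bimodal.

The generator reproduces group-mean magnitudes (baselines ≈ 6 g,
reversals to ≈ 9–13 g) and the designed kinetics, but it does **not**
simulate between-animal kinetic heterogeneity (all animals share a
pattern's shape; only baseline, reversal scale via normalization, and
observation noise vary), tolerance as a mechanism (tonic's decline is
phenomenological, via its decay midpoint), session-order carryover, or
the psychophysical staircase.  Passing tests therefore demonstrate that
the pipeline recovers what this generative family encodes — not that
real data satisfies the model.

### What normalization does to ground truth

Because normalization re-anchors each series at its own t = 0
observation, the normalized target is `(f_unit(t) − f_unit(0))·c`, not
`f_unit(t)` itself.  Generative parameters are exactly recoverable only
when the generative curve is negligible at t = 0 (`a₁·t_mid1 ≳ 9`).
Recovery tests are split accordingly: exact (≤1e−3 relative, in practice
~1e−13) recovery is asserted for quiescent-onset truths and for targets
generated directly from the model; the default study, whose slow
cohort-1 ramps have f_unit(0) up to ~0.1, is checked at the accuracy the
anchoring distortion permits (midpoints to ~1 min).

## Statistics

Cell-level comparisons are paired two-sided t-tests on within-animal
differences at α = 0.05 with no multiplicity correction: each
post-onset timepoint vs baseline (cohorts aggregated over the shared
first hour), each dynamic pattern vs tonic per timepoint, 75 and 90 min
vs 60 min on the 90-min cohort, and per-metric pattern-vs-tonic
contrasts on retained fits.  Zero-variance differences yield a flagged
degenerate result rather than an exception; fewer than three complete
pairs raises an insufficient-data error (reported as "unavailable" in
the slope contrasts, where QC exclusions can empty a cell).  Omnibus
context is provided by a two-way repeated-measures ANOVA
(pattern × time) on complete cases and a mixed-effects model (pattern
fixed, animal random intercept) for fitted metrics; follow-up
comparisons are not gated on the omnibus outcome, matching the reported
comparison structure.  QC exclusions apply to fitted metrics only; raw
threshold comparisons use all animals.

## Identifiability limits worth knowing

With dt = 15 min, a decay completing within ~1 sampling interval leaves
steepness censored at the fit bound, so per-fit wash-out slopes are
noisy and biased toward the bound for *all* patterns; replicate-level
orderings of 23-animal slope means hold in roughly 9 of 10 simulated
studies, not always.  Similarly, four uncorrected null contrasts at
α = 0.05 produce a spurious "decline" somewhere in ~9% of studies by
construction.  Conjunctions of several such directional claims therefore
cannot be expected much above ~85–90% per replicate under these designs;
single-study directional findings on slope₂-type metrics should be read
with that in mind.

## Problem sizes

Default analyses use the full design (23 animals, 115 fits).  Replicated
checks use 50 study replicates for directional reproduction, 500
replicates for type-I calibration, and 200 for recovery/power — sizes at
which Monte-Carlo error is small relative to the margins being asserted.
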