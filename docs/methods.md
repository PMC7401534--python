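# Methods

`keeljump` models one question: how does the positioning of a landing perch —
direction of the jump (up vs down), angle from the horizontal (flat vs steep)
and diagonal distance (50 vs 100 cm) — affect the forces a laying hen's keel
bone absorbs during a platform-to-perch transition, and the bird's
navigation behavior around it. The package contains the full chain: a
factorial study simulator with known ground truth, signal processing of
keel-mounted accelerometer traces into per-jump outcomes, and hierarchical
mixed-model inference with parametric-bootstrap model reduction.

## Study geometry and schedule

The eight conditions form a 2x2x2 factorial: direction x angle class x
diagonal distance. Angles are measured from the horizontal at the take-off
platform: 30°/60° for upward flat/steep, 15°/30° for downward flat/steep.
The platform sits at 60 cm (up) or 135 cm (down) above ground, so the perch
height follows as `platform ± d·sin(angle)` and the horizontal offset as
`d·cos(angle)`. The horizontal reference is the only reading consistent with
the design identity that the up/flat/50 and down/steep/100 perches sit at the
same height (both at 85 cm); the package asserts that identity exactly.

The schedule assigns 40 hens (20 per hybrid, housed 4–7 per pen in 8
single-hybrid pens) to all 8 conditions once each: 320 sessions over 16
testing days, half of the pens per day, 5 jumps per session (the first jump
of each session is acclimation and excluded from analysis by default).
Condition order is counterbalanced with seeded random Latin squares built
within each hybrid stratum, and the within-day testing order rotates across
days to balance time of day. Balance is checked against a tolerance on the
per-condition mean day-slot (default 1.0, scaled up for rosters with fewer
than 8 hens per stratum, where exact balance is impossible) rather than
solved as an exact combinatorial optimum. The protocol being emulated is
described both as spanning 17 days and as 320 sessions on 16 testing days;
the default is 16 testing days, and the discrepancy is surfaced here rather
than resolved.

## Kinetics

Traces are triaxial accelerometry in G units at 800 Hz (sensor range
±200 G). The combined magnitude is `a = sqrt(ax² + ay² + az²)` on the raw
axes — no gravity subtraction, so a resting sensor reads 1 G and all
reported forces include the static component. Force is Newton's second law
`F = m·a` with the hen's mean body mass (average of pre- and post-study
weighings). Per phase (take-off, flight, landing, delimited by the six video
events at millisecond resolution), the peak force is the maximum over the
phase window and the impulse is the literal average-force-times-duration,
`Ī·Δt`, computed as the sample mean times the window length; this agrees with
trapezoidal quadrature to O(1/n) and the tests state that tolerance.

Two unit conventions are exposed. `paper` mode (default) keeps acceleration
in G, so `F = m[kg]·a[G]` — the convention under which a 1.5 kg hen at 100 G
reads "150 N" and typical keel forces are 3–4 "N". `si` mode multiplies by
standard gravity (9.80665), giving physically correct newtons. The two modes
differ by exactly that factor everywhere and are never mixed in one table.
Neither convention is asserted to be the right one; keel forces reported in
this literature at a few "N" are consistent with the kg·G convention.

Event-to-sample alignment uses half-open windows `[start, end)` (each sample
belongs to exactly one phase even when a boundary hits a sample) and
nearest-sample rounding with ties toward the earlier sample. At 800 Hz the
1.25 ms sample period dominates the 1 ms annotation resolution, so
quantization tolerances are expressed as one sample of the peak force. The
video-to-logger clock offset is an explicit per-annotation field; estimating
it from screen timestamps is out of scope.

## Synthetic data

The generator is truth-first. Per-jump latent outcomes are drawn from the
same model family the inference stage fits:

    y* = Xβ + b_pen + b_hen + b_condition(hen) + b_date + ε

on the transformed scale per response, with the balancing indicator drawn
Bernoulli(logit⁻¹) under the same random structure. Default fixed-effect
coefficients are anchored to the magnitudes such an experiment reports (peak forces ≈ 3–4 N in the kg·G convention, take-off impulses
0.27–0.53 N·s, landing impulses 1.4–2.3 N·s, latencies 1–4 s, balancing
17–58%); default SDs put more variance at hen level than pen or date level.
Body-mass distributions (Nick Chick 1.6 ± 0.12 kg, Brown Nick 2.0 ± 0.15 kg)
are invented plumbing — the study reports none — and configurable.
Inverse-scale draws are clamped away from zero (η ≥ 0.08) and latencies
capped at 30 s so far-tail draws stay physically representable; the
truncation probability under the defaults is ≈ 5·10⁻⁴.

Traces are then rendered so that extraction recovers the drawn truth
exactly: each phase carries a baseline load `b ≤ 1 G` plus an analytically
tractable pulse — a flat-topped thrust pulse with quarter-sine ramps for
take-off, squared-sine wing-flap loading in flight, an exponential-decay
impact for landing — whose amplitude and area are solved in closed form from
the drawn peak force and impulse. When the target peak is below the standing
1 G force or the target impulse is small, the phase baseline drops below 1 G
(unloading, as in push-off or flight). Phase durations are drawn lognormally
and then pulled into the feasibility window `I/m ∈ (b·T, b·T + c·A·T)`
implied by the pulse shape. True phase boundaries snap to a 5 ms grid — the
common multiple of the 1 ms annotation resolution and the 1.25 ms sample
period — so millisecond annotations land exactly on samples. Gaussian sensor
noise (default 0.02 G per axis) is added last; samples are clipped to ±200 G
with a flag, and a pulse that would exceed the range warns.

What the generator does *not* emulate — and hence what passing tests do not
show about real recordings: sensor drift and orientation change, vest
movement artifacts, wingbeat harmonics and impact ringing, annotation error
in the video events, unsuccessful landings, and correlation of random
effects across responses (they are drawn independently per response).
Parameter-recovery results therefore certify the estimation machinery, not
robustness to real measurement pathologies.

## Inference

Each response is analyzed separately for upward and downward jumps; no model
pools directions (the angle classes mean different angles in the two
directions). Fixed effects are distance, angle, hybrid and all their
interactions; random intercepts are pen, hen within pen, condition within
hen (the four distance-by-angle cells of that direction), and calendar date
as a crossed factor. The jump index within a session is the finest level: it
is absorbed into the residual for Gaussian responses and kept as an explicit
observation-level intercept for the binomial balancing model (configurable;
with binary data its variance is weakly identified and often estimated at
zero, which is flagged as a singular fit rather than an error).

Transformations before Gaussian fitting: inverse (1/x) for the three peak
forces; log for impulses and latencies, except upward take-off impulse
(untransformed). Effect tables report model-based means per factor
combination, averaged equally over the factors not named, with Wald 95%
intervals back-transformed to the response scale; the inverse transformation
reverses order, so interval endpoints are swapped. Both scales are reported
because for an order-reversing transformation the transformed-scale test and
the response-scale pattern can disagree in marginal cases.

The Gaussian likelihood is written in profiled form: with variance ratios
γ_k = σ_k²/σ_e², both β and σ_e² have closed-form optima, leaving a K ≤ 4
dimensional optimization over log γ with an analytic gradient (L-BFGS-B,
two starts, Nelder-Mead polish on non-convergence; bounded scalar search for
K = 1). All linear algebra runs through a q×q Woodbury factorization
(q = total random levels, 224 at study scale), so one study-scale fit costs
well under a second and bootstrap refits on a fixed design are milliseconds.
ML is used for every model comparison (valid likelihood ratios), REML for
the final reported fit. The binomial model is fitted by Laplace
approximation: joint penalized IRLS for (β, u) inside an outer optimization
over log σ_k², with the observation-level block eliminated by Schur
complement so it costs O(n). Fits agree with lme4's `lmer` (ML and REML) and
`glmer` (Laplace) to ~1e-5 on shared fixtures; that cross-check is part of
the test suite.

Model comparison is a parametric bootstrap: simulate `n_sim` response
vectors from the reduced ML fit (drawing new random effects and residuals,
not conditioning on the estimated ones), refit both models on each, and
report p = (1 + #{T* ≥ T_obs}) / (n_ok + 1) — the finite-sample correction
guarantees p > 0. Refit failures are counted; more than 10% invalidates the
test. Simulation draws are keyed to grouping levels by first appearance in
the data, which makes seeded p-values invariant to relabeling of the levels.
Backward reduction tests every currently droppable term (one not contained
in any retained higher-order term — marginality is enforced), drops the
largest p above α (default 0.05), one term per iteration with refitting
before the next round, and stops when nothing droppable exceeds α; ties
break lexicographically. The default `n_sim` is 1000 for real runs; the
replicated studies in the tests use 200 (calibration) and 99 (reduction
replicates) to keep the suite fast.

Residual diagnostics use simulated quantile residuals: the per-observation
quantile of the observed value among `n_sim` unconditional simulations from
the fitted model, with seeded uniform tie-breaking for discrete responses,
summarized by a Kolmogorov–Smirnov statistic against uniformity. Because
observations sharing a random effect are dependent, the KS p-value is a
screening summary, not an exact test.

## Problem sizes in the replicated studies

- Bootstrap calibration: 200 replicates of a null distance effect on a
  reduced design (8 hens, hen-only random intercept, 64 downward jumps),
  n_sim = 200 per test.
- Coefficient coverage: 200 replicates at full study scale (40 hens, 1280
  non-acclimation jumps, the complete pen/hen/condition/date structure).
  Measured per-coefficient coverage is 92–97%.
- Reduction study: 25 replicates on 12 hens with a strong distance effect
  (0.6 on the log scale) and all other effects null, n_sim = 99. Scored as
  the distance-retention rate across replicates and the discard rate across
  the 100 interaction-replicate decisions. Note that a *fully*
  interaction-free final model occurs in only ~(1−α)⁴ ≈ 81% of replicates
  by construction — each null interaction survives its final test with
  probability ≈ α — so a calibrated reducer cannot be held to a 90%
  all-clean rate; the per-interaction discard rate (expected ≈ 95%) is the
  quantity α actually controls.

These sizes are the package's own choices for desk-scale replication; all
are configurable upward.

## Known limitations

- Wald intervals use a t reference with residual degrees of freedom; no
  Kenward–Roger or Satterthwaite correction (out of scope), so coverage for
  effects that vary only between pens (8 pens) leans on the pen variance
  being small.
- Random slopes, Bayesian fitting and axis-specific analysis are not
  implemented.
- The accelerometer's own 27 g mass does not enter any calculation.
- Flight impulse is computed but excluded from inference by default (flight
  duration is nearly collinear with distance).
- A full-defaults `analyze` run (14 models, study scale, n_sim = 1000) is a
  batch job, not an interactive one; reduce `n_sim` or the responses list
  for exploratory runs.
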