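# Methods

## The linear phase correction model

`groupsync` models an agent synchronising oscillatory movements to a cue
stream as a first-order error-correcting process. Timing events are
cycle-indexed (event *n* of the respondent corresponds to event *n* of its
cue). With cue onsets `c_n`, cue intervals `C_n = c_{n+1} − c_n`, and
observed asynchrony `A_n = t_n − c_n`:

```
I_n     = T_n − α A_n + M_{n+1} − M_n
A_{n+1} = A_n + I_n − C_n
```

* `T_n ~ N(C_n, σ²_T)` — the timekeeper: the internal representation of the
  cue interval. It is referenced to the **current** cue interval, so a
  simulated agent re-locks instantly to a step tempo change and, in a
  noiseless simulation, every position in a chain holds a constant offset to
  the metronome through the change. The consequences of this idealisation
  are discussed under *Limitations*.
* `M_n ~ N(μ_M, σ²_M)` — the motor delay between central command and
  observed event. Only its cycle-to-cycle differences enter the interval
  equation, so `μ_M` (the `mean_motor_delay` parameter) sets the agent's
  stationary mean asynchrony: a positive value reproduces a respondent that
  lags its cue, a negative one a respondent that anticipates it.
* `α` — the correction gain, the proportion of the last asynchrony corrected
  on the current movement; `0 < α < 2` is stable, and `0 < α < 1` is the
  empirically typical range.

Internally the recursion runs on the *delay-adjusted command asynchrony*
(the state excludes the constant `μ_M`); the published initial condition
`A_0 = 0` and the convention "first event at first cue onset + mean motor
delay" are then mutually consistent, and the spec-level examples (noiseless
full correction sits at a constant offset; an initial asynchrony decays
geometrically by `1 − α`) hold exactly.

Two derived results anchor the simulator's correctness and are verified in
the tests against brute-force recursions coded independently there:

* stationary asynchrony variance `(σ²_T + 2α σ²_M) / (α (2 − α))`;
* for α = 0 (uncoupled continuation), interval autocovariances
  `γ₀ = σ²_T + 2σ²_M`, `γ₁ = −σ²_M` (the two-level timekeeper/motor
  decomposition).

### Bimanual agents

Both hands share one timekeeper and one central command; the correction is
driven by the designated hand's asynchrony, and each hand adds independent
motor noise: `t^h_n = s_n + M^h_n`. A useful exact consequence (tested): the
inter-hand interval covariance equals the command interval variance up to a
designated-hand term, and the excess interval variance per hand is
`(2 ± α) σ²_M` — their mean is exactly `2 σ²_M`.

### The dual-cue integrator

The integrator corrects towards two cue streams with separate gains:

```
I_n = T_n − α_L A^L_n − α_R A^R_n + ΔM
```

with `T_n` referenced to a combination of the two cue intervals
(`timekeeper_ref`: `"mean"` default, `"left"`, `"right"`). The current-cycle
interval is used for the reference, consistent with the single-cue agent;
this makes the degenerate cases exact: `α_R = 0` reproduces the single-cue
agent bit-for-bit under the same seed, and identical cues with gains
`(α/2, α/2)` reproduce a single-cue agent with gain α. Stability requires
`0 < α_L + α_R < 2`. With cues out of phase, the stationary mean position
sits between them, weighted by the gains (`x̄ = Δ · α_R / (α_L + α_R)` for a
phase offset Δ). Whether a human integrator keeps one timekeeper or per-side
timekeepers is not established; the single shared timekeeper is the default
and the reference choice is exposed.

### Group topology and simulation order

The standard six-position topology: the leader (LD) paces both arms to the
metronome; each follower responds with its inward hand to the adjacent
member's outward hand (F1L right arm ← LD left arm, F2L right arm ← F1L left
arm, mirrored on the right chain); the integrator's right arm follows F2L's
left arm and its left arm follows F2R's right arm. Positions are simulated
in topological order; cyclic topologies are rejected. Each position draws an
independent RNG stream spawned from the master seed. A stability guard
aborts with the offending cycle index if any command asynchrony exceeds 10
local IOIs (configurable), rather than emitting runaway series.

### Default parameters (the simulated study conditions)

`σ_T = 20 ms`, `σ_M = 8 ms` at every position — within the range reported
for paced movement timing, and deliberately *constant along the chain*: the
increase of measured timing variability down the chain is emergent (each
agent's timekeeper tracks an increasingly noisy cue), not built in. Gains
rise along the chain (LD 0.35, F1 0.6, F2 0.8, IT 0.4 + 0.4), mirroring the
observation that followers of noisier cues correct harder. Mean motor delay
is +25 ms at LD (movement minima lag an auditory metronome), −10 ms at
followers (slight anticipation of a visual cue), 0 at IT. Metronome trials
hold 30 fast (IOI drawn uniformly from 450–550 ms) and 30 slow beats
(720–880 ms) with a step change at beat 31 and counterbalanced order.

## Kinematics

Event times are the minima of the vertical fingertip trajectory, one per
oscillation cycle. The trajectory is low-pass filtered at 20 Hz with a
zero-phase (forward–backward) Butterworth filter of one-way order 2 — the
filter order is not part of the published convention; order 2 run both ways
(effective order 4) is standard practice and configurable. Minima are
detected with a minimum separation (default half the nominal period) and a
prominence threshold (default 25% of the signal range) to reject noise
dimples.

Sub-sample refinement defaults to a least-squares parabola over ±10% of the
local cycle period around each detected minimum, with time rescaled per side
by the adjacent inter-minimum spacings. The rescaling matters at a tempo
change: valley curvature scales as 1/period², so a valley between a fast and
a slow cycle is asymmetric in real time and a symmetric parabola is pulled
several ms towards the flatter side; in cycle-relative time it is symmetric
again. A three-sample parabolic interpolation (`refine="3point"`) is also
available but is noise-limited: at measurement noise of 1–2% of movement
amplitude it locates minima to only ~6–10 ms, because the cosine trough is
flat relative to the filtered noise, whereas the windowed fit pools ~20
samples and reaches ~1–2 ms.

The trajectory synthesiser used for round-trip testing builds one raised-
cosine arc per inter-event cycle (minima exactly at the events, closed
form), extends half a cycle beyond the first and last events so boundary
minima are detectable, and adds white Gaussian sample noise. The documented
noise level for recovery claims is `noise_sd = 1%` of movement amplitude —
generous relative to optical motion capture, whose marker noise is well
below 1% of a 25–40 cm movement. At that level ≥ 99% of events are
recovered within one sample (5 ms) with no spurious detections; at 2% noise
recovery degrades gracefully (~95%). What the synthetic round trip does
*not* probe: non-sinusoidal movement shapes, amplitude drift, marker
dropout, or soft-tissue artefacts.

## Timing analysis

Alignment is nearest-event and one-to-one: each cue event accepts at most
one respondent event within ±`window_fraction` (default 0.5) of the local
cue IOI; conflicts are resolved by smaller |asynchrony| (deterministic,
order-independent), losers become missing pairs, and IMIs spanning a gap are
invalidated, never bridged. On cycle-indexed synthetic data at the default
noise levels the alignment recovers the true cycle pairing ≥ 99.9% of the
time (checked against the simulator's own indices, and against an exhaustive
minimum-cost assignment on small series).

Steady-state masking discards the 2 cycles before and 3 cycles from the
tempo change (both configurable; an optional initial discard defaults to 0),
leaving 55 of 60 cycles in the standard design. Cumulative asynchrony pairs
a position's events against the source metronome instead of its immediate
cue. Summaries report per-group mean and SD of asynchronies and IMIs over
valid cycles only, with explicit zero-count rows for empty groups.

## bGLS estimation

The regression form `I_n = c − α A_n + ε_n` with MA(1) noise is fitted by
iterated generalised least squares: start from ordinary least squares,
estimate residual autocovariances (γ₀, γ₁), clip to the admissible region,
rebuild the tridiagonal covariance, re-solve, and repeat until the relative
coefficient change falls below 1e-6 (max 50 iterations; non-convergence is
flagged and the last iterate returned). The explicit intercept absorbs the
mean produced interval (and, through it, the mean asynchrony term); no
pre-centering is done. Estimates are invariant to translating all event
times.

Numerical choices:

* **Bounds.** `σ̂²_M = clip(−γ̂₁, 0, 0.475 γ̂₀)`, `σ̂²_T = γ̂₀ − 2σ̂²_M`. The
  admissible boundary is γ₁ = −γ₀/2, but that is a unit root at which the
  MA(1) covariance is singular; an iteration that walks onto it effectively
  differences the regressors away and collapses all coefficients to zero.
  Stopping the clip at a 5% timekeeper share of γ₀ keeps the solve
  well-posed and leaves interior fits untouched.
* **Gaps.** Missing cycles break the MA(1) structure, so fits run on
  contiguous valid runs of at least 10 cycles and are pooled by an
  observation-weighted average (flagged `pooled`). In the pipeline, fits are
  computed per tempo segment and per trial-segment, then pooled the same
  way.
* **Degenerate data.** If residual variance is ~0 (noiseless input), the OLS
  solution is exact and returned with zero variance components.

**Bimanual fit.** Both hands' equations are stacked under the
shared-command covariance. Because the stacked design then carries the same
hand-averaged regressor in both blocks, the GLS solution reduces *exactly*
to a single-cue bGLS on the hand-averaged asynchronies and intervals; the
between-hand difference contrast carries no information about the gain (its
apparent slope is pure motor-noise endogeneity), only about motor noise.
Averaging halves the effective motor variance, so the pooled per-hand motor
variance is twice the averaged-series bound estimate, and the left/right
split uses the exact shared-command moments
`Var(A_L − A_R) = σ²_{M,L} + σ²_{M,R}` and
`2 Cov(A_L − A_R, Ā) = σ²_{M,L} − σ²_{M,R}`. This construction is the
package's own; the originally published bimanual stacking lives in
unavailable supplementary material, so this is a documented reconstruction,
validated by parameter recovery on simulated bimanual data.

**Dual-cue fit.** `I_n = c − α_L A^L_n − α_R A^R_n + ε_n`, same MA(1)
treatment, on cycles where both pairings share the respondent event. By
default the observed mean of the two cue intervals is subtracted from `I_n`
first (`subtract_reference=True`): the integrator's timekeeper is referenced
to the combined cue interval, which co-varies with both asynchrony
regressors, and leaving it in the residual attenuates both gains by ~35%
under realistic cue variability. The term vanishes when both cues are
isochronous. Identical cues make the regressors collinear; the fit then
falls back to single-cue and reports the combined gain with a `collinear`
flag. Note the two gains are only identifiable at all when the cue streams
are variable — two perfectly isochronous cues differ by a constant and are
collinear with the intercept by construction.

**Alternative motor-variance estimator.** For continuation-style data the
shared-command decomposition gives `σ̂²_{M,h} = (Var(I_h) − Cov(I_L, I_R))/2`;
negative estimates are clipped to zero and flagged. Under *coupled*
(synchronised) data this estimator is biased by the correction feedback
(the designated hand's exact excess is `(2 ± α) σ²_M`, see above), so it is
documented for continuation use and as a cross-check.

**Pairwise gains.** Every ordered position pair is aligned and fitted
single-cue, yielding a gain matrix with an undefined diagonal; fit failures
become missing cells.

## Nested integration test

Per participant-equivalent and tempo, the per-trial IMI series of IT, F2L
and F2R are intersected on joint validity within each trial and
concatenated across trials (intervals never span trial boundaries). The
reduced model regresses the integrator's mean-centred intervals on one
side's intervals, the full model on both, both without intercept, keeping
the printed degrees of freedom `(p, N − k − p)` with `k = p = 1`:

```
F = ((SSE_reduced − SSE_full) / p) / (SSE_full / (N − k − p))
```

The full model is judged better when p < .01. Both reduction directions are
computed. A perfect reduced fit reports F = 0 (p = 1); a perfect full fit
reports F = +∞ (p = 0); collinear predictors are an error. Mean-centring
consumes one degree of freedom that the printed formula does not count; the
measured null rejection rate at the .01 threshold is 0.0104 rather than
0.0100 at N = 108 (within the binomial error of any feasible check) — the
printed formula is kept deliberately.

## Pipeline

`run_synthetic_experiment` derives every trial's metronome and agent RNG
stream deterministically from the master seed, simulates the group, and runs
the identical analysis path used for external CSV data: alignment of each
respondent hand to its designated cue, steady-state masking, per-tempo
summaries, bimanual bGLS fits per single-cue position, a dual-cue fit at the
integrator (respondent stream = the per-cycle mean of its two hands, the
observable estimate of the shared command), and the nested tests. Outputs
are plain CSV/TSV/JSON with fixed column orders plus a manifest (config
hash, seed, versions); reruns are bit-identical. Role rotation is a
seed-derived permutation per block and affects only labelling. Analysis
problem sizes in the shipped tests and acceptance script (e.g. six replicate
six-trial sessions for the experiment-scale checks; 200 × 500-cycle
replicates for recovery) were chosen as the smallest sizes at which the
Monte-Carlo error is comfortably below the tolerances being checked.

## Limitations

* **Instant tempo tracking.** Referencing the timekeeper to the current cue
  interval makes tempo re-locking immediate and exact. Real performers
  smooth their tempo estimate over several cycles (the discard rule around
  the tempo change exists precisely because adaptation takes a few
  movements). Two measurable consequences on synthetic chain data: (i)
  fitted motor variance absorbs part of the cue's interval jitter and grows
  down the chain, where human data show it flat; (ii) pairwise gains at the
  chain end are pulled towards the source — F2's fitted gain on LD can
  slightly exceed its gain on its actual cue F1 — because the whole chain
  mean-reverts to its anchor, whereas human data show the adjacent-position
  gain always highest. Both are properties of the idealised generative
  choice, not of the estimators.
* The simulator has no period-correction process, no continuous
  (Kuramoto-style) coupling, and no event omissions or extra movements;
  missing-data handling in the analysis stages is exercised synthetically.
* The nested test, like any regression test, detects linear predictive
  improvement, not optimal (variance-weighted) integration; no
  maximum-likelihood integration weighting is implemented.
* Trajectory synthesis is a raised-cosine idealisation; see the kinematics
  section for what the round trip does and does not establish about real
  motion-capture data.
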