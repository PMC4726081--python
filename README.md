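# groupsync

Simulation and analysis of movement synchronisation in small groups arranged
as leader → follower → integrator timing chains.

When several people synchronise rhythmic movements but each can only see one
(or two) other members, timing information degrades as it propagates: every
link adds its own internal-clock and motor noise to the cue it passes on.
`groupsync` provides the full computational toolchain for studying this:

- **Simulation** of whole group sessions under the **linear phase correction
  (LPC)** model with known ground-truth parameters, including bimanual agents
  (two hands sharing one central command) and a dual-cue *integrator* who
  tracks both chain ends simultaneously;
- **Kinematics**: extraction of per-cycle timing events (the lowest vertical
  position of each oscillatory movement) from 200 Hz trajectories via a
  zero-phase low-pass Butterworth filter and sub-sample minimum refinement;
- **Timing analysis**: one-to-one nearest-event alignment of respondent to
  cue events, asynchronies, inter-movement intervals (IMIs), cumulative
  asynchronies against the source metronome, steady-state masking around a
  step tempo change, and tidy summary tables;
- **bGLS estimation** of the LPC parameters — correction gain α, timekeeper
  variance σ²_T, motor variance σ²_M — by bounded generalised least squares,
  with bimanual and dual-cue extensions and an alternative interval-covariance
  motor-variance estimator;
- **Cue-integration testing** via a nested regression F-test: are the
  integrator's intervals better predicted by both chains' interval series
  than by one alone?

## The model

Each agent produces one movement per cue event. With asynchrony
`A_n = t_n − c_n` (negative = respondent early), cue inter-onset intervals
`C_n`, timekeeper samples `T_n ~ N(C_n, σ²_T)` and motor delays
`M_n ~ N(μ_M, σ²_M)`:

```
I_n     = T_n − α · A_n + M_{n+1} − M_n        (produced interval)
A_{n+1} = A_n + I_n − C_n                      (asynchrony recursion)
```

`α` is the correction gain: the fraction of the previous asynchrony corrected
on the current movement (0 = none, 1 = full). The stationary asynchrony
variance is `(σ²_T + 2α σ²_M) / (α (2 − α))`, and for an uncoupled agent
(α = 0) the intervals have the classic two-level timing structure: lag-0
autocovariance `σ²_T + 2σ²_M`, lag-1 `−σ²_M`.

Estimation inverts the regression `I_n = c − α A_n + ε_n`, where `ε_n` is
MA(1) (diagonal `σ²_T + 2σ²_M`, off-diagonal `−σ²_M`), by iterating
generalised least squares with the residual autocovariances re-estimated and
*bounded* to the admissible region each step — this is what keeps both
variance components non-negative. See `docs/methods.md` for the bimanual and
dual-cue extensions and all numerical choices.

## Worked example

```bash
python examples/03_fit_lpc.py
```

simulates 500 synchronisation cycles at α = 0.5, σ_T = 20 ms, σ_M = 10 ms
and recovers the parameters:

```
   parameter    truth     bGLS
       alpha    0.500    0.491
  sigma_T ms     20.0     19.6
  sigma_M ms     10.0      9.7
OLS alpha on the same data: 0.636 (biased upward: it ignores the MA(1) noise structure)
```

The bounded-GLS estimate is close to truth while ordinary least squares on
the same data overestimates the gain by ~0.14 — the motor-noise difference
term correlates with the asynchrony regressor, and only the MA(1) weighting
corrects for it.

The other examples cover the chain simulator (`01`), the kinematics
round-trip (`02`), dual-cue fitting plus the nested integration test (`04`),
and a full six-trial session through the whole pipeline (`05`). Each prints
the numbers it computes and a one-line interpretation.

A thin CLI mirrors the pipeline for shell use:

```bash
groupsync simulate --out run/ --seed 7
groupsync analyze --events run/events.csv --metronome run/metronome.csv --out reanalysis/
groupsync report run/
```

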