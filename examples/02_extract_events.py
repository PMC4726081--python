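"""Round-trip the kinematics stage: build a noisy fingertip trajectory whose
minima are known timing events, filter it, and recover the events.
"""

import numpy as np

from groupsync import (
    AgentParams,
    FilterSpec,
    extract_events,
    generate_metronome,
    lowpass_filter,
    simulate_agent,
    synthesize_trajectory,
)

metronome = generate_metronome(seed=5)
agent = simulate_agent(
    metronome.onsets, AgentParams(alpha=0.5, sigma_T2=400.0, sigma_M2=64.0), seed=5
)

# 200 Hz vertical trajectory, measurement noise 1% of movement amplitude
traj = synthesize_trajectory(agent, amplitude=100.0, fs=200.0, noise_sd=1.0, seed=5)
filtered = lowpass_filter(traj, FilterSpec(cutoff_hz=20.0, order=2))
events = extract_events(filtered, min_separation_ms=0.5 * metronome.ioi_fast)

errors = np.array([np.min(np.abs(events.times - t)) for t in agent.times])
print(f"true events: {len(agent)}, detected: {len(events)}")
print(f"median |error|: {np.median(errors):.2f} ms, max: {errors.max():.2f} ms")
print(f"within one sample (5 ms): {np.mean(errors <= 5.0):.1%}")
print("The zero-phase 20 Hz Butterworth filter plus windowed-parabola minima "
      "refinement\nrecovers event times at sub-sample precision.")
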