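"""Simulator unit and property tests.

The stationary-variance and covariance-structure checks compare the simulator
against independently coded brute-force recursions written directly in the
tests, not against the library's own code paths.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from groupsync import (
    AgentParams,
    GroupTopology,
    SimulationInstabilityError,
    chain_topology,
    default_agent_params,
    generate_metronome,
    simulate_agent,
    simulate_bimanual_agent,
    simulate_group,
    simulate_integrator,
    synthesize_trajectory,
)
from groupsync.timing import align_events

from conftest import isochronous


def stationary_var(alpha, sigma_T2, sigma_M2):
    """Closed-form stationary asynchrony variance of a single-cue agent."""
    return (sigma_T2 + 2 * alpha * sigma_M2) / (alpha * (2 - alpha))


def brute_force_asynchronies(alpha, sigma_T, sigma_M, n, seed, ioi=500.0):
    """Independent oracle: direct recursion on observed asynchronies,
    A_{n+1} = (1-a) A_n + T' + dM, coded without the library."""
    r = np.random.default_rng(seed)
    tdev = r.normal(0, sigma_T, n)
    m = r.normal(0, sigma_M, n + 1)
    A = np.empty(n + 1)
    A[0] = 0.0
    for k in range(n):
        A[k + 1] = (1 - alpha) * A[k] + tdev[k] + m[k + 1] - m[k]
    return A


class TestMetronome:
    def test_standard_design(self):
        m = generate_metronome(seed=3)
        assert m.n_beats == 60
        d = np.diff(m.onsets)
        assert np.allclose(d[:30], d[0]) and 450 <= d[0] <= 550
        assert np.allclose(d[30:], d[30]) and 720 <= d[30] <= 880
        assert m.change_index == 31
        assert list(m.tempo_labels()[28:32]) == ["fast", "fast", "slow", "slow"]

    def test_degenerate_ranges_force_onsets(self):
        m = generate_metronome((500, 500), (800, 800), 2, 2, "fast_slow", seed=0)
        assert np.allclose(m.onsets, [0, 500, 1000, 1800])

    def test_slow_fast_order(self):
        m = generate_metronome((500, 500), (800, 800), 2, 2, "slow_fast", seed=0)
        assert np.allclose(m.onsets, [0, 800, 1600, 2100])
        assert m.change_index == 3

    def test_deterministic_under_seed(self):
        a = generate_metronome(seed=11)
        b = generate_metronome(seed=11)
        assert np.array_equal(a.onsets, b.onsets)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ioi_fast_range": (550, 450)},
            {"ioi_fast_range": (-10, 500)},
            {"n_fast": 0},
            {"order": "interleaved"},
        ],
    )
    def test_invalid_configuration(self, kwargs):
        with pytest.raises(ValueError):
            generate_metronome(**kwargs, seed=0)

    @given(
        ioi_fast=st.floats(400, 600),
        ioi_slow=st.floats(700, 900),
        n_fast=st.integers(1, 40),
        n_slow=st.integers(1, 40),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_schedule_invariants(self, ioi_fast, ioi_slow, n_fast, n_slow, seed):
        m = generate_metronome(
            (ioi_fast, ioi_fast), (ioi_slow, ioi_slow), n_fast, n_slow,
            "fast_slow", seed,
        )
        assert m.n_beats == n_fast + n_slow
        assert m.change_index == n_fast + 1
        d = np.diff(m.onsets)
        assert np.all(d > 0)
        assert np.allclose(d[:n_fast], ioi_fast)


class TestSingleCueAgent:
    def test_noiseless_full_correction(self):
        m = isochronous(20)
        p = AgentParams(alpha=1.0, mean_motor_delay=30.0)
        ev = simulate_agent(m.onsets, p, seed=0)
        assert np.allclose(ev.times, m.onsets + 30.0)

    def test_geometric_decay_of_initial_asynchrony(self):
        m = isochronous(6)
        ev = simulate_agent(
            m.onsets, AgentParams(alpha=0.5), seed=0, initial_asynchrony=40.0
        )
        assert np.allclose(ev.times - m.onsets, [40, 20, 10, 5, 2.5, 1.25])

    def test_deterministic_under_seed(self, noisy_params):
        m = isochronous(50)
        a = simulate_agent(m.onsets, noisy_params, seed=5)
        b = simulate_agent(m.onsets, noisy_params, seed=5)
        assert np.array_equal(a.times, b.times)

    def test_unstable_parameters_raise_with_cycle(self):
        m = isochronous(2000)
        with pytest.raises(SimulationInstabilityError, match="cycle"):
            simulate_agent(m.onsets, AgentParams(alpha=2.4, sigma_T2=400.0), seed=1)

    def test_stationary_variance_matches_closed_form_and_oracle(self):
        alpha, sT2, sM2 = 0.5, 400.0, 100.0
        theory = stationary_var(alpha, sT2, sM2)
        # independent brute-force recursion
        A = brute_force_asynchronies(alpha, 20.0, 10.0, 200_000, seed=42)
        assert np.var(A[100:]) == pytest.approx(theory, rel=0.03)
        # library simulator
        m = isochronous(50_000)
        ev = simulate_agent(
            m.onsets, AgentParams(alpha=alpha, sigma_T2=sT2, sigma_M2=sM2), seed=9
        )
        emp = np.var((ev.times - m.onsets)[100:])
        assert emp == pytest.approx(theory, rel=0.03)

    def test_continuation_has_wing_kristofferson_structure(self):
        # alpha = 0: intervals are timekeeper + differenced motor noise
        m = isochronous(200_001)
        p = AgentParams(alpha=0.0, sigma_T2=400.0, sigma_M2=100.0)
        ev = simulate_agent(m.onsets, p, seed=3, guard_factor=1e12)
        I = ev.intervals() - np.mean(ev.intervals())
        g0 = np.mean(I * I)
        g1 = np.mean(I[:-1] * I[1:])
        assert g0 == pytest.approx(600.0, rel=0.05)
        assert g1 == pytest.approx(-100.0, rel=0.05)

    def test_latents_reproduce_events(self, noisy_params):
        m = isochronous(30)
        ev, lat = simulate_agent(m.onsets, noisy_params, seed=2, return_latents=True)
        assert lat.timekeeper.size == 29
        assert np.allclose(
            ev.times, m.onsets + lat.command_asynchrony + lat.motor["only"]
        )


class TestBimanualAgent:
    def test_zero_motor_noise_gives_identical_hands(self):
        m = isochronous(40)
        p = AgentParams(alpha=0.6, sigma_T2=225.0, sigma_M2=0.0)
        L, R = simulate_bimanual_agent(m.onsets, p, seed=4)
        assert np.array_equal(L.times, R.times)

    def test_same_seed_bit_identical(self):
        m = isochronous(40)
        p = AgentParams(alpha=0.6, sigma_T2=225.0, sigma_M2=64.0)
        a = simulate_bimanual_agent(m.onsets, p, seed=4)
        b = simulate_bimanual_agent(m.onsets, p, seed=4)
        assert np.array_equal(a[0].times, b[0].times)
        assert np.array_equal(a[1].times, b[1].times)

    def test_interhand_interval_moments(self):
        # cov(I_L, I_R) ~ Var(shared command interval); Var(I_h) - cov ~ 2 sigma_M2
        m = isochronous(100_001)
        sM2 = 100.0
        p = AgentParams(alpha=0.5, sigma_T2=400.0, sigma_M2=sM2)
        L, R = simulate_bimanual_agent(m.onsets, p, seed=8)
        IL, IR = L.intervals(), R.intervals()
        cov = np.cov(IL, IR)[0, 1]
        excess_l = np.var(IL, ddof=1) - cov
        excess_r = np.var(IR, ddof=1) - cov
        # correction feeds the designated (left) hand's motor noise back into
        # the shared command: excess is (2+a) sM2 for it, (2-a) sM2 for the
        # other hand, so the hand-mean excess is exactly 2 sM2
        alpha = 0.5
        assert excess_l == pytest.approx((2 + alpha) * sM2, rel=0.10)
        assert excess_r == pytest.approx((2 - alpha) * sM2, rel=0.10)
        assert 0.5 * (excess_l + excess_r) == pytest.approx(2 * sM2, rel=0.08)


class TestIntegrator:
    def test_zero_right_gain_collapses_to_single_cue(self):
        m = isochronous(200)
        p2 = AgentParams(alpha_left=0.5, alpha_right=0.0, sigma_T2=400, sigma_M2=100)
        p1 = AgentParams(alpha=0.5, sigma_T2=400, sigma_M2=100)
        dual = simulate_integrator(m.onsets, m.onsets + 100.0, p2, seed=6)
        single = simulate_agent(m.onsets, p1, seed=6)
        assert np.allclose(dual.times, single.times)

    def test_identical_cues_merge_gains(self):
        m = isochronous(200)
        p2 = AgentParams(alpha_left=0.25, alpha_right=0.25, sigma_T2=400, sigma_M2=100)
        p1 = AgentParams(alpha=0.5, sigma_T2=400, sigma_M2=100)
        dual = simulate_integrator(m.onsets, m.onsets, p2, seed=6)
        single = simulate_agent(m.onsets, p1, seed=6)
        assert np.allclose(dual.times, single.times)

    def test_mean_asynchrony_weighted_towards_higher_gain(self):
        # cues 100 ms out of phase; stationary mean position solves
        # aL * x + aR * (x - 100) = 0  =>  x = 100 * aR / (aL + aR)
        m = isochronous(100_000)
        aL, aR = 0.3, 0.4
        p = AgentParams(alpha_left=aL, alpha_right=aR, sigma_T2=400, sigma_M2=100)
        ev = simulate_integrator(m.onsets, m.onsets + 100.0, p, seed=10)
        mean_async_left = np.mean((ev.times - m.onsets)[100:])
        expected = 100.0 * aR / (aL + aR)
        assert mean_async_left == pytest.approx(expected, abs=2.0)
        assert expected > 50.0  # pulled towards the higher-gain cue

    def test_truncates_to_shorter_cue(self):
        m = isochronous(50)
        p = AgentParams(alpha_left=0.3, alpha_right=0.3, sigma_T2=100, sigma_M2=25)
        ev = simulate_integrator(m.onsets, m.onsets[:30] + 40.0, p, seed=1)
        assert len(ev) == 30


class TestGroup:
    def test_zero_noise_constant_offsets(self, standard_metronome):
        topo = chain_topology()
        params = {
            pos: p.replace(sigma_T2=0.0, sigma_M2=0.0)
            for pos, p in default_agent_params().items()
        }
        trial = simulate_group(topo, params, standard_metronome, seed=0)
        for (pos, hand), series in trial.events.items():
            offsets = series.times - standard_metronome.onsets
            assert np.allclose(offsets, offsets[0], atol=1e-9), (pos, hand)

    def test_event_counts_conserved(self, standard_metronome):
        trial = simulate_group(
            chain_topology(), default_agent_params(), standard_metronome, seed=1
        )
        for series in trial.events.values():
            assert len(series) == standard_metronome.n_beats

    def test_same_seed_identical(self, standard_metronome):
        a = simulate_group(
            chain_topology(), default_agent_params(), standard_metronome, seed=2
        )
        b = simulate_group(
            chain_topology(), default_agent_params(), standard_metronome, seed=2
        )
        for key in a.events:
            assert np.array_equal(a.events[key].times, b.events[key].times)

    def test_cyclic_topology_rejected(self):
        topo = GroupTopology(
            {"A": [("left", "B", "left")], "B": [("left", "A", "left")]}
        )
        with pytest.raises(ValueError, match="cyclic"):
            topo.validate()

    def test_imi_variability_grows_along_chain(self):
        # homogeneous parameters: the cue stream gets noisier down the chain
        topo = chain_topology()
        params = {
            pos: AgentParams(
                alpha=0.7, sigma_T2=225.0, sigma_M2=64.0,
                alpha_left=None if pos != "IT" else 0.35,
                alpha_right=None if pos != "IT" else 0.35,
            )
            for pos in topo.positions
        }
        for pos in topo.positions:
            if pos == "IT":
                params[pos] = AgentParams(
                    alpha_left=0.35, alpha_right=0.35, sigma_T2=225.0, sigma_M2=64.0
                )
        sds = {"LD": [], "F1": [], "F2": []}
        for seed in range(30):
            m = generate_metronome(seed=seed)
            trial = simulate_group(topo, params, m, seed=seed)
            sds["LD"].append(np.std(np.diff(trial.events[("LD", "left")].times[:30])))
            sds["F1"].append(np.std(np.diff(trial.events[("F1L", "right")].times[:30])))
            sds["F2"].append(np.std(np.diff(trial.events[("F2L", "right")].times[:30])))
        assert np.mean(sds["LD"]) < np.mean(sds["F1"]) < np.mean(sds["F2"])


class TestTrajectory:
    def test_minima_exactly_at_events(self):
        events = np.array([400.0, 1200.0, 2000.0])
        traj = synthesize_trajectory(events, amplitude=50.0, fs=200.0)
        for e in events:
            lo = np.searchsorted(traj.time_ms, e - 300)
            hi = np.searchsorted(traj.time_ms, e + 300)
            tmin = traj.time_ms[lo + np.argmin(traj.z[lo:hi])]
            assert abs(tmin - e) <= 5.0  # one sample at 200 Hz

    def test_zero_amplitude_flat(self):
        from groupsync.kinematics import extract_events

        traj = synthesize_trajectory([0.0, 500.0, 1000.0], amplitude=0.0)
        assert np.allclose(traj.z, 0.0)
        assert len(extract_events(traj)) == 0

    def test_requires_two_events(self):
        with pytest.raises(ValueError):
            synthesize_trajectory([100.0])

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="sampling rate"):
            synthesize_trajectory([0.0, 10.0, 20.0], fs=100.0)


def test_alignment_recovers_cycle_pairing_on_synthetic_chain():
    """Nearest-event alignment finds the true cycle pairing on cycle-indexed
    data with moderate noise (the simulator's own indices are the oracle)."""
    hits = total = 0
    for seed in range(50):
        m = generate_metronome(seed=seed)
        p = AgentParams(alpha=0.6, sigma_T2=400.0, sigma_M2=64.0)
        ev = simulate_agent(m.onsets, p, seed=seed)
        paired = align_events(m.onsets, ev.times)
        matched = np.isfinite(paired.resp_times)
        total += m.n_beats
        hits += int(np.sum(paired.resp_times[matched] == ev.times[matched]))
    assert hits / total >= 0.999
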