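"""Synthetic movement-synchronisation experiments with known ground truth.

Agents produce one timing event per cue event (cycle-indexed) according to the
linear phase correction (LPC) model: each produced interval equals a noisy
timekeeper interval minus a gain ``alpha`` times the previous asynchrony, plus
the difference of two motor delays,

    I_n = T_n - alpha * A_n + M_{n+1} - M_n,
    A_{n+1} = A_n + I_n - C_n,

where ``C_n`` are the cue inter-onset intervals, ``T_n ~ N(C_n, sigma_T^2)``
and ``M_n ~ N(mean_motor_delay, sigma_M^2)``.  Internally the recursion runs
on the delay-adjusted command asynchrony (the state excludes the constant mean
motor delay), so a noiseless fully-correcting agent sits at a constant offset
of ``mean_motor_delay`` from its cue.  The stationary asynchrony variance of a
single-cue agent is (sigma_T^2 + 2*alpha*sigma_M^2) / (alpha * (2 - alpha)).

Bimanual agents share one central command and one timekeeper; the two hands
differ only by independent motor noise.  The integrator corrects against two
cue streams at once with separate gains.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "EventSeries",
    "MetronomeSchedule",
    "AgentParams",
    "GroupTopology",
    "SimulatedTrial",
    "Trajectory",
    "SimulationInstabilityError",
    "chain_topology",
    "generate_metronome",
    "simulate_agent",
    "simulate_bimanual_agent",
    "simulate_integrator",
    "simulate_integrator_bimanual",
    "simulate_group",
    "synthesize_trajectory",
    "default_agent_params",
]

METRONOME = "metronome"
#: canonical chain positions: leader, two followers per side, integrator
POSITIONS = ("LD", "F1L", "F1R", "F2L", "F2R", "IT")


class SimulationInstabilityError(RuntimeError):
    """Raised when an agent's asynchrony diverges beyond the stability guard."""

    def __init__(self, cycle: int, asynchrony: float, limit: float):
        self.cycle = cycle
        super().__init__(
            f"simulated asynchrony |{asynchrony:.1f}| ms exceeded the stability "
            f"guard ({limit:.1f} ms) at cycle {cycle}; parameters are unstable"
        )


def _as_times(x) -> np.ndarray:
    t = np.asarray(x.times if isinstance(x, EventSeries) else x, dtype=float)
    if t.ndim != 1:
        raise ValueError("event times must be one-dimensional")
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("event times must be strictly increasing")
    return t


@dataclass(frozen=True)
class EventSeries:
    """Ordered timing-event times (ms) for one effector."""

    times: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "times", _as_times(self.times))

    def __len__(self) -> int:
        return self.times.size

    def intervals(self) -> np.ndarray:
        """Inter-movement intervals I_n = t_{n+1} - t_n (ms)."""
        return np.diff(self.times)


@dataclass(frozen=True)
class MetronomeSchedule:
    """Pacing-cue onsets: an isochronous fast and slow segment with a step change.

    ``change_index`` is the 1-based beat index of the first post-change beat
    (beat 31 for the standard 30+30 design).
    """

    onsets: np.ndarray
    ioi_fast: float
    ioi_slow: float
    n_fast: int
    n_slow: int
    order: Literal["fast_slow", "slow_fast"]
    change_index: int

    def __post_init__(self):
        object.__setattr__(self, "onsets", _as_times(self.onsets))

    @property
    def n_beats(self) -> int:
        return self.onsets.size

    def events(self) -> EventSeries:
        return EventSeries(self.onsets, label=METRONOME)

    def tempo_labels(self) -> np.ndarray:
        """Per-beat tempo label ('fast'/'slow')."""
        first, second = (
            ("fast", "slow") if self.order == "fast_slow" else ("slow", "fast")
        )
        lab = np.empty(self.n_beats, dtype=object)
        lab[: self.change_index - 1] = first
        lab[self.change_index - 1 :] = second
        return lab


@dataclass(frozen=True)
class AgentParams:
    """Ground-truth LPC parameters of one agent.

    ``alpha`` is the phase-correction gain (dimensionless); dual-cue agents
    use ``alpha_left``/``alpha_right`` instead.  Variances are in ms²;
    ``mean_motor_delay`` (ms) is the constant offset between central command
    and observed event and sets the agent's mean asynchrony.
    """

    alpha: float | None = None
    alpha_left: float | None = None
    alpha_right: float | None = None
    sigma_T2: float = 0.0
    sigma_M2: float = 0.0
    mean_motor_delay: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.sigma_T2 < 0 or self.sigma_M2 < 0:
            raise ValueError("variances must be non-negative")
        for a in (self.alpha, self.alpha_left, self.alpha_right):
            if a is not None and not np.isfinite(a):
                raise ValueError("gains must be finite")

    @property
    def sigma_T(self) -> float:
        return float(np.sqrt(self.sigma_T2))

    @property
    def sigma_M(self) -> float:
        return float(np.sqrt(self.sigma_M2))

    def replace(self, **kw) -> "AgentParams":
        return dataclasses.replace(self, **kw)


#: cue_map entry: (respondent hand, cue position, cue hand); cue hand None = metronome
CueEntry = tuple[str, str, str | None]


@dataclass(frozen=True)
class GroupTopology:
    """Who watches whom: position -> list of (respondent hand, cue position, cue hand)."""

    cue_map: Mapping[str, Sequence[CueEntry]]

    @property
    def positions(self) -> tuple[str, ...]:
        return tuple(self.cue_map)

    def simulation_order(self) -> list[str]:
        """Positions sorted so every cue is simulated before its respondent."""
        graph = {
            pos: {cp for _, cp, _ in entries if cp != METRONOME}
            for pos, entries in self.cue_map.items()
        }
        try:
            return list(TopologicalSorter(graph).static_order())
        except CycleError as err:
            raise ValueError(f"cyclic cue topology: {err.args[1]}") from err

    def validate(self) -> None:
        for pos, entries in self.cue_map.items():
            if not entries:
                raise ValueError(f"position {pos!r} has no cue")
            for _, cue_pos, _ in entries:
                if cue_pos != METRONOME and cue_pos not in self.cue_map:
                    raise ValueError(f"{pos!r} cued by unknown position {cue_pos!r}")
        self.simulation_order()


def chain_topology() -> GroupTopology:
    """The standard six-person topology: a leader paced by the metronome, two
    two-person follower chains, and an integrator watching both chain ends.

    Each follower responds with the inward hand and cues the next person with
    the outward hand; the integrator's right arm follows the left chain's end
    (F2L left arm) and its left arm follows the right chain's end (F2R right
    arm).
    """
    return GroupTopology(
        {
            "LD": [("left", METRONOME, None), ("right", METRONOME, None)],
            "F1L": [("right", "LD", "left")],
            "F1R": [("left", "LD", "right")],
            "F2L": [("right", "F1L", "left")],
            "F2R": [("left", "F1R", "right")],
            "IT": [("right", "F2L", "left"), ("left", "F2R", "right")],
        }
    )


def generate_metronome(
    ioi_fast_range: tuple[float, float] = (450.0, 550.0),
    ioi_slow_range: tuple[float, float] = (720.0, 880.0),
    n_fast: int = 30,
    n_slow: int = 30,
    order: Literal["fast_slow", "slow_fast"] = "fast_slow",
    seed: int | np.random.Generator | None = None,
) -> MetronomeSchedule:
    """Draw one fast and one slow IOI uniformly from their ranges and lay out
    an isochronous two-segment schedule with a step tempo change.
    """
    for lo, hi in (ioi_fast_range, ioi_slow_range):
        if not (0 < lo <= hi):
            raise ValueError(f"invalid IOI range ({lo}, {hi})")
    if n_fast <= 0 or n_slow <= 0:
        raise ValueError("beat counts must be positive")
    rng = np.random.default_rng(seed)
    ioi_fast = float(rng.uniform(*ioi_fast_range))
    ioi_slow = float(rng.uniform(*ioi_slow_range))
    if order == "fast_slow":
        iois = [ioi_fast] * n_fast + [ioi_slow] * n_slow
        change = n_fast + 1
    elif order == "slow_fast":
        iois = [ioi_slow] * n_slow + [ioi_fast] * n_fast
        change = n_slow + 1
    else:
        raise ValueError(f"unknown order {order!r}")
    onsets = np.concatenate([[0.0], np.cumsum(iois[:-1])])
    return MetronomeSchedule(
        onsets=onsets,
        ioi_fast=ioi_fast,
        ioi_slow=ioi_slow,
        n_fast=n_fast,
        n_slow=n_slow,
        order=order,
        change_index=change,
    )


def _rng_for(params: AgentParams, seed) -> np.random.Generator:
    if seed is not None:
        return np.random.default_rng(seed)
    return np.random.default_rng(params.seed)


def _guard_limit(iois: np.ndarray, guard_factor: float) -> float:
    return guard_factor * float(np.median(iois))


def _run_lpc(
    cue: np.ndarray,
    alpha: float,
    t_dev: np.ndarray,
    m_dev_corr: np.ndarray,
    initial_asynchrony: float,
    guard_factor: float,
) -> np.ndarray:
    """Core LPC recursion on the delay-adjusted command asynchrony.

    ``m_dev_corr`` holds the motor deviations of the hand whose asynchrony the
    agent corrects against.  Returns the command-asynchrony state S (one entry
    per cue event); event times are cue + mean_delay + S + per-hand motor dev.
    """
    C = np.diff(cue)
    n = cue.size
    limit = _guard_limit(C, guard_factor)
    S = np.empty(n)
    S[0] = initial_asynchrony
    for k in range(n - 1):
        perceived = S[k] + m_dev_corr[k]
        T = C[k] + t_dev[k]
        S[k + 1] = S[k] + T - alpha * perceived - C[k]
        if abs(S[k + 1]) > limit:
            raise SimulationInstabilityError(k + 1, S[k + 1], limit)
    return S


@dataclass(frozen=True)
class AgentLatents:
    """Latent draws retained for oracle testing."""

    timekeeper: np.ndarray  # T_n (ms), length n-1
    motor: Mapping[str, np.ndarray]  # per-hand motor delays M_n (ms), length n
    command_asynchrony: np.ndarray  # S_n (ms), length n


def simulate_agent(
    cue,
    params: AgentParams,
    *,
    seed=None,
    initial_asynchrony: float = 0.0,
    guard_factor: float = 10.0,
    return_latents: bool = False,
):
    """Simulate a single-handed LPC agent, one event per cue event."""
    c = _as_times(cue)
    if c.size < 2:
        raise ValueError("cue must contain at least 2 events")
    if params.alpha is None:
        raise ValueError("single-cue agent requires params.alpha")
    rng = _rng_for(params, seed)
    t_dev = rng.normal(0.0, params.sigma_T, c.size - 1)
    m_dev = rng.normal(0.0, params.sigma_M, c.size)
    S = _run_lpc(c, params.alpha, t_dev, m_dev, initial_asynchrony, guard_factor)
    times = c + params.mean_motor_delay + S + m_dev
    out = EventSeries(times)
    if return_latents:
        lat = AgentLatents(
            timekeeper=np.diff(c) + t_dev,
            motor={"only": params.mean_motor_delay + m_dev},
            command_asynchrony=S,
        )
        return out, lat
    return out


def simulate_bimanual_agent(
    cue,
    params: AgentParams,
    *,
    designated: Literal["left", "right"] = "left",
    seed=None,
    initial_asynchrony: float = 0.0,
    guard_factor: float = 10.0,
    return_latents: bool = False,
):
    """Simulate a two-handed agent: one shared timekeeper and command, the
    correction driven by the designated hand's asynchrony, and independent
    motor noise per hand.
    """
    c = _as_times(cue)
    if c.size < 2:
        raise ValueError("cue must contain at least 2 events")
    if params.alpha is None:
        raise ValueError("bimanual agent requires params.alpha")
    rng = _rng_for(params, seed)
    t_dev = rng.normal(0.0, params.sigma_T, c.size - 1)
    m_left = rng.normal(0.0, params.sigma_M, c.size)
    m_right = rng.normal(0.0, params.sigma_M, c.size)
    m_corr = m_left if designated == "left" else m_right
    S = _run_lpc(c, params.alpha, t_dev, m_corr, initial_asynchrony, guard_factor)
    left = EventSeries(c + params.mean_motor_delay + S + m_left)
    right = EventSeries(c + params.mean_motor_delay + S + m_right)
    if return_latents:
        lat = AgentLatents(
            timekeeper=np.diff(c) + t_dev,
            motor={
                "left": params.mean_motor_delay + m_left,
                "right": params.mean_motor_delay + m_right,
            },
            command_asynchrony=S,
        )
        return left, right, lat
    return left, right


TimekeeperRef = Literal["mean", "left", "right"]


def _integrator_command(
    cl: np.ndarray,
    cr: np.ndarray,
    alpha_l: float,
    alpha_r: float,
    t_dev: np.ndarray,
    m_dev_corr_l: np.ndarray,
    m_dev_corr_r: np.ndarray,
    timekeeper_ref: TimekeeperRef,
    guard_factor: float,
) -> np.ndarray:
    """Dual-cue LPC recursion; returns central command times (excl. motor delay)."""
    n = cl.size
    CL, CR = np.diff(cl), np.diff(cr)
    if timekeeper_ref == "mean":
        ref = 0.5 * (CL + CR)
    elif timekeeper_ref == "left":
        ref = CL
    elif timekeeper_ref == "right":
        ref = CR
    else:
        raise ValueError(f"unknown timekeeper_ref {timekeeper_ref!r}")
    limit = _guard_limit(ref, guard_factor)
    total = alpha_l + alpha_r
    s = np.empty(n)
    # start on the cue the agent weights more (reduces start-up transient and
    # collapses exactly to the single-cue agent when one gain is zero)
    s[0] = (alpha_l * cl[0] + alpha_r * cr[0]) / total if total > 0 else 0.5 * (
        cl[0] + cr[0]
    )
    for k in range(n - 1):
        al = s[k] + m_dev_corr_l[k] - cl[k]
        ar = s[k] + m_dev_corr_r[k] - cr[k]
        T = ref[k] + t_dev[k]
        s[k + 1] = s[k] + T - alpha_l * al - alpha_r * ar
        drift = s[k + 1] - 0.5 * (cl[min(k + 1, n - 1)] + cr[min(k + 1, n - 1)])
        if abs(drift) > limit:
            raise SimulationInstabilityError(k + 1, drift, limit)
    return s


def simulate_integrator(
    cue_left,
    cue_right,
    params: AgentParams,
    *,
    timekeeper_ref: TimekeeperRef = "mean",
    seed=None,
    guard_factor: float = 10.0,
    return_latents: bool = False,
):
    """Simulate a dual-cue agent correcting against two cue streams at once.

    The produced interval is I_n = T_n - alpha_L*A^L_n - alpha_R*A^R_n + dM,
    with the timekeeper drawn around a reference interval combining the two
    cue streams (default: their mean).  Cycle counts are reconciled by
    truncation to the shorter cue.
    """
    cl, cr = _as_times(cue_left), _as_times(cue_right)
    if cl.size < 2 or cr.size < 2:
        raise ValueError("both cues must contain at least 2 events")
    n = min(cl.size, cr.size)
    cl, cr = cl[:n], cr[:n]
    if params.alpha_left is None or params.alpha_right is None:
        raise ValueError("integrator requires alpha_left and alpha_right")
    rng = _rng_for(params, seed)
    t_dev = rng.normal(0.0, params.sigma_T, n - 1)
    m_dev = rng.normal(0.0, params.sigma_M, n)
    s = _integrator_command(
        cl, cr, params.alpha_left, params.alpha_right,
        t_dev, m_dev, m_dev, timekeeper_ref, guard_factor,
    )
    times = s + params.mean_motor_delay + m_dev
    out = EventSeries(times)
    if return_latents:
        lat = AgentLatents(
            timekeeper=t_dev,  # deviations; reference interval depends on setting
            motor={"only": params.mean_motor_delay + m_dev},
            command_asynchrony=s - 0.5 * (cl + cr),
        )
        return out, lat
    return out


def simulate_integrator_bimanual(
    cue_left,
    cue_right,
    params: AgentParams,
    *,
    timekeeper_ref: TimekeeperRef = "mean",
    seed=None,
    guard_factor: float = 10.0,
):
    """Two-handed dual-cue integrator sharing one command.

    The right hand tracks the left cue and the left hand tracks the right cue
    (the crossed arrangement of the standard topology): each cue's correction
    term uses the asynchrony of the hand that responds to that cue.  Returns
    ``(left_hand, right_hand)`` event series.
    """
    cl, cr = _as_times(cue_left), _as_times(cue_right)
    if cl.size < 2 or cr.size < 2:
        raise ValueError("both cues must contain at least 2 events")
    n = min(cl.size, cr.size)
    cl, cr = cl[:n], cr[:n]
    if params.alpha_left is None or params.alpha_right is None:
        raise ValueError("integrator requires alpha_left and alpha_right")
    rng = _rng_for(params, seed)
    t_dev = rng.normal(0.0, params.sigma_T, n - 1)
    m_left = rng.normal(0.0, params.sigma_M, n)
    m_right = rng.normal(0.0, params.sigma_M, n)
    s = _integrator_command(
        cl, cr, params.alpha_left, params.alpha_right,
        t_dev, m_right, m_left, timekeeper_ref, guard_factor,
    )
    left = EventSeries(s + params.mean_motor_delay + m_left)
    right = EventSeries(s + params.mean_motor_delay + m_right)
    return left, right


@dataclass(frozen=True)
class SimulatedTrial:
    """One simulated group trial with ground truth."""

    metronome: MetronomeSchedule
    events: Mapping[tuple[str, str], EventSeries]  # (position, hand) -> events
    truth: Mapping[str, AgentParams]
    topology: GroupTopology
    internal: Mapping[str, AgentLatents] | None = None


def default_agent_params(positions: Sequence[str] = POSITIONS) -> dict[str, AgentParams]:
    """Realistic per-position defaults for the standard chain.

    Timekeeper and motor SDs are 20 and 8 ms everywhere (within the range
    reported for paced movement timing); correction gain rises along the chain
    as observed in visually-coupled chains, and the integrator splits a
    comparable total gain over its two cues.  The leader lags its auditory
    metronome by a small positive offset; followers lead their visual cue
    slightly.
    """
    base = dict(sigma_T2=400.0, sigma_M2=64.0)
    table = {
        "LD": AgentParams(alpha=0.35, mean_motor_delay=25.0, **base),
        "F1L": AgentParams(alpha=0.6, mean_motor_delay=-10.0, **base),
        "F1R": AgentParams(alpha=0.6, mean_motor_delay=-10.0, **base),
        "F2L": AgentParams(alpha=0.8, mean_motor_delay=-10.0, **base),
        "F2R": AgentParams(alpha=0.8, mean_motor_delay=-10.0, **base),
        "IT": AgentParams(alpha_left=0.4, alpha_right=0.4, mean_motor_delay=0.0, **base),
    }
    return {p: table[p] for p in positions}


def simulate_group(
    topology: GroupTopology,
    params: Mapping[str, AgentParams],
    metronome: MetronomeSchedule,
    seed=None,
    *,
    timekeeper_ref: TimekeeperRef = "mean",
    guard_factor: float = 10.0,
    keep_latents: bool = False,
) -> SimulatedTrial:
    """Simulate every position of a group trial in topological order.

    Single-cue positions are simulated as bimanual agents (shared command,
    independent per-hand motor noise); a position with two cue entries is a
    bimanual integrator.  Per-position RNG streams are spawned
    deterministically from ``seed`` unless an agent carries its own seed.
    """
    topology.validate()
    order = topology.simulation_order()
    missing = [p for p in order if p not in params]
    if missing:
        raise ValueError(f"missing AgentParams for positions {missing}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(order))
    events: dict[tuple[str, str], EventSeries] = {}
    latents: dict[str, AgentLatents] = {}

    def cue_series(cue_pos: str, cue_hand: str | None) -> EventSeries:
        if cue_pos == METRONOME:
            return metronome.events()
        return events[(cue_pos, cue_hand)]

    for pos, child in zip(order, children):
        p = params[pos]
        rng = np.random.default_rng(p.seed if p.seed is not None else child)
        entries = topology.cue_map[pos]
        try:
            if len(entries) == 1 or all(
                e[1:] == entries[0][1:] for e in entries
            ):  # single cue stream (possibly listed once per hand)
                resp_hand, cue_pos, cue_hand = entries[0]
                cue = cue_series(cue_pos, cue_hand)
                res = simulate_bimanual_agent(
                    cue, p, designated=resp_hand, seed=rng,
                    guard_factor=guard_factor, return_latents=keep_latents,
                )
                left, right = res[0], res[1]
                if keep_latents:
                    latents[pos] = res[2]
            elif len(entries) == 2:
                by_hand = {h: (cp, ch) for h, cp, ch in entries}
                if set(by_hand) != {"left", "right"}:
                    raise ValueError(
                        f"dual-cue position {pos!r} must cue one entry per hand"
                    )
                # "left cue" = the cue the RIGHT hand responds to in the crossed
                # standard layout; map by the responding hand instead.
                cue_for_right = cue_series(*by_hand["right"])
                cue_for_left = cue_series(*by_hand["left"])
                pp = p if p.alpha_left is not None else p.replace(
                    alpha_left=p.alpha / 2, alpha_right=p.alpha / 2, alpha=None
                )
                left, right = simulate_integrator_bimanual(
                    cue_for_right, cue_for_left, pp, timekeeper_ref=timekeeper_ref,
                    seed=rng, guard_factor=guard_factor,
                )
            else:
                raise ValueError(f"position {pos!r} has {len(entries)} cue entries")
        except SimulationInstabilityError as err:
            raise RuntimeError(f"position {pos!r}: {err}") from err
        events[(pos, "left")] = left
        events[(pos, "right")] = right

    return SimulatedTrial(
        metronome=metronome,
        events=events,
        truth=dict(params),
        topology=topology,
        internal=latents if keep_latents else None,
    )


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled vertical position of one effector."""

    time_ms: np.ndarray
    z: np.ndarray
    effector: str = ""

    def __post_init__(self):
        t = np.asarray(self.time_ms, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if t.shape != z.shape or t.ndim != 1:
            raise ValueError("time and z must be 1-D arrays of equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "z", z)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        if self.time_ms.size < 2:
            raise ValueError("need at least 2 samples to define a rate")
        return 1000.0 / float(self.time_ms[1] - self.time_ms[0])


def synthesize_trajectory(
    events,
    amplitude: float = 1.0,
    fs: float = 200.0,
    noise_sd: float = 0.0,
    seed=None,
    effector: str = "",
) -> Trajectory:
    """Build a smooth oscillatory trajectory whose minima sit exactly at the
    event times: one raised-cosine arc per inter-event cycle, plus optional
    additive Gaussian sample noise.
    """
    t_ev = _as_times(events)
    if t_ev.size < 2:
        raise ValueError("need at least 2 events to synthesize a trajectory")
    min_ioi = float(np.min(np.diff(t_ev)))
    if fs <= 2 * 1000.0 / min_ioi:
        raise ValueError("sampling rate below twice the movement frequency")
    dt = 1000.0 / fs
    # half-cycle lead-in/out so the first and last minima are interior
    lead = 0.5 * (t_ev[1] - t_ev[0])
    tail = 0.5 * (t_ev[-1] - t_ev[-2])
    t = np.arange(t_ev[0] - lead, t_ev[-1] + tail + 0.5 * dt, dt)
    idx = np.clip(np.searchsorted(t_ev, t, side="right") - 1, 0, t_ev.size - 2)
    span = t_ev[idx + 1] - t_ev[idx]
    phase = (t - t_ev[idx]) / span
    z = 0.5 * amplitude * (1.0 - np.cos(2.0 * np.pi * phase))
    if noise_sd > 0:
        z = z + np.random.default_rng(seed).normal(0.0, noise_sd, z.size)
    return Trajectory(time_ms=t, z=z, effector=effector)
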