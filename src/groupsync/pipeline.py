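"""End-to-end synthetic experiments and the analysis chain.

``run_synthetic_experiment`` generates a complete multi-trial session for the
six-position chain (metronomes, LPC agents, role rotation), then pushes the
events through the same analysis path used for external data:
alignment -> steady-state masking -> descriptive summaries -> bGLS fits
(bimanual per position, dual-cue at the integrator) -> nested integration
tests on concatenated trials.  Everything is deterministic under the master
seed, and all outputs are plain CSV/TSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as gio
from .bgls import LPCFit, fit_bimanual, fit_dual_cue
from .integration import both_directions, concatenate_trials
from .kinematics import FilterSpec, extract_events, lowpass_filter
from .simulate import (
    METRONOME,
    AgentParams,
    EventSeries,
    GroupTopology,
    MetronomeSchedule,
    Trajectory,
    chain_topology,
    default_agent_params,
    generate_metronome,
    simulate_group,
)
from .timing import PairedTiming, align_events, steady_state_mask, summarize

__all__ = ["ExperimentConfig", "ExperimentResult", "run_synthetic_experiment", "run_analysis"]


@dataclass
class ExperimentConfig:
    """Design and analysis settings of one synthetic session.

    Defaults mirror the standard design: 6 blocks of 6 trials, 30 fast +
    30 slow beats per trial with the fast IOI drawn from 450-550 ms and the
    slow IOI from 720-880 ms, presentation order counterbalanced within each
    block, roles rotated across blocks, and the two cycles before / three
    cycles from the tempo change discarded from analysis.
    """

    n_blocks: int = 6
    trials_per_block: int = 6
    ioi_fast_range: tuple[float, float] = (450.0, 550.0)
    ioi_slow_range: tuple[float, float] = (720.0, 880.0)
    n_fast: int = 30
    n_slow: int = 30
    agent_params: dict[str, AgentParams] = field(default_factory=default_agent_params)
    timekeeper_ref: str = "mean"
    window_fraction: float = 0.5
    n_pre: int = 2
    n_post: int = 3
    initial_discard: int = 0
    filter_cutoff_hz: float = 20.0
    filter_order: int = 2
    master_seed: int = 0

    def topology(self) -> GroupTopology:
        return chain_topology()

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(cutoff_hz=self.filter_cutoff_hz, order=self.filter_order)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["agent_params"] = {k: dataclasses.asdict(v) for k, v in self.agent_params.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        d["agent_params"] = {
            k: AgentParams(**v) for k, v in d.get("agent_params", {}).items()
        }
        for key in ("ioi_fast_range", "ioi_slow_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class ExperimentResult:
    """Bundle of all experiment outputs (tidy tables plus raw objects)."""

    config: ExperimentConfig
    events: pd.DataFrame
    metronomes: pd.DataFrame
    paired: pd.DataFrame
    fits: pd.DataFrame
    nested: pd.DataFrame
    summary: pd.DataFrame
    roles: pd.DataFrame | None = None
    truth: Mapping[str, AgentParams] | None = None
    manifest: dict | None = None

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gio.write_table(self.events, out / "events.csv")
        gio.write_table(self.metronomes, out / "metronome.csv")
        gio.write_table(self.paired, out / "paired_timing.csv")
        gio.write_table(self.fits, out / "fits.tsv")
        gio.write_table(self.nested, out / "nested_tests.tsv")
        gio.write_table(self.summary, out / "summary.tsv")
        if self.roles is not None:
            gio.write_table(self.roles, out / "roles.csv")
        if self.truth is not None:
            (out / "truth.json").write_text(gio.truth_to_json(self.truth))
        if self.manifest is not None:
            (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return out


def _hand_mean_series(left: EventSeries, right: EventSeries) -> EventSeries:
    """Per-cycle average of the two hands — the best observable estimate of
    the shared central command, used as the integrator's respondent stream."""
    n = min(len(left), len(right))
    return EventSeries(0.5 * (left.times[:n] + right.times[:n]))


def _trial_mask(schedule: MetronomeSchedule, cfg: ExperimentConfig) -> np.ndarray:
    mask = steady_state_mask(schedule, cfg.n_pre, cfg.n_post)
    if cfg.initial_discard > 0:
        mask[: cfg.initial_discard] = False
    return mask


def _analyze_trial(
    trial_id: int,
    schedule: MetronomeSchedule,
    events: Mapping[tuple[str, str], EventSeries],
    topology: GroupTopology,
    cfg: ExperimentConfig,
):
    """Per-trial alignment and masking.

    Returns (paired rows, per-position cue pairings for fitting, per-position
    cycle-indexed IMI arrays for the nested test).
    """
    mask = _trial_mask(schedule, cfg)
    tempo = schedule.tempo_labels()
    paired_frames = []
    pairings: dict[str, dict] = {}
    imi_arrays: dict[str, np.ndarray] = {}

    def lookup(cue_pos, cue_hand) -> EventSeries:
        if cue_pos == METRONOME:
            return schedule.events()
        return events[(cue_pos, cue_hand)]

    for pos in topology.positions:
        entries = topology.cue_map[pos]
        hand_pairs: dict[str, PairedTiming] = {}
        for resp_hand, cue_pos, cue_hand in entries:
            cue = lookup(cue_pos, cue_hand)
            p = align_events(cue, events[(pos, resp_hand)], cfg.window_fraction)
            p = p.apply_mask(mask[: p.cycles.size])
            p.tempo = tempo[: p.cycles.size]
            hand_pairs[resp_hand] = p
            paired_frames.append(
                p.to_frame(
                    trial_id=trial_id, position=pos, hand=resp_hand,
                    cue=f"{cue_pos}/{cue_hand or ''}".rstrip("/"), measure="cue",
                )
            )
        # cumulative asynchrony against the source metronome (first entry's hand)
        resp_hand0 = entries[0][0]
        pc = align_events(
            schedule.onsets, events[(pos, resp_hand0)], cfg.window_fraction
        ).apply_mask(mask)
        pc.tempo = tempo
        paired_frames.append(
            pc.to_frame(
                trial_id=trial_id, position=pos, hand=resp_hand0,
                cue=METRONOME, measure="cumulative",
            )
        )

        if len(entries) == 2 and len({e[1:] for e in entries}) == 2:
            # dual-cue position: re-align the hand-mean stream to both cues
            resp = _hand_mean_series(events[(pos, "left")], events[(pos, "right")])
            by_hand = {h: (cp, ch) for h, cp, ch in entries}
            pl = align_events(lookup(*by_hand["right"]), resp, cfg.window_fraction)
            pr = align_events(lookup(*by_hand["left"]), resp, cfg.window_fraction)
            pl = pl.apply_mask(mask[: pl.cycles.size])
            pr = pr.apply_mask(mask[: pr.cycles.size])
            pl.tempo = tempo[: pl.cycles.size]
            pr.tempo = tempo[: pr.cycles.size]
            pairings[pos] = {"kind": "dual", "left": pl, "right": pr}
            imi_source = pl
        else:
            # single-cue position: align BOTH hands to the shared cue for the
            # bimanual fit (the second hand mirrors the respondent hand's cue)
            resp_hand, cue_pos, cue_hand = entries[0]
            cue = lookup(cue_pos, cue_hand)
            other = "right" if resp_hand == "left" else "left"
            if other not in hand_pairs:
                po = align_events(cue, events[(pos, other)], cfg.window_fraction)
                po = po.apply_mask(mask[: po.cycles.size])
                po.tempo = tempo[: po.cycles.size]
                hand_pairs[other] = po
            pairings[pos] = {
                "kind": "bimanual",
                "left": hand_pairs["left"],
                "right": hand_pairs["right"],
            }
            imi_source = hand_pairs[resp_hand]

        imis = np.append(imi_source.imis, np.nan)
        ok = imi_source.valid & np.isfinite(imi_source.resp_times)
        usable = np.append(ok[:-1] & ok[1:], False)
        imi_arrays[pos] = np.where(usable, imis, np.nan)

    return paired_frames, pairings, imi_arrays


def _fit_position_tempo(
    pairings: list[dict], tempo_masks: list[np.ndarray]
) -> LPCFit:
    """Fit one position at one tempo by concatenating its trials' pairings.

    Per-trial segments stay separate runs inside the fit (the valid mask has a
    forced break between trials), preserving the MA(1) structure within runs.
    """
    kind = pairings[0]["kind"]
    parts_l, parts_r = [], []
    for pairing, tm in zip(pairings, tempo_masks):
        for key, acc in (("left", parts_l), ("right", parts_r)):
            p: PairedTiming = pairing[key]
            pm = p.apply_mask(tm[: p.cycles.size])
            acc.append(pm)
    pl = _concat_pairings(parts_l)
    pr = _concat_pairings(parts_r)
    if kind == "dual":
        return fit_dual_cue(pl, pr)
    return fit_bimanual(pl, pr)


_TRIAL_SPACING_MS = 1e6  # larger than any trial; identical across cue streams


def _concat_pairings(parts: list[PairedTiming]) -> PairedTiming:
    """Stack per-trial pairings with a guaranteed invalid break between trials.

    Each trial k is shifted by the same fixed spacing k * 1e6 ms regardless of
    its cue stream, so left- and right-cue pairings of the same respondent
    stay time-aligned after concatenation."""
    cycles, cues, resps, valids = [], [], [], []
    cyc0 = 0
    for k, p in enumerate(parts):
        shift = k * _TRIAL_SPACING_MS
        cycles.append(p.cycles + cyc0)
        cues.append(p.cue_times + shift)
        resps.append(p.resp_times + shift)
        v = p.valid.copy()
        if v.size:
            v[-1] = False  # break the MA(1) run at the trial boundary
        valids.append(v)
        cyc0 += p.cycles.size
    return PairedTiming(
        cycles=np.concatenate(cycles),
        cue_times=np.concatenate(cues),
        resp_times=np.concatenate(resps),
        valid=np.concatenate(valids),
    )


def _tempo_cycle_mask(schedule: MetronomeSchedule, tempo: str) -> np.ndarray:
    return schedule.tempo_labels() == tempo


def _run_analysis_core(
    cfg: ExperimentConfig,
    trials: list[tuple[int, MetronomeSchedule, Mapping[tuple[str, str], EventSeries]]],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    topology = cfg.topology()
    paired_frames = []
    per_trial_pairings: list[dict] = []
    per_trial_imis: list[dict[str, np.ndarray]] = []
    schedules: list[MetronomeSchedule] = []
    for trial_id, schedule, events in trials:
        frames, pairings, imis = _analyze_trial(
            trial_id, schedule, events, topology, cfg
        )
        paired_frames.extend(frames)
        per_trial_pairings.append(pairings)
        per_trial_imis.append(imis)
        schedules.append(schedule)

    paired = pd.concat(paired_frames, ignore_index=True)

    # -- bGLS fits per position x tempo, pooled over trials ------------------
    fit_rows = []
    for pos in topology.positions:
        for tempo in ("fast", "slow"):
            tms = [_tempo_cycle_mask(s, tempo) for s in schedules]
            plist = [pt[pos] for pt in per_trial_pairings]
            try:
                fit = _fit_position_tempo(plist, tms)
            except ValueError as err:
                fit_rows.append({"position": pos, "tempo": tempo, "error": str(err)})
                continue
            fit_rows.append(
                {
                    "position": pos,
                    "tempo": tempo,
                    "alpha": fit.alpha,
                    "alpha_left": fit.alpha_left,
                    "alpha_right": fit.alpha_right,
                    "sigma_T2": fit.sigma_T2,
                    "sigma_M2": fit.sigma_M2,
                    "n": fit.n_obs,
                    "converged": fit.converged,
                }
            )
    fits = pd.DataFrame(fit_rows)

    # -- nested integration tests on concatenated trials ---------------------
    nested_rows = []
    need = {"IT", "F2L", "F2R"}
    if need <= set(topology.positions):
        for tempo in ("fast", "slow"):
            per_trial = []
            for imis, s in zip(per_trial_imis, schedules):
                tm = _tempo_cycle_mask(s, tempo)
                per_trial.append(
                    {p: np.where(tm, imis[p], np.nan) for p in ("IT", "F2L", "F2R")}
                )
            series, _ = concatenate_trials(per_trial)
            try:
                res = both_directions(series["IT"], series["F2L"], series["F2R"])
            except ValueError as err:
                nested_rows.append({"tempo": tempo, "error": str(err)})
                continue
            for direction, r in res.items():
                nested_rows.append(
                    {
                        "tempo": tempo,
                        "direction": direction,
                        "n": r.n_obs,
                        "sse_reduced": r.sse_reduced,
                        "sse_full": r.sse_full,
                        "F": r.F,
                        "p_value": r.p_value,
                        "significant": r.significant_at_01,
                    }
                )
    nested = pd.DataFrame(nested_rows)

    cue_rows = paired[paired["measure"] == "cue"]
    summary = summarize(cue_rows, by=["position", "tempo"])
    return paired, fits, nested, summary


def run_synthetic_experiment(
    cfg: ExperimentConfig, out_dir=None
) -> ExperimentResult:
    """Simulate and analyse a full session under the configured design."""
    topology = cfg.topology()
    topology.validate()
    ss = np.random.SeedSequence(cfg.master_seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])

    events_frames, metro_frames, role_rows = [], [], []
    trials = []
    trial_id = 0
    participants = [f"P{i + 1}" for i in range(len(topology.positions))]
    for block in range(cfg.n_blocks):
        # role rotation: a fresh permutation of participants over positions
        perm = order_rng.permutation(len(participants))
        for pos, pi in zip(topology.positions, perm):
            role_rows.append(
                {"block": block + 1, "position": pos, "participant": participants[pi]}
            )
        # counterbalanced presentation order within the block
        half = cfg.trials_per_block // 2
        orders = ["fast_slow"] * half + ["slow_fast"] * (cfg.trials_per_block - half)
        orders = [orders[i] for i in order_rng.permutation(len(orders))]
        for order in orders:
            child = np.random.SeedSequence((cfg.master_seed, trial_id))
            s_metro, s_group = child.spawn(2)
            schedule = generate_metronome(
                cfg.ioi_fast_range, cfg.ioi_slow_range, cfg.n_fast, cfg.n_slow,
                order, seed=np.random.default_rng(s_metro),
            )
            trial = simulate_group(
                topology, cfg.agent_params, schedule, seed=s_group,
                timekeeper_ref=cfg.timekeeper_ref,
            )
            trials.append((trial_id, schedule, trial.events))
            events_frames.append(gio.events_to_frame(trial, trial_id))
            metro_frames.append(gio.metronome_to_frame(schedule, trial_id))
            trial_id += 1

    paired, fits, nested, summary = _run_analysis_core(cfg, trials)
    manifest = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "n_trials": trial_id,
        "numpy": np.__version__,
    }
    result = ExperimentResult(
        config=cfg,
        events=pd.concat(events_frames, ignore_index=True),
        metronomes=pd.concat(metro_frames, ignore_index=True),
        paired=paired,
        fits=fits,
        nested=nested,
        summary=summary,
        roles=pd.DataFrame(role_rows),
        truth=cfg.agent_params,
        manifest=manifest,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def events_from_trajectories(
    trajectories: Mapping[tuple[int, str, str], Trajectory],
    cfg: ExperimentConfig,
    nominal_ioi_ms: float = 500.0,
) -> pd.DataFrame:
    """Kinematics stage: filter each trajectory and extract per-cycle minima,
    emitting an events table in the documented schema."""
    spec = cfg.filter_spec()
    rows = []
    for (trial_id, pos, hand), traj in trajectories.items():
        filtered = lowpass_filter(traj, spec)
        ev = extract_events(filtered, min_separation_ms=0.5 * nominal_ioi_ms)
        for cycle, t in enumerate(ev.times):
            rows.append((trial_id, pos, hand, cycle, t))
    return pd.DataFrame(rows, columns=gio.EVENTS_COLUMNS)


def run_analysis(
    events: pd.DataFrame,
    metronomes: pd.DataFrame,
    cfg: ExperimentConfig,
    out_dir=None,
) -> ExperimentResult:
    """Analyse externally supplied (or re-loaded) event tables.

    ``events`` and ``metronomes`` follow the documented CSV schemas; the
    result carries no ground truth.
    """
    gio._check_columns(events, gio.EVENTS_COLUMNS, "events table")
    gio._check_columns(metronomes, gio.METRONOME_COLUMNS, "metronome table")
    trials = []
    for trial_id in sorted(events["trial_id"].unique()):
        ev = gio.events_map_from_frame(events[events["trial_id"] == trial_id])
        ms = metronomes[metronomes["trial_id"] == trial_id]
        if ms.empty:
            raise gio.SchemaError(f"no metronome rows for trial {trial_id}")
        schedule = gio.metronome_from_frame(ms)
        trials.append((int(trial_id), schedule, ev))
    paired, fits, nested, summary = _run_analysis_core(cfg, trials)
    result = ExperimentResult(
        config=cfg,
        events=events,
        metronomes=metronomes,
        paired=paired,
        fits=fits,
        nested=nested,
        summary=summary,
        manifest={"config_hash": cfg.config_hash(), "n_trials": len(trials)},
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
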