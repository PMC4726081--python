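"""Plain-text interchange formats.

All tables are CSV/TSV with fixed column order; parameters travel as JSON.

events CSV      trial_id, position, hand, cycle, event_time_ms
metronome CSV   trial_id, beat, onset_ms, segment
paired CSV      trial_id, position, hand, cycle, cue_ms, resp_ms, async_ms,
                imi_ms, valid, tempo
trajectory CSV  time_ms, z
truth JSON      {position: {alpha, ..., sigma_T2, sigma_M2, mean_motor_delay}}
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import (
    AgentParams,
    EventSeries,
    MetronomeSchedule,
    SimulatedTrial,
    Trajectory,
)

EVENTS_COLUMNS = ["trial_id", "position", "hand", "cycle", "event_time_ms"]
METRONOME_COLUMNS = ["trial_id", "beat", "onset_ms", "segment"]
PAIRED_COLUMNS = [
    "trial_id", "position", "hand", "cycle", "cue_ms", "resp_ms",
    "async_ms", "imi_ms", "valid", "tempo",
]


class SchemaError(ValueError):
    """A table does not conform to its documented schema."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")


def events_to_frame(trial: SimulatedTrial, trial_id: int = 0) -> pd.DataFrame:
    rows = []
    for (pos, hand), series in trial.events.items():
        for cycle, t in enumerate(series.times):
            rows.append((trial_id, pos, hand, cycle, t))
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def metronome_to_frame(
    schedule: MetronomeSchedule, trial_id: int = 0
) -> pd.DataFrame:
    lab = schedule.tempo_labels()
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "beat": np.arange(1, schedule.n_beats + 1),
            "onset_ms": schedule.onsets,
            "segment": lab,
        },
        columns=METRONOME_COLUMNS,
    )


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, EVENTS_COLUMNS, f"events file {path}")
    if df["event_time_ms"].isna().any():
        bad = int(df.index[df["event_time_ms"].isna()][0])
        raise SchemaError(f"events file {path}: missing event_time_ms at row {bad}")
    return df


def read_metronome(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, METRONOME_COLUMNS, f"metronome file {path}")
    return df


def metronome_from_frame(df: pd.DataFrame) -> MetronomeSchedule:
    """Rebuild a schedule from its CSV representation (one trial)."""
    df = df.sort_values("beat")
    onsets = df["onset_ms"].to_numpy(dtype=float)
    seg = df["segment"].to_numpy()
    iois = np.diff(onsets)
    first = seg[0]
    change_pos = np.nonzero(seg != first)[0]
    change_index = int(change_pos[0]) + 1 if change_pos.size else len(seg)
    fast_iois = iois[np.nonzero(seg[:-1] == "fast")[0]]
    slow_iois = iois[np.nonzero(seg[:-1] == "slow")[0]]
    return MetronomeSchedule(
        onsets=onsets,
        ioi_fast=float(np.median(fast_iois)) if fast_iois.size else np.nan,
        ioi_slow=float(np.median(slow_iois)) if slow_iois.size else np.nan,
        n_fast=int(np.sum(seg == "fast")),
        n_slow=int(np.sum(seg == "slow")),
        order="fast_slow" if first == "fast" else "slow_fast",
        change_index=change_index,
    )


def events_map_from_frame(
    df: pd.DataFrame,
) -> dict[tuple[str, str], EventSeries]:
    out: dict[tuple[str, str], EventSeries] = {}
    for (pos, hand), g in df.groupby(["position", "hand"], sort=True):
        g = g.sort_values("cycle")
        out[(str(pos), str(hand))] = EventSeries(
            g["event_time_ms"].to_numpy(dtype=float), label=f"{pos}/{hand}"
        )
    return out


def truth_to_json(truth: Mapping[str, AgentParams]) -> str:
    return json.dumps(
        {pos: dataclasses.asdict(p) for pos, p in truth.items()}, indent=2
    )


def truth_from_json(text: str) -> dict[str, AgentParams]:
    return {pos: AgentParams(**d) for pos, d in json.loads(text).items()}


def write_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame({"time_ms": traj.time_ms, "z": traj.z}).to_csv(path, index=False)


def read_trajectory(path, effector: str = "") -> Trajectory:
    df = pd.read_csv(path)
    _check_columns(df, ["time_ms", "z"], f"trajectory file {path}")
    return Trajectory(
        time_ms=df["time_ms"].to_numpy(dtype=float),
        z=df["z"].to_numpy(dtype=float),
        effector=effector,
    )


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df.to_csv(path, index=False, sep=sep)
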