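"""Alignment of respondent events to cue events and timing descriptives.

Asynchrony A_n = respondent time - cue time (negative = respondent early);
IMI I_n = time between a respondent's consecutive events.  Matching is
nearest-event, one-to-one, with a window of a fraction of the local cue IOI
so events cannot be captured across cycles at a tempo change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MetronomeSchedule, _as_times

__all__ = [
    "PairedTiming",
    "align_events",
    "steady_state_mask",
    "cumulative_asynchrony",
    "summarize",
]


@dataclass
class PairedTiming:
    """Cue/respondent events paired per cycle.

    Unmatched cues have NaN ``resp_times`` (and NaN asynchrony); ``imis[n]``
    spans cycles n -> n+1 and is NaN when either end is missing (gaps are not
    bridged).  ``valid`` marks cycles usable for estimation (matched, and
    surviving any steady-state mask applied afterwards); ``tempo`` carries
    optional per-cycle labels.
    """

    cycles: np.ndarray
    cue_times: np.ndarray
    resp_times: np.ndarray
    valid: np.ndarray
    tempo: np.ndarray | None = None

    def __post_init__(self):
        n = self.cycles.size
        for name in ("cue_times", "resp_times", "valid"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length mismatch")

    @property
    def asynchronies(self) -> np.ndarray:
        """A_n = resp - cue (ms); NaN where unmatched."""
        return self.resp_times - self.cue_times

    @property
    def imis(self) -> np.ndarray:
        """I_n = resp(n+1) - resp(n) (ms), length n-1; NaN across gaps."""
        return np.diff(self.resp_times)

    @property
    def n_matched(self) -> int:
        return int(np.sum(np.isfinite(self.resp_times)))

    def apply_mask(self, mask: np.ndarray) -> "PairedTiming":
        """Return a copy whose validity is ANDed with ``mask`` (per cycle)."""
        if mask.size != self.cycles.size:
            raise ValueError("mask length mismatch")
        return PairedTiming(
            cycles=self.cycles,
            cue_times=self.cue_times,
            resp_times=self.resp_times,
            valid=self.valid & np.asarray(mask, dtype=bool),
            tempo=self.tempo,
        )

    def to_frame(self, **meta) -> pd.DataFrame:
        """Long-format table; extra keyword columns (position, hand, ...) are
        broadcast."""
        imi = np.append(self.imis, np.nan)
        df = pd.DataFrame(
            {
                "cycle": self.cycles,
                "cue_ms": self.cue_times,
                "resp_ms": self.resp_times,
                "async_ms": self.asynchronies,
                "imi_ms": imi,
                "valid": self.valid,
                "tempo": self.tempo if self.tempo is not None else pd.NA,
            }
        )
        for k, v in meta.items():
            df[k] = v
        return df


def align_events(cue, resp, window_fraction: float = 0.5) -> PairedTiming:
    """Pair each cue event with its closest respondent event, one-to-one.

    A respondent event is eligible for cue event n only within
    ``window_fraction`` x the local cue IOI; when two cues compete for the
    same respondent event (or one cue has several candidates) the pairing
    with the smallest absolute asynchrony wins and the loser goes missing.
    """
    c = _as_times(cue)
    if c.size == 0:
        raise ValueError("cue series is empty")
    r = _as_times(resp)
    if not (0 < window_fraction <= 1):
        raise ValueError("window_fraction must be in (0, 1]")

    n = c.size
    cycles = np.arange(n)
    resp_times = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    if r.size == 0:
        return PairedTiming(cycles, c.copy(), resp_times, valid)

    if n >= 2:
        d = np.diff(c)
        local = np.minimum(np.append(d, d[-1]), np.concatenate([[d[0]], d]))
    else:
        local = np.full(1, np.inf)
    win = window_fraction * local

    # candidate pairs within the window, greedily matched by |asynchrony|
    cand: list[tuple[float, int, int]] = []
    for i in range(n):
        lo = np.searchsorted(r, c[i] - win[i], side="left")
        hi = np.searchsorted(r, c[i] + win[i], side="right")
        for j in range(lo, hi):
            cand.append((abs(r[j] - c[i]), i, j))
    cand.sort()
    cue_taken = np.zeros(n, dtype=bool)
    resp_taken = np.zeros(r.size, dtype=bool)
    for _, i, j in cand:
        if not cue_taken[i] and not resp_taken[j]:
            cue_taken[i] = resp_taken[j] = True
            resp_times[i] = r[j]
            valid[i] = True
    return PairedTiming(cycles, c.copy(), resp_times, valid)


def steady_state_mask(
    schedule: MetronomeSchedule, n_pre: int = 2, n_post: int = 3
) -> np.ndarray:
    """Boolean mask over cycles excluding the tempo-change transient.

    The ``n_pre`` cycles before the change and the ``n_post`` cycles from the
    change onward are masked out (False); with the standard 30+30 design and
    defaults, beats 29-33 drop and 55 cycles remain.
    """
    n = schedule.n_beats
    change = schedule.change_index  # 1-based first post-change beat
    if not (1 <= change <= n):
        raise ValueError(f"change_index {change} outside 1..{n}")
    mask = np.ones(n, dtype=bool)
    lo = max(0, change - 1 - n_pre)
    hi = min(n, change - 1 + n_post)
    mask[lo:hi] = False
    return mask


def cumulative_asynchrony(
    resp, metronome: MetronomeSchedule, window_fraction: float = 0.5
) -> PairedTiming:
    """Pair a position's events against the source metronome rather than its
    immediate cue, measuring how asynchrony accumulates along the chain."""
    paired = align_events(metronome.onsets, resp, window_fraction)
    paired.tempo = metronome.tempo_labels()
    return paired


def summarize(
    frame: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Per-group mean/SD of asynchronies and IMIs over valid cycles.

    ``frame`` is long-format as produced by :meth:`PairedTiming.to_frame`
    (columns async_ms, imi_ms, valid, plus grouping columns).  Groups present
    in the input but with no valid cycles yield a row with count 0.
    """
    by = by or ["position", "tempo"]
    rows = []
    for keys, g in frame.groupby(by, dropna=False, sort=True, observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        gv = g[g["valid"].astype(bool)]
        a = gv["async_ms"].dropna()
        i = gv["imi_ms"].dropna()
        rows.append(
            dict(zip(by, keys))
            | {
                "n_async": len(a),
                "mean_async_ms": a.mean() if len(a) else np.nan,
                "sd_async_ms": a.std(ddof=1) if len(a) > 1 else np.nan,
                "n_imi": len(i),
                "mean_imi_ms": i.mean() if len(i) else np.nan,
                "sd_imi_ms": i.std(ddof=1) if len(i) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
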