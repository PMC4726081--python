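import numpy as np
import pytest

from groupsync import AgentParams, MetronomeSchedule, generate_metronome
from groupsync.timing import PairedTiming


def make_paired(cue_times, resp_times, valid=None) -> PairedTiming:
    """Fully-valid pairing from matched cue/respondent arrays (test shortcut
    for cycle-indexed synthetic data where alignment is trivial)."""
    cue = np.asarray(cue_times, dtype=float)
    resp = np.asarray(resp_times, dtype=float)
    if valid is None:
        valid = np.ones(cue.size, dtype=bool)
    return PairedTiming(
        cycles=np.arange(cue.size),
        cue_times=cue.copy(),
        resp_times=resp.copy(),
        valid=np.asarray(valid, dtype=bool),
    )


def isochronous(n: int, ioi: float = 500.0) -> MetronomeSchedule:
    """A constant-tempo schedule (no tempo change within the series)."""
    return MetronomeSchedule(
        onsets=ioi * np.arange(n),
        ioi_fast=ioi,
        ioi_slow=ioi,
        n_fast=n,
        n_slow=0,
        order="fast_slow",
        change_index=n,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def standard_metronome():
    return generate_metronome(seed=7)


@pytest.fixture
def noisy_params():
    return AgentParams(alpha=0.5, sigma_T2=400.0, sigma_M2=64.0)
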