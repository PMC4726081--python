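"""Nested-regression test for dual-cue interval integration.

Are the integrator's inter-movement intervals better predicted by the
interval series of *both* chain ends than by one alone?  The reduced model
regresses the integrator's (mean-centred) intervals on one side's intervals,
the full model on both; the drop in residual sum of squares is tested with

    F = ((SSE_reduced - SSE_full) / p) / (SSE_full / (N - k - p)),

with k = 1 coefficient in the reduced model and p = 1 added coefficient, and
the full model judged better when the F-distribution p-value is below 0.01.
No intercept is fitted: the series are mean-centred first, keeping the stated
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["NestedFResult", "concatenate_trials", "nested_f_test", "both_directions"]


@dataclass(frozen=True)
class NestedFResult:
    """Outcome of one reduced-vs-full nested regression comparison."""

    sse_reduced: float
    sse_full: float
    k: int
    p_added: int
    n_obs: int
    F: float
    p_value: float
    significant_at_01: bool
    coef_reduced: float
    coef_full: tuple[float, float]

    @property
    def dof(self) -> tuple[int, int]:
        return (self.p_added, self.n_obs - self.k - self.p_added)


def concatenate_trials(
    per_trial: Sequence[Mapping[str, np.ndarray]],
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Concatenate per-trial interval series across trials, position-wise.

    Each element of ``per_trial`` maps position -> interval series for one
    trial (NaN marks invalid cycles).  Within a trial, cycles are intersected
    on joint validity across all positions so the series stay cycle-aligned;
    intervals never span trial boundaries because concatenation happens after
    the per-trial diff.  Returns the concatenated series per position and the
    indices at which each new trial starts (boundary flags).
    """
    if not per_trial:
        raise ValueError("no trials given")
    positions = list(per_trial[0])
    chunks: dict[str, list[np.ndarray]] = {p: [] for p in positions}
    boundaries = []
    total = 0
    for t, trial in enumerate(per_trial):
        if set(trial) != set(positions):
            raise ValueError(f"trial {t} positions differ from trial 0")
        arrs = {p: np.asarray(trial[p], dtype=float) for p in positions}
        n = min(a.size for a in arrs.values())
        joint = np.ones(n, dtype=bool)
        for a in arrs.values():
            joint &= np.isfinite(a[:n])
        for p in positions:
            chunks[p].append(arrs[p][:n][joint])
        boundaries.append(total)
        total += int(joint.sum())
    series = {p: np.concatenate(chunks[p]) for p in positions}
    return series, np.asarray(boundaries, dtype=int)


def _sse_no_intercept(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), coef


def nested_f_test(
    y: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    *,
    alpha_level: float = 0.01,
) -> NestedFResult:
    """Compare y ~ x1 (reduced) against y ~ x1 + x2 (full), mean-centred,
    no intercept.

    A perfect full fit (SSE_full = 0) is reported as F = +inf with p = 0.
    Collinear predictors are an error.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (y.shape == x1.shape == x2.shape) or y.ndim != 1:
        raise ValueError("y, x1, x2 must be 1-D arrays of equal length")
    k, p_added = 1, 1
    n = y.size
    if n < k + p_added + 2:
        raise ValueError(f"need at least {k + p_added + 2} observations, got {n}")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(x1)) or np.any(~np.isfinite(x2)):
        raise ValueError("inputs contain non-finite values")

    yc = y - y.mean()
    x1c = x1 - x1.mean()
    x2c = x2 - x2.mean()
    s1, s2 = np.linalg.norm(x1c), np.linalg.norm(x2c)
    if s1 == 0 or s2 == 0:
        raise ValueError("a predictor is constant")
    if abs(x1c @ x2c) >= (1 - 1e-12) * s1 * s2:
        raise ValueError("predictors x1 and x2 are collinear")

    sse_red, coef_red = _sse_no_intercept(yc, x1c[:, None])
    sse_full, coef_full = _sse_no_intercept(yc, np.column_stack([x1c, x2c]))
    sse_full = min(sse_full, sse_red)  # guard against round-off breaking nesting

    df2 = n - k - p_added
    scale = float(yc @ yc)
    if sse_red <= 1e-12 * scale:
        # the reduced model is already perfect: no improvement possible
        F, p_value = 0.0, 1.0
    elif sse_full <= max(1e-12 * sse_red, 1e-300):
        F, p_value = float("inf"), 0.0
    else:
        F = ((sse_red - sse_full) / p_added) / (sse_full / df2)
        p_value = float(stats.f.sf(F, p_added, df2))
    return NestedFResult(
        sse_reduced=sse_red,
        sse_full=sse_full,
        k=k,
        p_added=p_added,
        n_obs=n,
        F=float(F),
        p_value=p_value,
        significant_at_01=p_value < alpha_level,
        coef_reduced=float(coef_red[0]),
        coef_full=(float(coef_full[0]), float(coef_full[1])),
    )


def both_directions(
    y: np.ndarray, x_left: np.ndarray, x_right: np.ndarray, **kw
) -> dict[str, NestedFResult]:
    """Run the nested test in both directions, as reported per participant:
    left-side-reduced (is the right side needed?) and right-side-reduced."""
    return {
        "left_reduced": nested_f_test(y, x_left, x_right, **kw),
        "right_reduced": nested_f_test(y, x_right, x_left, **kw),
    }
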