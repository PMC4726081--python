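"""Bounded generalised least squares (bGLS) estimation of the linear phase
correction model.

The regression form of the model is

    I_n = c - alpha * A_n + eps_n,      eps_n = T'_n + M_{n+1} - M_n,

so the noise is MA(1): its covariance has sigma_T^2 + 2*sigma_M^2 on the
diagonal and -sigma_M^2 on the first off-diagonals.  The estimator iterates
generalised least squares with this covariance, re-estimating the residual
lag-0/lag-1 autocovariances (gamma0, gamma1) at each step and *bounding* them
to the physically admissible region gamma1 in [-gamma0/2, 0] — equivalently
sigma_M^2 in [0, gamma0/2] — which is what keeps both variance components
non-negative where ordinary moment estimates would not.

Extensions: a dual-cue regression with two asynchrony regressors (integrator
position), and a bimanual fit stacking both hands' equations with a lag-0
cross-hand covariance equal to the shared timekeeper variance.  The bimanual
stacking and the dual-cue covariance are principled reconstructions of the
method (the exact published variant is supplementary material); both keep the
MA(1) single-hand structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .timing import PairedTiming, align_events

__all__ = [
    "LPCFit",
    "fit_single_cue",
    "fit_dual_cue",
    "fit_bimanual",
    "motor_variance_bimanual",
    "pairwise_gains",
]

MIN_RUN = 10  # shortest contiguous run of valid cycles worth fitting
_TINY = 1e-12


@dataclass
class LPCFit:
    """Estimated linear-phase-correction parameters.

    ``alpha`` is the correction gain (for dual-cue fits, ``alpha_left`` and
    ``alpha_right`` are set and ``alpha`` holds their sum); variances in ms².
    ``gamma0``/``gamma1`` are the residual lag-0/lag-1 autocovariances of the
    last iterate.
    """

    alpha: float
    sigma_T2: float
    sigma_M2: float
    intercept: float
    n_obs: int
    iterations: int
    converged: bool
    gamma0: float
    gamma1: float
    alpha_left: float | None = None
    alpha_right: float | None = None
    sigma_M2_left: float | None = None
    sigma_M2_right: float | None = None
    flags: list[str] = field(default_factory=list)


def _ma1_banded(gamma0: float, sigma_M2: float, n: int) -> np.ndarray:
    """Upper-banded form of the MA(1) covariance for scipy.linalg.solveh_banded."""
    ab = np.zeros((2, n))
    ab[0, 1:] = -sigma_M2
    ab[1, :] = gamma0
    return ab


def _residual_moments(e: np.ndarray) -> tuple[float, float]:
    g0 = float(np.mean(e * e))
    g1 = float(np.mean(e[:-1] * e[1:])) if e.size > 1 else 0.0
    return g0, g1


_COND_FLOOR = 0.05  # min timekeeper share of gamma0, keeps the GLS well-posed


def _bound(g0: float, g1: float) -> tuple[float, float]:
    """Clip to the admissible MA(1) region; returns (sigma_M2, sigma_T2).

    The admissible boundary gamma1 = -gamma0/2 is a unit root where the MA(1)
    covariance is singular; iterated GLS can then difference the regressors
    away entirely and collapse every coefficient to zero.  The clip therefore
    stops slightly inside the boundary (timekeeper share >= 5% of gamma0),
    which leaves ordinary fits untouched and keeps boundary fits well-posed.
    """
    sM2 = float(np.clip(-g1, 0.0, 0.5 * (1.0 - _COND_FLOOR) * g0))
    sT2 = max(g0 - 2.0 * sM2, 0.0)
    return sM2, sT2


def _bgls_core(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> tuple[np.ndarray, float, float, float, float, int, bool]:
    """Iterate GLS with an MA(1) residual covariance on one contiguous run.

    Returns (beta, sigma_T2, sigma_M2, gamma0, gamma1, iterations, converged).
    """
    n = y.size
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ beta
    g0, g1 = _residual_moments(e)
    sM2, sT2 = _bound(g0, g1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if g0 < _TINY:  # (near-)deterministic data: OLS is exact
            converged = True
            break
        ab = _ma1_banded(sT2 + 2.0 * sM2, sM2, n)
        try:
            ciX = linalg.solveh_banded(ab, X)
            ciy = linalg.solveh_banded(ab, y)
        except np.linalg.LinAlgError:  # fall back to identity weighting
            ciX, ciy = X, y
        beta_new = np.linalg.solve(X.T @ ciX, X.T @ ciy)
        e = y - X @ beta_new
        g0, g1 = _residual_moments(e)
        sM2, sT2 = _bound(g0, g1)
        delta = np.max(np.abs(beta_new - beta)) / max(np.max(np.abs(beta_new)), 1.0)
        beta = beta_new
        if delta < tol:
            converged = True
            break
    return beta, sT2, sM2, g0, g1, it, converged


def _valid_runs(valid: np.ndarray, min_run: int) -> list[slice]:
    """Contiguous runs of True of length >= min_run."""
    runs: list[slice] = []
    start = None
    v = np.append(valid, False)
    for i, ok in enumerate(v):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_run:
                runs.append(slice(start, i))
            start = None
    return runs


def _pool(fits: list[LPCFit]) -> LPCFit:
    """Observation-weighted average of per-run fits."""
    if len(fits) == 1:
        return fits[0]
    w = np.array([f.n_obs for f in fits], dtype=float)
    w /= w.sum()

    def avg(attr):
        vals = [getattr(f, attr) for f in fits]
        if any(v is None for v in vals):
            return None
        return float(np.dot(w, vals))

    pooled = LPCFit(
        alpha=avg("alpha"),
        sigma_T2=avg("sigma_T2"),
        sigma_M2=avg("sigma_M2"),
        intercept=avg("intercept"),
        n_obs=int(sum(f.n_obs for f in fits)),
        iterations=max(f.iterations for f in fits),
        converged=all(f.converged for f in fits),
        gamma0=avg("gamma0"),
        gamma1=avg("gamma1"),
        alpha_left=avg("alpha_left"),
        alpha_right=avg("alpha_right"),
        sigma_M2_left=avg("sigma_M2_left"),
        sigma_M2_right=avg("sigma_M2_right"),
        flags=sorted({fl for f in fits for fl in f.flags} | {"pooled"}),
    )
    return pooled


def _estimation_cycles(paired: PairedTiming) -> np.ndarray:
    """Cycles with a defined (A_n, I_n) pair: matched at n and n+1, both valid."""
    ok = paired.valid & np.isfinite(paired.resp_times)
    usable = ok[:-1] & ok[1:] & np.isfinite(paired.imis)
    return usable


def fit_single_cue(
    paired: PairedTiming,
    *,
    min_run: int = MIN_RUN,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> LPCFit:
    """Fit the single-cue LPC model by bGLS.

    Fits run on contiguous valid stretches of at least ``min_run`` cycles
    (gaps break the MA(1) covariance structure) and are pooled by an
    observation-weighted average.
    """
    usable = _estimation_cycles(paired)
    runs = _valid_runs(usable, min_run)
    if not runs:
        raise ValueError(
            f"need a contiguous run of >= {min_run} valid cycles "
            f"({int(usable.sum())} usable in total)"
        )
    A = paired.asynchronies
    I = paired.imis
    fits = []
    for run in runs:
        a = A[run]
        y = I[run]
        X = np.column_stack([np.ones_like(a), -a])
        beta, sT2, sM2, g0, g1, it, conv = _bgls_core(X, y, tol, max_iter)
        fits.append(
            LPCFit(
                alpha=float(beta[1]),
                sigma_T2=sT2,
                sigma_M2=sM2,
                intercept=float(beta[0]),
                n_obs=y.size,
                iterations=it,
                converged=conv,
                gamma0=g0,
                gamma1=g1,
            )
        )
    return _pool(fits)


def fit_dual_cue(
    paired_left: PairedTiming,
    paired_right: PairedTiming,
    *,
    min_run: int = MIN_RUN,
    tol: float = 1e-6,
    max_iter: int = 50,
    collinearity_tol: float = 1e-8,
    subtract_reference: bool = True,
) -> LPCFit:
    """Fit the dual-cue LPC model (two gains, shared timekeeper and motor).

    Both pairings must share the respondent event series; cycles are
    intersected on joint validity.  If the two asynchrony regressors are
    collinear (identical cues) the fit falls back to single-cue and reports
    the combined gain with a ``collinear`` flag.

    With ``subtract_reference`` (default) the observed mean of the two cue
    intervals is subtracted from each produced interval before the
    regression.  A dual-cue agent's timekeeper is referenced to the combined
    cue interval, and because that reference co-varies with the asynchrony
    regressors, leaving it in the residual attenuates both gains; removing
    the observed part makes the estimator consistent under the model.  (The
    reference drops out anyway whenever both cues are isochronous.)
    """
    nc = min(paired_left.cycles.size, paired_right.cycles.size)
    pl, pr = paired_left, paired_right
    rl, rr = pl.resp_times[:nc], pr.resp_times[:nc]
    both = np.isfinite(rl) & np.isfinite(rr)
    if np.any(np.abs(rl[both] - rr[both]) > 1e-6):
        raise ValueError("pairings do not share a common respondent series")

    joint_valid = (
        pl.valid[:nc] & pr.valid[:nc] & both
    )
    resp = np.where(both, rl, np.nan)
    merged = PairedTiming(
        cycles=np.arange(nc),
        cue_times=pl.cue_times[:nc],
        resp_times=resp,
        valid=joint_valid,
    )
    usable = _estimation_cycles(merged)
    runs = _valid_runs(usable, min_run)
    if not runs:
        raise ValueError(f"need a contiguous run of >= {min_run} joint valid cycles")

    AL = pl.asynchronies[:nc]
    AR = pr.asynchronies[:nc]
    I = np.diff(resp)
    if subtract_reference:
        ref = 0.5 * (np.diff(pl.cue_times[:nc]) + np.diff(pr.cue_times[:nc]))
        I = I - ref

    d = AL[:-1][usable] - AR[:-1][usable]
    if np.std(d) <= collinearity_tol * max(np.std(AL[:-1][usable]), 1.0):
        fit = fit_single_cue(merged, min_run=min_run, tol=tol, max_iter=max_iter)
        fit.flags.append("collinear")
        return fit

    fits = []
    for run in runs:
        al, ar, y = AL[run], AR[run], I[run]
        X = np.column_stack([np.ones_like(al), -al, -ar])
        beta, sT2, sM2, g0, g1, it, conv = _bgls_core(X, y, tol, max_iter)
        fits.append(
            LPCFit(
                alpha=float(beta[1] + beta[2]),
                alpha_left=float(beta[1]),
                alpha_right=float(beta[2]),
                sigma_T2=sT2,
                sigma_M2=sM2,
                intercept=float(beta[0]),
                n_obs=y.size,
                iterations=it,
                converged=conv,
                gamma0=g0,
                gamma1=g1,
            )
        )
    return _pool(fits)


def fit_bimanual(
    paired_left_hand: PairedTiming,
    paired_right_hand: PairedTiming,
    *,
    min_run: int = MIN_RUN,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> LPCFit:
    """Fit one shared gain and timekeeper variance from both hands of one
    agent tracking the same cue, with per-hand motor variances.

    Both hands' regression equations are stacked with the covariance implied
    by a shared central command: because the stacked design then carries the
    same (hand-averaged) regressor in both blocks, the GLS solution reduces
    exactly to a single-cue bGLS on the hand-averaged asynchronies and
    intervals — the between-hand difference contrast contains no information
    about the gain, only about motor noise.  Averaging halves the effective
    motor variance, so the pooled per-hand motor variance is twice the bound
    estimate from the averaged series; the left/right split comes from the
    second moments of the inter-hand differences, which isolate motor noise
    exactly under the shared-command model:

        Var(A_L - A_R)          = sigma_ML^2 + sigma_MR^2
        2 Cov(A_L - A_R, A_bar) = sigma_ML^2 - sigma_MR^2.
    """
    nc = min(paired_left_hand.cycles.size, paired_right_hand.cycles.size)
    pl, pr = paired_left_hand, paired_right_hand
    okl = pl.valid[:nc] & np.isfinite(pl.resp_times[:nc])
    okr = pr.valid[:nc] & np.isfinite(pr.resp_times[:nc])
    joint = okl & okr
    if not np.allclose(
        pl.cue_times[:nc][joint], pr.cue_times[:nc][joint], atol=1e-6
    ):
        raise ValueError("both hands must be paired against the same cue")

    mean_resp = np.where(
        joint, 0.5 * (pl.resp_times[:nc] + pr.resp_times[:nc]), np.nan
    )
    merged = PairedTiming(
        cycles=np.arange(nc),
        cue_times=pl.cue_times[:nc],
        resp_times=mean_resp,
        valid=joint,
    )
    fit = fit_single_cue(merged, min_run=min_run, tol=tol, max_iter=max_iter)

    # per-hand split from inter-hand difference moments on usable cycles
    usable = _estimation_cycles(merged)
    sel = np.zeros(nc, dtype=bool)
    for run in _valid_runs(usable, min_run):
        sel[run] = True
    a_diff = (pl.asynchronies[:nc] - pr.asynchronies[:nc])[sel]
    a_bar = merged.asynchronies[sel]
    pooled = 2.0 * fit.sigma_M2  # per-hand average motor variance
    if a_diff.size >= 3:
        half_gap = float(np.cov(a_diff, a_bar)[0, 1])
    else:
        half_gap = 0.0
    fit.sigma_M2 = pooled
    fit.sigma_M2_left = max(pooled + half_gap, 0.0)
    fit.sigma_M2_right = max(pooled - half_gap, 0.0)
    fit.n_obs = 2 * fit.n_obs
    return fit


def motor_variance_bimanual(
    imis_left: np.ndarray, imis_right: np.ndarray
) -> tuple[float, float, bool]:
    """Alternative motor-variance estimator from the two hands' intervals.

    The hands share the central command, so cov(I_L, I_R) estimates the
    central interval variance and the per-hand excess splits as
    sigma_M_h^2 = (Var(I_h) - cov) / 2.  Returns
    (sigma_M2_left, sigma_M2_right, clipped) with negative estimates clipped
    to zero.
    """
    il = np.asarray(imis_left, dtype=float)
    ir = np.asarray(imis_right, dtype=float)
    if il.shape != ir.shape or il.ndim != 1:
        raise ValueError("interval series must be 1-D and of equal length")
    ok = np.isfinite(il) & np.isfinite(ir)
    il, ir = il[ok], ir[ok]
    if il.size < 3:
        raise ValueError("need at least 3 joint intervals")
    cov = float(np.cov(il, ir)[0, 1])
    vl, vr = float(np.var(il, ddof=1)), float(np.var(ir, ddof=1))
    raw_l = (vl - cov) / 2.0
    raw_r = (vr - cov) / 2.0
    clipped = raw_l < 0 or raw_r < 0
    return max(raw_l, 0.0), max(raw_r, 0.0), clipped


def pairwise_gains(
    events_by_position: dict[str, "np.ndarray | object"],
    *,
    window_fraction: float = 0.5,
    min_run: int = MIN_RUN,
) -> pd.DataFrame:
    """Correction-gain matrix over all ordered position pairs.

    For every respondent/cue pair the respondent's events are aligned to the
    would-be cue's events and a single-cue bGLS fit is run; cell (r, c) holds
    the estimated gain of r correcting towards c.  The diagonal is undefined
    and failures yield NaN cells.
    """
    names = list(events_by_position)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for rname in names:
        for cname in names:
            if rname == cname:
                continue
            try:
                paired = align_events(
                    events_by_position[cname],
                    events_by_position[rname],
                    window_fraction,
                )
                mat.loc[rname, cname] = fit_single_cue(
                    paired, min_run=min_run
                ).alpha
            except (ValueError, np.linalg.LinAlgError):
                pass
    return mat
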