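"""Voxelwise mono-exponential T2* fitting and thresholded ROI means.

The signal model is the standard gradient-echo decay

    S(TE) = S0 * exp(-TE / T2*)

with S0 the fitted amplitude at TE = 0 (proton-density-weighted) and T2* the
effective transverse relaxation time in milliseconds.  Fitting minimises the
sum of squared residuals over all acquired echoes, initialised from an
ordinary least-squares fit of ln S against TE and refined by damped
Gauss-Newton (Levenberg-Marquardt) steps.  The whole map is fitted as one
batched problem: the model has only two parameters per voxel, so the normal
equations are solved in closed form across all voxels simultaneously.

T2* is constrained to (0, cap] during fitting (default cap 1000 msec) so that
near-fluid voxels converge stably; the physiological exclusion of fluid
happens later, at reporting time, via the 500 msec threshold of
:func:`mean_t2star`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError
from .io import BinaryMask, EchoTimes, MultiEchoVolume, ScalarMap

__all__ = [
    "FitResult",
    "loglinear_init",
    "fit_monoexponential",
    "fit_t2star_map",
    "mean_t2star",
    "DEFAULT_T2STAR_CAP",
    "DEFAULT_REPORT_THRESHOLD",
]

#: Upper bound on fitted T2* (msec); keeps fluid-like voxels numerically stable.
DEFAULT_T2STAR_CAP = 1000.0
#: Reporting threshold (msec) excluding fluid partial-volume voxels from ROI means.
DEFAULT_REPORT_THRESHOLD = 500.0

_T2_MIN = 1e-3  # msec; lower bound keeping the decay rate finite


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-voxel fit.

    ``converged`` is False when the voxel carries no fittable decay (all-zero
    signal, fewer than two usable echoes, or a non-decaying log-linear trend
    with no better nonlinear optimum); such voxels propagate as NaN, never as
    silent zeros.
    """

    s0: float
    t2star: float
    converged: bool
    residual_sse: float

    def __post_init__(self) -> None:
        if self.converged:
            assert self.s0 > 0 and self.t2star > 0 and self.residual_sse >= 0


def _sse(signal: np.ndarray, te: np.ndarray, s0: np.ndarray, r2: np.ndarray) -> np.ndarray:
    pred = s0[..., None] * np.exp(-np.multiply.outer(r2, te))
    return np.sum((signal - pred) ** 2, axis=-1)


def _loglinear_batch(signal: np.ndarray, te: np.ndarray):
    """Vectorised OLS of ln(signal) on TE.  signal: (N, E).

    Returns (s0, t2, usable): slope must be strictly negative and at least
    two samples positive; non-positive samples are excluded from the log fit.
    """
    pos = signal > 0
    n = pos.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(pos, np.log(np.where(pos, signal, 1.0)), 0.0)
    sx = np.where(pos, te, 0.0).sum(axis=1)
    sy = logs.sum(axis=1)
    sxx = np.where(pos, te**2, 0.0).sum(axis=1)
    sxy = (np.where(pos, te, 0.0) * logs).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = n * sxx - sx**2
        slope = np.where(denom > 0, (n * sxy - sx * sy) / np.where(denom > 0, denom, 1.0), 0.0)
        intercept = np.where(n > 0, (sy - slope * sx) / np.maximum(n, 1), 0.0)
    # slope must be meaningfully negative: a numerically-zero slope on a
    # constant signal would imply an absurd (effectively infinite) T2*
    usable = (n >= 2) & (slope < -1e-12)
    with np.errstate(over="ignore"):
        s0 = np.exp(np.clip(intercept, -700, 700))
    t2 = np.where(usable, -1.0 / np.where(slope < 0, slope, -1.0), np.nan)
    return s0, t2, usable


def loglinear_init(signal, echoes: EchoTimes) -> FitResult:
    """Log-domain OLS initializer: slope = -1/T2*, intercept = ln S0.

    Non-positive samples are excluded; fewer than two positive samples, or a
    non-negative slope (non-decaying signal), yields ``converged=False``.
    """
    te = echoes.as_array()
    signal = np.asarray(signal, dtype=float)
    if signal.shape != te.shape:
        raise FormatError("signal length %d != number of echoes %d" % (signal.size, te.size))
    s0, t2, usable = _loglinear_batch(signal[None, :], te)
    if not usable[0]:
        return FitResult(s0=np.nan, t2star=np.nan, converged=False, residual_sse=np.nan)
    sse = float(_sse(signal[None, :], te, s0, 1.0 / t2)[0])
    return FitResult(s0=float(s0[0]), t2star=float(t2[0]), converged=True, residual_sse=sse)


def _lm_batch(signal: np.ndarray, te: np.ndarray, s0: np.ndarray, r2: np.ndarray,
              r2_lo: float, r2_hi: float, max_iter: int = 60, rtol: float = 1e-14):
    """Damped Gauss-Newton refinement of (S0, R2*=1/T2*), batched over voxels.

    Only improving steps are accepted, so the returned SSE never exceeds the
    SSE at the (box-projected) starting point.  Parameters are projected into
    the feasible box after every candidate step.
    """
    s0 = np.clip(s0.astype(float), 1e-300, None)
    r2 = np.clip(r2.astype(float), r2_lo, r2_hi)
    lam = np.full(s0.shape, 1e-3)
    sse = _sse(signal, te, s0, r2)
    active = np.ones(s0.shape, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        e = np.exp(-np.multiply.outer(r2, te))  # (N, E)
        pred = s0[:, None] * e
        res = signal - pred
        j_s0 = e
        j_r2 = -s0[:, None] * te[None, :] * e
        a11 = np.sum(j_s0 * j_s0, axis=1)
        a12 = np.sum(j_s0 * j_r2, axis=1)
        a22 = np.sum(j_r2 * j_r2, axis=1)
        g1 = np.sum(j_s0 * res, axis=1)
        g2 = np.sum(j_r2 * res, axis=1)
        d11 = a11 * (1 + lam)
        d22 = a22 * (1 + lam)
        det = d11 * d22 - a12**2
        ok = det > 0
        det = np.where(ok, det, 1.0)
        ds0 = np.where(ok, (g1 * d22 - g2 * a12) / det, 0.0)
        dr2 = np.where(ok, (g2 * d11 - g1 * a12) / det, 0.0)
        s0_new = np.clip(s0 + ds0, 1e-300, None)
        r2_new = np.clip(r2 + dr2, r2_lo, r2_hi)
        sse_new = _sse(signal, te, s0_new, r2_new)
        improved = active & ok & (sse_new < sse)
        rel_gain = np.where(sse > 0, (sse - sse_new) / np.maximum(sse, 1e-300), 0.0)
        s0 = np.where(improved, s0_new, s0)
        r2 = np.where(improved, r2_new, r2)
        sse = np.where(improved, sse_new, sse)
        lam = np.where(improved, lam * 0.3, lam * 5.0)
        # retire voxels whose relative SSE improvement has flattened out
        active = active & ~(improved & (rel_gain < rtol)) & (lam < 1e12)
    return s0, r2, sse


def fit_monoexponential(signal, echoes: EchoTimes, cap: float = DEFAULT_T2STAR_CAP) -> FitResult:
    """Nonlinear least-squares fit of S(TE) = S0·exp(-TE/T2*) at one voxel.

    All echoes (including numerically zero samples) enter the SSE; the
    log-linear initializer skips non-positive samples only in its own
    log-domain regression.  T2* is constrained to (0, cap].
    """
    te = echoes.as_array()
    signal = np.asarray(signal, dtype=float)
    if signal.shape != te.shape:
        raise FormatError("signal length %d != number of echoes %d" % (signal.size, te.size))
    if np.count_nonzero(signal > 0) < 2:
        return FitResult(s0=np.nan, t2star=np.nan, converged=False, residual_sse=np.nan)
    init = loglinear_init(signal, echoes)
    if init.converged:
        s0_init, t2_init = init.s0, min(init.t2star, cap)
    else:
        # non-decaying but positive signal: start at the slow-decay boundary
        s0_init, t2_init = float(np.mean(signal[signal > 0])), cap
    r2_lo, r2_hi = 1.0 / cap, 1.0 / _T2_MIN
    s0, r2, sse = _lm_batch(
        signal[None, :], te, np.array([s0_init]), np.array([1.0 / t2_init]), r2_lo, r2_hi
    )
    return FitResult(
        s0=float(s0[0]), t2star=float(1.0 / r2[0]), converged=True, residual_sse=float(sse[0])
    )


def fit_t2star_map(
    volume: MultiEchoVolume,
    roi: BinaryMask | None = None,
    cap: float = DEFAULT_T2STAR_CAP,
) -> tuple[ScalarMap, ScalarMap]:
    """Fit every voxel (optionally restricted to an ROI) and return (T2*, S0) maps.

    Voxels that fail the fit preconditions are marked invalid (NaN + validity
    0) and excluded from every downstream mean or texture computation.
    """
    te = volume.echoes.as_array()
    geom = volume.geometry
    if roi is not None:
        if roi.geometry != geom:
            raise FormatError("ROI and volume are on different grids")
        sel = roi.as_bool()
    else:
        sel = np.ones(geom.dims, dtype=bool)

    signals = volume.data[sel]  # (N, E)
    t2_map = np.full(geom.dims, np.nan)
    s0_map = np.full(geom.dims, np.nan)
    validity = np.zeros(geom.dims, dtype=np.uint8)
    if signals.size:
        fittable = (signals > 0).sum(axis=1) >= 2
        s0_i, t2_i, usable = _loglinear_batch(signals, te)
        s0_start = np.where(usable, s0_i, np.nanmean(np.where(signals > 0, signals, np.nan), axis=1))
        t2_start = np.where(usable, np.minimum(t2_i, cap), cap)
        r2_lo, r2_hi = 1.0 / cap, 1.0 / _T2_MIN
        idx = np.where(fittable)[0]
        if idx.size:
            s0_f, r2_f, _ = _lm_batch(
                signals[idx],
                te,
                np.nan_to_num(s0_start[idx], nan=1.0),
                1.0 / np.clip(t2_start[idx], _T2_MIN, cap),
                r2_lo,
                r2_hi,
            )
            t2_vals = np.full(signals.shape[0], np.nan)
            s0_vals = np.full(signals.shape[0], np.nan)
            t2_vals[idx] = 1.0 / r2_f
            s0_vals[idx] = s0_f
            t2_map[sel] = t2_vals
            s0_map[sel] = s0_vals
            vflat = np.zeros(signals.shape[0], dtype=np.uint8)
            vflat[idx] = 1
            validity[sel] = vflat

    t2 = ScalarMap(data=t2_map, geometry=geom, units="msec", validity=validity)
    s0 = ScalarMap(data=s0_map, geometry=geom, units="a.u.", validity=validity)
    return t2, s0


def mean_t2star(
    t2star: ScalarMap,
    mask: BinaryMask,
    threshold: float = DEFAULT_REPORT_THRESHOLD,
) -> float:
    """Mean T2* over in-mask, valid voxels below the fluid-exclusion threshold.

    The 500 msec default excludes voxels dominated by amniotic fluid or CSF
    partial-volume signal.  Returns NaN when no voxel qualifies.
    """
    if t2star.geometry != mask.geometry:
        raise FormatError("T2* map and mask are on different grids")
    sel = mask.as_bool() & t2star.validity.astype(bool)
    vals = t2star.data[sel]
    vals = vals[vals < threshold]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())
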