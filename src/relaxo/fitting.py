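"""Voxel-per-voxel nonlinear T1 and T2 map estimation from magnitude series.

Two interchangeable optimizer backends fit the same model family:

* ``LEAST_SQUARES_LM`` — Levenberg-Marquardt (scipy ``least_squares``,
  analytic Jacobian);
* ``SIMPLEX`` — Nelder-Mead on the sum of squared residuals, restarted once
  from the found optimum to guard against premature simplex collapse.

Models
------
Inversion recovery (magnitude, three parameters A, B, T1)::

    s(TI) = |A * (1 - B * exp(-TI / T1))|

B is free (2 = perfect inversion) and absorbs imperfect inversion and
incomplete TR recovery. The absolute value reflects magnitude data without
phase; T1 initialization is taken from the signal-minimum TI (the null
point of a perfectly inverted recovery sits at TI = T1 * ln 2) with a
multistart over neighboring TIs to avoid the null-point local minimum.

Multi-echo decay (two parameters A, T2)::

    s(TE) = A * exp(-TE / T2)

initialized by log-linear regression on the early echoes. An optional
constant noise-floor offset term is available but off by default.

After fitting, a plausibility filter marks voxels invalid where the
estimate is non-positive or exceeds 3000 ms (T1) / 300 ms (T2); invalid
voxels carry NaN in ``value_ms`` and are excluded downstream via ``valid``.
Each voxel is fitted independently: results for any sub-block equal the
corresponding sub-block of the full fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Callable

import numpy as np
from scipy import optimize

from .volume_io import AcquisitionProtocol, ImageSeries, Modality

__all__ = [
    "Optimizer",
    "FitOptions",
    "ParameterMap",
    "ir_model",
    "t2_model",
    "fit_t1_map",
    "fit_t2_map",
    "filter_map",
    "grid_search_fit",
]

LN2 = float(np.log(2.0))
T1_BOUND_MS = 3000.0
T2_BOUND_MS = 300.0


class Optimizer(str, Enum):
    LEAST_SQUARES_LM = "lm"
    SIMPLEX = "simplex"


@dataclass(frozen=True)
class FitOptions:
    """Optimizer backend, convergence controls and plausibility bounds."""

    optimizer: Optimizer = Optimizer.LEAST_SQUARES_LM
    max_iterations: int = 500
    convergence_tol: float = 1e-6
    multistart_null_points: int = 3
    t1_bounds_ms: tuple[float, float] = (0.0, T1_BOUND_MS)
    t2_bounds_ms: tuple[float, float] = (0.0, T2_BOUND_MS)
    min_signal: float | None = None  # None -> 3x estimated background level
    t2_noise_floor_offset: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "optimizer", Optimizer(self.optimizer))
        if self.max_iterations <= 0 or self.convergence_tol <= 0:
            raise ValueError("max_iterations and convergence_tol must be > 0")
        for lo, hi in (self.t1_bounds_ms, self.t2_bounds_ms):
            if not (lo >= 0 and hi > lo):
                raise ValueError("bounds must satisfy 0 <= lo < hi")
        if self.multistart_null_points < 1:
            raise ValueError("multistart_null_points must be >= 1")


@dataclass
class ParameterMap:
    """Per-voxel fitted relaxation time with amplitudes, residual and mask.

    Invalid voxels (skipped background or filtered implausible fits) hold
    NaN in ``value_ms`` and False in ``valid``.
    """

    value_ms: np.ndarray
    amplitude: np.ndarray
    secondary: np.ndarray | None
    residual_rms: np.ndarray
    valid: np.ndarray
    modality: Modality
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value_ms.shape != self.valid.shape:
            raise ValueError("value_ms and valid shapes differ")


# ---------------------------------------------------------------------------
# Model equations


def ir_model(ti_ms, a, b, t1_ms):
    """Magnitude inversion-recovery signal |a * (1 - b * exp(-ti/t1))|."""
    if np.any(np.asarray(t1_ms) <= 0):
        raise ValueError("t1_ms must be > 0")
    ti = np.asarray(ti_ms, dtype=float)
    return np.abs(a * (1.0 - b * np.exp(-ti / t1_ms)))


def t2_model(te_ms, a, t2_ms):
    """Mono-exponential decay a * exp(-te/t2)."""
    if np.any(np.asarray(t2_ms) <= 0):
        raise ValueError("t2_ms must be > 0")
    te = np.asarray(te_ms, dtype=float)
    return a * np.exp(-te / t2_ms)


# ---------------------------------------------------------------------------
# Per-voxel solvers


def _ir_residual(params: np.ndarray, ti: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, t1 = params
    t1 = abs(t1) if t1 != 0 else 1e-6
    f = a * (1.0 - b * np.exp(-ti / t1))
    return np.abs(f) - y


def _ir_jac(params: np.ndarray, ti: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, t1 = params
    t1 = abs(t1) if t1 != 0 else 1e-6
    e = np.exp(-ti / t1)
    f = a * (1.0 - b * e)
    s = np.sign(f)
    jac = np.empty((len(ti), 3))
    jac[:, 0] = s * (1.0 - b * e)
    jac[:, 1] = s * (-a * e)
    jac[:, 2] = s * (-a * b * e * ti / t1**2)
    return jac


def _t2_residual(params: np.ndarray, te: np.ndarray, y: np.ndarray) -> np.ndarray:
    if len(params) == 3:
        a, t2, c = params
    else:
        (a, t2), c = params, 0.0
    t2 = abs(t2) if t2 != 0 else 1e-6
    return a * np.exp(-te / t2) + c - y


def _t2_jac(params: np.ndarray, te: np.ndarray, y: np.ndarray) -> np.ndarray:
    if len(params) == 3:
        a, t2, _ = params
    else:
        a, t2 = params
    t2 = abs(t2) if t2 != 0 else 1e-6
    e = np.exp(-te / t2)
    jac = np.empty((len(te), len(params)))
    jac[:, 0] = e
    jac[:, 1] = a * e * te / t2**2
    if len(params) == 3:
        jac[:, 2] = 1.0
    return jac


def _nm_run(
    sse: Callable, start: np.ndarray, f_ref: float, options: FitOptions, maxiter: int
):
    return optimize.minimize(
        sse,
        start,
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "xatol": options.convergence_tol * max(1.0, np.max(np.abs(start))),
            "fatol": options.convergence_tol * max(f_ref, 1e-12),
        },
    )


def _solve_multistart(
    residual: Callable,
    jac: Callable,
    starts: list[np.ndarray],
    times: np.ndarray,
    y: np.ndarray,
    options: FitOptions,
) -> tuple[np.ndarray, float] | None:
    """Best fit over multistart initializations; (params, SSE) or None.

    LM runs fully from every start (cheap with the analytic Jacobian). The
    simplex backend screens starts with a coarse Nelder-Mead pass, then
    polishes the winner with a full run plus one restart from the found
    optimum (a fresh simplex guards against premature collapse).
    """
    if options.optimizer is Optimizer.LEAST_SQUARES_LM:
        best_p, best_sse = None, np.inf
        for x0 in starts:
            try:
                res = optimize.least_squares(
                    residual,
                    x0,
                    jac=jac,
                    args=(times, y),
                    method="lm",
                    xtol=options.convergence_tol,
                    ftol=options.convergence_tol,
                    max_nfev=options.max_iterations * len(x0),
                )
            except Exception:
                continue
            if 2 * res.cost < best_sse:
                best_p, best_sse = res.x, float(2 * res.cost)
        return None if best_p is None else (best_p, best_sse)

    sse = lambda p: float(np.sum(residual(p, times, y) ** 2))
    coarse_iter = min(40, options.max_iterations)
    seed_x, seed_f = None, np.inf
    for x0 in starts:
        res = _nm_run(sse, x0, sse(x0), options, coarse_iter)
        if res.fun < seed_f:
            seed_x, seed_f = res.x, res.fun
    if seed_x is None:
        return None
    best = _nm_run(sse, seed_x, seed_f, options, options.max_iterations)
    restart = _nm_run(sse, best.x, best.fun, options, options.max_iterations)
    if restart.fun < best.fun:
        best = restart
    return best.x, float(best.fun)


def _estimate_min_signal(data: np.ndarray, options: FitOptions) -> float:
    """Default skip threshold: 3x the median border-voxel peak signal."""
    if options.min_signal is not None:
        return float(options.min_signal)
    peak = data.max(axis=3)
    border = np.ones(peak.shape, dtype=bool)
    if all(s > 2 for s in peak.shape):
        border[1:-1, 1:-1, 1:-1] = False
    return 3.0 * float(np.median(peak[border]))


def _t1_starts(ti: np.ndarray, y: np.ndarray, options: FitOptions) -> list[np.ndarray]:
    """Multistart T1 initializations around the observed signal minimum."""
    a0 = float(np.max(y))
    imin = int(np.argmin(y))
    candidates = [imin]
    for off in range(1, len(ti)):
        for j in (imin - off, imin + off):
            if 0 <= j < len(ti) and j not in candidates:
                candidates.append(j)
        if len(candidates) >= options.multistart_null_points:
            break
    starts = []
    for j in candidates[: options.multistart_null_points]:
        t1_0 = float(np.clip(ti[j] / LN2, 1.0, options.t1_bounds_ms[1]))
        starts.append(np.array([a0, 2.0, t1_0]))
    return starts


def _t2_start(te: np.ndarray, y: np.ndarray, options: FitOptions) -> np.ndarray:
    """Log-linear regression on the first half of echoes."""
    half = max(3, len(te) // 2)
    yy = y[:half]
    pos = yy > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(te[:half][pos], np.log(yy[pos]), 1)
        t2_0 = -1.0 / slope if slope < 0 else options.t2_bounds_ms[1]
        a0 = float(np.exp(intercept))
    else:
        t2_0, a0 = 50.0, float(np.max(y))
    t2_0 = float(np.clip(t2_0, 1.0, options.t2_bounds_ms[1]))
    if options.t2_noise_floor_offset:
        return np.array([a0, t2_0, 0.0])
    return np.array([a0, t2_0])


def _fit_map(
    series: ImageSeries,
    options: FitOptions,
    modality: Modality,
) -> ParameterMap:
    if series.protocol.modality is not modality:
        raise ValueError(
            f"series modality {series.protocol.modality} != expected {modality}"
        )
    times = series.protocol.times
    if len(times) < 3:
        raise ValueError("need >= 3 time points")
    is_t1 = modality is Modality.IR_T1
    residual = _ir_residual if is_t1 else _t2_residual
    jac = _ir_jac if is_t1 else _t2_jac

    shape = series.data.shape[:3]
    value = np.full(shape, np.nan)
    amplitude = np.full(shape, np.nan)
    secondary = np.full(shape, np.nan) if is_t1 else None
    resid = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)

    min_signal = _estimate_min_signal(series.data, options)
    flat = series.data.reshape(-1, len(times)).astype(float)
    fit_mask = flat.max(axis=1) > max(min_signal, 0.0)

    for idx in np.flatnonzero(fit_mask):
        y = flat[idx]
        if is_t1:
            starts = _t1_starts(times, y, options)
        else:
            starts = [_t2_start(times, y, options)]
        solved = _solve_multistart(residual, jac, starts, times, y, options)
        if solved is None:
            continue
        best_p, best_sse = solved
        iz = np.unravel_index(idx, shape)
        # time-constant parameters enter the model through |.|; normalize sign
        tval = abs(best_p[2] if is_t1 else best_p[1])
        value[iz] = tval
        amplitude[iz] = best_p[0]
        if is_t1:
            secondary[iz] = best_p[1]
        resid[iz] = np.sqrt(best_sse / len(times))
        valid[iz] = True

    pm = ParameterMap(
        value_ms=value,
        amplitude=amplitude,
        secondary=secondary,
        residual_rms=resid,
        valid=valid,
        modality=modality,
        provenance={
            "optimizer": options.optimizer.value,
            "min_signal": min_signal,
            "n_times": len(times),
        },
    )
    return filter_map(pm, options)


def fit_t1_map(series: ImageSeries, options: FitOptions | None = None) -> ParameterMap:
    """Fit the magnitude IR model voxel by voxel; returns a filtered T1 map."""
    return _fit_map(series, options or FitOptions(), Modality.IR_T1)


def fit_t2_map(series: ImageSeries, options: FitOptions | None = None) -> ParameterMap:
    """Fit the mono-exponential decay voxel by voxel; returns a filtered T2 map."""
    return _fit_map(series, options or FitOptions(), Modality.MULTIECHO_T2)


def filter_map(pm: ParameterMap, options: FitOptions | None = None) -> ParameterMap:
    """Discard implausible fits: value <= 0 or beyond the modality bound.

    Bounds are 3000 ms for T1 and 300 ms for T2, inclusive at the bound
    (strictly "greater than" is discarded). Values are left untouched;
    only the validity mask changes. Idempotent.
    """
    options = options or FitOptions()
    bound = (
        options.t1_bounds_ms[1]
        if pm.modality is Modality.IR_T1
        else options.t2_bounds_ms[1]
    )
    with np.errstate(invalid="ignore"):
        ok = (pm.value_ms > 0) & (pm.value_ms <= bound)
    return ParameterMap(
        value_ms=pm.value_ms,
        amplitude=pm.amplitude,
        secondary=pm.secondary,
        residual_rms=pm.residual_rms,
        valid=pm.valid & ok,
        modality=pm.modality,
        provenance={**pm.provenance, "filter_bound_ms": bound},
    )


# ---------------------------------------------------------------------------
# Brute-force grid oracle (testing aid)


def grid_search_fit(
    signal: np.ndarray,
    protocol: AcquisitionProtocol,
    value_grid: np.ndarray,
    model: str,
) -> tuple[float, float]:
    """Exhaustive search over a grid of candidate time constants.

    For each grid value, the decay term is fixed and the amplitude terms are
    solved in closed form by linear least squares; for the magnitude IR
    model every monotone sign pattern of the recovery curve is tried and
    the residual is evaluated against the true absolute-value objective.

    Returns ``(best_value_ms, best_residual_rms)``. Intended as a slow,
    independent oracle for optimizer testing.
    """
    grid = np.asarray(value_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty value grid")
    y = np.asarray(signal, dtype=float)
    times = protocol.times
    n = len(times)
    if model not in ("ir", "t2"):
        raise ValueError(f"model must be 'ir' or 't2', got {model!r}")

    best_value, best_sse = float(grid[0]), np.inf
    for v in grid:
        e = np.exp(-times / v)
        if model == "t2":
            denom = float(e @ e)
            a = float(e @ y) / denom if denom > 0 else 0.0
            r = a * e - y
            sse = float(r @ r)
        else:
            # signed model u - w*e fitted to polarity-restored data; the
            # recovery crosses zero at most once so only threshold sign
            # patterns (first k points negative) need be tried
            design = np.stack([np.ones(n), -e], axis=1)
            sse = np.inf
            for k in range(n + 1):
                ysigned = y.copy()
                ysigned[:k] *= -1.0
                coef, *_ = np.linalg.lstsq(design, ysigned, rcond=None)
                fitted = design @ coef
                r = np.abs(fitted) - y
                sse = min(sse, float(r @ r))
        if sse < best_sse:
            best_value, best_sse = float(v), sse
    return best_value, float(np.sqrt(best_sse / n))
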