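"""Constraint filtering of posterior draws and derived kinetic quantities.

Per draw, the cubic's critical points give the peak time (t_max, local
maximum of the fitted curve), minimum time (t_min), peak concentration
(cort_max, the cubic evaluated at t_max), distribution time (= t_max) and
elimination time (= t_min - t_max).  Draws are retained only when a local
maximum exists at t > 0 and the curve stays strictly positive across the
sampling window.

Note on cort_max: the source methodology describes back-substituting t_max
into the first-derivative equation, which is identically zero at a critical
point; we evaluate the cubic itself at t_max, which is the only reading
that yields a concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import N_COEF, PosteriorDraws, predict_curve

DEFAULT_GRID_STEP = 0.1  # hours, positivity check resolution


def cubic_eval(beta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Horner evaluation ((b3*t + b2)*t + b1)*t + b0, elementwise.

    Horner keeps scalar and vectorized evaluation bitwise identical, so
    exported draw tables can be recounted exactly.
    """
    beta = np.asarray(beta, dtype=float)
    b0, b1, b2, b3 = beta[..., 0], beta[..., 1], beta[..., 2], beta[..., 3]
    return ((b3 * t + b2) * t + b1) * t + b0


@dataclass(frozen=True)
class CriticalPoints:
    """Times of the cubic's local maximum / minimum; None when absent."""

    t_max: float | None
    t_min: float | None


def critical_points(coeffs: np.ndarray) -> CriticalPoints:
    """Solve 3*b3*t^2 + 2*b2*t + b1 = 0 and classify the roots.

    Classification is by the sign of the second derivative 6*b3*t + 2*b2
    (negative -> local maximum).  Returns (None, None) when the derivative
    has no real root with a sign change (monotone cubic, or b3 = b2 = 0).
    """
    b0, b1, b2, b3 = np.asarray(coeffs, dtype=float)
    if b3 != 0.0:
        disc = b2 * b2 - 3.0 * b3 * b1
        if disc <= 0.0:
            return CriticalPoints(None, None)
        # numerically stable quadratic roots (avoids cancellation for small b3)
        sq = np.sqrt(disc)
        q = -(b2 + np.copysign(sq, b2)) if b2 != 0.0 else -sq
        with np.errstate(over="ignore"):
            r1 = q / (3.0 * b3)
        r2 = b1 / q
        if np.isfinite(r1):
            out = {"t_max": None, "t_min": None}
            for r in (r1, r2):
                second = 6.0 * b3 * r + 2.0 * b2
                if second < 0:
                    out["t_max"] = float(r)
                elif second > 0:
                    out["t_min"] = float(r)
            return CriticalPoints(**out)
        # 3*b3 underflows against q: one root beyond float range, treat the
        # derivative as effectively quadratic
    if b2 == 0.0:
        return CriticalPoints(None, None)  # linear: no interior extremum
    t = -b1 / (2.0 * b2)
    if b2 < 0:
        return CriticalPoints(t_max=t, t_min=None)
    return CriticalPoints(t_max=None, t_min=t)


def _critical_points_vec(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (t_max, t_min) for an (n, 4) coefficient array; NaN = absent."""
    b1, b2, b3 = beta[:, 1], beta[:, 2], beta[:, 3]
    t_max = np.full(len(beta), np.nan)
    t_min = np.full(len(beta), np.nan)

    cubic = b3 != 0.0
    disc = b2 * b2 - 3.0 * b3 * b1
    ok = cubic & (disc > 0.0)
    if np.any(ok):
        sq = np.sqrt(disc[ok])
        q = np.where(b2[ok] != 0.0, -(b2[ok] + np.copysign(sq, b2[ok])), -sq)
        with np.errstate(over="ignore"):
            r1 = q / (3.0 * b3[ok])
        r2 = b1[ok] / q
        # second derivative sign: 6*b3*r + 2*b2; for b3>0 the smaller root is
        # the max, for b3<0 the larger one
        pos = b3[ok] > 0
        t_max[ok] = np.where(pos, np.minimum(r1, r2), np.maximum(r1, r2))
        t_min[ok] = np.where(pos, np.maximum(r1, r2), np.minimum(r1, r2))
        # leading coefficient so small one root overflowed: effectively quadratic
        blown = np.zeros(len(beta), dtype=bool)
        blown[ok] = ~np.isfinite(r1)
        if np.any(blown):
            cubic = cubic & ~blown
            t_max[blown] = np.nan
            t_min[blown] = np.nan

    quad = (~cubic) & (b2 != 0.0)
    if np.any(quad):
        vertex = -b1[quad] / (2.0 * b2[quad])
        is_max = b2[quad] < 0
        t_max[quad] = np.where(is_max, vertex, np.nan)
        t_min[quad] = np.where(is_max, np.nan, vertex)
    return t_max, t_min


def constraint_filter(
    draws: PosteriorDraws,
    window: tuple[float, float],
    grid_step: float = DEFAULT_GRID_STEP,
) -> PosteriorDraws:
    """Set ``retained_mask``: local max exists at t > 0 AND the cubic is
    strictly positive at every grid point spanning the window.

    Draws are never deleted; the mask is recorded on the returned object
    (same instance, mutated in place for the mask and returned for
    chaining).
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must satisfy lo < hi")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    beta = draws.flat_beta
    t_max, _ = _critical_points_vec(beta)
    has_max = ~np.isnan(t_max) & (t_max > 0.0)
    curves = predict_curve(beta, grid)
    positive = np.all(curves > 0.0, axis=1)
    draws.retained_mask = (has_max & positive).reshape(draws.sigma.shape)
    return draws


def derive_all(draws: PosteriorDraws) -> pd.DataFrame:
    """Derived kinetic quantities for every retained draw.

    Returns a frame indexed by flat draw id with columns t_max, t_min,
    cort_max, distribution_time, elimination_time and min_before_max.
    elimination_time is NaN (flagged via min_before_max) for draws whose
    local minimum precedes the maximum (b3 < 0), where "time from peak to
    minimum" is undefined.
    """
    mask = draws.flat_retained
    if not mask.any():
        raise ValueError(
            "no retained draws: every posterior draw violated the a priori "
            "constraints (positive curve, local max at t > 0)"
        )
    beta = draws.flat_beta[mask]
    t_max, t_min = _critical_points_vec(beta)
    if np.any(np.isnan(t_max)):
        raise RuntimeError("retained draw without a local maximum (contract breach)")
    cort_max = cubic_eval(beta, t_max)
    elim = t_min - t_max
    min_before_max = ~np.isnan(t_min) & (elim <= 0)
    elim = np.where(np.isnan(t_min) | min_before_max, np.nan, elim)
    return pd.DataFrame(
        {
            "draw": np.flatnonzero(mask),
            "t_max": t_max,
            "t_min": t_min,
            "cort_max": cort_max,
            "distribution_time": t_max,
            "elimination_time": elim,
            "min_before_max": min_before_max,
        }
    ).set_index("draw")


QUANTITIES = ("t_max", "t_min", "cort_max", "distribution_time", "elimination_time")


def summarize_derived(derived: pd.DataFrame, ci_level: float = 0.90) -> pd.DataFrame:
    """Mean and equal-tailed credible interval per derived quantity.

    Quantiles use linear interpolation between order statistics.  NaN
    entries (flagged elimination times) are dropped per quantity; the
    effective draw count is reported alongside.
    """
    if derived.empty:
        raise ValueError("no derived draws to summarize")
    alpha = (1.0 - ci_level) / 2.0
    rows = []
    for q in QUANTITIES:
        vals = derived[q].dropna().to_numpy()
        if vals.size == 0:
            rows.append({"quantity": q, "mean": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n": 0})
            continue
        lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
        rows.append(
            {"quantity": q, "mean": float(vals.mean()), "ci_low": float(lo),
             "ci_high": float(hi), "n": int(vals.size)}
        )
    out = pd.DataFrame(rows).set_index("quantity")
    bad = out.dropna().query("ci_low > ci_high")
    if len(bad):
        raise AssertionError(f"CI bounds out of order for {bad.index.tolist()}")
    return out


def grid_argmax(coeffs: np.ndarray, window: tuple[float, float], step: float = 0.01
                ) -> tuple[float, float]:
    """Brute-force argmax of a cubic over a window (independent oracle)."""
    lo, hi = window
    grid = np.arange(lo, hi + step / 2, step)
    vals = predict_curve(np.asarray(coeffs, dtype=float), grid)
    i = int(np.argmax(vals))
    return float(grid[i]), float(vals[i])
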