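"""Sigmoidal melting-curve models and nonlinear fits.

The soluble (non-denatured) fraction of a protein after a brief heat
challenge at temperature ``T`` is modeled by a four-parameter sigmoid,

    I(T) = I_min + (I_max - I_min) / (1 + exp[(T_m/T - 1) * s * T_m])

with asymptotic plateaus ``I_min``/``I_max``, the melting point ``T_m`` at
the curve midpoint and a slope parameter ``s`` (negative for proteins that
melt, i.e. lose solubility with heating).  An equivalent two-parameter shape
description uses ``a`` and ``b`` via ``exp[-(a/T - b)]`` with
``T_m = a/b`` and ``s = -b**2/a``.

Temperatures are in degrees Celsius throughout: melting points are reported
on the Celsius scale and the model is fitted on a Celsius grid, so the
``T_m/T`` ratio is a Celsius-scale ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class MeltingParams:
    """Parameters of the sigmoidal melting model."""

    i_min: float
    i_max: float
    tm: float
    s: float

    def predict(self, temperature) -> np.ndarray:
        return melting_model(temperature, self.i_min, self.i_max, self.tm, self.s)

    def as_ab(self) -> tuple[float, float]:
        """Return the (a, b) shape parameters: b = -s*T_m, a = -s*T_m**2."""
        return -self.s * self.tm**2, -self.s * self.tm


@dataclass
class FitDiagnostics:
    converged: bool
    n_params: int = 4
    rss: float = float("nan")
    n_points: int = 0
    start: Optional[tuple] = None
    failure_reason: Optional[str] = None


def melting_model(temperature, i_min: float, i_max: float, tm: float, s: float):
    """Evaluate the four-parameter melting sigmoid at Celsius temperature(s).

    Raises ``ValueError`` for non-positive temperatures (the model's
    ``T_m/T`` ratio is undefined there).
    """
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Celsius scale)")
    z = (tm / t - 1.0) * s * tm
    # clip the exponent to avoid overflow for extreme starts during fitting
    out = i_min + (i_max - i_min) / (1.0 + np.exp(np.clip(z, -700, 700)))
    return out if out.shape else float(out)


def melting_model_ab(temperature, i_min: float, i_max: float, a: float, b: float):
    """Evaluate the (a, b)-parameterized sigmoid, exp[-(a/T - b)] form."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Celsius scale)")
    z = -(a / t - b)
    out = i_min + (i_max - i_min) / (1.0 + np.exp(np.clip(z, -700, 700)))
    return out if out.shape else float(out)


def params_from_ab(a: float, b: float) -> tuple[float, float]:
    """Convert shape parameters (a, b) to (T_m, s) = (a/b, -b**2/a)."""
    if a == 0 or b == 0:
        raise ValueError("a and b must be nonzero")
    return a / b, -(b**2) / a


def ab_from_params(tm: float, s: float) -> tuple[float, float]:
    """Inverse of :func:`params_from_ab`: a = -s*T_m**2, b = -s*T_m."""
    if tm == 0 or s == 0:
        raise ValueError("tm and s must be nonzero")
    return -s * tm**2, -s * tm


def _half_crossing_temperature(t: np.ndarray, y: np.ndarray) -> float:
    """Temperature where the data first cross halfway between min and max."""
    half = 0.5 * (np.min(y) + np.max(y))
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    below = ys <= half
    if below.any() and not below.all():
        i = int(np.argmax(below)) if not below[0] else int(np.argmax(~below))
        i = max(1, min(i, len(ts) - 1))
        return float(0.5 * (ts[i - 1] + ts[i]))
    return float(np.median(ts))


def fit_melting(
    temperatures: Sequence[float],
    intensities: Sequence[float],
    allow_fallback: bool = True,
    xtol: float = 1e-8,
) -> tuple[Optional[MeltingParams], FitDiagnostics]:
    """Least-squares fit of the melting sigmoid.

    A small multi-start grid is tried (two ``T_m`` starts: the median
    temperature and the half-range crossing; two slope starts; plateaus from
    the data range) and the lowest-RSS converged solution wins.  If the
    four-parameter fit fails or lands on a parameter bound, a
    three-parameter fit with ``I_min = 0`` is attempted as fallback.
    Unweighted least squares.
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(intensities, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]

    diag = FitDiagnostics(converged=False, n_points=len(y))
    n_distinct = len(np.unique(t))
    if n_distinct < 4:
        if n_distinct < 3:
            raise ValueError(
                f"need >=3 distinct temperatures, got {n_distinct}"
            )
        # only the 3-parameter model is identifiable
        params, diag = _fit_mode(t, y, n_params=3, xtol=xtol)
        return params, diag

    params, diag = _fit_mode(t, y, n_params=4, xtol=xtol)
    if params is None and allow_fallback:
        params, diag = _fit_mode(t, y, n_params=3, xtol=xtol)
        if params is None:
            diag.failure_reason = "4- and 3-parameter fits both failed"
    return params, diag


def _sigmoid_parts(t, i_min, i_max, tm, s):
    z = np.clip((tm / t - 1.0) * s * tm, -700, 700)
    e = np.exp(z)
    d = 1.0 / (1.0 + e)
    return z, e, d


def _jac4(t, i_min, i_max, tm, s):
    z, e, d = _sigmoid_parts(t, i_min, i_max, tm, s)
    dz = -(i_max - i_min) * d * d * e
    return np.column_stack([
        1.0 - d,                      # d/d i_min
        d,                            # d/d i_max
        dz * (2.0 * s * tm / t - s),  # d/d tm
        dz * (tm**2 / t - tm),        # d/d s
    ])


def _jac3(t, i_max, tm, s):
    return _jac4(t, 0.0, i_max, tm, s)[:, 1:]


def _fit_mode(t, y, n_params: int, xtol: float):
    tm_lo, tm_hi = float(t.min() - 10.0), float(t.max() + 10.0)
    y_min, y_max = float(np.min(y)), float(np.max(y))
    span = max(y_max - y_min, abs(y_max), 1e-12)

    tm_starts = (float(np.median(t)), _half_crossing_temperature(t, y))
    s_starts = (-0.5, -0.05)

    best = None  # (rss, popt, start)
    for tm0 in tm_starts:
        for s0 in s_starts:
            if n_params == 4:
                p0 = [max(y_min, 0.0), y_max, tm0, s0]
                lower = [0.0, 1e-12, tm_lo, -10.0]
                upper = [np.inf, np.inf, tm_hi, 10.0]
                model, jac = melting_model, _jac4
            else:
                p0 = [y_max, tm0, s0]
                lower = [1e-12, tm_lo, -10.0]
                upper = [np.inf, tm_hi, 10.0]

                def model(temp, i_max, tm, s):
                    return melting_model(temp, 0.0, i_max, tm, s)

                jac = _jac3

            try:
                popt, _ = curve_fit(
                    model, t, y, p0=p0, jac=jac,
                    bounds=(lower, upper), xtol=xtol, maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((model(t, *popt) - y) ** 2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, popt, (tm0, s0))

    diag = FitDiagnostics(converged=False, n_params=n_params, n_points=len(y))
    if best is None:
        diag.failure_reason = f"{n_params}-parameter fit did not converge"
        return None, diag

    rss, popt, start = best
    if n_params == 4:
        i_min, i_max, tm, s = (float(v) for v in popt)
    else:
        i_min = 0.0
        i_max, tm, s = (float(v) for v in popt)

    # a T_m pinned to the search bound means the curve shape is not
    # determined by the data -> treat as non-converged (caller may fall back)
    if abs(tm - tm_lo) < 1e-6 or abs(tm - tm_hi) < 1e-6:
        diag.failure_reason = "melting point at search bound"
        return None, diag
    if n_params == 4 and i_min >= i_max:
        diag.failure_reason = "plateaus inverted (I_min >= I_max)"
        return None, diag

    diag.converged = True
    diag.rss = rss
    diag.start = start
    return MeltingParams(i_min=i_min, i_max=i_max, tm=tm, s=s), diag


def fit_scaling_factor(
    intensities: Sequence[float],
    temperatures: Sequence[float],
    frozen: MeltingParams,
) -> float:
    """Least-squares scale factor of data onto a frozen melting curve.

    Fits ``I_i(T) = sf_i * model(T)`` with the model parameters held fixed;
    the single-parameter least-squares solution is closed form,
    ``sf = sum(y*m) / sum(m**2)`` with ``m`` the frozen model values.
    """
    y = np.asarray(intensities, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    keep = np.isfinite(y) & np.isfinite(t)
    y, t = y[keep], t[keep]
    if len(y) == 0:
        raise ValueError("no finite data points")
    m = np.asarray(frozen.predict(t), dtype=float)
    denom = float(np.sum(m**2))
    if denom == 0:
        raise ValueError("frozen model evaluates to zero at all points")
    return float(np.sum(y * m) / denom)
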