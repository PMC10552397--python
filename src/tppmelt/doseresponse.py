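"""Sigmoidal dose-response fitting for compound-concentration-range data.

The relative soluble-protein intensity as a function of compound
concentration is modeled with the standard four-parameter log-logistic
curve in log10-dose,

    y(c) = r_low + (r_high - r_low) / (1 + 10^[H * (pc - pEC50)])

where ``pc = -log10(c in M)`` and ``pEC50 = -log10(EC50 in M)``.  At
``c = EC50`` the curve sits halfway between the plateaus.  The
parameterization carries an exact symmetry (negating ``H`` while swapping
the plateaus leaves the curve unchanged); fitted parameters are
canonicalized to ``H > 0`` so the response direction is simply
``sign(r_high - r_low)``.

Fit quality is rated by a pseudo-coefficient of determination,
pseudo-R^2 = 1 - RSS/TSS ("pseudo" because the model is nonlinear).
Proteins whose 50 deg C fit exceeds a pseudo-R^2 threshold (default 0.8)
are dose responders; contrasting against the 37 deg C control
discriminates thermal-stability effects (high pseudo-R^2 difference) from
abundance effects (similar dose response at both temperatures).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

#: Multi-start grid for the first series of fits.
PEC50_STARTS = (9.5, 8.2, 6.8, 5.5)
HILL_STARTS = (-3.0, -0.33, 0.33, 3.0)

PEC50_BOUNDS = (4.0, 12.0)


@dataclass(frozen=True)
class DoseResponseParams:
    """Four-parameter log-logistic curve (canonical H > 0)."""

    pec50: float
    hill: float
    r_low: float
    r_high: float

    def predict(self, concentration_nm):
        return dr_model(concentration_nm, self.pec50, self.hill,
                        self.r_low, self.r_high)

    @property
    def ec50_nm(self) -> float:
        return pec50_to_ec50(self.pec50)


@dataclass
class DoseResponseFit:
    params: Optional[DoseResponseParams]
    pseudo_r2: float
    converged: bool
    on_bound: bool = False
    constant_data: bool = False
    start: Optional[tuple] = None
    rss: float = float("nan")
    n_points: int = 0


@dataclass
class DoseResponseResult:
    """Per-protein 50 vs 37 deg C dose-response contrast."""

    protein_id: str
    fit_50: DoseResponseFit
    fit_37: DoseResponseFit
    direction: str  # positive | negative | none
    mechanism: str  # stability | abundance | mixed | none

    @property
    def pseudo_r2_50(self) -> float:
        return self.fit_50.pseudo_r2

    @property
    def pseudo_r2_37(self) -> float:
        return self.fit_37.pseudo_r2

    @property
    def r2_difference(self) -> float:
        return self.fit_50.pseudo_r2 - self.fit_37.pseudo_r2


def _pc(concentration_nm):
    c = np.asarray(concentration_nm, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be positive (vehicle is handled "
                         "by normalization, not on the log-dose axis)")
    return 9.0 - np.log10(c)


def dr_model(concentration_nm, pec50: float, hill: float,
             r_low: float, r_high: float):
    """Evaluate the log-logistic dose-response curve at nM concentration."""
    pc = _pc(concentration_nm)
    z = hill * (pc - pec50)
    out = r_low + (r_high - r_low) / (1.0 + np.power(10.0, np.clip(z, -300, 300)))
    return out if out.shape else float(out)


def _dr_jac(concentration_nm, pec50, hill, r_low, r_high):
    pc = _pc(concentration_nm)
    z = np.clip(hill * (pc - pec50), -300, 300)
    p = np.power(10.0, z)
    f = 1.0 / (1.0 + p)
    span = r_high - r_low
    ln10 = np.log(10.0)
    dfdz = -ln10 * p * f * f
    return np.column_stack([
        span * dfdz * (-hill),        # d/d pec50
        span * dfdz * (pc - pec50),   # d/d hill
        1.0 - f,                      # d/d r_low
        f,                            # d/d r_high
    ])


def pec50_to_ec50(pec50: float) -> float:
    """Convert pEC50 (molar scale) to EC50 in nM: 10^(9 - pEC50)."""
    return float(10.0 ** (9.0 - pec50))


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (for display)."""
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + digits - 1))


def fit_dose_response(
    concentrations_nm: Sequence[float],
    responses: Sequence[float],
    xtol: float = 1e-10,
) -> DoseResponseFit:
    """Best-of-16 multi-start least-squares fit of the dose-response curve.

    Only nonzero concentrations enter the fit (at least 4 distinct ones are
    required); the vehicle point has no defensible log-dose coordinate.
    The winning fit is canonicalized to ``hill > 0``.  A fit whose pEC50
    lands on the search bound [4, 12] is flagged (``on_bound``) and treated
    as a non-responder downstream.
    """
    c = np.asarray(concentrations_nm, dtype=float)
    y = np.asarray(responses, dtype=float)
    keep = np.isfinite(c) & np.isfinite(y) & (c > 0)
    c, y = c[keep], y[keep]
    n_distinct = len(np.unique(c))
    if n_distinct < 4:
        raise ValueError(f"need >=4 distinct nonzero concentrations, got {n_distinct}")

    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return DoseResponseFit(params=None, pseudo_r2=0.0, converged=False,
                               constant_data=True, n_points=len(y))

    # plateau starts taken from the dose extremes so either direction is
    # reachable from every grid point
    order = np.argsort(c)
    lo_start = float(np.mean(y[order][: max(1, len(y) // 4)]))
    hi_start = float(np.mean(y[order][-max(1, len(y) // 4):]))

    best = None
    for p0_pec50 in PEC50_STARTS:
        for p0_h in HILL_STARTS:
            p0 = [p0_pec50, p0_h, lo_start, hi_start]
            try:
                popt, _ = curve_fit(
                    dr_model, c, y, p0=p0, jac=_dr_jac,
                    bounds=([PEC50_BOUNDS[0], -20, -np.inf, -np.inf],
                            [PEC50_BOUNDS[1], 20, np.inf, np.inf]),
                    xtol=xtol, maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((dr_model(c, *popt) - y) ** 2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, popt, (p0_pec50, p0_h))

    if best is None:
        return DoseResponseFit(params=None, pseudo_r2=0.0, converged=False,
                               n_points=len(y))

    rss, popt, start = best
    pec50, hill, r_low, r_high = (float(v) for v in popt)
    if hill < 0:  # collapse the sign symmetry
        hill, r_low, r_high = -hill, r_high, r_low
    on_bound = (
        abs(pec50 - PEC50_BOUNDS[0]) < 1e-6 or abs(pec50 - PEC50_BOUNDS[1]) < 1e-6
    )
    params = DoseResponseParams(pec50=pec50, hill=hill, r_low=r_low, r_high=r_high)
    return DoseResponseFit(
        params=params, pseudo_r2=1.0 - rss / tss, converged=True,
        on_bound=on_bound, start=start, rss=rss, n_points=len(y),
    )


def classify_ccr(
    protein_id: str,
    fit_50: DoseResponseFit,
    fit_37: DoseResponseFit,
    r2_threshold: float = 0.8,
    r2_difference_threshold: float = 0.4,
) -> DoseResponseResult:
    """Call responder direction and mechanism from the 50/37 deg C contrast.

    direction: positive/negative by the plateau contrast of the 50 deg C
    fit when its pseudo-R^2 reaches the responder threshold, else none.
    mechanism (responders only): *stability* when the dose response is
    confined to 50 deg C (large pseudo-R^2 difference, 37 deg C below
    threshold); *abundance* when both temperatures respond in the same
    direction; *mixed* otherwise.
    """
    direction = "none"
    if (fit_50.converged and not fit_50.on_bound
            and fit_50.pseudo_r2 >= r2_threshold):
        delta = fit_50.params.r_high - fit_50.params.r_low
        direction = "positive" if delta > 0 else "negative"

    mechanism = "none"
    if direction != "none":
        r2_diff = fit_50.pseudo_r2 - fit_37.pseudo_r2
        resp_37 = fit_37.converged and fit_37.pseudo_r2 >= r2_threshold
        if resp_37:
            delta37 = fit_37.params.r_high - fit_37.params.r_low
            dir_37 = "positive" if delta37 > 0 else "negative"
            mechanism = "abundance" if dir_37 == direction else "mixed"
        elif r2_diff >= r2_difference_threshold:
            mechanism = "stability"
        else:
            mechanism = "mixed"

    return DoseResponseResult(
        protein_id=protein_id, fit_50=fit_50, fit_37=fit_37,
        direction=direction, mechanism=mechanism,
    )
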