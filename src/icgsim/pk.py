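"""Pharmacokinetic parameters of an ICG liver function test.

From a simulated plasma disappearance curve the module derives the clinical
ICG parameters: elimination rate constant kel (log-linear fit on the
mono-exponential window), plasma disappearance rate PDR = 100·kel [%/min],
half-life t_1/2 = ln(2)/kel [min], retention ratios R15/R20 (% of the
back-extrapolated initial concentration remaining at 15/20 min), AUC and
clearance (Dose/AUC for a bolus, rate/C_ss for a constant infusion).

PDR and t_1/2 are derived fields of kel, never independently fit, so the
identities PDR = 100·kel and t_1/2·kel = ln 2 hold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DoseProtocol, Timecourse, check_steady_state

__all__ = [
    "PKResult", "fit_kel", "retention", "auc_inf",
    "clearance_bolus", "clearance_infusion", "compute_pk",
    "DEFAULT_FIT_WINDOW", "KEL_FLOOR",
]

#: default log-linear fit window [min] post bolus: inside the clinical
#: mono-exponential phase, past the initial mixing transient
DEFAULT_FIT_WINDOW = (5.0, 15.0)

#: kel below this (1/min) is treated as "no elimination" (flat curve)
KEL_FLOOR = 1e-9


@dataclass(frozen=True)
class PKResult:
    """Derived PK parameters of one ICG test."""

    kel: float            # 1/min
    pdr: float            # %/min, = 100 * kel
    t_half: float         # min, = ln(2) / kel
    r15: float            # % of back-extrapolated C0 at 15 min
    r20: float            # % at 20 min
    auc_inf: float        # mg*min/L
    cl: float             # mL/min
    cl_per_bw: float      # mL/min/kg
    er: float | None      # hepatic extraction ratio (infusion tests only)
    c0: float             # back-extrapolated initial concentration [mg/L]
    fit_window: tuple[float, float]
    fit_r_squared: float


def fit_kel(tc: Timecourse,
            window: tuple[float, float] = DEFAULT_FIT_WINDOW
            ) -> tuple[float, float, float]:
    """Log-linear fit of the plasma curve: returns (kel, r², C0).

    Least-squares slope of ln C vs t on the window; kel is the negated
    slope, C0 the back-extrapolated intercept at t = 0.
    """
    t = tc.time
    c = tc.plasma_concentration
    mask = (t >= window[0]) & (t <= window[1])
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 sampling points in fit window {window}")
    tw, cw = t[mask], c[mask]
    if np.any(cw <= 0):
        raise ValueError("non-positive plasma concentrations in fit window")
    logc = np.log(cw)
    slope, intercept = np.polyfit(tw, logc, 1)
    resid = logc - (slope * tw + intercept)
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(-slope), r2, float(np.exp(intercept))


def retention(tc: Timecourse, t: float, c0: float) -> float:
    """Retention ratio 100·C(t)/C0 [%] (linear interpolation off-grid)."""
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    ct = float(np.interp(t, tc.time, tc.plasma_concentration))
    return 100.0 * ct / c0


def auc_inf(tc: Timecourse, kel: float) -> float:
    """AUC to infinity: trapezoidal over the grid plus tail C(t_end)/kel."""
    auc_grid = float(np.trapezoid(tc.plasma_concentration, tc.time))
    c_end = float(tc.plasma_concentration[-1])
    if kel <= KEL_FLOOR:
        if c_end > 0:
            raise ValueError("AUC diverges: kel <= 0 with nonzero terminal concentration")
        return auc_grid
    return auc_grid + c_end / kel


def clearance_bolus(dose: float, auc: float) -> float:
    """Bolus clearance CL = Dose/AUC_inf, in mL/min (dose mg, AUC mg·min/L)."""
    if dose == 0:
        return 0.0
    if auc <= 0:
        raise ValueError("AUC must be positive for a nonzero dose")
    return 1000.0 * dose / auc


def clearance_infusion(rate: float, c_ss: float) -> float:
    """Infusion clearance CL = rate/C_ss in mL/min (rate mg/min, C_ss mg/L)."""
    if rate <= 0:
        raise ValueError("infusion clearance requires a positive infusion rate")
    if c_ss <= 0:
        raise ValueError("steady-state concentration must be positive")
    return 1000.0 * rate / c_ss


def compute_pk(tc: Timecourse,
               window: tuple[float, float] = DEFAULT_FIT_WINDOW) -> PKResult:
    """Assemble the full PKResult for one simulated ICG test.

    For bolus tests clearance is Dose/AUC_inf; for infusion tests clearance is
    rate/C_ss at verified steady state and the extraction ratio is reported.
    A non-eliminating curve (kel below floor, e.g. absent OATP1B3) yields
    retention ~100%, infinite half-life and zero clearance.
    """
    protocol = tc.protocol
    kel, r2, c0 = fit_kel(tc, window)
    kel = max(kel, 0.0)
    pdr = 100.0 * kel
    t_half = math.log(2.0) / kel if kel > KEL_FLOOR else math.inf
    r15 = retention(tc, 15.0, c0)
    r20 = retention(tc, 20.0, c0)

    bw = tc.params.body_weight
    er = None
    if protocol.mode == "bolus":
        dose = float(tc.dose_mg[-1])
        if kel > KEL_FLOOR:
            auc = auc_inf(tc, kel)
            cl = clearance_bolus(dose, auc)
        else:
            auc = math.inf
            cl = 0.0
    else:
        check_steady_state(tc)
        c_ss = float(tc.plasma_concentration[-1])
        cl = clearance_infusion(protocol.infusion_rate, c_ss)
        auc = math.inf
        c_in = float(tc.liver_inflow_concentration[-1])
        if c_in > 0:
            er = float((c_in - tc.liver_outflow_concentration[-1]) / c_in)
        else:
            er = 0.0
    return PKResult(
        kel=kel, pdr=pdr, t_half=t_half, r15=r15, r20=r20, auc_inf=auc,
        cl=cl, cl_per_bw=cl / bw, er=er, c0=c0,
        fit_window=(float(window[0]), float(window[1])), fit_r_squared=r2)
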