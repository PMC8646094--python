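"""Computational experiments over the ICG model.

Reproduces the study design of the variability analysis: six-factor
parameter scans across four cirrhosis degrees, per-individual ICG tests over
a virtual cohort, stratified summary statistics (Tukey boxplot statistics),
PK-parameter correlation analyses (R20 vs t_1/2 collapse, bolus vs infusion
clearance, PDR dose comparison) and single-factor contribution scans.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .model import (DoseProtocol, Individual, INFUSION_PROTOCOL,
                    ModelParameters, REFERENCE_PARAMETERS, SimulationError,
                    simulate)
from .pk import DEFAULT_FIT_WINDOW, PKResult, compute_pk

__all__ = [
    "ScanSpec", "CIRRHOSIS_DEGREES", "SCAN_FACTORS", "default_grid",
    "run_scan", "run_individual", "run_population", "stratify", "correlate",
    "dose_comparison", "single_factor_contribution",
]

#: f_cirrhosis values encoding control, mild, moderate, severe cirrhosis
CIRRHOSIS_DEGREES = (0.0, 0.40, 0.70, 0.81)

#: scannable factors and how each maps onto an Individual field
SCAN_FACTORS = {
    "f_bloodflow": "f_bloodflow",
    "f_cardiac_output": "f_cardiac_output",
    "f_oatp1b3": "f_oatp1b3",
    "fv_liver": "fv_liver",
    "body_weight": "body_weight",
    "bil_ext": "bil_ext",
}

_REFERENCE_VALUES = {
    "f_bloodflow": 1.0, "f_cardiac_output": 1.0, "f_oatp1b3": 1.0,
    "fv_liver": 0.021, "body_weight": 75.0, "bil_ext": 1.0,
}

_PK_FIELDS = ("kel", "pdr", "t_half", "r15", "r20", "auc_inf", "cl",
              "cl_per_bw", "c0", "fit_r_squared")


def default_grid(factor: str, n: int = 21) -> np.ndarray:
    """Default scan grid: linear [0.2, 2.0]x reference for relative scalers,
    [40, 140] kg for body weight, [0.01, 0.04] L/kg for liver volume, and a
    log grid over [1, 100]x for bilirubin."""
    if factor == "bil_ext":
        return np.logspace(0.0, 2.0, n)
    if factor == "body_weight":
        return np.linspace(40.0, 140.0, n)
    if factor == "fv_liver":
        return np.linspace(0.01, 0.04, n)
    if factor in SCAN_FACTORS:
        return np.linspace(0.2, 2.0, n)
    raise ValueError(f"unknown scan factor {factor!r}")


@dataclass(frozen=True)
class ScanSpec:
    """One-factor parameter scan across cirrhosis degrees."""

    factor: str
    grid: np.ndarray | None = None
    degrees: tuple[float, ...] = CIRRHOSIS_DEGREES
    protocol: DoseProtocol = field(default_factory=DoseProtocol)
    log_scale: bool | None = None   # informational; bilirubin grids are log

    def __post_init__(self) -> None:
        if self.factor not in SCAN_FACTORS:
            raise ValueError(f"unknown scan factor {self.factor!r}; "
                             f"expected one of {sorted(SCAN_FACTORS)}")
        grid = np.asarray(self.grid if self.grid is not None
                          else default_grid(self.factor), dtype=float)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be non-empty and strictly increasing")
        object.__setattr__(self, "grid", grid)
        if self.log_scale is None:
            object.__setattr__(self, "log_scale", self.factor == "bil_ext")
        for d in self.degrees:
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"cirrhosis degree {d} outside [0, 1]")


def _individual_for(factor: str, value: float, f_cirrhosis: float) -> Individual:
    kwargs = {SCAN_FACTORS[factor]: value, "f_cirrhosis": f_cirrhosis}
    return Individual(**kwargs)


def _pk_row(res: PKResult) -> dict:
    row = {f: getattr(res, f) for f in _PK_FIELDS}
    row["er"] = res.er
    return row


def run_individual(individual: Individual,
                   protocol: DoseProtocol,
                   defaults: ModelParameters = REFERENCE_PARAMETERS,
                   window: tuple[float, float] = DEFAULT_FIT_WINDOW) -> PKResult:
    """Simulate one ICG test and compute its PK parameters."""
    return compute_pk(simulate(individual, protocol, defaults), window)


def run_scan(spec: ScanSpec,
             defaults: ModelParameters = REFERENCE_PARAMETERS) -> pd.DataFrame:
    """Run the scan: one row per (grid value x cirrhosis degree).

    All other factors stay at reference.  A failing simulation flags its row
    (``failed = True``) and the scan continues.
    """
    rows = []
    ref_value = _REFERENCE_VALUES[spec.factor]
    for value in spec.grid:
        for degree in spec.degrees:
            row = {"factor": spec.factor, "value": float(value),
                   "f_cirrhosis": float(degree),
                   "is_reference": bool(np.isclose(value, ref_value) and degree == 0.0),
                   "failed": False}
            try:
                ind = _individual_for(spec.factor, float(value), float(degree))
                row.update(_pk_row(run_individual(ind, spec.protocol, defaults)))
            except (SimulationError, ValueError) as exc:
                row["failed"] = True
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def _cohort_individual(rec: dict) -> Individual:
    return Individual(
        age=rec["age"], sex=rec["sex"], body_weight=rec["body_weight_kg"],
        height=rec.get("height_cm", 170.0),
        ethnicity=str(rec.get("ethnicity", "unspecified")),
        fv_liver=rec["fv_liver"], f_bloodflow=rec["f_bloodflow"],
        f_cardiac_output=rec.get("f_cardiac_output", 1.0),
        f_oatp1b3=rec["f_oatp1b3"], f_cirrhosis=rec.get("f_cirrhosis", 0.0),
        bil_ext=rec.get("bil_ext", 1.0))


def _population_row(rec: dict, degree: float, protocol: DoseProtocol,
                    defaults: ModelParameters) -> dict:
    row = dict(rec)
    row["f_cirrhosis"] = degree
    row["failed"] = False
    try:
        ind = dataclasses.replace(_cohort_individual(rec), f_cirrhosis=degree)
        row.update(_pk_row(run_individual(ind, protocol, defaults)))
    except (SimulationError, ValueError) as exc:
        row["failed"] = True
        row["error"] = str(exc)
    return row


def run_population(cohort: pd.DataFrame,
                   protocol: DoseProtocol | None = None,
                   degrees: tuple[float, ...] = (0.0,),
                   defaults: ModelParameters = REFERENCE_PARAMETERS,
                   n_jobs: int = 1,
                   max_failure_fraction: float = 1e-3) -> pd.DataFrame:
    """Per-individual ICG test (default bolus 0.5 mg/kg) for every cohort row
    and cirrhosis degree.

    Embarrassingly parallel: rows are computed independently and assembled in
    cohort order, so the result is identical for any worker count.
    """
    if protocol is None:
        protocol = DoseProtocol(mode="bolus", bolus_dose=0.5)
    records = cohort.to_dict("records")
    tasks = [(rec, float(d)) for rec in records for d in degrees]
    if n_jobs == 1:
        rows = [_population_row(rec, d, protocol, defaults) for rec, d in tasks]
    else:
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_population_row)(rec, d, protocol, defaults)
            for rec, d in tasks)
    out = pd.DataFrame(rows)
    # dict round-trip drops categorical dtype; restore the physical ordering
    if "age_group" in out.columns:
        out["age_group"] = pd.Categorical(
            out["age_group"], categories=["18-40", "41-65", "66-84"], ordered=True)
    if "weight_class" in out.columns:
        out["weight_class"] = pd.Categorical(
            out["weight_class"],
            categories=["40-60", "60-80", "80-100", "100-140"], ordered=True)
    n_failed = int(out["failed"].sum())
    if n_failed > max_failure_fraction * len(out):
        msgs = out.loc[out["failed"], "error"].head(5).tolist()
        raise SimulationError(
            f"{n_failed}/{len(out)} individual simulations failed; first errors: {msgs}")
    return out


def _tukey_whiskers(x: np.ndarray, q1: float, q3: float) -> tuple[float, float]:
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_bound) & (x <= hi_bound)]
    if inside.size == 0:
        return q1, q3
    return float(inside.min()), float(inside.max())


def stratify(results: pd.DataFrame,
             by: tuple[str, ...] = ("age_group", "weight_class", "sex"),
             parameters: tuple[str, ...] = ("cl", "pdr", "r15", "t_half"),
             ) -> pd.DataFrame:
    """Per-subgroup n, median, quartiles and Tukey whisker bounds.

    Empty subgroups are emitted with n = 0 and null statistics, matching the
    boxplot convention of the stratified analysis.
    """
    missing = [c for c in by if c not in results.columns]
    if missing:
        raise ValueError(f"results lack stratification columns: {missing}")
    # emit the full label grid, including empty cells
    import itertools
    levels = []
    for c in by:
        col = results[c]
        if isinstance(col.dtype, pd.CategoricalDtype):
            levels.append(list(col.cat.categories))
        else:
            levels.append(sorted(col.dropna().unique()))
    groups = {k if isinstance(k, tuple) else (k,): g
              for k, g in results.groupby(list(by), observed=True, dropna=True)}
    rows = []
    for key in itertools.product(*levels):
        g = groups.get(key, results.iloc[0:0])
        base = dict(zip(by, key))
        base["n"] = len(g)
        for p in parameters:
            x = g[p].to_numpy(dtype=float) if len(g) else np.array([])
            x = x[np.isfinite(x)]
            if x.size == 0:
                stats = {f"{p}_{s}": np.nan for s in
                         ("median", "q1", "q3", "whisker_lo", "whisker_hi")}
            else:
                q1, med, q3 = np.percentile(x, [25, 50, 75])
                lo, hi = _tukey_whiskers(x, q1, q3)
                stats = {f"{p}_median": med, f"{p}_q1": q1, f"{p}_q3": q3,
                         f"{p}_whisker_lo": lo, f"{p}_whisker_hi": hi}
            base.update(stats)
        rows.append(base)
    return pd.DataFrame(rows)


def correlate(results: pd.DataFrame, x: str, y: str) -> dict:
    """Fit the relation between two PK parameters across a population.

    R20 vs t_1/2 (and R20 vs kel) follow the closed form
    R20 = 100 · 2^(−20 / t_1/2) = 100 · exp(−20 · kel): because every PK
    parameter of a subject is computed from the same disappearance curve, all
    population variability collapses onto this curve.  Other pairs (e.g. CL
    vs PDR, bolus vs infusion CL) are fit linearly through least squares.

    Returns fit kind, coefficients, residuals and residual spread.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 rows to correlate")
    xv = results[x].to_numpy(dtype=float)
    yv = results[y].to_numpy(dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("degenerate (constant) inputs")

    if {x, y} == {"r20", "t_half"}:
        th = xv if x == "t_half" else yv
        r20 = yv if x == "t_half" else xv
        pred = 100.0 * np.power(2.0, -20.0 / th)
        resid = r20 - pred
        return {"kind": "closed_form", "model": "r20 = 100 * 2**(-20/t_half)",
                "residuals": resid, "max_abs_residual": float(np.max(np.abs(resid)))}
    if {x, y} == {"r20", "kel"}:
        k = xv if x == "kel" else yv
        r20 = yv if x == "kel" else xv
        pred = 100.0 * np.exp(-20.0 * k)
        resid = r20 - pred
        return {"kind": "closed_form", "model": "r20 = 100 * exp(-20*kel)",
                "residuals": resid, "max_abs_residual": float(np.max(np.abs(resid)))}

    slope, intercept = np.polyfit(xv, yv, 1)
    pred = slope * xv + intercept
    resid = yv - pred
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot else 1.0
    cv = float(np.std(resid) / np.mean(np.abs(yv))) if np.mean(np.abs(yv)) else np.nan
    return {"kind": "linear", "slope": float(slope), "intercept": float(intercept),
            "r_squared": r2, "residuals": resid, "residual_cv": cv,
            "max_abs_residual": float(np.max(np.abs(resid)))}


def dose_comparison(cohort: pd.DataFrame,
                    dose_a: float = 0.5, dose_b: float = 5.0,
                    defaults: ModelParameters = REFERENCE_PARAMETERS,
                    t_end: float = 30.0) -> pd.DataFrame:
    """Paired PDR at two weight-based bolus doses for every cohort row."""
    proto_a = DoseProtocol(mode="bolus", bolus_dose=dose_a, t_end=t_end)
    proto_b = DoseProtocol(mode="bolus", bolus_dose=dose_b, t_end=t_end)
    rows = []
    for rec in cohort.to_dict("records"):
        ind = _cohort_individual(rec)
        pa = run_individual(ind, proto_a, defaults)
        pb = run_individual(ind, proto_b, defaults)
        rel = abs(pa.pdr - pb.pdr) / pa.pdr if pa.pdr > 0 else np.nan
        rows.append({"subject_id": rec.get("subject_id"),
                     "pdr_low_dose": pa.pdr, "pdr_high_dose": pb.pdr,
                     "relative_deviation": rel})
    return pd.DataFrame(rows)


def single_factor_contribution(results: pd.DataFrame, factor: str,
                               n_points: int = 21,
                               protocol: DoseProtocol | None = None,
                               defaults: ModelParameters = REFERENCE_PARAMETERS,
                               ) -> pd.DataFrame:
    """Vary one factor alone over the range it spans in the cohort results.

    All remaining factors sit at reference; emits CL-PDR pairs for overlay
    against the jointly varied population cloud.
    """
    allowed = ("f_bloodflow", "f_oatp1b3", "fv_liver", "body_weight")
    if factor not in allowed:
        raise ValueError(f"factor must be one of {allowed}")
    col = {"body_weight": "body_weight_kg"}.get(factor, factor)
    values = results[col].to_numpy(dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        grid = np.array([lo])
    else:
        grid = np.linspace(lo, hi, n_points)
    if protocol is None:
        protocol = DoseProtocol(mode="bolus", bolus_dose=0.5)
    rows = []
    for v in grid:
        ind = _individual_for(factor, float(v), 0.0)
        res = run_individual(ind, protocol, defaults)
        rows.append({"factor": factor, "value": float(v),
                     "cl": res.cl, "pdr": res.pdr})
    return pd.DataFrame(rows)
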