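"""Treatment-schedule simulation with time-varying ¹⁰B concentration.

During a BNCT irradiation the cellular ¹⁰B concentration follows the
pharmacokinetics of the carrier (BPA): it rises after injection, peaks,
and decays over the dose-delivery period.  Since the capture-product
dose rate and the field's saturation-corrected lineal energy both track
the concentration, delivery is modelled as a piecewise-constant
schedule whose per-interval (dose rate, y*) pair comes from mixing the
background and boron components at the interval-midpoint concentration.
The total physical dose of the plan is authoritative: modelled rates
are rescaled by one global factor so the delivered dose matches it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .core import (
    GY_PER_MIN_TO_GY_PER_H,
    CellLineParams,
    IrradiationSchedule,
    RadiationQuality,
    neg_log_survival_constant,
    neg_log_survival_schedule,
)
from .microdosimetry import DomainGeometry, QualityComponents, mix_quality

__all__ = [
    "BoronTimeline",
    "DeliveryPlan",
    "concentration_at",
    "build_schedule",
    "plan_dose_response",
]


@dataclass
class BoronTimeline:
    """¹⁰B concentration (ppm) vs time (min since irradiation start).

    Interpolation is monotone-preserving cubic ("pchip") by default —
    a spline that cannot overshoot below zero between non-negative
    knots — or piecewise linear.  Outside the knot range the boundary
    value is held.
    """

    times_min: np.ndarray
    ppm: np.ndarray
    method: str = "pchip"

    def __post_init__(self) -> None:
        self.times_min = np.atleast_1d(np.asarray(self.times_min, float))
        self.ppm = np.atleast_1d(np.asarray(self.ppm, float))
        if self.times_min.size == 0:
            raise ValueError("empty timeline")
        if self.times_min.shape != self.ppm.shape:
            raise ValueError("times and concentrations must have equal length")
        if self.times_min.size > 1 and np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.ppm < 0):
            raise ValueError("concentrations must be non-negative")
        if self.method not in ("pchip", "linear"):
            raise ValueError(f"unknown interpolation method {self.method!r}")


def concentration_at(timeline: BoronTimeline, t) -> np.ndarray | float:
    """Interpolated concentration (ppm) at time(s) t (min), clamped at 0.

    Beyond the first/last knot the boundary value is held constant.
    """
    t_arr = np.asarray(t, dtype=float)
    tk, ck = timeline.times_min, timeline.ppm
    if tk.size == 1:
        out = np.full_like(t_arr, ck[0], dtype=float)
    elif timeline.method == "linear":
        out = np.interp(t_arr, tk, ck)
    else:
        interp = PchipInterpolator(tk, ck, extrapolate=False)
        out = interp(t_arr)
        out = np.where(t_arr <= tk[0], ck[0], out)
        out = np.where(t_arr >= tk[-1], ck[-1], out)
    out = np.maximum(out, 0.0)
    return out if np.ndim(t) else float(out)


@dataclass
class DeliveryPlan:
    """One BNCT delivery regimen.

    ``total_dose_gy`` is the prescribed physical dose, delivered over
    ``duration_min`` with the given two-component field quality.
    ``dt_min`` optionally fixes the discretisation sub-interval; when
    None it is chosen from the convergence rule (see build_schedule).
    """

    total_dose_gy: float
    duration_min: float
    components: QualityComponents
    dt_min: float | None = None

    def __post_init__(self) -> None:
        if self.total_dose_gy <= 0:
            raise ValueError("total dose must be positive")
        if self.duration_min <= 0:
            raise ValueError("duration must be positive")
        if self.dt_min is not None and self.dt_min <= 0:
            raise ValueError("dt_min must be positive")


def _choose_dt_min(
    plan: DeliveryPlan, repair_rate: float | None, approx_max_rate_gy_min: float
) -> float:
    """Sub-interval satisfying (a+c)·ΔT ≤ 0.05 and per-interval dose ≤ 0.1 Gy."""
    dt = plan.duration_min / 20.0
    if repair_rate is not None and repair_rate > 0:
        dt = min(dt, 0.05 / repair_rate * 60.0)
    if approx_max_rate_gy_min > 0:
        dt = min(dt, 0.1 / approx_max_rate_gy_min)
    return dt


def build_schedule(
    plan: DeliveryPlan,
    timeline: BoronTimeline,
    repair_rate: float | None = None,
    geom: DomainGeometry | None = None,
) -> IrradiationSchedule:
    """Discretise a plan into a piecewise-constant irradiation schedule.

    Per-interval dose rate and y* are obtained by mixing the field
    components at the interval-midpoint ¹⁰B concentration; all rates are
    then rescaled by a single factor so the summed dose equals the
    plan's total dose.
    """
    geom = geom or DomainGeometry()
    c_peak = float(np.max(timeline.ppm))
    max_rate, _ = mix_quality(plan.components, c_peak)
    dt_min = plan.dt_min or _choose_dt_min(plan, repair_rate, max_rate)
    n = max(int(math.ceil(plan.duration_min / dt_min)), 1)
    dt_min = plan.duration_min / n
    mid = (np.arange(n) + 0.5) * dt_min
    conc = np.asarray(concentration_at(timeline, mid))
    mixed = [mix_quality(plan.components, c) for c in conc]
    rates_gy_min = np.array([r for r, _ in mixed])
    y_stars = np.array([ys for _, ys in mixed])
    modelled_dose = float(np.sum(rates_gy_min) * dt_min)
    if modelled_dose <= 0:
        raise ValueError("modelled schedule delivers zero dose")
    rates_gy_min *= plan.total_dose_gy / modelled_dose
    return IrradiationSchedule(
        dt_h=dt_min / 60.0,
        dose_rates_gy_h=rates_gy_min * GY_PER_MIN_TO_GY_PER_H,
        y_stars=y_stars,
        geom=geom,
    )


def _converged_nls(
    params: CellLineParams,
    plan: DeliveryPlan,
    timeline: BoronTimeline,
    geom: DomainGeometry | None,
    rel_tol: float = 1e-4,
    max_halvings: int = 8,
) -> float:
    """−ln S for a plan, halving ΔT until the change is below rel_tol."""
    sched = build_schedule(plan, timeline, repair_rate=params.repair_rate, geom=geom)
    nls = neg_log_survival_schedule(params, sched)
    dt = sched.dt_h * 60.0
    for _ in range(max_halvings):
        dt /= 2.0
        sched = build_schedule(replace(plan, dt_min=dt), timeline, geom=geom)
        nls_new = neg_log_survival_schedule(params, sched)
        if abs(nls_new - nls) <= rel_tol * max(abs(nls_new), 1e-30):
            return nls_new
        nls = nls_new
    return nls


def _time_at_dose(schedule: IrradiationSchedule, dose: float) -> float:
    """Time (h) at which the schedule's cumulative dose reaches ``dose``."""
    d_per = schedule.dose_rates_gy_h * schedule.dt_h
    cum = np.concatenate([[0.0], np.cumsum(d_per)])
    if dose > cum[-1] * (1 + 1e-12):
        raise ValueError(f"dose {dose} exceeds the plan total {cum[-1]}")
    dose = min(dose, cum[-1])
    idx = int(np.searchsorted(cum, dose, side="right")) - 1
    idx = min(idx, schedule.n_intervals - 1)
    remaining = dose - cum[idx]
    rate = schedule.dose_rates_gy_h[idx]
    frac = remaining / (rate * schedule.dt_h) if rate > 0 else 1.0
    return (idx + min(frac, 1.0)) * schedule.dt_h


def plan_dose_response(
    params: CellLineParams,
    plan: DeliveryPlan,
    timeline: BoronTimeline,
    dose_grid,
    geom: DomainGeometry | None = None,
) -> pd.DataFrame:
    """Survival vs cumulative dose along a delivery plan.

    For each grid dose D the schedule is truncated at the time its
    cumulative dose reaches D (a plan of shorter duration and total
    dose D over the same timeline).  The acute reference column is the
    instantaneous-delivery survival at the quality given by the
    time-averaged ¹⁰B concentration over the full delivery.

    Returns a DataFrame with columns dose_Gy, survival, survival_acute.
    """
    geom = geom or DomainGeometry()
    dose_grid = np.atleast_1d(np.asarray(dose_grid, float))
    if np.any(dose_grid < 0) or np.any(dose_grid > plan.total_dose_gy * (1 + 1e-9)):
        raise ValueError("dose grid must lie within [0, total plan dose]")
    full = build_schedule(plan, timeline, repair_rate=params.repair_rate, geom=geom)

    # acute reference at the delivery-averaged concentration
    t_dense = np.linspace(0.0, plan.duration_min, 512)
    c_avg = float(np.trapezoid(concentration_at(timeline, t_dense), t_dense) / plan.duration_min)
    _, y_star_avg = mix_quality(plan.components, c_avg)
    q_avg = RadiationQuality.from_y_star(y_star_avg, geom)

    surv = np.empty_like(dose_grid)
    for i, D in enumerate(dose_grid):
        if D == 0.0:
            surv[i] = 1.0
            continue
        t_h = _time_at_dose(full, D)
        sub = replace(plan, total_dose_gy=D, duration_min=t_h * 60.0, dt_min=None)
        surv[i] = math.exp(-_converged_nls(params, sub, timeline, geom))
    acute_nls = (
        (params.alpha0 + q_avg.gamma * params.beta0) * dose_grid
        + params.beta0 * dose_grid**2
    )
    return pd.DataFrame(
        {
            "dose_Gy": dose_grid,
            "survival": surv,
            "survival_acute": np.exp(-acute_nls),
        }
    )
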