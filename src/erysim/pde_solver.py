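"""Numerical integration of the five coupled maturity-transport equations.

Scheme: first-order upwind in maturity with explicit Euler in time, classes
chained by boundary fluxes (``v_k u_k(t, 0) = v_{k-1} u_{k-1}(t, mu_max)``,
with the stem-cell commitment ``S0`` feeding BFU-E).  Cells crossing the
erythrocyte right boundary at age ``T_RBC`` leave the system — the lifespan is
an absorbing boundary.  The step size obeys the CFL bound using the capped
maximum reticulocyte velocity, so one fixed ``dt`` is valid for a whole run
regardless of the EPO trajectory.

Two steady-state constructions are provided:

* :func:`steady_state` — the analytic profile ``u(mu) = (f/v) exp(((beta-alpha)/v) mu)``
  per class (piecewise over the neocytolysis window), used to validate the
  solver's accuracy;
* :func:`discrete_steady_state` — the exact fixed point of the upwind update,
  ``u[j] = u[j-1] / (1 - (beta - alpha_j) dmu / v)``, which the time stepping
  preserves to rounding.  It is the initial condition for simulations and the
  anchor of the stem-cell calibration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import lfilter

from . import model_core as mc
from ._kernel import run_segment
from .model_core import BloodEvent, PatientParameters, PopulationClass, PopulationState
from .observation import PatientProfile, hgb_from_count

__all__ = [
    "GridConfig",
    "SimulationResult",
    "CFLError",
    "SimulationError",
    "boundary_influx",
    "advance",
    "simulate",
    "steady_state",
    "discrete_steady_state",
    "total_rbc",
]


class CFLError(ValueError):
    """Raised when a requested time step violates the CFL stability bound."""


class SimulationError(RuntimeError):
    """Raised when the state becomes non-finite (numerical instability)."""


@dataclass(frozen=True)
class GridConfig:
    """Maturity resolution of the solver.

    ``dmu`` is the node spacing (maturity-days) of the four marrow classes and
    ``dmu_ery`` that of the much longer erythrocyte class; ``cfl`` is the safety
    fraction of the stability bound used for the time step.
    """

    dmu: float = 0.25
    dmu_ery: float = 1.0
    cfl: float = 0.8

    @classmethod
    def coarse(cls) -> "GridConfig":
        """Halved resolution used by the estimation/recovery harnesses."""
        return cls(dmu=0.5, dmu_ery=2.0)


@dataclass
class SimulationResult:
    """Time grids of cell count, EPO, and simulated Hgb at treatment times."""

    times: np.ndarray          # days, the solver grid
    rbc_count: np.ndarray      # circulating erythrocytes (cells) over time
    epo: np.ndarray            # total EPO (U/l) over time
    record_times: np.ndarray   # treatment times (days)
    record_idx: np.ndarray     # their indices on the solver grid
    hgb_post: np.ndarray       # simulated post-dialysis Hgb (g/dl) at treatments
    final_state: PopulationState


# ---------------------------------------------------------------------------
# grids and steady states


def _class_lengths(p: PatientParameters) -> tuple[float, ...]:
    return (*p.constants.maturity_span, p.t_rbc)


def _grids(p: PatientParameters, grid: GridConfig) -> list[tuple[int, float]]:
    """Per class: (number of nodes, node spacing); spacing divides the span."""
    out = []
    for k, length in enumerate(_class_lengths(p)):
        target = grid.dmu_ery if k == 4 else grid.dmu
        n = max(2, round(length / target))
        out.append((n + 1, length / n))
    return out


def _time_step(p: PatientParameters, grid: GridConfig) -> float:
    """CFL-safe step: velocities are 1 except marrow reticulocytes (<= v_max)."""
    caps = (1.0, 1.0, 1.0, p.constants.v_max, 1.0)
    specs = _grids(p, grid)
    return grid.cfl * min(d / v for (_, d), v in zip(specs, caps))


def _node_rates(p: PatientParameters, e_const: float, k: int, nodes: int, dmu: float):
    """(net rate beta - alpha at nodes 1..n-1, velocity) for class ``k`` at constant EPO."""
    c = p.constants
    beta = c.beta[k]
    v = mc.maturation_velocity(mc.CLASS_NAMES[k], e_const, p)
    j = np.arange(1, nodes)
    if k == 4:
        neo = mc.neocytolysis_rate(e_const, 0.0, p)
        alpha = np.where(j * dmu <= c.mu_neo, neo, 0.0)
    elif k == 1:
        alpha = np.full(nodes - 1, mc.apoptosis_rate("CFU_E", e_const, 0.0, p))
    else:
        alpha = np.full(nodes - 1, (c.alpha_bfue, None, c.alpha_erythroblast, c.alpha_marrow_reticulocyte, None)[k])
    return beta - alpha, v


def _chained_profiles(p, e_const, grid, s0, discrete):
    specs = _grids(p, grid)
    classes = []
    influx = s0
    for k, (nodes, dmu) in enumerate(specs):
        r, v = _node_rates(p, e_const, k, nodes, dmu)
        if v <= 0:
            raise ValueError("maturation velocity must be positive")
        u = np.empty(nodes)
        u[0] = influx / v
        if discrete:
            denom = 1.0 - r * dmu / v
            if np.any(denom <= 0):
                raise ValueError("resolution too coarse for the net growth rate (dmu*(beta-alpha)/v >= 1)")
            u[1:] = u[0] * np.cumprod(1.0 / denom)
        else:
            mu = np.arange(1, nodes) * dmu
            u[1:] = u[0] * np.exp(np.cumsum(r * dmu) / v)  # == exp(int (beta-alpha) dmu / v)
        classes.append(PopulationClass(mc.CLASS_NAMES[k], _class_lengths(p)[k], np.arange(nodes) * dmu, u))
        influx = v * u[-1]
    return PopulationState(0.0, classes)


def steady_state(p: PatientParameters, e_const: float, grid: GridConfig | None = None,
                 s0: float | None = None) -> PopulationState:
    """Analytic steady profile at constant EPO, chained from the stem-cell influx."""
    grid = grid or GridConfig()
    s0 = p.s0 if s0 is None else s0
    if s0 is None:
        raise ValueError("stem-cell influx s0 is not set")
    if e_const < 0:
        raise ValueError("EPO concentration must be non-negative")
    return _chained_profiles(p, e_const, grid, s0, discrete=False)


def discrete_steady_state(p: PatientParameters, e_const: float, grid: GridConfig | None = None,
                          s0: float | None = None) -> PopulationState:
    """Exact fixed point of the upwind update at constant EPO (dt-independent)."""
    grid = grid or GridConfig()
    s0 = p.s0 if s0 is None else s0
    if s0 is None:
        raise ValueError("stem-cell influx s0 is not set")
    if e_const < 0:
        raise ValueError("EPO concentration must be non-negative")
    return _chained_profiles(p, e_const, grid, s0, discrete=True)


def total_rbc(state: PopulationState) -> float:
    """Circulating erythrocytes (incl. blood reticulocytes): trapezoidal count."""
    return state.classes[4].total


def boundary_influx(k: int, state: PopulationState, e_total: float, p: PatientParameters) -> float:
    """Cells/day entering class ``k``: S0 for BFU-E, upstream outflux otherwise."""
    if k == 0:
        if p.s0 is None:
            raise ValueError("stem-cell influx s0 is not set")
        return p.s0
    up = state.classes[k - 1]
    v_up = mc.maturation_velocity(up.name, e_total, p)
    return v_up * float(up.density[-1])


# ---------------------------------------------------------------------------
# time stepping


def _kernel_args(p: PatientParameters, dmus: Sequence[float]):
    c = p.constants
    return (
        dmus[0], dmus[1], dmus[2], dmus[3], dmus[4],
        c.beta[0], c.beta[1], c.beta[2], c.beta[3],
        c.alpha_bfue, c.alpha_erythroblast, c.alpha_marrow_reticulocyte,
        c.alpha_min, c.alpha_max, p.s_alpha,
        c.v_min, c.v_max, p.s_v,
        c.e_neo, c.mu_neo, c.alpha_neo,
    )


def advance(state: PopulationState, dt: float, e_total: float, p: PatientParameters,
            s0: float | None = None) -> PopulationState:
    """One upwind step of all five classes; raises :class:`CFLError` if unstable."""
    s0 = p.s0 if s0 is None else s0
    new = state.copy()
    dmus = [c.dmu for c in new.classes]
    for k, c in enumerate(new.classes):
        v = mc.maturation_velocity(c.name, e_total, p)
        if v * dt > dmus[k] * (1 + 1e-12):
            raise CFLError(
                f"dt={dt} violates the CFL bound for class {c.name}: v*dt={v * dt:.4g} > dmu={dmus[k]:.4g}"
            )
    rbc = np.empty(1)
    run_segment(
        *[c.density for c in new.classes],
        np.array([e_total]), dt, *_kernel_args(p, dmus),
        0.0 if s0 is None else s0, rbc,
    )
    new.time = state.time + dt
    return new


def _epo_total_on_grid(n_points: int, dt: float, dose_idx: np.ndarray, dose_units: np.ndarray,
                       p: PatientParameters, v_d: float) -> np.ndarray:
    """Total EPO at grid times: exact recursion of the elimination ODE.

    A bolus at grid index ``m_i`` contributes ``(dose/V_d) * exp(-k (m - m_i) dt)``
    for ``m >= m_i`` — identical to the closed form evaluated at grid times.
    """
    impulses = np.zeros(n_points)
    np.add.at(impulses, dose_idx, dose_units / v_d)
    decay = math.exp(-mc._LN2 * 24.0 / p.t_half * dt)
    e_exo = lfilter([1.0], [1.0, -decay], impulses)
    return p.e_endo + e_exo


def simulate(
    p: PatientParameters,
    profile: PatientProfile,
    t_end: float,
    doses: Iterable[tuple[float, float]] = (),
    events: Iterable[BloodEvent] = (),
    grid: GridConfig | None = None,
    s0: float | None = None,
    initial_state: PopulationState | None = None,
    record_times: Sequence[float] | None = None,
) -> SimulationResult:
    """Integrate the full model over ``[0, t_end]`` days.

    ``doses`` are (time, units) ESA boluses; ``events`` bleed/transfusion events;
    both are snapped to the solver grid.  The initial condition defaults to the
    discrete steady state at the endogenous EPO level.  Hgb is evaluated at
    ``record_times`` through the observation model (post-dialytic blood volume).
    """
    grid = grid or GridConfig()
    s0 = p.s0 if s0 is None else s0
    if s0 is None:
        raise ValueError("stem-cell influx s0 is not set (calibrate or pass explicitly)")
    if t_end <= 0:
        raise ValueError("t_end must be positive")

    specs = _grids(p, grid)
    dmus = [d for _, d in specs]
    dt = _time_step(p, grid)
    n_steps = max(1, math.ceil(t_end / dt - 1e-12))
    n_points = n_steps + 1

    doses = sorted(doses)
    dose_idx = np.array([min(n_steps, max(0, round(t / dt))) for t, _ in doses], dtype=np.int64)
    dose_units = np.array([d for _, d in doses], dtype=float)
    v_d = mc.distribution_volume(p, profile.weight_kg)
    epo = _epo_total_on_grid(n_points, dt, dose_idx, dose_units, p, v_d)

    if initial_state is None:
        initial_state = discrete_steady_state(p, p.e_endo, grid, s0)
    state = initial_state.copy()
    u = [c.density for c in state.classes]

    ev_by_idx: dict[int, list[BloodEvent]] = {}
    for ev in events:
        idx = min(n_steps, max(0, round(ev.time / dt)))
        ev_by_idx.setdefault(idx, []).append(ev)

    def apply_events(idx: int) -> None:
        for ev in ev_by_idx.get(idx, ()):
            if ev.kind == "bleed":
                frac = ev.magnitude / (profile.tbv_post * 1000.0)
                if frac > 1.0:
                    raise ValueError("bleed volume exceeds total blood volume")
                u[4] *= 1.0 - frac
            else:
                u[4] += ev.cells / p.t_rbc

    rbc = np.empty(n_points)
    apply_events(0)
    rbc[0] = np.trapezoid(u[4], dx=dmus[4])

    kargs = _kernel_args(p, dmus)
    cur = 0
    for b in sorted(i for i in ev_by_idx if i > 0) + [n_steps]:
        b = min(b, n_steps)
        if b > cur:
            run_segment(u[0], u[1], u[2], u[3], u[4], epo[cur:b], dt, *kargs, s0, rbc[cur + 1:b + 1])
            cur = b
        if b in ev_by_idx and b > 0:
            apply_events(b)
            rbc[b] = np.trapezoid(u[4], dx=dmus[4])

    if not np.all(np.isfinite(rbc)):
        bad = int(np.argmax(~np.isfinite(rbc)))
        raise SimulationError(
            f"state became non-finite at t={bad * dt:.2f} d "
            f"(t_rbc={p.t_rbc:.3g}, t_half={p.t_half:.3g}, s_alpha={p.s_alpha:.3g}, s_v={p.s_v:.3g})"
        )

    record_times = np.asarray([] if record_times is None else record_times, dtype=float)
    record_idx = np.clip(np.round(record_times / dt).astype(np.int64), 0, n_steps)
    hgb_post = hgb_from_count(rbc[record_idx], profile.tbv_post, p.constants.mch_pg)

    state.time = n_steps * dt
    return SimulationResult(
        times=np.arange(n_points) * dt,
        rbc_count=rbc,
        epo=epo,
        record_times=record_times,
        record_idx=record_idx,
        hgb_post=np.asarray(hgb_post, dtype=float),
        final_state=state,
    )
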