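"""Patient-specific parameter identification.

Five quantities are estimated per patient from the adaptation-period
post-dialysis Hgb series: RBC lifespan, endogenous EPO level, ESA half-life,
and the two bone-marrow response slopes (CFU-E apoptosis, reticulocyte
maturation velocity).  The stem-cell influx ``S0`` is not searched: it is fixed
by the blood volume and a steady-state argument — the model is linear in the
cell densities, so the influx that reproduces the first observed Hgb at steady
state follows from a single reference profile by rescaling.

The cost is the unweighted sum of squared residuals between simulated and
measured post-dialysis Hgb.  It is minimized by multi-start Nelder-Mead
(unconstrained, but searched in log-parameter space so every candidate is
positive), followed by restarts around the incumbent with ~±10% multiplicative
perturbations until two consecutive restarts fail to improve the cost by 0.1%,
and an optional coordinate-wise refinement pass.  Everything is deterministic
given the seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .evaluation import mape
from .model_core import BloodEvent, ModelConstants, PatientParameters
from .observation import PatientProfile
from .pde_solver import GridConfig, SimulationError, discrete_steady_state, simulate, total_rbc
from .records_io import TreatmentRecord, filter_eligible, records_to_events, relative_days

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_RANGES",
    "EstimationConfig",
    "EstimationResult",
    "IneligibleDataError",
    "FitData",
    "prepare_fit_data",
    "calibrate_stem_influx",
    "cost",
    "estimate",
    "split_adaptation_prediction",
]

PARAM_NAMES = ("t_rbc", "e_endo", "t_half", "s_alpha", "s_v")

#: initial-guess ranges ("physiologically reasonable"), mirroring cohort estimates
DEFAULT_RANGES = {
    "t_rbc": (35.0, 135.0),    # days
    "e_endo": (2.0, 20.0),     # U/l
    "t_half": (4.0, 12.0),     # hours
    "s_alpha": (0.001, 0.03),  # l/U
    "s_v": (0.001, 0.2),
}

_PENALTY = 1.0e10  # large-but-finite cost for failed simulations


class IneligibleDataError(ValueError):
    """The record set fails the >42 measurements / >=2 administrations rule."""


@dataclass(frozen=True)
class EstimationConfig:
    n_starts: int = 4
    n_screen: int = 32                  # cheap LHS pre-screen; best n_starts survive
    perturbation: float = 0.10          # relative restart magnitude
    max_iter: int = 600                 # Nelder-Mead iterations per run
    xatol: float = 1e-3                 # simplex tolerance, log-parameter space
    fatol: float = 1e-10                # cost-spread tolerance, (g/dl)^2
    seed: int = 0
    adaptation_days: float = 150.0
    coordinate_refine: bool = False
    max_restarts: int = 10
    grid: GridConfig = field(default_factory=GridConfig)
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    constants: ModelConstants = field(default_factory=ModelConstants)

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if not 0.0 < self.perturbation < 1.0:
            raise ValueError("perturbation must be in (0, 1)")


@dataclass
class RunRecord:
    kind: str                 # "start" | "restart" | "refine"
    start: np.ndarray         # initial parameter vector (physical scale)
    params: np.ndarray        # converged vector
    cost: float
    n_evals: int


@dataclass
class EstimationResult:
    params_hat: PatientParameters
    cost: float
    mape_adaptation: float
    runs: list[RunRecord]
    n_function_evals: int


@dataclass
class FitData:
    """Adaptation-window data in solver coordinates (days since first session)."""

    times: np.ndarray              # all rows
    post: np.ndarray               # measured post-Hgb, NaN when missing
    pre: np.ndarray                # measured pre-Hgb, NaN when missing
    fit_mask: np.ndarray           # rows entering the residual
    doses: list[tuple[float, float]]
    events: list[BloodEvent]
    target_hgb: float              # first observed post-Hgb (steady-state anchor)
    t_end: float


def prepare_fit_data(records: Sequence[TreatmentRecord]) -> FitData:
    records = sorted(records, key=lambda r: r.session_end)
    if not records:
        raise ValueError("empty record set")
    t = relative_days(records)
    post = np.array([np.nan if r.post_hgb is None else r.post_hgb for r in records])
    pre = np.array([np.nan if r.pre_hgb is None else r.pre_hgb for r in records])
    kept, _ = filter_eligible(records)
    kept_ids = {id(r) for r in kept}
    fit_mask = np.array([id(r) in kept_ids and np.isfinite(p) for r, p in zip(records, post)])
    if not fit_mask.any():
        raise ValueError("no usable post-dialysis measurements")
    doses = [(float(ti), float(r.esa_dose)) for r, ti in zip(records, t) if r.esa_dose > 0]
    return FitData(
        times=t,
        post=post,
        pre=pre,
        fit_mask=fit_mask,
        doses=doses,
        events=records_to_events(records),
        target_hgb=float(post[fit_mask][0]),
        t_end=float(t[-1]) if t[-1] > 0 else 1.0,
    )


def calibrate_stem_influx(p: PatientParameters, profile: PatientProfile,
                          target_post_hgb: float, grid: GridConfig | None = None) -> float:
    """Stem-cell influx whose steady state reproduces ``target_post_hgb``.

    The transport equations are linear in the densities, so the steady count
    scales exactly with the influx: one reference profile at ``S0 = 1`` gives
    ``S0 = N_target / N_ref``.
    """
    if not 2.0 < target_post_hgb < 20.0:
        raise ValueError(f"target Hgb {target_post_hgb} g/dl outside the supported (2, 20) range")
    n_target = target_post_hgb * profile.tbv_post * 10.0 * 1e12 / p.constants.mch_pg
    n_ref = total_rbc(discrete_steady_state(p, p.e_endo, grid, s0=1.0))
    if n_ref <= 0:
        raise ValueError("reference steady state has zero cell count")
    return n_target / n_ref


def _simulate_fit(theta, data: FitData, profile: PatientProfile,
                  grid: GridConfig, constants: ModelConstants):
    p = PatientParameters(
        t_rbc=float(theta[0]), e_endo=float(theta[1]), t_half=float(theta[2]),
        s_alpha=float(theta[3]), s_v=float(theta[4]), constants=constants,
    )
    s0 = calibrate_stem_influx(p, profile, data.target_hgb, grid)
    sim = simulate(
        p, profile, t_end=data.t_end, doses=data.doses, events=data.events,
        grid=grid, s0=s0, record_times=data.times,
    )
    return p.with_s0(s0), sim


def cost(theta, data: FitData, profile: PatientProfile,
         grid: GridConfig | None = None, constants: ModelConstants | None = None) -> float:
    """Sum of squared post-dialysis Hgb residuals, (g/dl)^2.

    Any simulation failure (implausible candidate, instability) maps to a
    large-but-finite penalty so the simplex search can continue.
    """
    grid = grid or GridConfig()
    constants = constants or ModelConstants()
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (5,) or not np.all(np.isfinite(theta)):
        return _PENALTY
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # plausibility warnings during search
            _, sim = _simulate_fit(theta, data, profile, grid, constants)
        resid = sim.hgb_post[data.fit_mask] - data.post[data.fit_mask]
        value = float(resid @ resid)
        return value if np.isfinite(value) else _PENALTY
    except (ValueError, OverflowError, FloatingPointError, SimulationError):
        return _PENALTY


def split_adaptation_prediction(records: Sequence[TreatmentRecord],
                                adaptation_days: float = 150.0):
    """Half-open split: records before ``first + adaptation_days`` are the
    adaptation set, everything at or after it is the prediction set."""
    if not records:
        raise ValueError("empty record set")
    records = sorted(records, key=lambda r: r.session_end)
    t = relative_days(records)
    adaptation = [r for r, ti in zip(records, t) if ti < adaptation_days]
    prediction = [r for r, ti in zip(records, t) if ti >= adaptation_days]
    return adaptation, prediction


def estimate(records: Sequence[TreatmentRecord], profile: PatientProfile,
             config: EstimationConfig | None = None) -> EstimationResult:
    """Multi-start Nelder-Mead identification of the five patient parameters."""
    config = config or EstimationConfig()
    adaptation, _ = split_adaptation_prediction(records, config.adaptation_days)
    kept, _ = filter_eligible(adaptation)
    n_doses = sum(1 for r in adaptation if r.esa_dose > 0)
    if len(kept) <= 42 or n_doses < 2:
        raise IneligibleDataError(
            f"patient ineligible: {len(kept)} eligible measurements (>42 required), "
            f"{n_doses} ESA administrations (at least 2 required)"
        )
    data = prepare_fit_data(adaptation)

    n_evals = 0

    def objective(log_theta):
        nonlocal n_evals
        n_evals += 1
        return cost(np.exp(log_theta), data, profile, config.grid, config.constants)

    rng = np.random.default_rng(config.seed)
    lo = np.log([config.ranges[k][0] for k in PARAM_NAMES])
    hi = np.log([config.ranges[k][1] for k in PARAM_NAMES])
    sampler = qmc.LatinHypercube(d=5, seed=int(rng.integers(2**31 - 1)))
    candidates = lo + sampler.random(max(config.n_screen, config.n_starts)) * (hi - lo)
    screen = np.array([objective(x) for x in candidates])
    starts = candidates[np.argsort(screen, kind="stable")[: config.n_starts]]

    nm_options = {"maxiter": config.max_iter, "xatol": config.xatol, "fatol": config.fatol}
    runs: list[RunRecord] = []

    def run_nm(x0, kind):
        before = n_evals
        res = minimize(objective, x0, method="Nelder-Mead", options=nm_options)
        runs.append(RunRecord(kind, np.exp(x0), np.exp(res.x), float(res.fun), n_evals - before))
        return res

    best_x, best_fun = None, np.inf
    for x0 in starts:
        res = run_nm(x0, "start")
        if res.fun < best_fun:
            best_x, best_fun = res.x, float(res.fun)

    # restart around the incumbent with ~±10% multiplicative perturbations
    stall = 0
    for _ in range(config.max_restarts):
        if stall >= 2:
            break
        factors = rng.uniform(1.0 - config.perturbation, 1.0 + config.perturbation, 5)
        res = run_nm(best_x + np.log(factors), "restart")
        improvement = (best_fun - res.fun) / max(best_fun, 1e-300)
        if res.fun < best_fun:
            best_x, best_fun = res.x, float(res.fun)
        stall = stall + 1 if improvement < 1e-3 else 0

    if config.coordinate_refine:
        x = best_x.copy()
        for i in range(5):
            before = n_evals
            res_i = minimize(
                lambda z, i=i: objective(np.concatenate([x[:i], z, x[i + 1:]])),
                [x[i]], method="Nelder-Mead", options=nm_options,
            )
            x_cand = x.copy()
            x_cand[i] = float(res_i.x[0])
            runs.append(RunRecord("refine", np.exp(x), np.exp(x_cand), float(res_i.fun), n_evals - before))
            if res_i.fun < best_fun:
                x = x_cand
                best_x, best_fun = x.copy(), float(res_i.fun)

    theta_hat = np.exp(best_x)
    for name, value in zip(PARAM_NAMES, theta_hat):
        low, high = config.ranges[name]
        if not low / 2 <= value <= high * 2:
            warnings.warn(
                f"estimated {name} = {value:.4g} is far outside the physiological "
                f"starting range [{low}, {high}]", stacklevel=2,
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params_hat, sim = _simulate_fit(theta_hat, data, profile, config.grid, config.constants)
    fit_mape = mape(data.post[data.fit_mask], sim.hgb_post[data.fit_mask])

    return EstimationResult(
        params_hat=params_hat,
        cost=float(best_fun),
        mape_adaptation=fit_mape,
        runs=runs,
        n_function_evals=n_evals,
    )
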