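"""Virtual hemodialysis patients with monitor-like Hgb series.

The clinical data the analysis targets (per-treatment optical Hgb readings,
ESA doses, anthropometrics) are not publicly deposited, so every stage of the
pipeline is exercised on synthetic patients built to the cohort's printed
statistics: thrice-weekly sessions over a 150-day adaptation period plus
follow-up, roughly 53±7 usable measurements per adaptation period, RBC
lifespans 73±20 days truncated to 33–137, ESA half-lives with median 6.3 h in
3.8–13.6, endogenous EPO at CKD-5 levels, bone-marrow slopes log-uniform over
the reported ranges, and ESA dosing on the 17.94 U/kg/treatment scale.

Dosing is produced by a simple titration controller (the source records real
prescriptions but no algorithm): the per-kg dose steps up or down by 25% — at
most every two weeks — whenever the trailing two-week mean of measured Hgb
leaves the 10–11.5 g/dl guideline band.  Measurements carry multiplicative
noise, an independently sampled pre/post fluid-shift ratio, and i.i.d.
missingness (the first session is always recorded: it anchors the steady-state
initial condition).  The whole generator is a pure function of (seed, config).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._kernel import run_segment
from .estimation import calibrate_stem_influx
from .model_core import BloodEvent, ModelConstants, PatientParameters, distribution_volume
from .observation import PatientProfile, hgb_from_count
from .pde_solver import (
    GridConfig, SimulationResult, _epo_total_on_grid, _grids, _kernel_args,
    _time_step, discrete_steady_state,
)
from .records_io import TreatmentRecord

__all__ = [
    "CohortConfig",
    "BleedSpec",
    "SyntheticPatient",
    "TitrationPolicy",
    "sample_patient",
    "dosing_policy",
    "measure",
    "generate_patient",
    "generate_cohort",
    "inject_events",
]

#: records start on a Monday morning; sessions Mon/Wed/Fri
BASE_SESSION_START = pd.Timestamp("2013-01-07 08:00:00")
SESSION_HOURS = 3.5

#: cohort statistics driving the parameter and anthropometric draws
COHORT_STATS = {
    "male_frac": 0.5167,
    "height_cm": (166.5, 9.7, 140.0, 200.0),        # truncated normal
    "weight_pre_kg": (78.6, 19.7, 40.0, 160.0),
    "idwg_kg": 2.56,                                  # pre minus post weight
    "t_rbc": (73.0, 20.0, 33.0, 137.0),
    "e_endo": (8.0, 3.0, 1.0, 25.0),
    "log_t_half": (math.log(6.3), 0.32, math.log(3.8), math.log(13.6)),
    "s_alpha": (0.0013, 0.0208),                      # log-uniform
    "s_v": (0.0007, 0.1864),
}


@dataclass(frozen=True)
class CohortConfig:
    adaptation_days: float = 150.0
    prediction_days: float = 90.0
    noise_cv: float = 0.03            # multiplicative measurement noise
    missing_prob: float = 0.18        # i.i.d. per-session dropout (~53 of 65 kept)
    fluid_shift_range: tuple[float, float] = (1.02, 1.12)  # post/pre Hgb ratio
    init_hgb_mean: float = 8.75       # un-dosed steady-state Hgb, g/dl (renal anemia)
    init_hgb_sd: float = 0.5
    init_hgb_bounds: tuple[float, float] = (7.5, 10.0)
    hgb_low: float = 10.0             # titration band (guideline 9-11.5 g/dl,
    hgb_high: float = 11.5            # treat-to upper limit)
    base_dose_per_kg: float = 18.0    # U/kg/treatment, cohort mean scale
    dose_cap_per_kg: float = 100.0
    dose_step: float = 0.25
    trailing_days: float = 14.0
    adjust_interval_days: float = 14.0
    dose_round_to: float = 100.0      # syringes come in 100 U increments
    grid: GridConfig = field(default_factory=GridConfig)
    constants: ModelConstants = field(default_factory=ModelConstants)


@dataclass(frozen=True)
class BleedSpec:
    """A multi-day bleed followed by a packed-red-cell transfusion."""

    start_day: float
    daily_volume_ml: float = 150.0
    n_days: int = 5
    transfusion_units: float = 2.0
    transfusion_day: float | None = None   # default: the day after the bleed ends

    def events(self, horizon: float) -> list[BloodEvent]:
        evs = [
            BloodEvent("bleed", self.start_day + i, self.daily_volume_ml)
            for i in range(self.n_days)
        ]
        if self.transfusion_units > 0:
            t_day = self.transfusion_day
            if t_day is None:
                t_day = self.start_day + self.n_days
            evs.append(BloodEvent("transfusion", t_day, self.transfusion_units))
        times = [e.time for e in evs]
        if len(set(times)) != len(times):
            raise ValueError("overlapping blood events at identical timestamps")
        if min(times) < 0 or max(times) > horizon:
            raise ValueError("blood events outside the simulation horizon")
        return evs


@dataclass
class SyntheticPatient:
    patient_id: str
    seed: int
    config: CohortConfig
    profile: PatientProfile
    true_params: PatientParameters      # includes the calibrated stem-cell influx
    init_hgb: float
    session_days: np.ndarray
    true_post_hgb: np.ndarray           # noise-free post-dialysis Hgb per session
    records: list[TreatmentRecord]
    events: list[BloodEvent]
    bleed_spec: BleedSpec | None = None


# ---------------------------------------------------------------------------
# parameter sampling


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def sample_patient(rng, stats: dict | None = None,
                   constants: ModelConstants | None = None):
    """Draw one virtual patient: ``(profile, parameters)`` without ``S0``.

    ``rng`` is a seed or a ``numpy.random.Generator``; ``stats`` overrides
    entries of :data:`COHORT_STATS`.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    s = {**COHORT_STATS, **(stats or {})}
    sex = "male" if rng.random() < s["male_frac"] else "female"
    height = _truncnorm(rng, *s["height_cm"])
    weight_post = _truncnorm(rng, *s["weight_pre_kg"]) - s["idwg_kg"]
    profile = PatientProfile(sex=sex, height_cm=height, weight_kg=weight_post)
    params = PatientParameters(
        t_rbc=_truncnorm(rng, *s["t_rbc"]),
        e_endo=_truncnorm(rng, *s["e_endo"]),
        t_half=math.exp(_truncnorm(rng, *s["log_t_half"])),
        s_alpha=math.exp(rng.uniform(*np.log(s["s_alpha"]))),
        s_v=math.exp(rng.uniform(*np.log(s["s_v"]))),
        constants=constants or ModelConstants(),
    )
    return profile, params


# ---------------------------------------------------------------------------
# dosing policy


class TitrationPolicy:
    """Stateful ±25% ESA titration against the 10–11.5 g/dl band.

    The per-kg dose is adjusted at most once per ``adjust_interval_days``, based
    on the trailing two-week mean of measured Hgb, and clipped to
    ``[0, dose_cap_per_kg]``; doses are rounded to 100 U.
    """

    def __init__(self, config: CohortConfig | None = None):
        self.config = config or CohortConfig()
        self.dose_per_kg = self.config.base_dose_per_kg
        self._last_adjust_day = -math.inf

    def next_dose(self, trailing_mean_hgb: float | None, weight_kg: float,
                  day: float = 0.0) -> float:
        c = self.config
        if trailing_mean_hgb is not None and day - self._last_adjust_day >= c.adjust_interval_days:
            if trailing_mean_hgb > c.hgb_high:
                self.dose_per_kg *= 1.0 - c.dose_step
                self._last_adjust_day = day
            elif trailing_mean_hgb < c.hgb_low:
                self.dose_per_kg *= 1.0 + c.dose_step
                self._last_adjust_day = day
        self.dose_per_kg = min(max(self.dose_per_kg, 0.0), c.dose_cap_per_kg)
        # treatment is held entirely while Hgb sits above the band (the marrow
        # pipeline and the long RBC lifespan make overshoots otherwise persist)
        if trailing_mean_hgb is not None and trailing_mean_hgb > c.hgb_high:
            return 0.0
        return round(self.dose_per_kg * weight_kg / c.dose_round_to) * c.dose_round_to


def dosing_policy(current_hgb: float, weight_kg: float, policy: TitrationPolicy,
                  day: float = 0.0) -> float:
    """One titration step: dose (U) for this treatment given the trailing Hgb."""
    if current_hgb is not None and not current_hgb > 0:
        raise ValueError("Hgb must be positive")
    return policy.next_dose(current_hgb, weight_kg, day)


# ---------------------------------------------------------------------------
# measurement model


def _noisy_measurement(rng: np.random.Generator, true_post: float, noise_cv: float,
                       fluid_shift_range: tuple[float, float]):
    """(post, pre) measured pair: multiplicative noise plus a fluid-shift ratio."""
    z = rng.standard_normal()
    ratio = rng.uniform(*fluid_shift_range)
    post = true_post * (1.0 + noise_cv * z)
    return post, post / ratio


def measure(sim: SimulationResult, noise_cv: float, missing_prob: float,
            rng, patient_id: str = "synthetic",
            fluid_shift_range: tuple[float, float] = (1.02, 1.12)) -> list[TreatmentRecord]:
    """Turn simulated treatment-time Hgb into monitor-like records.

    Per session the post-dialysis value gets multiplicative noise
    ``(1 + noise_cv * N(0,1))`` and the pre-dialysis value divides out an
    independent fluid-shift ratio; sessions after the first are dropped i.i.d.
    with ``missing_prob`` (the row is kept with Hgb marked missing).
    """
    if noise_cv < 0 or not 0 <= missing_prob < 1:
        raise ValueError("noise_cv must be >= 0 and missing_prob in [0, 1)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    records = []
    for j, (t, hgb) in enumerate(zip(sim.record_times, sim.hgb_post)):
        post, pre = _noisy_measurement(rng, float(hgb), noise_cv, fluid_shift_range)
        missing = j > 0 and rng.random() < missing_prob
        start = BASE_SESSION_START + pd.Timedelta(days=float(t))
        records.append(TreatmentRecord(
            patient_id=patient_id,
            session_start=start,
            session_end=start + pd.Timedelta(hours=SESSION_HOURS),
            pre_hgb=None if missing else pre,
            post_hgb=None if missing else post,
        ))
    return records


# ---------------------------------------------------------------------------
# closed-loop generation


def generate_patient(seed: int, config: CohortConfig | None = None,
                     bleed_spec: BleedSpec | None = None,
                     patient_id: str | None = None) -> SyntheticPatient:
    """Simulate one virtual patient under feedback ESA titration.

    The model is advanced session to session; at each session the (noisy)
    measurement is taken, the titration policy chooses the dose, and the bolus
    enters the EPO forcing from that instant on.  The arithmetic matches
    :func:`erysim.pde_solver.simulate` step for step, so replaying the recorded
    doses against the true parameters reproduces the records exactly when the
    noise is switched off.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    profile, params = sample_patient(rng, constants=config.constants)
    init_hgb = _truncnorm(rng, config.init_hgb_mean, config.init_hgb_sd,
                          *config.init_hgb_bounds)
    s0 = calibrate_stem_influx(params, profile, init_hgb, config.grid)
    params = params.with_s0(s0)

    horizon = config.adaptation_days + config.prediction_days
    session_days = []
    week = 0
    while True:
        new = [7 * week + off for off in (0.0, 2.0, 4.0) if 7 * week + off < horizon]
        if not new:
            break
        session_days.extend(new)
        week += 1
    session_days = np.array(session_days)

    grid = config.grid
    specs = _grids(params, grid)
    dmus = [d for _, d in specs]
    dt = _time_step(params, grid)
    t_end = float(session_days[-1])
    n_steps = max(1, math.ceil(t_end / dt - 1e-12))
    sess_idx = {min(n_steps, max(0, round(d / dt))): j for j, d in enumerate(session_days)}

    events = bleed_spec.events(horizon) if bleed_spec is not None else []
    ev_by_idx: dict[int, list[BloodEvent]] = {}
    for ev in events:
        ev_by_idx.setdefault(min(n_steps, max(0, round(ev.time / dt))), []).append(ev)

    state = discrete_steady_state(params, params.e_endo, grid, s0)
    u = [c.density for c in state.classes]
    kargs = _kernel_args(params, dmus)
    v_d = distribution_volume(params, profile.weight_kg)
    c_mch = params.constants.mch_pg

    policy = TitrationPolicy(config)
    dose_idx: list[int] = []
    dose_units: list[float] = []
    meas_hist: list[tuple[float, float]] = []
    true_post: list[float] = []
    records: list[TreatmentRecord] = []
    origin_end = BASE_SESSION_START + pd.Timedelta(hours=SESSION_HOURS)

    cur = 0
    for idx in sorted(set(sess_idx) | set(ev_by_idx) | {n_steps}):
        if idx > cur:
            epo = _epo_total_on_grid(
                idx + 1, dt, np.array(dose_idx, dtype=np.int64),
                np.array(dose_units), params, v_d,
            )
            buf = np.empty(idx - cur)
            run_segment(u[0], u[1], u[2], u[3], u[4], epo[cur:idx], dt, *kargs, s0, buf)
            cur = idx
        for ev in ev_by_idx.get(idx, ()):
            if ev.kind == "bleed":
                frac = ev.magnitude / (profile.tbv_post * 1000.0)
                if frac > 1.0:
                    raise ValueError("bleed volume exceeds total blood volume")
                u[4] *= 1.0 - frac
            else:
                u[4] += ev.cells / params.t_rbc

        if idx in sess_idx:
            j = sess_idx[idx]
            day = float(session_days[j])
            tp = hgb_from_count(float(np.trapezoid(u[4], dx=dmus[4])), profile.tbv_post, c_mch)
            true_post.append(tp)
            post_m, pre_m = _noisy_measurement(rng, tp, config.noise_cv, config.fluid_shift_range)
            missing = j > 0 and rng.random() < config.missing_prob
            if not missing:
                meas_hist.append((day, post_m))
            trailing = [v for d, v in meas_hist if day - d <= config.trailing_days]
            dose = policy.next_dose(
                float(np.mean(trailing)) if trailing else None, profile.weight_kg, day,
            )
            if dose > 0:
                dose_idx.append(idx)
                dose_units.append(dose)
            start = BASE_SESSION_START + pd.Timedelta(days=day)
            records.append(TreatmentRecord(
                patient_id=patient_id or f"SYN{seed:06d}",
                session_start=start,
                session_end=start + pd.Timedelta(hours=SESSION_HOURS),
                pre_hgb=None if missing else pre_m,
                post_hgb=None if missing else post_m,
                esa_dose=dose,
            ))

    for ev in events:
        end = origin_end + pd.Timedelta(days=ev.time)
        records.append(TreatmentRecord(
            patient_id=patient_id or f"SYN{seed:06d}",
            session_start=end - pd.Timedelta(minutes=5),
            session_end=end,
            pre_hgb=None,
            post_hgb=None,
            event_kind=ev.kind,
            event_magnitude=ev.magnitude,
        ))
    records.sort(key=lambda r: r.session_end)

    return SyntheticPatient(
        patient_id=patient_id or f"SYN{seed:06d}",
        seed=seed,
        config=config,
        profile=profile,
        true_params=params,
        init_hgb=init_hgb,
        session_days=session_days,
        true_post_hgb=np.array(true_post),
        records=records,
        events=events,
        bleed_spec=bleed_spec,
    )


def generate_cohort(n: int, seed: int, config: CohortConfig | None = None) -> list[SyntheticPatient]:
    """``n`` independent virtual patients from one master seed."""
    seeds = np.random.default_rng(seed).integers(1, 2**31 - 1, size=n)
    return [
        generate_patient(int(s), config, patient_id=f"SYN{i:03d}")
        for i, s in enumerate(seeds)
    ]


def inject_events(patient: SyntheticPatient, bleed_spec: BleedSpec | None) -> SyntheticPatient:
    """Regenerate a patient with a bleed/transfusion scenario added.

    Records are rebuilt from the stored (seed, config) so the result stays a
    pure function of its inputs; ``None`` returns the patient unchanged.
    """
    if bleed_spec is None:
        return patient
    return generate_patient(patient.seed, patient.config, bleed_spec, patient.patient_id)
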