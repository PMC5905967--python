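"""Five-class age-structured model of erythropoiesis.

Red blood cell production is represented as a cascade of five maturity-structured
population classes — BFU-E, CFU-E, erythroblasts, marrow reticulocytes and
circulating erythrocytes (which include blood reticulocytes).  Each class carries
a density ``u(t, mu)`` of cells per maturity-day; cells advance in maturity with a
velocity ``v``, proliferate with rate ``beta`` and die with rate ``alpha``, and the
outflux of one class is the boundary influx of the next.  Erythropoietin (EPO)
acts at two points of the cascade:

* survival of CFU-E progenitors — apoptosis decreases with EPO
  (``alpha_min + (alpha_max - alpha_min) * exp(-s_alpha * E)``);
* maturation speed of marrow reticulocytes — velocity increases linearly with
  EPO up to a cap (``min(v_max, v_min + s_v * E)``).

A drop of EPO below a threshold additionally triggers neocytolysis, the selective
destruction of the youngest circulating erythrocytes (age ``<= mu_neo``).

Endogenous EPO release is assumed constant for a dialysis patient (the renal
feedback loop is destroyed), while exogenous ESA boluses decay with first-order
elimination, so total EPO has a closed form.  Blood losses and transfusions act
directly on the erythrocyte class.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "ModelConstants",
    "PatientParameters",
    "EpoState",
    "BloodEvent",
    "PopulationClass",
    "PopulationState",
    "apoptosis_rate",
    "proliferation_rate",
    "maturation_velocity",
    "neocytolysis_rate",
    "epo_concentration",
    "distribution_volume",
    "apply_blood_event",
]

#: the five erythroid classes, in maturation order
CLASS_NAMES = ("BFU_E", "CFU_E", "erythroblast", "marrow_reticulocyte", "erythrocyte")

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class ModelConstants:
    """Fixed physiological constants shared by all patients.

    The defaults are calibrated so that a healthy reference subject
    (``s_alpha = 0.02``, ``s_v = 0.08``, ``E = 10 U/l``, ``T_RBC = 120 d``)
    settles at a normal hemoglobin around 14.5 g/dl once the stem-cell influx is
    matched to the blood volume.  All values can be overridden per run.
    """

    #: maturity-domain length (days) of BFU-E, CFU-E, erythroblasts, marrow retics
    maturity_span: tuple[float, float, float, float] = (7.0, 6.0, 5.0, 3.0)
    #: proliferation rate per class (1/day); mature erythrocytes do not divide
    beta: tuple[float, float, float, float, float] = (0.5, 0.5, 0.7, 0.0, 0.0)
    alpha_bfue: float = 0.02          # baseline apoptosis, 1/day
    alpha_erythroblast: float = 0.02
    alpha_marrow_reticulocyte: float = 0.0
    alpha_min: float = 0.01           # CFU-E apoptosis floor at saturating EPO, 1/day
    alpha_max: float = 0.25           # CFU-E apoptosis in the absence of EPO, 1/day
    v_min: float = 0.1                # marrow-reticulocyte velocity floor
    v_max: float = 2.5                # and cap, maturity-days/day
    e_neo: float = 5.0                # neocytolysis EPO threshold, U/l
    mu_neo: float = 14.0              # neocyte age window, days
    alpha_neo: float = 0.4            # maximal neocytolysis rate, 1/day
    mch_pg: float = 29.0              # mean corpuscular hemoglobin, pg/cell
    vd_l_per_kg: float = 0.055        # ESA distribution volume per kg body weight
    donor_cells_per_ml: float = 5.0e9 # RBC concentration of donated blood
    donor_unit_ml: float = 473.0      # volume of one donated unit ("a pint")

    def class_index(self, name: str) -> int:
        try:
            return CLASS_NAMES.index(name)
        except ValueError:
            raise KeyError(f"unknown population class {name!r}") from None


@dataclass(frozen=True)
class PatientParameters:
    """The five patient-specific quantities plus fixed constants.

    ``t_rbc`` (RBC lifespan, days), ``e_endo`` (endogenous EPO, U/l), ``t_half``
    (ESA elimination half-life, hours), ``s_alpha`` (slope of the CFU-E
    apoptosis-prevention function, l/U) and ``s_v`` (slope of the reticulocyte
    maturation-velocity function) are estimated per patient; ``s0`` (stem-cell
    influx into BFU-E, cells/day) is set by steady-state calibration against the
    blood volume.  ``v_d`` optionally overrides the weight-derived ESA
    distribution volume (liters).
    """

    t_rbc: float
    e_endo: float
    t_half: float
    s_alpha: float
    s_v: float
    s0: float | None = None
    v_d: float | None = None
    constants: ModelConstants = field(default_factory=ModelConstants)

    def __post_init__(self) -> None:
        if not self.t_rbc > 0:
            raise ValueError(f"RBC lifespan must be positive, got {self.t_rbc}")
        if not self.t_half > 0:
            raise ValueError(f"ESA half-life must be positive, got {self.t_half}")
        if self.e_endo < 0 or self.s_alpha < 0 or self.s_v < 0:
            raise ValueError("e_endo, s_alpha and s_v must be non-negative")
        c = self.constants
        if c.alpha_min > c.alpha_max or c.v_min > c.v_max:
            raise ValueError("rate bounds must be ordered (alpha_min<=alpha_max, v_min<=v_max)")
        if not 10.0 < self.t_rbc < 200.0:
            warnings.warn(
                f"RBC lifespan {self.t_rbc:.1f} d is outside the plausible (10, 200) range",
                stacklevel=2,
            )

    def with_s0(self, s0: float) -> "PatientParameters":
        return replace(self, s0=s0)


@dataclass(frozen=True)
class EpoState:
    """Decomposition of serum EPO into its two sources (U/l)."""

    e_exo: float
    e_endo: float

    def __post_init__(self) -> None:
        if self.e_exo < 0 or self.e_endo < 0:
            raise ValueError("EPO concentrations must be non-negative")

    @property
    def e_total(self) -> float:
        return self.e_exo + self.e_endo


@dataclass(frozen=True)
class BloodEvent:
    """A discrete hemorrhage or packed-red-cell transfusion.

    ``magnitude`` is milliliters lost for a bleed and the number of transfused
    units for a transfusion (one US unit: 473 ml at 5e9 cells/ml, i.e. about
    23.65e11 cells).
    """

    kind: str                     # "bleed" | "transfusion"
    time: float                   # days on the simulation clock
    magnitude: float              # ml (bleed) or units (transfusion)
    cells_per_ml: float = 5.0e9
    unit_volume_ml: float = 473.0

    def __post_init__(self) -> None:
        if self.kind not in ("bleed", "transfusion"):
            raise ValueError(f"unknown blood event kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("event magnitude must be non-negative")

    @property
    def cells(self) -> float:
        """Cells added by a transfusion (0 for a bleed)."""
        if self.kind != "transfusion":
            return 0.0
        return self.magnitude * self.unit_volume_ml * self.cells_per_ml


@dataclass
class PopulationClass:
    """One maturity-structured class: nodes ``grid`` on [0, mu_max], density in
    cells per maturity-day."""

    name: str
    mu_max: float
    grid: np.ndarray
    density: np.ndarray

    @property
    def dmu(self) -> float:
        return float(self.grid[1] - self.grid[0])

    @property
    def total(self) -> float:
        """Cell count: trapezoidal integral of the density over maturity."""
        return float(np.trapezoid(self.density, dx=self.dmu))

    def copy(self) -> "PopulationClass":
        return PopulationClass(self.name, self.mu_max, self.grid, self.density.copy())


@dataclass
class PopulationState:
    """All five classes at one time point, in maturation order."""

    time: float
    classes: list[PopulationClass]

    @property
    def total_counts(self) -> np.ndarray:
        return np.array([c.total for c in self.classes])

    def copy(self) -> "PopulationState":
        return PopulationState(self.time, [c.copy() for c in self.classes])


# ---------------------------------------------------------------------------
# EPO-dependent rate functions


def apoptosis_rate(class_name: str, e_total: float, mu: float, p: PatientParameters) -> float:
    """Apoptosis rate (1/day) of ``class_name`` at EPO level ``e_total`` and age ``mu``.

    CFU-E survival is the main EPO lever: the rate decays exponentially from
    ``alpha_max`` (no EPO) to ``alpha_min`` (saturating EPO) with slope
    ``s_alpha``.  Circulating erythrocytes die only by neocytolysis (and by
    reaching the lifespan boundary, which is handled by the solver); the
    remaining classes have constant baseline rates.
    """
    c = p.constants
    k = c.class_index(class_name)
    if e_total < 0:
        raise ValueError("EPO concentration must be non-negative")
    if k == 1:  # CFU-E
        return c.alpha_min + (c.alpha_max - c.alpha_min) * math.exp(-p.s_alpha * e_total)
    if k == 4:  # erythrocyte
        return neocytolysis_rate(e_total, mu, p)
    return (c.alpha_bfue, None, c.alpha_erythroblast, c.alpha_marrow_reticulocyte, None)[k]


def proliferation_rate(class_name: str, e_total: float, p: PatientParameters) -> float:
    """Proliferation rate (1/day); constant per class, zero for erythrocytes."""
    if e_total < 0:
        raise ValueError("EPO concentration must be non-negative")
    return p.constants.beta[p.constants.class_index(class_name)]


def maturation_velocity(class_name: str, e_total: float, p: PatientParameters) -> float:
    """Maturation velocity (maturity-days per day).

    Marrow reticulocytes speed up linearly with EPO, ``min(v_max, v_min + s_v*E)``;
    every other class matures at unit velocity, so its maturity coordinate is
    elapsed time in the class.
    """
    c = p.constants
    k = c.class_index(class_name)
    if e_total < 0:
        raise ValueError("EPO concentration must be non-negative")
    if k == 3:
        return min(c.v_max, c.v_min + p.s_v * e_total)
    return 1.0


def neocytolysis_rate(e_total: float, mu: float, p: PatientParameters) -> float:
    """Extra death rate of neocytes when EPO falls below the threshold.

    Returns ``alpha_neo * max(0, (E_neo - E)/E_neo)`` for ages ``mu <= mu_neo``
    and zero otherwise: fully suppressed EPO kills neocytes at ``alpha_neo``,
    and the effect vanishes continuously at ``E = E_neo``.
    """
    c = p.constants
    if mu > c.mu_neo:
        return 0.0
    return c.alpha_neo * max(0.0, (c.e_neo - e_total) / c.e_neo)


# ---------------------------------------------------------------------------
# EPO pharmacokinetics


def distribution_volume(p: PatientParameters, weight_kg: float) -> float:
    """ESA distribution volume in liters (override or 0.055 l per kg)."""
    if p.v_d is not None:
        if p.v_d <= 0:
            raise ValueError("distribution volume must be positive")
        return p.v_d
    v = p.constants.vd_l_per_kg * weight_kg
    if v <= 0:
        raise ValueError("distribution volume must be positive")
    return v


def epo_concentration(
    t: float | np.ndarray,
    doses: Iterable[tuple[float, float]],
    p: PatientParameters,
    v_d_l: float,
) -> float | np.ndarray:
    """Total serum EPO (U/l) at time(s) ``t`` (days).

    Each intravenous bolus of ``dose`` units given at ``t_i`` raises the
    concentration by ``dose / V_d`` instantaneously and decays with first-order
    elimination half-life ``t_half`` (hours), on top of the constant endogenous
    level::

        E(t) = E_endo + sum_{t_i <= t} (dose_i / V_d) * 2**(-(t - t_i) * 24 / t_half)

    This is the exact solution of ``dE_exo/dt = -(ln 2 / t_half) E_exo`` with
    impulse inputs.
    """
    if v_d_l <= 0:
        raise ValueError("distribution volume must be positive")
    t_arr = np.asarray(t, dtype=float)
    e = np.full(t_arr.shape, p.e_endo, dtype=float)
    k_per_day = _LN2 * 24.0 / p.t_half
    for t_i, dose in doses:
        mask = t_arr >= t_i
        e[mask] += (dose / v_d_l) * np.exp(-k_per_day * (t_arr[mask] - t_i))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(e)
    return e


# ---------------------------------------------------------------------------
# Blood events


def apply_blood_event(state: PopulationState, event: BloodEvent, tbv_l: float) -> PopulationState:
    """Return a new state with a bleed or transfusion applied to the erythrocytes.

    A bleed removes a fraction ``volume / TBV`` of every circulating cell
    (marrow classes are untouched); a transfusion adds
    ``units * unit_volume_ml * cells_per_ml`` cells spread uniformly over the
    maturity range ``[0, T_RBC]``.
    """
    if tbv_l <= 0:
        raise ValueError("total blood volume must be positive")
    new = state.copy()
    ery = new.classes[4]
    if event.kind == "bleed":
        frac = event.magnitude / (tbv_l * 1000.0)
        if frac > 1.0:
            raise ValueError(
                f"bleed volume {event.magnitude} ml exceeds total blood volume {tbv_l} l"
            )
        ery.density *= 1.0 - frac
    else:
        # uniform density increment integrates exactly to the transfused count
        ery.density += event.cells / ery.mu_max
    return new
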