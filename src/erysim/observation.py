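"""Mapping model state to measurable hemoglobin.

The model tracks a cell count; the clinic measures a concentration.  The link
is the patient's total blood volume (TBV), estimated post-dialysis from sex,
height and weight with the Nadler formula, and the mean corpuscular hemoglobin
(MCH).  Pre-dialysis values differ from post-dialysis values only through the
ultrafiltration-driven change in blood volume, which is handled algebraically:
the measured pre/post ratio fixes the pre-dialysis blood volume, and the
simulated post-dialysis Hgb is rescaled with it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PatientProfile", "nadler_tbv", "hgb_from_count", "pre_dialysis_hgb"]

# Nadler (1962) regression constants; h in meters, w in kg, result in liters.
_NADLER = {
    "male": (0.3669, 0.03219, 0.6041),
    "female": (0.3561, 0.03308, 0.1833),
}


def nadler_tbv(sex: str, height_cm: float, weight_kg: float) -> float:
    """Total blood volume (liters) from sex, height (cm) and weight (kg)."""
    if sex not in _NADLER:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if not 100.0 < height_cm < 230.0:
        raise ValueError(f"height {height_cm} cm outside the supported (100, 230) range")
    if not 25.0 < weight_kg < 300.0:
        raise ValueError(f"weight {weight_kg} kg outside the supported (25, 300) range")
    a, b, c = _NADLER[sex]
    h = height_cm / 100.0
    return a * h**3 + b * weight_kg + c


@dataclass(frozen=True)
class PatientProfile:
    """Anthropometrics needed by the observation model.

    ``weight_kg`` is the (average) post-dialytic weight, so :attr:`tbv_post`
    is the post-dialysis total blood volume.
    """

    sex: str
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        nadler_tbv(self.sex, self.height_cm, self.weight_kg)  # validates ranges

    @property
    def tbv_post(self) -> float:
        return nadler_tbv(self.sex, self.height_cm, self.weight_kg)


def hgb_from_count(n_rbc, tbv_l: float, mch_pg: float):
    """Hemoglobin (g/dl) of ``n_rbc`` cells in ``tbv_l`` liters at ``mch_pg`` pg/cell.

    ``Hgb = n * MCH * 1e-12 g / (TBV * 10 dl)``; accepts scalars or arrays.
    """
    if tbv_l <= 0:
        raise ValueError("total blood volume must be positive")
    hgb = np.asarray(n_rbc, dtype=float) * mch_pg * 1e-12 / (tbv_l * 10.0)
    return float(hgb) if hgb.ndim == 0 else hgb


def pre_dialysis_hgb(post_hgb_sim, post_hgb_clm: float, pre_hgb_clm: float,
                     post_tbv: float) -> tuple[float, float]:
    """Convert simulated post-dialysis Hgb to the pre-dialysis value.

    The measured pre/post pair fixes the pre-dialysis blood volume,
    ``preTBV = postHgb_CLM * postTBV / preHgb_CLM``, and the simulated value is
    rescaled onto it, ``preHgb_sim = postHgb_sim * postTBV / preTBV`` — which
    collapses to ``preHgb_sim = postHgb_sim * preHgb_CLM / postHgb_CLM``.
    Returns ``(preTBV, preHgb_sim)``.
    """
    if pre_hgb_clm <= 0 or post_hgb_clm <= 0:
        raise ValueError("measured Hgb values must be positive")
    if post_tbv <= 0:
        raise ValueError("post-dialysis blood volume must be positive")
    pre_tbv = post_hgb_clm * post_tbv / pre_hgb_clm
    pre_hgb_sim = post_hgb_sim * post_tbv / pre_tbv
    return pre_tbv, pre_hgb_sim
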