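"""Error metrics and the windowed prediction assessment.

Adaptation-period fit quality is reported as the mean absolute percentage error
(MAPE) on post-dialysis Hgb — the quantity the parameters were fitted to.
Prediction-period accuracy is reported on pre-dialysis Hgb (the clinically
customary presentation) in consecutive half-open 30-day windows after the
adaptation period; a patient contributes to a window only if follow-up data
reach into it.  Distributions of estimated parameters are compared to reference
samples with the Kantorovich (first Wasserstein / earth mover's) distance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import wasserstein_distance

__all__ = [
    "mape",
    "kantorovich",
    "WindowError",
    "windowed_prediction_error",
    "summarize_windows",
    "EvaluationReport",
]


def mape(y, g) -> float:
    """Mean absolute percentage error, ``(100/N) * sum |y_i - g_i| / |y_i|``.

    ``y`` are the measurements, ``g`` the model outputs at the same times.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.shape != g.shape or y.ndim != 1 or y.size == 0:
        raise ValueError("y and g must be equal-length non-empty 1-D arrays")
    if np.any(y == 0):
        raise ValueError("MAPE is undefined for zero measurements")
    return float(100.0 * np.mean(np.abs(y - g) / np.abs(y)))


def kantorovich(p_est, p_data) -> float:
    """Kantorovich (Wasserstein-1, earth mover's) distance between two samples.

    On the line it equals the integral of the absolute difference of the
    empirical CDFs; for equal-size samples the optimal coupling is the sorted
    pairing.
    """
    p_est = np.asarray(p_est, dtype=float)
    p_data = np.asarray(p_data, dtype=float)
    if p_est.size == 0 or p_data.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(wasserstein_distance(p_est, p_data))


@dataclass(frozen=True)
class WindowError:
    start_day: float
    end_day: float
    mape_pct: float
    n_points: int


def windowed_prediction_error(times_days, measured, simulated,
                              window_days: float = 30.0) -> list[WindowError]:
    """Per-window MAPE over consecutive ``[k*w, (k+1)*w)`` windows.

    ``times_days`` are measured from the start of the prediction period; a
    point at exactly a window edge belongs to the later window.  Windows
    without data are omitted.
    """
    t = np.asarray(times_days, dtype=float)
    y = np.asarray(measured, dtype=float)
    g = np.asarray(simulated, dtype=float)
    if t.size == 0:
        raise ValueError("prediction records must be non-empty")
    ok = np.isfinite(y) & np.isfinite(g)
    t, y, g = t[ok], y[ok], g[ok]
    rows = []
    for k in range(int(np.floor(t.max() / window_days)) + 1 if t.size else 0):
        in_win = (t >= k * window_days) & (t < (k + 1) * window_days)
        if in_win.any():
            rows.append(WindowError(
                start_day=k * window_days,
                end_day=(k + 1) * window_days,
                mape_pct=mape(y[in_win], g[in_win]),
                n_points=int(in_win.sum()),
            ))
    return rows


def summarize_windows(per_patient: list[list[WindowError]],
                      window_days: float = 30.0) -> list[dict]:
    """Cohort summary: median per-patient MAPE per window, with the number of
    patients still followed up (decreasing with horizon)."""
    by_start: dict[float, list[float]] = {}
    for rows in per_patient:
        for w in rows:
            by_start.setdefault(w.start_day, []).append(w.mape_pct)
    return [
        {
            "start_day": start,
            "end_day": start + window_days,
            "median_mape_pct": float(np.median(vals)),
            "n_patients": len(vals),
        }
        for start, vals in sorted(by_start.items())
    ]


@dataclass
class EvaluationReport:
    """Cohort-level adaptation and prediction errors."""

    mape_adaptation: dict[str, float]        # per patient, %
    windows: list[dict]                      # cohort window summary
    per_patient_windows: dict[str, list[WindowError]]
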