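"""Treatment-record CSV format, eligibility filtering and flat config files.

One row per dialysis session (or per standalone bleed/transfusion event):

    patient_id,session_start,session_end,pre_hgb,post_hgb,esa_dose,event_kind,event_magnitude

Timestamps are ISO-8601 and timezone-naive (clinic-local); Hgb is g/dl, the ESA
dose is units of epoetin alfa (0 when none was given); ``event_magnitude`` is ml
for a bleed and transfused units for a transfusion.  Missing measurements are
written as ``NA`` — the row is kept, because its dose (known from pharmacy
records rather than the bedside monitor) still drives the model.  Bleeds or
transfusions between sessions appear as measurement-free rows.

Eligibility follows the clinical screening of the source data: individual
readings with pre-dialysis Hgb below 5 or above 20 g/dl are discarded, and a
patient enters the analysis only with more than 42 eligible measurements and at
least two ESA administrations in the adaptation window.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import BloodEvent

__all__ = [
    "COLUMNS",
    "TreatmentRecord",
    "read_records",
    "write_records",
    "filter_eligible",
    "check_eligibility",
    "relative_days",
    "records_to_events",
    "load_config",
]

COLUMNS = (
    "patient_id", "session_start", "session_end",
    "pre_hgb", "post_hgb", "esa_dose", "event_kind", "event_magnitude",
)

EVENT_KINDS = ("none", "bleed", "transfusion")


@dataclass
class TreatmentRecord:
    """One dialysis session (or standalone blood event)."""

    patient_id: str
    session_start: pd.Timestamp
    session_end: pd.Timestamp
    pre_hgb: float | None
    post_hgb: float | None
    esa_dose: float = 0.0
    event_kind: str = "none"
    event_magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.session_end <= self.session_start:
            raise ValueError("session_end must be after session_start")
        for v, name in ((self.pre_hgb, "pre_hgb"), (self.post_hgb, "post_hgb")):
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive when present, got {v}")
        if self.esa_dose < 0:
            raise ValueError("esa_dose must be non-negative")
        if self.event_kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.event_kind!r}")


def _parse_hgb(text: str):
    if text in ("NA", "", "nan"):
        return None
    return float(text)


def read_records(path: str | Path) -> list[TreatmentRecord]:
    """Read a treatment-record CSV; malformed rows are reported with line numbers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(TreatmentRecord(
                patient_id=row.patient_id,
                session_start=pd.Timestamp(row.session_start),
                session_end=pd.Timestamp(row.session_end),
                pre_hgb=_parse_hgb(row.pre_hgb),
                post_hgb=_parse_hgb(row.post_hgb),
                esa_dose=float(row.esa_dose) if row.esa_dose != "" else 0.0,
                event_kind=row.event_kind or "none",
                event_magnitude=float(row.event_magnitude) if row.event_magnitude != "" else 0.0,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, line {i + 2}: {exc}") from exc
    return records


def write_records(records: Iterable[TreatmentRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "session_start": r.session_start.isoformat(),
            "session_end": r.session_end.isoformat(),
            "pre_hgb": "NA" if r.pre_hgb is None else repr(float(r.pre_hgb)),
            "post_hgb": "NA" if r.post_hgb is None else repr(float(r.post_hgb)),
            "esa_dose": repr(float(r.esa_dose)),
            "event_kind": r.event_kind,
            "event_magnitude": repr(float(r.event_magnitude)),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(COLUMNS)).to_csv(path, index=False)


def filter_eligible(records: Sequence[TreatmentRecord]):
    """Record-level screening: drop rows without a usable pre-dialysis reading.

    Returns ``(kept, dropped)`` with ``dropped`` a list of ``(record, reason)``;
    the two parts partition the input.  The thresholds are strict: 5.0 and
    20.0 g/dl themselves are kept.
    """
    kept, dropped = [], []
    for r in records:
        if r.pre_hgb is None or r.post_hgb is None:
            dropped.append((r, "missing_measurement"))
        elif r.pre_hgb < 5.0:
            dropped.append((r, "pre_hgb_below_5"))
        elif r.pre_hgb > 20.0:
            dropped.append((r, "pre_hgb_above_20"))
        else:
            kept.append(r)
    return kept, dropped


def check_eligibility(records: Sequence[TreatmentRecord], adaptation_days: float = 150.0):
    """Patient-level rule on the adaptation window: >42 eligible measurements
    and >=2 ESA administrations.  Returns ``(eligible, reasons)``."""
    if not records:
        return False, ["no records"]
    t = relative_days(records)
    window = [r for r, ti in zip(records, t) if ti < adaptation_days]
    kept, _ = filter_eligible(window)
    n_doses = sum(1 for r in window if r.esa_dose > 0)
    reasons = []
    if len(kept) <= 42:
        reasons.append(f"only {len(kept)} eligible measurements (>42 required)")
    if n_doses < 2:
        reasons.append(f"only {n_doses} ESA administrations (at least 2 required)")
    return not reasons, reasons


def relative_days(records: Sequence[TreatmentRecord], origin: pd.Timestamp | None = None) -> np.ndarray:
    """Session-end times in days since the first record's session end."""
    if not records:
        return np.array([])
    origin = records[0].session_end if origin is None else origin
    return np.array([(r.session_end - origin) / pd.Timedelta(days=1) for r in records])


def records_to_events(records: Sequence[TreatmentRecord], origin: pd.Timestamp | None = None) -> list[BloodEvent]:
    """Blood events carried by the records, on the relative-days clock."""
    t = relative_days(records, origin)
    return [
        BloodEvent(kind=r.event_kind, time=float(ti), magnitude=r.event_magnitude)
        for r, ti in zip(records, t)
        if r.event_kind != "none"
    ]


def load_config(path: str | Path) -> dict:
    """Flat ``key = value`` config file; values parsed as float when possible."""
    cfg = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}, line {i}: expected 'key = value'")
        key, value = (s.strip() for s in line.split("=", 1))
        try:
            cfg[key] = float(value)
        except ValueError:
            cfg[key] = value
    return cfg
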