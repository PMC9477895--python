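"""Per-eye 24-h IOP summary variables and ocular perfusion pressure.

From each eye's five-point diurnal profile the standard summaries are
T_avg (mean), T_max (peak), T_min (trough) and IOP_var = T_max − T_min.
Mean ocular perfusion pressure combines admission blood pressure with IOP:

    MAP  = DBP + (SBP − DBP) / 3
    MOPP = 2/3 · (MAP − IOP)

Missing time points are skipped (complete-case within the profile, never
imputed — absent entries are a fact of the hand-drawn sheets).  Summaries
require at least two present time points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientData, InvalidBloodPressure
from .layout import OUTPATIENT_LABELS, TIME_LABELS, Eye

#: Cohort-table column suffix per time label ("10:00" → "t10").
TIME_COLUMNS = {"10:00": "t10", "14:00": "t14", "17:00": "t17",
                "21:00": "t21", "24:00": "t24"}


@dataclass(frozen=True)
class PerfusionInputs:
    """Admission systolic/diastolic blood pressure, mmHg."""

    sbp: float
    dbp: float

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp > 0:
            raise InvalidBloodPressure(f"need SBP > DBP > 0, got {self.sbp}/{self.dbp}")

    @property
    def map_mmhg(self) -> float:
        return self.dbp + (self.sbp - self.dbp) / 3.0


def summarize_profile(values_by_time: dict[str, float]
                      ) -> tuple[float, float, float, float]:
    """(T_avg, T_max, T_min, IOP_var) over the present time points."""
    vals = [v for v in values_by_time.values() if v is not None and not np.isnan(v)]
    if len(vals) < 2:
        raise InsufficientData(f"need >= 2 time points, got {len(vals)}")
    t_max, t_min = float(max(vals)), float(min(vals))
    return float(np.mean(vals)), t_max, t_min, t_max - t_min


def outpatient_subset(values_by_time: dict[str, float]) -> dict[str, float]:
    """Restrict a profile to outpatient office hours (10 AM, 2 PM, 5 PM)."""
    return {t: v for t, v in values_by_time.items() if t in OUTPATIENT_LABELS}


def compute_mopp(perfusion: PerfusionInputs, iop_mmhg: float) -> float:
    """Mean ocular perfusion pressure, mmHg."""
    return (2.0 / 3.0) * (perfusion.map_mmhg - iop_mmhg)


@dataclass
class EyeProfile:
    """One eye's five-point profile with derived summaries.

    ``mopp`` uses the profile's T_avg as the IOP term by default (the
    per-time-point alternative is available through ``compute_mopp``).
    """

    eye: Eye
    values_by_time: dict[str, float]
    t_avg: float | None = None
    t_max: float | None = None
    t_min: float | None = None
    iop_var: float | None = None
    mopp: float | None = None

    @classmethod
    def from_values(cls, eye: Eye, values_by_time: dict[str, float],
                    perfusion: PerfusionInputs | None = None) -> "EyeProfile":
        prof = cls(eye=Eye(eye), values_by_time=dict(values_by_time))
        try:
            prof.t_avg, prof.t_max, prof.t_min, prof.iop_var = \
                summarize_profile(values_by_time)
        except InsufficientData:
            return prof
        if perfusion is not None:
            prof.mopp = compute_mopp(perfusion, prof.t_avg)
        return prof


def augment_profiles(df: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns to a per-eye table.

    Expects one row per (patient, eye) with columns ``t10 t14 t17 t21 t24``
    (missing entries as NaN) and optionally ``sbp``/``dbp``.  Appends
    ``t_avg t_max t_min iop_var`` and, where blood pressure is present,
    ``mopp``; rows with fewer than two time points keep NaN summaries.
    """
    out = df.copy()
    cols = list(TIME_COLUMNS.values())
    vals = out[cols].to_numpy(dtype=float)
    n_present = np.sum(~np.isnan(vals), axis=1)
    with np.errstate(invalid="ignore"):
        t_avg = np.nanmean(vals, axis=1)
        t_max = np.nanmax(np.where(np.isnan(vals), -np.inf, vals), axis=1)
        t_min = np.nanmin(np.where(np.isnan(vals), np.inf, vals), axis=1)
    enough = n_present >= 2
    out["t_avg"] = np.where(enough, t_avg, np.nan)
    out["t_max"] = np.where(enough, t_max, np.nan)
    out["t_min"] = np.where(enough, t_min, np.nan)
    out["iop_var"] = out["t_max"] - out["t_min"]
    if {"sbp", "dbp"}.issubset(out.columns):
        map_ = out["dbp"] + (out["sbp"] - out["dbp"]) / 3.0
        out["mopp"] = (2.0 / 3.0) * (map_ - out["t_avg"])
    return out
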