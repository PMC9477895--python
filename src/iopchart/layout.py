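"""Geometric description of the 24-h IOP profile form.

The historical inpatient protocol records applanation tonometry at five
clock times — 10 AM, 2 PM, 5 PM, 9 PM and midnight — on an A4 sheet with a
rectangular plot frame: the x axis carries five vertical examination-time
lines, the y axis is pressure in mmHg.  Left-eye values are drawn in red,
right-eye values in blue.  ``ChartLayout`` captures the template geometry
needed both to render synthetic sheets and to convert detected pixel
positions back into (eye, time, mmHg) records.

Pixel convention: origin at the top-left corner, y increases downward,
coordinates are 0-based.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict

from .errors import OutOfFrame

#: Protocol examination times, left to right on the form.  The midnight
#: reading (supine, handheld tonometer) is the fifth, rightmost line.
TIME_LABELS: tuple[str, ...] = ("10:00", "14:00", "17:00", "21:00", "24:00")

#: Outpatient office hours subset (10 AM, 2 PM, 5 PM).
OUTPATIENT_LABELS: tuple[str, ...] = ("10:00", "14:00", "17:00")


class Eye(str, enum.Enum):
    LEFT = "left"    # drawn in red on the historical forms
    RIGHT = "right"  # drawn in blue

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ChartLayout:
    """Template geometry of one profile sheet (defaults: A4 at 150 dpi)."""

    page_w_px: int = 1240
    page_h_px: int = 1754
    frame: tuple[int, int, int, int] = (160, 260, 1120, 1540)  # x0, y0, x1, y1
    time_line_xs: tuple[int, ...] = (320, 480, 640, 800, 960)
    time_labels: tuple[str, ...] = TIME_LABELS
    axis_min_mmhg: float = 0.0
    axis_max_mmhg: float = 50.0
    grid_step_mmhg: float = 5.0
    dpi: int = 150
    # name and date fields sit above the frame, in page coordinates
    name_box: tuple[int, int, int, int] = (160, 80, 700, 180)
    date_box: tuple[int, int, int, int] = (760, 70, 1180, 190)

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.frame
        if not (x0 < x1 and y0 < y1):
            raise ValueError("frame must satisfy x0<x1 and y0<y1")
        if len(self.time_labels) != 5 or len(self.time_line_xs) != 5:
            raise ValueError("exactly 5 time lines/labels are required")
        xs = self.time_line_xs
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("time_line_xs must be strictly increasing")
        if not all(x0 < x < x1 for x in xs):
            raise ValueError("time lines must lie strictly inside the frame")
        if not self.axis_min_mmhg < self.axis_max_mmhg:
            raise ValueError("axis_min_mmhg must be below axis_max_mmhg")

    @property
    def marker_radius(self) -> int:
        """Radius of a plotted entry disc, ~dpi/30 (≈1 mm on paper)."""
        return max(3, round(self.dpi / 30))

    def value_to_pixel(self, time_slot: str, iop_mmhg: float) -> tuple[float, float]:
        """Map (clock time, mmHg) to the pixel centre of the plotted mark."""
        if time_slot not in self.time_labels:
            raise ValueError(f"unknown time slot {time_slot!r}")
        if not self.axis_min_mmhg <= iop_mmhg <= self.axis_max_mmhg:
            raise OutOfFrame(f"{iop_mmhg} mmHg outside axis range")
        x = float(self.time_line_xs[self.time_labels.index(time_slot)])
        _, y0, _, y1 = self.frame
        frac = (iop_mmhg - self.axis_min_mmhg) / (self.axis_max_mmhg - self.axis_min_mmhg)
        return x, y1 - frac * (y1 - y0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ChartLayout":
        d = dict(d)
        for key in ("frame", "time_line_xs", "time_labels", "name_box", "date_box"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class AxisCalibration:
    """Linear y-pixel ↔ mmHg map derived from the detected frame edges.

    ``value(y) = axis_min + (y_bottom − y) / (y_bottom − y_top) · (axis_max − axis_min)``
    — strictly decreasing in y (pressure grows upward on the sheet).
    """

    y_bottom_px: float
    y_top_px: float
    axis_min_mmhg: float
    axis_max_mmhg: float

    def __post_init__(self) -> None:
        if not self.y_top_px < self.y_bottom_px:
            raise ValueError("y_top_px must be above (smaller than) y_bottom_px")
        if not self.axis_min_mmhg < self.axis_max_mmhg:
            raise ValueError("axis_min_mmhg must be below axis_max_mmhg")

    def pixel_to_value(self, y_px: float, tolerance_px: float = 2.0) -> float:
        """mmHg at pixel row ``y_px`` (real-valued, before any rounding)."""
        if not (self.y_top_px - tolerance_px) <= y_px <= (self.y_bottom_px + tolerance_px):
            raise OutOfFrame(f"y={y_px} outside frame rows "
                             f"[{self.y_top_px}, {self.y_bottom_px}]")
        frac = (self.y_bottom_px - y_px) / (self.y_bottom_px - self.y_top_px)
        return self.axis_min_mmhg + frac * (self.axis_max_mmhg - self.axis_min_mmhg)

    def value_to_pixel(self, iop_mmhg: float) -> float:
        frac = (iop_mmhg - self.axis_min_mmhg) / (self.axis_max_mmhg - self.axis_min_mmhg)
        return self.y_bottom_px - frac * (self.y_bottom_px - self.y_top_px)


@dataclass
class ChartEntry:
    """One plotted IOP point: which eye, which protocol time, how many mmHg."""

    eye: Eye
    time_slot: str
    iop_mmhg: int
    px: tuple[float, float] | None = None  # (x, y) centroid, filled on render/extract

    def __post_init__(self) -> None:
        self.eye = Eye(self.eye)
        if self.time_slot not in TIME_LABELS:
            raise ValueError(f"time_slot must be one of {TIME_LABELS}")

    def key(self) -> tuple[Eye, str]:
        return (self.eye, self.time_slot)


@dataclass
class GroundTruth:
    """Everything needed to score an extraction run against a rendered sheet."""

    patient_id: str
    exam_date: tuple[int, int, int]  # (day, month, year)
    entries: list[ChartEntry] = field(default_factory=list)
    layout: ChartLayout = field(default_factory=ChartLayout)

    def to_dict(self) -> dict:
        d, m, y = self.exam_date
        return {
            "patient_id": self.patient_id,
            "exam_date": {"d": d, "m": m, "y": y},
            "layout": self.layout.to_dict(),
            "entries": [
                {"eye": e.eye.value, "time": e.time_slot, "iop": e.iop_mmhg,
                 "px": list(e.px) if e.px is not None else None}
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        date = d["exam_date"]
        return cls(
            patient_id=d["patient_id"],
            exam_date=(date["d"], date["m"], date["y"]),
            layout=ChartLayout.from_dict(d["layout"]),
            entries=[
                ChartEntry(Eye(e["eye"]), e["time"], e["iop"],
                           tuple(e["px"]) if e.get("px") else None)
                for e in d["entries"]
            ],
        )
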