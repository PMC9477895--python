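"""Chart digitization: frame detection, time-line detection, entry extraction.

The pipeline mirrors how a technician reads the sheet.  First the page is
deskewed and the plot frame located (largest dark near-rectangular contour);
the five vertical examination-time lines are then found with Canny edge
detection followed by a Hough line transform restricted to near-vertical
angles; finally color-specific masks (red = left eye, blue = right eye)
isolate the plotted discs, whose pixel centroids map linearly back to
(clock time, mmHg) because the form geometry is fixed.

Accuracy bookkeeping follows the manual-verification convention: a *false
entry* is a detected entry with an incorrect value; a *missed entry* is a
ground-truth entry the software did not detect at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.feature import canny
from skimage.transform import hough_line, hough_line_peaks

from .digits import DigitClassifier, patch_from_glyph
from .errors import DateUnparsed, NoFrameFound, TimeAxisAmbiguous
from .layout import (TIME_LABELS, AxisCalibration, ChartEntry, ChartLayout,
                     Eye, GroundTruth)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable thresholds of the digitization pipeline.

    Hue bounds are degrees on the 0–360 color wheel; red wraps around zero.
    ``marker_area_px`` brackets the plausible disc size after one 3×3
    morphological opening has removed the thin connecting polyline.
    """

    red_hue_deg: tuple[float, float, float, float] = (0.0, 12.0, 348.0, 360.0)
    blue_hue_deg: tuple[float, float] = (200.0, 260.0)
    min_saturation: float = 0.35
    min_value: float = 0.25
    marker_area_px: tuple[int, int] = (25, 650)
    dark_level: int = 110           # gray level below which a pixel is "ink"
    frame_min_area_frac: float = 0.20
    vertical_tol_deg: float = 3.0   # |angle from vertical| for time lines
    line_span_frac: float = 0.60    # required dark fraction of frame height
    cluster_gap_frac: float = 0.03  # x-gap separating distinct line clusters
    date_min_ink_px: int = 40


@dataclass
class FrameResult:
    """Deskewed page, detected frame corners (page coords) and the crop."""

    corners: np.ndarray            # (4, 2) x,y: TL, TR, BR, BL
    crop: np.ndarray               # RGB uint8, axis-aligned plot area
    page: np.ndarray               # full deskewed RGB page
    bbox: tuple[int, int, int, int]  # x0, y0, x1, y1 in page coords
    skew_deg: float


def _to_array(image) -> np.ndarray:
    if isinstance(image, Image.Image):
        return np.asarray(image.convert("RGB"))
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image")
    return arr


def _estimate_skew(gray: np.ndarray) -> float:
    """Page tilt in degrees from near-vertical Hough lines (downsampled 2×)."""
    small = gray[::2, ::2] / 255.0
    edges = canny(small, sigma=1.5)
    thetas = np.deg2rad(np.linspace(-4.0, 4.0, 161))
    h, theta, d = hough_line(edges, theta=thetas)
    _, angles, _ = hough_line_peaks(h, theta, d, num_peaks=12,
                                    threshold=0.4 * h.max())
    if len(angles) == 0:
        return 0.0
    return float(np.rad2deg(np.median(angles)))


def detect_frame(image, config: ExtractionConfig | None = None) -> FrameResult:
    """Locate the plot frame and return the deskewed, cropped plot area.

    Raises ``NoFrameFound`` when no dark contour covers at least
    ``frame_min_area_frac`` of the page.
    """
    config = config or ExtractionConfig()
    arr = _to_array(image)
    gray = np.asarray(Image.fromarray(arr).convert("L"), dtype=float)
    skew = _estimate_skew(gray)
    if abs(skew) > 0.05:
        # the Hough normal angle of the tilted verticals is minus the page
        # rotation, so rotating by +skew straightens the page
        pil = Image.fromarray(arr).rotate(skew, resample=Image.BILINEAR,
                                          fillcolor=(255, 255, 255))
        arr = np.asarray(pil)
        gray = np.asarray(pil.convert("L"), dtype=float)
    dark = gray < config.dark_level
    labels, n = ndimage.label(dark)
    if n == 0:
        raise NoFrameFound("page contains no dark ink")
    objects = ndimage.find_objects(labels)
    page_area = arr.shape[0] * arr.shape[1]
    best, best_area = None, 0
    for sl in objects:
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        if h * w > best_area:
            best, best_area = sl, h * w
    if best is None or best_area < config.frame_min_area_frac * page_area:
        raise NoFrameFound(
            f"largest contour bbox covers {best_area / page_area:.1%} "
            f"of the page (< {config.frame_min_area_frac:.0%})")
    y0, y1 = best[0].start, best[0].stop - 1
    x0, x1 = best[1].start, best[1].stop - 1
    corners = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)
    crop = arr[y0:y1 + 1, x0:x1 + 1]
    return FrameResult(corners=corners, crop=crop, page=arr,
                       bbox=(x0, y0, x1, y1), skew_deg=skew)


def detect_time_lines(crop: np.ndarray,
                      config: ExtractionConfig | None = None) -> np.ndarray:
    """Five x-positions of the examination-time lines, increasing order.

    Canny edges feed a Hough transform restricted to near-vertical angles;
    surviving candidates must actually span most of the frame height, and
    are clustered along x.  Raises ``TimeAxisAmbiguous`` unless exactly
    five clusters remain (frame verticals are excluded by an edge margin).
    """
    config = config or ExtractionConfig()
    gray = np.asarray(Image.fromarray(crop).convert("L"), dtype=float)
    h_px, w_px = gray.shape
    small = gray[::2, ::2]
    edges = canny(small / 255.0, sigma=1.2)
    tol = np.deg2rad(config.vertical_tol_deg)
    thetas = np.linspace(-tol, tol, 61)
    acc, theta, dist = hough_line(edges, theta=thetas)
    _, angles, dists = hough_line_peaks(
        acc, theta, dist, num_peaks=40,
        threshold=0.4 * config.line_span_frac * small.shape[0], min_distance=3)
    y_mid = small.shape[0] / 2.0
    dark = gray < (config.dark_level + 30)
    margin = config.cluster_gap_frac * w_px
    xs = []
    for ang, d in zip(angles, dists):
        x = 2.0 * (d - y_mid * np.sin(ang)) / np.cos(ang)
        if not margin < x < w_px - margin:
            continue  # frame verticals
        lo, hi = int(max(0, x - 3)), int(min(w_px, x + 4))
        span = dark[:, lo:hi].any(axis=1).mean()
        if span >= config.line_span_frac:
            xs.append(x)
    if not xs:
        raise TimeAxisAmbiguous(0)
    xs = np.sort(xs)
    gap = config.cluster_gap_frac * w_px
    clusters, current = [], [xs[0]]
    for x in xs[1:]:
        if x - current[-1] > gap:
            clusters.append(np.mean(current))
            current = [x]
        else:
            current.append(x)
    clusters.append(np.mean(current))
    if len(clusters) != 5:
        raise TimeAxisAmbiguous(len(clusters))
    # refine each cluster to the ink-weighted column centroid of the line
    ink = np.maximum(0.0, (config.dark_level + 40) - gray)
    refined = []
    for x in clusters:
        lo, hi = int(max(0, x - 4)), int(min(w_px, x + 5))
        weights = ink[:, lo:hi].sum(axis=0)
        if weights.sum() > 0:
            x = float((weights * np.arange(lo, hi)).sum() / weights.sum())
        refined.append(x)
    return np.asarray(refined)


def pixel_to_value(y_px: float, calibration: AxisCalibration) -> float:
    """mmHg at pixel row ``y_px`` under the linear axis calibration."""
    return calibration.pixel_to_value(y_px)


def color_masks(crop: np.ndarray, config: ExtractionConfig | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (red, blue) pencil masks.  Disjoint by construction.

    Thresholds are standard HSV (hue in degrees, saturation = chroma/value);
    the hue is only evaluated on sufficiently saturated pixels, which keeps
    the page-sized computation cheap without changing the HSV semantics.
    """
    config = config or ExtractionConfig()
    arr = crop.astype(np.int32)
    mx = arr.max(axis=2)
    mn = arr.min(axis=2)
    chroma = mx - mn
    with np.errstate(divide="ignore", invalid="ignore"):
        sat_ok = ((chroma >= config.min_saturation * np.maximum(mx, 1))
                  & (mx >= config.min_value * 255.0) & (chroma > 0))
    idx = np.nonzero(sat_ok)
    r, g, b = (arr[..., i][idx].astype(float) for i in range(3))
    c = chroma[idx].astype(float)
    m = mx[idx].astype(float)
    hue = np.empty_like(c)
    is_r = m == r
    is_g = ~is_r & (m == g)
    is_b = ~is_r & ~is_g
    hue[is_r] = (60.0 * (g[is_r] - b[is_r]) / c[is_r]) % 360.0
    hue[is_g] = 60.0 * (b[is_g] - r[is_g]) / c[is_g] + 120.0
    hue[is_b] = 60.0 * (r[is_b] - g[is_b]) / c[is_b] + 240.0
    r0, r1, r2, r3 = config.red_hue_deg
    red = np.zeros(crop.shape[:2], dtype=bool)
    blue = np.zeros(crop.shape[:2], dtype=bool)
    red[idx] = ((hue >= r0) & (hue <= r1)) | ((hue >= r2) & (hue <= r3))
    b0, b1 = config.blue_hue_deg
    blue[idx] = (hue >= b0) & (hue <= b1)
    return red, blue


def extract_entries(crop: np.ndarray, calibration: AxisCalibration,
                    time_xs: np.ndarray,
                    config: ExtractionConfig | None = None) -> list[ChartEntry]:
    """Convert colored marks in the crop to (eye, time, mmHg) records.

    One 3×3 morphological opening strips the connecting polyline; remaining
    components in the marker-area range are assigned to the nearest time
    line (within half the minimum inter-line gap) and their centroid row is
    mapped to mmHg.  If several same-color components land on one slot the
    largest is kept and the conflict logged.  An empty list is valid.
    """
    config = config or ExtractionConfig()
    time_xs = np.asarray(time_xs, dtype=float)
    half_gap = np.diff(np.sort(time_xs)).min() / 2.0
    lo_a, hi_a = config.marker_area_px
    red, blue = color_masks(crop, config)
    structure = np.ones((3, 3), dtype=bool)
    best: dict[tuple[Eye, str], tuple[float, ChartEntry]] = {}
    for eye, mask in ((Eye.LEFT, red), (Eye.RIGHT, blue)):
        opened = ndimage.binary_opening(mask, structure=structure)
        labels, n = ndimage.label(opened)
        if n == 0:
            continue
        flat = labels[opened]
        areas = np.bincount(flat, minlength=n + 1)[1:]
        ys, xs_pix = np.nonzero(opened)
        cy_sum = np.bincount(flat, weights=ys, minlength=n + 1)[1:]
        cx_sum = np.bincount(flat, weights=xs_pix, minlength=n + 1)[1:]
        centroids = np.stack([cy_sum / areas, cx_sum / areas], axis=1)
        for area, (cy, cx) in zip(areas, centroids):
            if not lo_a <= area <= hi_a:
                continue
            slot_i = int(np.argmin(np.abs(time_xs - cx)))
            if abs(time_xs[slot_i] - cx) > half_gap:
                continue
            try:
                value = calibration.pixel_to_value(cy, tolerance_px=3.0)
            except Exception:
                continue
            mmhg = int(round(np.clip(value, calibration.axis_min_mmhg,
                                     calibration.axis_max_mmhg)))
            entry = ChartEntry(eye, TIME_LABELS[slot_i], mmhg, px=(cx, cy))
            key = entry.key()
            if key in best:
                log.warning("conflicting %s components at slot %s: "
                            "keeping largest (areas %.0f vs %.0f)",
                            eye.value, entry.time_slot, best[key][0], area)
                if area > best[key][0]:
                    best[key] = (area, entry)
            else:
                best[key] = (area, entry)
    entries = [e for _, e in best.values()]
    entries.sort(key=lambda e: (e.eye.value, TIME_LABELS.index(e.time_slot)))
    return entries


def _map_box(box, template_frame, detected_bbox):
    """Affine-map a template-coordinate box into detected-page coordinates."""
    tx0, ty0, tx1, ty1 = template_frame
    dx0, dy0, dx1, dy1 = detected_bbox
    sx = (dx1 - dx0) / (tx1 - tx0)
    sy = (dy1 - dy0) / (ty1 - ty0)
    bx0, by0, bx1, by1 = box
    return (dx0 + (bx0 - tx0) * sx, dy0 + (by0 - ty0) * sy,
            dx0 + (bx1 - tx0) * sx, dy0 + (by1 - ty0) * sy)


def read_date(image, classifier: DigitClassifier,
              layout: ChartLayout | None = None,
              frame_bbox: tuple[int, int, int, int] | None = None,
              config: ExtractionConfig | None = None,
              ) -> tuple[tuple[int, int, int], np.ndarray]:
    """Read the handwritten exam date (d, m, y) from the date box.

    Ink components in the date field are segmented left→right and each is
    classified as a digit; the expected pattern is ``dd mm yyyy`` (eight
    digits).  Returns the date and the per-digit confidence vector.
    Raises ``DateUnparsed`` on any other digit count.
    """
    config = config or ExtractionConfig()
    layout = layout or ChartLayout()
    arr = _to_array(image)
    box = layout.date_box
    if frame_bbox is not None:
        box = _map_box(box, layout.frame, frame_bbox)
    x0, y0, x1, y1 = (int(round(v)) for v in box)
    region = np.asarray(Image.fromarray(arr[y0:y1, x0:x1]).convert("L"),
                        dtype=float)
    ink = region < 128
    labels, n = ndimage.label(ink)
    comps = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        area = int((labels[sl] == i).sum())
        if area < config.date_min_ink_px:
            continue
        cx = (sl[1].start + sl[1].stop) / 2.0
        comps.append((cx, sl, i))
    comps.sort(key=lambda t: t[0])
    if len(comps) != 8:
        raise DateUnparsed(f"expected 8 date digits, found {len(comps)}")
    patches = []
    for _, sl, i in comps:
        sub = region[sl].copy()
        sub[labels[sl] != i] = 255.0   # suppress neighbouring strokes
        patches.append(patch_from_glyph(sub))
    patches = np.asarray(patches)
    digits = classifier.predict(patches)
    proba = classifier.predict_proba(patches)
    conf = proba.max(axis=1)
    d = 10 * digits[0] + digits[1]
    m = 10 * digits[2] + digits[3]
    y = 1000 * digits[4] + 100 * digits[5] + 10 * digits[6] + digits[7]
    return (int(d), int(m), int(y)), conf


@dataclass
class CurveReport:
    """Accuracy accounting for one curve (one eye on one sheet)."""

    eye: Eye
    detected: int = 0
    correct: int = 0
    false_entries: int = 0
    missed_entries: int = 0


@dataclass
class ExtractionReport:
    """Detected / false / missed accounting for one sheet (two curves)."""

    detected: int = 0
    correct: int = 0
    false_entries: int = 0
    missed_entries: int = 0
    per_eye: dict = field(default_factory=dict)
    matches: list = field(default_factory=list)  # (eye, slot, predicted, truth)

    def to_dict(self) -> dict:
        return {
            "detected": self.detected, "correct": self.correct,
            "false_entries": self.false_entries,
            "missed_entries": self.missed_entries,
            "per_eye": {e.value: vars(c) | {"eye": e.value}
                        for e, c in self.per_eye.items()},
        }


def evaluate_extraction(predicted: list[ChartEntry], truth: GroundTruth,
                        tolerance_mmhg: int = 0) -> ExtractionReport:
    """Score predictions against ground truth on one sheet.

    Matching is on (eye, time slot).  A matched prediction whose value
    differs from the truth by more than ``tolerance_mmhg`` is a false
    entry, as is a prediction with no ground-truth slot; a ground-truth
    slot with no prediction is a missed entry.
    """
    report = ExtractionReport(per_eye={e: CurveReport(e) for e in Eye})
    truth_map = {e.key(): e.iop_mmhg for e in truth.entries}
    pred_map: dict[tuple[Eye, str], int] = {}
    for p in predicted:
        pred_map[p.key()] = p.iop_mmhg
    for key, value in pred_map.items():
        eye = key[0]
        curve = report.per_eye[eye]
        curve.detected += 1
        if key in truth_map:
            report.matches.append((eye, key[1], value, truth_map[key]))
            if abs(value - truth_map[key]) <= tolerance_mmhg:
                curve.correct += 1
            else:
                curve.false_entries += 1
        else:
            curve.false_entries += 1
    for key in truth_map:
        if key not in pred_map:
            report.per_eye[key[0]].missed_entries += 1
    for curve in report.per_eye.values():
        report.detected += curve.detected
        report.correct += curve.correct
        report.false_entries += curve.false_entries
        report.missed_entries += curve.missed_entries
    return report


@dataclass
class ChartReading:
    """Full digitization result for one sheet."""

    entries: list[ChartEntry]
    time_xs: np.ndarray
    calibration: AxisCalibration
    frame: FrameResult
    exam_date: tuple[int, int, int] | None = None
    date_confidence: np.ndarray | None = None


def read_chart(image, layout: ChartLayout | None = None,
               config: ExtractionConfig | None = None,
               classifier: DigitClassifier | None = None) -> ChartReading:
    """Run the whole pipeline on one sheet image.

    The template layout supplies the axis value range (and, when a digit
    classifier is given, the date-box location); all geometry is detected
    from the image itself.
    """
    layout = layout or ChartLayout()
    config = config or ExtractionConfig()
    frame = detect_frame(image, config)
    h = frame.crop.shape[0]
    calibration = AxisCalibration(
        y_bottom_px=float(h - 1), y_top_px=0.0,
        axis_min_mmhg=layout.axis_min_mmhg, axis_max_mmhg=layout.axis_max_mmhg)
    time_xs = detect_time_lines(frame.crop, config)
    entries = extract_entries(frame.crop, calibration, time_xs, config)
    reading = ChartReading(entries=entries, time_xs=time_xs,
                           calibration=calibration, frame=frame)
    if classifier is not None:
        try:
            reading.exam_date, reading.date_confidence = read_date(
                frame.page, classifier, layout, frame_bbox=frame.bbox,
                config=config)
        except DateUnparsed as exc:
            log.warning("date not parsed: %s", exc)
    return reading
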