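"""Synthetic 24-h IOP profile sheet renderer and dataset factory.

Because no scanned chart archive is publicly deposited, the extraction
pipeline is validated against sheets rendered by this module with exact
ground truth: a black plot frame, gray horizontal gridlines every 5 mmHg,
five black vertical examination-time lines, one filled disc per entry (red
for the left eye, blue for the right), a thin same-color polyline joining
each eye's discs in time order, a machine-font name label and jittered
"handwritten" date digits.  Scan degradation (rotation, sensor noise, JPEG
blocking, speckle, color drift) is applied after drawing.

Rendering is a pure function of (ground truth, noise parameters, seed).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .digits import _load_font, render_digit
from .errors import ConfigError, OutOfFrame
from .layout import TIME_LABELS, ChartEntry, ChartLayout, Eye, GroundTruth

RED = (214, 32, 32)     # left-eye pencil
BLUE = (32, 56, 200)    # right-eye pencil
GRID_GRAY = (186, 186, 186)
POLYLINE_WIDTH = 2


@dataclass(frozen=True)
class NoiseParams:
    """Scan-degradation model applied to a rendered sheet.

    rotation_deg     uniform page tilt in [-r, +r] degrees
    gaussian_sigma   additive pixel noise, gray levels (0-255 scale)
    jpeg_quality     lossy re-encode quality; None disables the round-trip
    dropout_prob     probability each drawn entry is omitted from the sheet
    color_jitter_deg uniform hue shift applied to the whole page, degrees
    speckle_density  fraction of pixels replaced by dark specks
    """

    rotation_deg: float = 0.0
    gaussian_sigma: float = 0.0
    jpeg_quality: int | None = None
    dropout_prob: float = 0.0
    color_jitter_deg: float = 0.0
    speckle_density: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigError("dropout_prob must be in [0, 1]")
        if not 0.0 <= self.speckle_density <= 1.0:
            raise ConfigError("speckle_density must be in [0, 1]")
        for name in ("rotation_deg", "gaussian_sigma", "color_jitter_deg"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")


#: Named degradation presets.  "scan" mimics an ordinary office scanner
#: (slight tilt, sensor noise sigma 8 gray levels, JPEG quality 70);
#: "harsh" adds speckle, stronger noise and color drift.
NOISE_PRESETS: dict[str, NoiseParams] = {
    "clean": NoiseParams(),
    "scan": NoiseParams(rotation_deg=2.0, gaussian_sigma=8.0, jpeg_quality=70,
                        color_jitter_deg=3.0),
    "harsh": NoiseParams(rotation_deg=3.0, gaussian_sigma=14.0, jpeg_quality=45,
                         color_jitter_deg=6.0, speckle_density=1.5e-4),
}


def _draw_static(draw: ImageDraw.ImageDraw, layout: ChartLayout) -> None:
    x0, y0, x1, y1 = layout.frame
    v = layout.axis_min_mmhg
    while v <= layout.axis_max_mmhg:
        _, y = layout.value_to_pixel(layout.time_labels[0], v)
        draw.line([(x0, y), (x1, y)], fill=GRID_GRAY, width=1)
        v += layout.grid_step_mmhg
    draw.rectangle([x0, y0, x1, y1], outline=(0, 0, 0), width=3)
    for x in layout.time_line_xs:
        draw.line([(x, y0), (x, y1)], fill=(0, 0, 0), width=3)
    font = _load_font("DejaVuSans.ttf", 26)
    for x, label in zip(layout.time_line_xs, layout.time_labels):
        draw.text((x, y1 + 14), label, font=font, fill=(0, 0, 0), anchor="ma")
    small = _load_font("DejaVuSans.ttf", 20)
    step = max(layout.grid_step_mmhg, 5.0)
    v = layout.axis_min_mmhg
    while v <= layout.axis_max_mmhg:
        _, y = layout.value_to_pixel(layout.time_labels[0], v)
        draw.text((x0 - 12, y), f"{v:g}", font=small, fill=(0, 0, 0), anchor="rm")
        v += step


def _draw_date(img: Image.Image, exam_date: tuple[int, int, int],
               layout: ChartLayout, rng: np.random.Generator) -> None:
    """Place jittered digit glyphs for dd mm yyyy inside the date box."""
    d, m, y = exam_date
    text = f"{d:02d} {m:02d} {y:04d}"
    bx0, by0, bx1, by1 = layout.date_box
    # size the glyphs so eight digits plus two group gaps fit with clear
    # inter-digit whitespace (touching digits would merge on segmentation)
    size = min(by1 - by0 - 10, (bx1 - bx0 - 16) * 4 // 29)
    gap, space = int(size * 0.78), int(size * 0.5)
    x = bx0 + 8
    cy = (by0 + by1) // 2
    for ch in text:
        if ch == " ":
            x += space
            continue
        glyph = render_digit(int(ch), rng, size=size)
        mask = Image.eval(glyph, lambda p: 255 - p)
        ink = Image.new("RGB", glyph.size, (25, 25, 35))
        img.paste(ink, (x, cy - size // 2), mask)
        x += gap


def _entry_positions(truth: GroundTruth) -> dict[tuple[Eye, str], tuple[float, float]]:
    """Pixel centres per entry; coincident left/right marks are nudged apart.

    When both eyes share the same (time, value) cell the clinician's marks
    overlap; the renderer offsets them ±4 px horizontally (value unchanged)
    so both colors stay visible, as on real sheets.
    """
    pos: dict[tuple[Eye, str], tuple[float, float]] = {}
    by_cell: dict[tuple[str, int], list[ChartEntry]] = {}
    for e in truth.entries:
        by_cell.setdefault((e.time_slot, e.iop_mmhg), []).append(e)
    for (slot, value), group in by_cell.items():
        x, y = truth.layout.value_to_pixel(slot, value)
        if len(group) == 1:
            pos[group[0].key()] = (x, y)
        else:
            for e in group:
                dx = -4.0 if e.eye is Eye.LEFT else 4.0
                pos[e.key()] = (x + dx, y)
    return pos


def _apply_noise(img: Image.Image, noise: NoiseParams,
                 rng: np.random.Generator) -> Image.Image:
    if noise.rotation_deg > 0:
        angle = rng.uniform(-noise.rotation_deg, noise.rotation_deg)
        img = img.rotate(angle, resample=Image.BILINEAR, fillcolor=(255, 255, 255))
    if noise.color_jitter_deg > 0:
        shift = rng.uniform(-noise.color_jitter_deg, noise.color_jitter_deg)
        hsv = np.asarray(img.convert("HSV"), dtype=np.int16)
        hsv[..., 0] = (hsv[..., 0] + int(round(shift / 360.0 * 255.0))) % 256
        img = Image.fromarray(hsv.astype(np.uint8), "HSV").convert("RGB")
    arr = np.asarray(img, dtype=float)
    if noise.gaussian_sigma > 0:
        arr = arr + rng.normal(0.0, noise.gaussian_sigma, arr.shape)
    if noise.speckle_density > 0:
        h, w, _ = arr.shape
        n = int(noise.speckle_density * h * w)
        ys = rng.integers(0, h, n)
        xs = rng.integers(0, w, n)
        arr[ys, xs] = rng.uniform(0, 90, (n, 1))
    img = Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8))
    if noise.jpeg_quality is not None:
        buf = _io.BytesIO()
        img.save(buf, format="JPEG", quality=int(noise.jpeg_quality))
        buf.seek(0)
        img = Image.open(buf).convert("RGB")
        img.load()
    return img


def render_chart(truth: GroundTruth, noise: NoiseParams | None = None,
                 seed: int = 0) -> Image.Image:
    """Render one profile sheet; deterministic for fixed (truth, noise, seed)."""
    noise = noise or NoiseParams()
    layout = truth.layout
    for e in truth.entries:
        if not layout.axis_min_mmhg <= e.iop_mmhg <= layout.axis_max_mmhg:
            raise OutOfFrame(f"entry {e.iop_mmhg} mmHg outside axis range")
    rng = np.random.default_rng(seed)
    img = Image.new("RGB", (layout.page_w_px, layout.page_h_px), (255, 255, 255))
    draw = ImageDraw.Draw(img)
    _draw_static(draw, layout)

    positions = _entry_positions(truth)
    keep = [e for e in truth.entries
            if noise.dropout_prob == 0.0 or rng.random() >= noise.dropout_prob]
    for e in truth.entries:   # record intended centroids on the truth object
        e.px = positions[e.key()]
    for eye, color in ((Eye.LEFT, RED), (Eye.RIGHT, BLUE)):
        pts = [positions[e.key()] for e in sorted(
            (e for e in keep if e.eye is eye),
            key=lambda e: TIME_LABELS.index(e.time_slot))]
        if len(pts) >= 2:
            draw.line(pts, fill=color, width=POLYLINE_WIDTH)
        r = layout.marker_radius
        for x, y in pts:
            draw.ellipse([x - r, y - r, x + r, y + r], fill=color)

    font = _load_font("DejaVuSans.ttf", 30)
    nx, ny = layout.name_box[0], (layout.name_box[1] + layout.name_box[3]) // 2
    draw.text((nx, ny), f"Patient: {truth.patient_id}", font=font,
              fill=(0, 0, 0), anchor="lm")
    _draw_date(img, truth.exam_date, layout, rng)
    return _apply_noise(img, noise, rng)


@dataclass(frozen=True)
class ProfileParams:
    """Distribution of plotted IOP values and per-entry missingness.

    Defaults reproduce the cohort the tool was built for: integer readings
    around 14.8 ± 3.5 mmHg, and roughly 8.4 of the 10 possible entries
    actually present per sheet (clinicians occasionally skip a reading).
    """

    mean_mmhg: float = 14.8
    sd_mmhg: float = 3.5
    missing_prob: float = 0.16

    def __post_init__(self) -> None:
        if self.sd_mmhg <= 0 or not 0 <= self.missing_prob <= 1:
            raise ConfigError("sd_mmhg must be > 0 and missing_prob in [0, 1]")


def sample_truth(rng: np.random.Generator, layout: ChartLayout | None = None,
                 params: ProfileParams | None = None,
                 patient_id: str = "P0000") -> GroundTruth:
    """Draw one sheet's ground truth (values, missingness, exam date)."""
    layout = layout or ChartLayout()
    params = params or ProfileParams()
    lo, hi = layout.axis_min_mmhg, layout.axis_max_mmhg
    entries = []
    for eye in (Eye.LEFT, Eye.RIGHT):
        for slot in layout.time_labels:
            if params.missing_prob and rng.random() < params.missing_prob:
                continue
            v = int(np.clip(round(rng.normal(params.mean_mmhg, params.sd_mmhg)), lo, hi))
            entries.append(ChartEntry(eye, slot, v))
    year = int(rng.integers(2017, 2020))
    month = int(rng.integers(1, 13))
    day = int(rng.integers(1, 29))
    return GroundTruth(patient_id=patient_id, exam_date=(day, month, year),
                       entries=entries, layout=layout)


def generate_dataset(n_charts: int, params: ProfileParams | None = None,
                     noise: NoiseParams | None = None, seed: int = 0,
                     layout: ChartLayout | None = None,
                     ) -> list[tuple[Image.Image, GroundTruth]]:
    """Render ``n_charts`` sheets with ground truth; reproducible under seed."""
    if n_charts < 1:
        raise ConfigError("n_charts must be >= 1")
    params = params or ProfileParams()
    noise = noise or NoiseParams()
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_charts):
        truth_seed, render_seed = (int(s) for s in master.integers(0, 2**31, 2))
        truth = sample_truth(np.random.default_rng(truth_seed), layout, params,
                             patient_id=f"P{i:04d}")
        out.append((render_chart(truth, noise, seed=render_seed), truth))
    return out
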