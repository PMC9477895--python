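"""Handwriting-proxy digit rendering and the date-digit classifier.

Exam dates on the historical sheets are handwritten.  Real handwriting
samples are not shipped with the package, so the renderer draws each digit
from one of several vector fonts and applies a random affine jitter
(rotation, shear, scale, translation) — a deterministic, self-contained
proxy that keeps the classifier trainable from code alone.  The classifier
is a small multinomial logistic model over 16×16 normalized patches; its
provenance tag records that it was fit on these synthetic glyphs, not on
any external handwriting corpus.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from skimage.transform import resize

PATCH = 16  # classifier input is PATCH x PATCH, float in [0, 1]


def _font_dir() -> str:
    import matplotlib

    return os.path.join(matplotlib.get_data_path(), "fonts", "ttf")


_FONT_FILES = (
    "DejaVuSans.ttf",
    "DejaVuSans-Bold.ttf",
    "DejaVuSans-Oblique.ttf",
    "DejaVuSerif.ttf",
    "DejaVuSerif-Italic.ttf",
    "DejaVuSansMono.ttf",
    "DejaVuSansMono-Bold.ttf",
)

_font_cache: dict[tuple[str, int], ImageFont.FreeTypeFont] = {}


def _load_font(name: str, size: int) -> ImageFont.FreeTypeFont:
    key = (name, size)
    if key not in _font_cache:
        _font_cache[key] = ImageFont.truetype(os.path.join(_font_dir(), name), size)
    return _font_cache[key]


def render_digit(digit: int, rng: np.random.Generator, size: int = 48) -> Image.Image:
    """Render one jittered digit glyph on a white square canvas ("L" mode)."""
    if not 0 <= digit <= 9:
        raise ValueError("digit must be in 0..9")
    fname = _FONT_FILES[rng.integers(len(_FONT_FILES))]
    # drawn on a 2x supersampled canvas, so the glyph fills ~55-70% of the
    # final tile with solid strokes after downsampling
    font = _load_font(fname, int(size * rng.uniform(1.3, 1.6)))
    canvas = Image.new("L", (size * 2, size * 2), 255)
    draw = ImageDraw.Draw(canvas)
    draw.text((size, size), str(digit), font=font, fill=0, anchor="mm")
    # affine jitter: rotate, shear, scale about the canvas centre
    theta = np.deg2rad(rng.uniform(-9.0, 9.0))
    shear = rng.uniform(-0.12, 0.12)
    sx = rng.uniform(0.88, 1.12)
    sy = rng.uniform(0.88, 1.12)
    c, s = np.cos(theta), np.sin(theta)
    m = np.array([[c / sx, (-s + shear) / sx], [s / sy, c / sy]])
    cx = size + rng.uniform(-2, 2)
    a, b = m[0]
    d, e = m[1]
    canvas = canvas.transform(
        canvas.size, Image.AFFINE,
        (a, b, cx - a * size - b * size, d, e, cx - d * size - e * size),
        resample=Image.BILINEAR, fillcolor=255)
    return canvas.resize((size, size), Image.LANCZOS)


def patch_from_glyph(img: np.ndarray) -> np.ndarray:
    """Normalize a grayscale glyph crop to a PATCH×PATCH ink-intensity patch.

    The ink bounding box is cropped, padded to a square (so aspect ratio is
    preserved) and resampled; output values are ink fractions in [0, 1].
    """
    ink = 1.0 - np.asarray(img, dtype=float) / 255.0
    rows = np.flatnonzero(ink.max(axis=1) > 0.2)
    cols = np.flatnonzero(ink.max(axis=0) > 0.2)
    if rows.size == 0 or cols.size == 0:
        return np.zeros((PATCH, PATCH))
    ink = ink[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    h, w = ink.shape
    side = max(h, w)
    sq = np.zeros((side, side))
    r0, c0 = (side - h) // 2, (side - w) // 2
    sq[r0:r0 + h, c0:c0 + w] = ink
    return resize(sq, (PATCH, PATCH), anti_aliasing=True)


@dataclass
class DigitClassifier:
    """Ten-class digit recognizer for the date field.

    Wraps an opaque fitted model; prediction is deterministic for fixed
    weights.  ``provenance`` records the training source.
    """

    model: object
    classes: tuple[int, ...] = tuple(range(10))
    provenance: str = "synthetic-font-digits"

    def predict(self, patches: np.ndarray) -> np.ndarray:
        """Class labels for an (n, PATCH, PATCH) or (n, PATCH²) array."""
        x = np.asarray(patches, dtype=float).reshape(len(patches), -1)
        return self.model.predict(x).astype(int)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=float).reshape(len(patches), -1)
        return self.model.predict_proba(x)


def train_digit_classifier(n_per_class: int = 400, seed: int = 0) -> DigitClassifier:
    """Fit the date-digit classifier on freshly rendered jittered glyphs.

    A single-hidden-layer network over the normalized patches separates the
    ten jittered font classes essentially perfectly while training in a few
    seconds, so nothing heavier is warranted for this field.
    """
    from sklearn.neural_network import MLPClassifier

    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for digit in range(10):
        for _ in range(n_per_class):
            xs.append(patch_from_glyph(render_digit(digit, rng)).ravel())
            ys.append(digit)
    model = MLPClassifier(hidden_layer_sizes=(128,), max_iter=300,
                          random_state=seed)
    model.fit(np.asarray(xs), np.asarray(ys))
    return DigitClassifier(model=model)


_default_classifier: DigitClassifier | None = None


def default_classifier() -> DigitClassifier:
    """Process-wide lazily trained classifier (trained once, then cached)."""
    global _default_classifier
    if _default_classifier is None:
        _default_classifier = train_digit_classifier()
    return _default_classifier
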