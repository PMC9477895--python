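# Methods

## The digitization model

A 24-h IOP profile sheet is modelled as a fixed-geometry form: a
rectangular plot frame on an A4 page, five vertical examination-time
lines (10:00, 14:00, 17:00, 21:00, 24:00 — the midnight reading is the
rightmost line, historically taken supine with a handheld tonometer),
horizontal gridlines every 5 mmHg, and per-entry marks drawn as filled
discs joined by a thin polyline, red for the left eye and blue for the
right.  The default template is A4 at 150 dpi (1240×1754 px) with an
axis of 0–50 mmHg; the historical forms' true axis limits are not
documented anywhere we know of, so the template is a reconstruction and
every geometric assumption is exposed through `ChartLayout`.

The pipeline stages and their numerical choices:

1. **Deskew.**  Page tilt is estimated from near-vertical Hough lines
   (Canny edges on a 2× downsampled grayscale, normal angles within ±4°
   sampled at 0.05° resolution, median of the peak angles).  Tilts below
   0.05° are left alone.  Residual tilt after deskew is ≲0.05°, i.e.
   sub-pixel displacement over the frame height.
2. **Frame.**  The largest connected dark component (gray < 110) must
   cover ≥ 20% of the page in bounding-box area, else `NoFrameFound`.
   Its bounding box is the frame; the crop is axis-aligned.  The frame
   stroke is ~3 px, so box edges sit within ~1 px of the drawn
   rectangle — at 25.6 px/mmHg this is ≪ the 0.5 mmHg rounding margin.
3. **Time lines.**  Canny + Hough on the 2× downsampled crop restricted
   to |angle from vertical| ≤ 3°; candidates must actually span ≥ 60% of
   the frame height in dark pixels (this rejects stray Hough peaks),
   edge margins of 3% of the frame width exclude the frame verticals,
   and candidates are clustered along x with a 3%-width gap.  Exactly
   five clusters are required (`TimeAxisAmbiguous` otherwise); each
   cluster is then refined to the ink-weighted column centroid, which
   recovers the drawn line centre to ~0.1 px.
4. **Entries.**  HSV masks — red: hue ∈ [0°,12°] ∪ [348°,360°], blue:
   hue ∈ [200°,260°], both with saturation ≥ 0.35 and value ≥ 0.25.  The
   historical sheets' pencil colors are not spectrally characterized, so
   these windows are wide and configurable.  One 3×3 binary opening
   removes the connecting polyline (markers are discs of radius
   ≈ dpi/30 ≥ 3× the 2 px stroke, so they survive).  Components with
   25–650 px of area are accepted, assigned to the nearest time line if
   within half the minimum inter-line gap, and their centroid row is
   mapped through the linear axis calibration and rounded to integer
   mmHg (tonometry granularity).  If two same-color components land on
   one slot the larger wins and the conflict is logged.
5. **Date.**  The date box is mapped from template to page coordinates
   via the detected frame, ink components ≥ 40 px are ordered left to
   right, and exactly eight digits (dd mm yyyy) are expected, else
   `DateUnparsed`.  Each patch is bbox-cropped, square-padded, resampled
   to 16×16 and classified.

**Scoring** follows the manual-verification convention: predictions and
truth are matched on (eye, time slot); a matched value differing by more
than the tolerance (default 0 mmHg — whether the historical check allowed
±1 is unstated, so exact match is the default) is a *false entry*, as is
a prediction with no true entry at that slot; a true entry with no
prediction is a *missed entry*.

## The digit classifier

Real handwriting is not shipped.  Digits are rendered from seven DejaVu
font faces with random affine jitter (rotation ±9°, shear ±0.12, scale
0.88–1.12, sub-pixel translation) on a 2× supersampled canvas, and a
single-hidden-layer MLP (128 units) is trained on 400 fresh glyphs per
class.  Held-out accuracy on the same glyph distribution is ≥ 99%; the
classifier's `provenance` field records the synthetic origin.  This is a
proxy: performance on genuine handwriting is untested and would require
fine-tuning on labelled crops.  Machine-printed patient names are left to
a pluggable external OCR engine and are excluded from accuracy
accounting.

## The synthetic-sheet generator

`generate_dataset` draws integer readings from a truncated normal
(default 14.8 ± 3.5 mmHg, clipped to the axis) with per-entry missingness
0.16, giving ≈ 8.4 of the 10 possible entries per sheet — the entry rate
observed in the clinical archive this tool was built around.  Scan
degradation presets: *clean* (nothing), *scan* (tilt uniform ±2°,
Gaussian sensor noise σ = 8 gray levels, JPEG quality 70, hue jitter ±3°),
*harsh* (±3°, σ = 14, quality 45, hue ±6°, speckle 1.5·10⁻⁴).  When both
eyes share one (time, value) cell the marks are nudged ±4 px apart
horizontally, as overlapping pencil marks would be.  Rendering is a pure
function of (truth, noise, seed).

What the generator does *not* emulate: pencil texture and pressure
variation, smudges and erasures, paper folds, ruled-form misprints,
non-disc marker styles (crosses, ticks), and real handwriting.  Passing
the synthetic benchmarks therefore demonstrates the pipeline's geometric
and chromatic correctness under scan-type degradation, not performance on
an arbitrary historical archive.

## IOP summaries and perfusion pressure

T_avg/T_max/T_min are computed over the present time points only
(complete-case within profile; at least two points required); IOP_var =
T_max − T_min.  The outpatient subset keeps 10:00/14:00/17:00.  MOPP =
⅔·(MAP − IOP) with MAP = DBP + (SBP − DBP)/3 from admission blood
pressure.  Which IOP enters MOPP is genuinely ambiguous in routine
practice; the package defaults to the eye's T_avg and exposes
`compute_mopp` for per-time-point use.

## Cohort statistics

- **Progression** uses a transparent normative-slope rule (sector
  progresses iff RNFL slope < −0.5 µm/yr, configurable, AND its p-value
  if supplied is < α), replacing the proprietary device algorithm; all
  reports state the rule.  Worst quadrant is the most negative slope
  among TS/TI/T (the global sector is a composite and excluded), ties
  broken in the fixed order TS, TI, T.
- **Cut-offs / ROC**: sensitivity = P(T_max ≥ c | progressor),
  specificity = P(T_max < c | non-progressor); the ROC sweeps unique
  score values and its trapezoid AUC equals the Mann–Whitney probability
  with ties counted ½ (verified against pair enumeration).
- **Spearman** is the Pearson correlation of mid-ranks; p is the exact
  permutation probability for n ≤ 8 and the t approximation otherwise.
- **Paired-eye phi** is the 2×2 correlation with chi² = n·phi².  The
  inter-ocular dependency adjustment used historically is unnamed, so it
  is exposed as a variance-inflation divisor on chi² (default 1 =
  unadjusted).
- **Logistic regression** is a maximum-likelihood binomial fit
  (statsmodels) reporting exp(slope) as the odds ratio per covariate
  unit with the Wald p; complete separation is detected up front and
  flagged with an infinite OR.
- **Wilcoxon signed-rank** drops zero differences, uses exact sign
  enumeration for n ≤ 12 and the continuity-corrected, tie-corrected
  normal approximation otherwise.
- No multiplicity correction is applied (reports carry the test count).

## The cohort simulator

Continuous right/left pairs come from a bivariate Gaussian copula; the
requested Spearman correlation is converted to the latent Pearson value
with ρ_p = 2·sin(πρ_s/6), and margins are scaled to the requested
mean/SD.  Primary sampled variables per eye are T_max, IOP_var, MOPP and
a latent mean-position fraction; T_min = T_max − IOP_var (floored at 0)
and the five-point profile is back-filled so that the profile max/min
equal T_max/T_min exactly and the profile mean sits within 0.2 mmHg of
its target (three middle readings chosen as integers summing to the
required total).  All IOPs are integers.  Consequences worth knowing:

- T_avg and T_min are **emergent**, not copula-targeted: because T_avg is
  functionally tied to T_max and IOP_var, its inter-eye Spearman comes
  out near 0.75 rather than the 0.51 used for the latent fraction.  The
  targeted (and tested) recoveries are T_max, IOP_var, MOPP, the sector
  slopes, phi and the logistic OR.
- MOPP is simulated directly on its own copula rather than recomputed
  from blood pressure, so its inter-eye correlation is controlled
  exactly; the sbp/dbp columns are provenance only.
- Paired progression flags are drawn from the 2×2 implied by
  (prevalence p, phi): p11 = p² + φ·p(1−p), with infeasible combinations
  rejected by the closed-form Fréchet bounds
  φ ≥ (max(0, 2p−1) − p²)/(p(1−p)).  The logistic IOP_var effect tilts
  the *temporal-sector* flag per eye (β₀ calibrated so the marginal rate
  is 0.232 at the mean IOP_var), leaving the paired-flag dependence
  untouched; sector flags are otherwise independent tilts, a documented
  simplification of the unknown joint sector distribution.

## Problem sizes and determinism

The shipped benchmarks use 100 scanner-degraded and 200 clean sheets for
the extraction envelopes, 5000 patients for correlation/phi recovery and
10000 for the logistic odds ratio — sizes at which the Monte-Carlo error
of each estimate is several times smaller than its acceptance band.
Everything is driven by explicit integer seeds: rendering, degradation,
dataset sampling, classifier training and cohort simulation are pure
functions of their parameters and seed, and the CLI records seeds in all
provenance headers.

## Known limitations

Single-day, five-point protocols only; disc-style markers are assumed
(the historical marker style is unrecorded); no GUI error correction
(corrections enter via edited CSV); digit reading is font-proxy trained;
the normative-slope rule is a transparent stand-in, not the device
algorithm, and cohort-level conclusions from simulated data inherit the
simulator's assumptions listed above.
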