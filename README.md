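# iopchart

Digitize manually drawn 24-hour intraocular-pressure (IOP) chart sheets
and analyze the resulting paired-eye cohorts.

Many European clinics admitted glaucoma patients for nycthemeral (24-h)
IOP monitoring: applanation tonometry at 10 AM, 2 PM, 5 PM, 9 PM and
midnight, recorded by hand on A4 sheets with a printed plot frame — left
eye in red pencil, right eye in blue.  Decades of such archives exist only
on paper.  `iopchart` is for researchers who want to turn scans of those
sheets into structured per-eye measurements and run the standard clinical
analytics on top: diurnal summaries, perfusion pressure, progression
cut-off/ROC evaluation, and inter-eye correlation.

## What it does

**Digitization.**  The page is deskewed, the plot frame is located as the
largest dark contour, the five vertical examination-time lines are found
with Canny edge detection plus a Hough line transform restricted to
near-vertical angles, and color-specific HSV masks isolate the red and
blue marks.  Because the form geometry is fixed, a mark's pixel row maps
linearly to mmHg:

    value(y) = axis_min + (y_bottom − y) / (y_bottom − y_top) · (axis_max − axis_min)

A 3×3 morphological opening separates the filled entry discs from the
thin connecting polyline.  Handwritten exam dates are read by segmenting
the date box into digit patches and classifying each with a small neural
network trained on synthetically jittered font glyphs.  Accuracy is scored
the way a manual verifier would: a *false entry* has a wrong value, a
*missed entry* was not detected at all.

**Synthetic sheets.**  No chart archive is publicly deposited, so the
package ships a renderer that draws the same sheets with exact ground
truth and configurable scan degradation (tilt, sensor noise, JPEG
blocking, speckle, hue drift).  Every pipeline claim is tested against it.

**Clinical metrics.**  Per eye: T_avg, T_max, T_min, IOP_var = T_max −
T_min, the outpatient-hours (10 AM/2 PM/5 PM) subsets, and mean ocular
perfusion pressure MOPP = ⅔·(MAP − IOP) with MAP = DBP + (SBP − DBP)/3.

**Cohort statistics.**  Normative-slope RNFL progression classification,
cut-off sensitivity/specificity and ROC/AUC for peak-IOP criteria,
Spearman rank correlation (exact permutation p for n ≤ 8), paired-eye phi
with chi-square, binomial logistic odds ratios, OLS, and the paired
Wilcoxon signed-rank test (exact sign enumeration for n ≤ 12) — plus a
paired-eye cohort simulator (Gaussian copula with the Spearman→Pearson
sine transform) so every statistic has a parameter-recovery test.

## Worked example

`examples/render_and_extract.py` renders one two-eye sheet with
scanner-like degradation and digitizes it back:

```
deskewed page tilt estimate: +1.25 deg
exam date read from handwriting: (7, 3, 2018)
   left eye  10:00  16 mmHg
   left eye  14:00  14 mmHg
   ...
  right eye  24:00  16 mmHg
detected 10, correct 10, false 0, missed 0
```

Each line is an (eye, clock time, mmHg) record inferred purely from
pixels; the final line scores the run against the sheet's ground truth —
here all ten entries were recovered with their exact integer values
despite the 1.25° tilt, noise and JPEG recompression.

`examples/cohort_analysis.py` closes the simulation loop on 2000
patients:

```
paired progression phi 0.322 (p 6.32e-47), 2x2 table [[706, 334], [343, 617]]
  T_max >= 15 mmHg [   24H]  sens 73.8%  spec 25.9%
  T_max >= 22 mmHg [   24H]  sens 17.0%  spec 84.0%
```

i.e. the analysis battery re-estimates the generating inter-eye
dependence, and the historical 15/22 mmHg peak-IOP cut-offs show the
familiar unsatisfactory sensitivity–specificity trade-off.

There is also a thin CLI over the same library:

```sh
iopchart synth --n 20 --seed 1 --noise-preset scan --out charts/
iopchart extract --in charts/ --out entries.csv --eval-truth charts/
iopchart metrics --in entries.csv --out summaries.csv
iopchart simulate-cohort --n 5000 --seed 7 --out cohort.csv
iopchart analyze --cohort cohort.csv --cutoffs 15,22 --out analysis/
```

## Layout

```
src/iopchart/
  layout.py    form geometry, pixel <-> mmHg calibration
  generate.py  synthetic sheet renderer + dataset factory
  digits.py    jittered-glyph rendering and the date-digit classifier
  extract.py   deskew, frame, time lines, color masks, scoring
  bench.py     render -> digitize -> score accuracy benchmark
  metrics.py   T_avg/T_max/T_min/IOP_var, outpatient subset, MOPP
  stats.py     progression rule, cutoffs, ROC, Spearman, phi, OR, Wilcoxon
  simulate.py  paired-eye cohort simulator (Gaussian copula)
  report.py    full analysis battery on a cohort table
  cli.py       click command line (synth/extract/metrics/simulate/analyze)
examples/      one narrative script per capability
docs/methods.md  model, parameter and design notes
```
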