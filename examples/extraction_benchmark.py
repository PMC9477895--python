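"""Measure digitization accuracy on a batch of degraded synthetic sheets.

Renders 20 sheets under the "scan" preset (tilt up to 2°, Gaussian sensor
noise sigma 8 gray levels, JPEG quality 70), digitizes each and scores it
against its own ground truth.  The figures of merit are false entries
(wrong value) and missed entries (not detected) per curve — one curve is
one eye on one sheet.
"""

from iopchart.bench import extraction_benchmark
from iopchart.generate import NOISE_PRESETS

totals = extraction_benchmark(20, NOISE_PRESETS["scan"], seed=42)
print(f"charts: {totals['n_charts']}  curves: {totals['curves']}")
print(f"detected {totals['detected']}  correct {totals['correct']}")
print(f"false entries per curve : {totals['false_per_curve']:.3f}")
print(f"missed entries per curve: {totals['missed_per_curve']:.3f}")
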