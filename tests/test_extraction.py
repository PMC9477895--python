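"""Digitization pipeline: frame, time lines, entries, dates, scoring."""

import numpy as np
import pytest
from PIL import Image, ImageDraw

from iopchart import (ChartEntry, ChartLayout, Eye, GroundTruth, NoiseParams,
                      evaluate_extraction, read_chart, read_date, render_chart)
from iopchart.digits import patch_from_glyph, render_digit
from iopchart.errors import DateUnparsed, NoFrameFound, TimeAxisAmbiguous
from iopchart.extract import color_masks, detect_frame, detect_time_lines
from iopchart.generate import NOISE_PRESETS


class TestFrameDetection:
    def test_clean_frame_corners_within_2px(self, clean_chart, layout):
        fr = detect_frame(clean_chart)
        x0, y0, x1, y1 = layout.frame
        expected = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float)
        assert np.abs(fr.corners - expected).max() <= 2.0

    def test_rotated_page_recovered_exactly(self, example_truth):
        """A 2° tilted sheet still yields a perfect digitization after
        deskew — the full round trip recovers every entry."""
        img = render_chart(example_truth, NoiseParams(), seed=4)
        img = img.rotate(2.0, resample=Image.BILINEAR, fillcolor=(255, 255, 255))
        rep = evaluate_extraction(read_chart(img).entries, example_truth)
        assert rep.false_entries == 0 and rep.missed_entries == 0
        assert rep.correct == len(example_truth.entries)

    def test_blank_page_raises(self):
        with pytest.raises(NoFrameFound):
            detect_frame(Image.new("RGB", (600, 800), (255, 255, 255)))


class TestTimeLines:
    def test_positions_within_2px_of_truth(self, clean_chart, layout):
        fr = detect_frame(clean_chart)
        xs = detect_time_lines(fr.crop)
        expected = np.asarray(layout.time_line_xs, float) - layout.frame[0]
        assert len(xs) == 5
        assert np.abs(np.sort(xs) - expected).max() <= 2.0

    def test_erased_line_reports_found_four(self, clean_chart, layout):
        img = clean_chart.copy()
        draw = ImageDraw.Draw(img)
        x = layout.time_line_xs[2]
        draw.rectangle([x - 4, layout.frame[1] + 3, x + 4, layout.frame[3] - 3],
                       fill=(255, 255, 255))
        fr = detect_frame(img)
        with pytest.raises(TimeAxisAmbiguous) as exc:
            detect_time_lines(fr.crop)
        assert exc.value.found == 4

    def test_harsh_preset_mostly_survives(self, example_truth, layout):
        """Under the harsh preset (speckle, strong noise, deep JPEG) the
        five lines are still localized within 3 px in ≥95% of renders."""
        ok = 0
        n_runs = 50
        expected = np.asarray(layout.time_line_xs, float) - layout.frame[0]
        for seed in range(n_runs):
            img = render_chart(example_truth, NOISE_PRESETS["harsh"], seed=seed)
            try:
                fr = detect_frame(img)
                xs = detect_time_lines(fr.crop)
            except (NoFrameFound, TimeAxisAmbiguous):
                continue
            if np.abs(np.sort(xs) - expected).max() <= 3.0:
                ok += 1
        assert ok >= 0.95 * n_runs


class TestEntryExtraction:
    def test_clean_roundtrip_every_entry(self, clean_chart, example_truth):
        rep = evaluate_extraction(read_chart(clean_chart).entries, example_truth)
        assert rep.false_entries == 0 and rep.missed_entries == 0
        assert rep.correct == rep.detected == 10

    def test_empty_chart_yields_empty_list(self, layout):
        truth = GroundTruth("E", (1, 1, 2018), [], layout)
        img = render_chart(truth, NoiseParams(), seed=0)
        assert read_chart(img).entries == []

    def test_overlapping_red_and_blue_marks_both_recovered(self, layout):
        """Left and right plotted at the same (time, value) must both come
        back, one per eye — the color masks are disjoint."""
        entries = [ChartEntry(Eye.LEFT, "14:00", 18),
                   ChartEntry(Eye.RIGHT, "14:00", 18)]
        truth = GroundTruth("O", (2, 2, 2018), entries, layout)
        img = render_chart(truth, NoiseParams(), seed=0)
        rep = evaluate_extraction(read_chart(img).entries, truth)
        assert rep.correct == 2 and rep.missed_entries == 0

    def test_masks_disjoint_under_scan_noise(self, example_truth):
        img = render_chart(example_truth, NOISE_PRESETS["scan"], seed=17)
        red, blue = color_masks(np.asarray(detect_frame(img).crop))
        assert not np.any(red & blue)


class TestEvaluation:
    def test_wrong_value_is_false_entry(self, example_truth, layout):
        truth = GroundTruth("T", (1, 1, 2018),
                            [ChartEntry(Eye.LEFT, "10:00", 16)], layout)
        pred = [ChartEntry(Eye.LEFT, "10:00", 17)]
        rep = evaluate_extraction(pred, truth, tolerance_mmhg=0)
        assert rep.false_entries == 1 and rep.missed_entries == 0
        # a ±1 tolerance instead counts it correct
        rep1 = evaluate_extraction(pred, truth, tolerance_mmhg=1)
        assert rep1.false_entries == 0 and rep1.correct == 1

    def test_undetected_entry_is_missed(self, layout):
        truth = GroundTruth("T", (1, 1, 2018),
                            [ChartEntry(Eye.LEFT, "10:00", 16)], layout)
        rep = evaluate_extraction([], truth)
        assert rep.false_entries == 0 and rep.missed_entries == 1

    def test_spurious_prediction_is_false(self, layout):
        truth = GroundTruth("T", (1, 1, 2018), [], layout)
        rep = evaluate_extraction([ChartEntry(Eye.RIGHT, "17:00", 20)], truth)
        assert rep.false_entries == 1 and rep.missed_entries == 0

    def test_identical_sets_all_correct(self, example_truth):
        rep = evaluate_extraction(list(example_truth.entries), example_truth)
        assert rep.false_entries == rep.missed_entries == 0
        assert rep.correct == rep.detected


class TestDateReading:
    def test_clean_date_recovered(self, clean_chart, example_truth,
                                  digit_classifier):
        date, conf = read_date(clean_chart, digit_classifier)
        assert date == example_truth.exam_date
        assert conf.shape == (8,)

    def test_empty_date_box_unparsed(self, layout, digit_classifier):
        truth = GroundTruth("E", (1, 1, 2018), [], layout)
        img = render_chart(truth, NoiseParams(), seed=0)
        blank = img.copy()
        ImageDraw.Draw(blank).rectangle(layout.date_box, fill=(255, 255, 255))
        with pytest.raises(DateUnparsed):
            read_date(blank, digit_classifier)

    def test_per_digit_accuracy_on_held_out_glyphs(self, digit_classifier,
                                                   rng):
        """≥98% per-digit accuracy on 200 fresh jittered renders per run."""
        correct = total = 0
        for _ in range(200):
            d = int(rng.integers(0, 10))
            patch = patch_from_glyph(np.asarray(render_digit(d, rng)))
            correct += int(digit_classifier.predict([patch])[0] == d)
            total += 1
        assert correct / total >= 0.98
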