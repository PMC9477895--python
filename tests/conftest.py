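import numpy as np
import pytest

from iopchart import (ChartEntry, ChartLayout, Eye, GroundTruth, NoiseParams,
                      render_chart, train_digit_classifier)


@pytest.fixture(scope="session")
def layout():
    return ChartLayout()


@pytest.fixture(scope="session")
def example_truth(layout):
    """Two full five-point curves at known values."""
    left = [16, 14, 15, 12, 13]
    right = [18, 17, 19, 15, 16]
    entries = [ChartEntry(Eye.LEFT, t, v) for t, v in zip(layout.time_labels, left)]
    entries += [ChartEntry(Eye.RIGHT, t, v) for t, v in zip(layout.time_labels, right)]
    return GroundTruth("P0001", (7, 3, 2018), entries, layout)


@pytest.fixture(scope="session")
def clean_chart(example_truth):
    return render_chart(example_truth, NoiseParams(), seed=1)


@pytest.fixture(scope="session")
def digit_classifier():
    return train_digit_classifier()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
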