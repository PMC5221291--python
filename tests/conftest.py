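"""Shared fixtures: the calibrated baseline and the full experiment grid.

Calibration and the nine 20 s grid runs are expensive, so they are computed
once per session and shared by the metric, experiment and acceptance tests.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from cvloop import baseline_config, calibrate_baseline, run_grid

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline():
    """The shipped failing-heart fixture (pre-calibration)."""
    return baseline_config()


@pytest.fixture(scope="session")
def calibration(baseline):
    """Calibration result anchoring the baseline to SV 20 mL / EDV 100 mL."""
    return calibrate_baseline(baseline)


@pytest.fixture(scope="session")
def calibrated(calibration):
    """The calibrated model configuration."""
    return calibration.config


@pytest.fixture(scope="session")
def grid(calibrated):
    """The full 3 conditions x 3 groups grid on the calibrated model."""
    return run_grid(calibrated)
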