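"""Shared fixtures: synthetic curves and processed depot maps.

Heavy artifacts (raster scans, assembled maps) are session-scoped so
the cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from mesomap.indexing import detect_peaks, subtract_baseline
from mesomap.mapping import assemble_map, radial_profile
from mesomap.synthetic import (generate_curve, generate_raster,
                               scenario_four_week, scenario_one_day)


def process(curve):
    """Baseline-subtract and detect peaks; returns (subtracted, peaks)."""
    sub = subtract_baseline(curve)
    return sub, detect_peaks(sub)


@pytest.fixture(scope="session")
def fd3m_curve():
    """Noiseless single-phase Fd3m pattern at a = 172 A."""
    return generate_curve([("Fd3m", 172.0, 1.0)])


@pytest.fixture(scope="session")
def one_day_map():
    """Assembled phase map of the 1-day scenario (coarse 0.2 mm pitch)."""
    scan = generate_raster(scenario_one_day(), pixel_pitch=0.2)
    return assemble_map(scan)


@pytest.fixture(scope="session")
def four_week_map():
    scan = generate_raster(scenario_four_week(), pixel_pitch=0.2)
    return assemble_map(scan)


@pytest.fixture(scope="session")
def one_day_profile(one_day_map):
    return radial_profile(one_day_map)


@pytest.fixture(scope="session")
def four_week_profile(four_week_map):
    return radial_profile(four_week_map)
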