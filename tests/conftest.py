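"""Shared fixtures for the test suite.

The heavier synthetic fixtures are session-scoped so that simulation and
AR-IRLS costs are paid once.  All randomness is seeded; seeds are fixed
constants chosen up front, not tuned.
"""

from __future__ import annotations

import numpy as np
import pytest

from nirsac import (
    HRFSpec,
    SAParams,
    inject_canonical_hrf,
    intensity_to_od,
    make_probe_layout,
    make_trial_schedule,
    od_to_hemoglobin,
    simulate_rest_recording,
)
from nirsac.constants import FS
from nirsac.preprocess import HemoSeries, bandpass
from nirsac.synth import SAComponent


ZERO_SA = SAParams(
    components=(SAComponent(0.10, 0.0, 0.03),),
    noise_sd=0.0,
    gain_heterogeneity=0.0,
)


@pytest.fixture(scope="session")
def layout():
    return make_probe_layout()


@pytest.fixture(scope="session")
def sim_schedule():
    """Five-trial SIM blocked design (fixed seed)."""
    return make_trial_schedule("SIM", 5, seed=7)


@pytest.fixture(scope="session")
def zero_noise_hemo(layout, sim_schedule):
    """Noise-free, SA-free recording with HRFs injected into channels 6/8.

    The downstream signal should be exactly the injected templates.
    """
    raw = simulate_rest_recording(
        layout, sim_schedule.end_time + 15, ZERO_SA, age=65.0, seed=0
    )
    od = intensity_to_od(raw)
    hemo = od_to_hemoglobin(od, 65.0)
    return inject_canonical_hrf(hemo, sim_schedule, HRFSpec({6: 10.0, 8: 5.0}))


@pytest.fixture(scope="session")
def sa_hemo(layout, sim_schedule):
    """Band-passed semisimulated recording with default (strong shared) SA."""
    raw = simulate_rest_recording(
        layout, sim_schedule.end_time + 15, SAParams(), age=65.0, seed=11
    )
    od = intensity_to_od(raw)
    hemo = od_to_hemoglobin(od, 65.0)
    hemo = inject_canonical_hrf(hemo, sim_schedule, HRFSpec({6: 10.0, 8: 5.0}))
    return bandpass(hemo)


def make_hemo(layout, hbo: np.ndarray, hbr: np.ndarray, fs: float = FS) -> HemoSeries:
    """Wrap plain arrays (24 x T) as a HemoSeries with nothing pruned."""
    return HemoSeries(
        hbo.astype(float), hbr.astype(float), fs, layout, np.zeros(layout.n_total, bool)
    )
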