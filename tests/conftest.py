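from datetime import datetime, timedelta

import numpy as np
import pytest

from sagru.cgm_data import Cohort, GlucoseReading, PatientSeries


def make_series(values, patient_id="P1", start="2023-04-01T00:00", cadence_minutes=15,
                gaps_after=()):
    """Build a PatientSeries from glucose values at a regular cadence.

    ``gaps_after`` lists indices after which an extra cadence interval is
    inserted (simulating a dropped reading).
    """
    t = datetime.fromisoformat(start)
    readings = []
    for i, v in enumerate(values):
        readings.append(GlucoseReading(t, float(v)))
        t += timedelta(minutes=cadence_minutes)
        if i in gaps_after:
            t += timedelta(minutes=cadence_minutes)
    return PatientSeries(patient_id, readings, cadence_minutes=cadence_minutes)


@pytest.fixture
def rng():
    return np.random.default_rng(20230401)


@pytest.fixture
def flat_cohort():
    """Three patients with constant glucose — trivially learnable."""
    return Cohort([
        make_series([120.0] * 40, patient_id=f"P{i}") for i in range(3)
    ])
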