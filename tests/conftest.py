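import pytest

from dxalo.core import (
    PatientScan,
    Region,
    RegionMeasurement,
    Side,
    TissueMasses,
)

#: Baseline per-region tissue masses (adipose, muscle, bone) in grams for
#: a hand-checkable phantom patient.
BASE = {
    Region.HEMIHEAD: (700.0, 1600.0, 200.0),
    Region.ARM: (500.0, 1200.0, 100.0),
    Region.FOREARM: (250.0, 700.0, 50.0),
    Region.HAND: (100.0, 280.0, 20.0),
    Region.HEMIPELVIS: (1200.0, 2600.0, 200.0),
    Region.THIGH: (2000.0, 4700.0, 300.0),
    Region.LEG: (700.0, 1700.0, 100.0),
    Region.FOOT: (200.0, 560.0, 40.0),
}


def build_scan(
    patient_id="P1",
    scale=None,
    clinical=frozenset(),
    drop=frozenset(),
    **kwargs,
):
    """Build a bilateral scan from the phantom baseline.

    ``scale`` maps (region, side) -> multiplier applied to all three
    tissue masses of that record; ``drop`` removes (region, side)
    records entirely.
    """
    scale = scale or {}
    measurements = []
    for region, (a, m, b) in BASE.items():
        for side in Side:
            if (region, side) in drop:
                continue
            k = scale.get((region, side), 1.0)
            measurements.append(
                RegionMeasurement(region, side, TissueMasses(a * k, m * k, b * k))
            )
    return PatientScan(
        patient_id=patient_id,
        measurements=measurements,
        clinical_affected=set(clinical),
        **kwargs,
    )


@pytest.fixture
def symmetric_scan():
    return build_scan()


@pytest.fixture
def left_thigh_overgrown_scan():
    """Left thigh 20% heavier, labeled clinically affected."""
    return build_scan(
        scale={(Region.THIGH, Side.LEFT): 1.2},
        clinical={(Region.THIGH, Side.LEFT)},
    )
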