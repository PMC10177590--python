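import numpy as np
import pytest

from transwell import (
    AssayDesign,
    Direction,
    DrugSpec,
    ReceiverPoint,
    TranswellGeometry,
    WellTimeSeries,
)


@pytest.fixture
def geometry() -> TranswellGeometry:
    return TranswellGeometry()


@pytest.fixture
def metoprolol() -> DrugSpec:
    return DrugSpec("metoprolol", 267.36)


@pytest.fixture
def design(metoprolol, geometry) -> AssayDesign:
    return AssayDesign(drug=metoprolol, donor_concentration_mg_ml=0.4,
                       direction=Direction.AP_TO_BL, geometry=geometry)


def make_series(design, concentrations, times=None, c0=0.4, donor_end=None,
                well_id="w1", loq=float("nan")):
    """Build a WellTimeSeries from raw numbers; None entries become BLQ."""
    times = list(times) if times is not None else list(
        design.sampling_times_min)[: len(concentrations)]
    points = [
        ReceiverPoint(t, float("nan"), True) if c is None else ReceiverPoint(t, c)
        for t, c in zip(times, concentrations)
    ]
    return WellTimeSeries(well_id=well_id, design=design,
                          receiver_measurements=points,
                          donor_start_concentration=c0,
                          donor_end_concentration=donor_end, loq=loq)


@pytest.fixture
def series_factory(design):
    def factory(concentrations, **kwargs):
        return make_series(design, concentrations, **kwargs)
    return factory
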