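import numpy as np
import pytest

from coldsense.caimg import RatioTrace
from coldsense.protocols import make_temperature_protocol

IMAGING_ANNOTATIONS = {
    "baseline": (0.0, 50.0),
    "ramp": (50.0, 80.0),
    "high_k": (200.0, 230.0),
}


def flat_trace(
    fr_level=0.5,
    response_peak=None,
    peak_t=70.0,
    high_k_level=1.3,
    cell_id="c0",
    duration=240,
):
    """Hand-built noise-free imaging trace: constant baseline, optional single
    response sample, sustained High-K+ plateau."""
    t = np.arange(0.0, duration + 1.0)
    fr = np.full_like(t, fr_level)
    h0, h1 = IMAGING_ANNOTATIONS["high_k"]
    fr[(t >= h0) & (t <= h1)] = high_k_level
    if response_peak is not None:
        fr[np.searchsorted(t, peak_t)] = response_peak
    return RatioTrace(
        cell_id=cell_id, times=t, fr=fr, annotations=dict(IMAGING_ANNOTATIONS)
    )


@pytest.fixture(scope="session")
def cooling_protocol():
    return make_temperature_protocol("cooling_ramp")


@pytest.fixture(scope="session")
def broad_protocol():
    return make_temperature_protocol("broad_ramp", duration_s=300.0)
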