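import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pftinterp import FlowVolumeCurve


def make_triangle_curve(
    vc: float = 4.0,
    pef: float = 8.0,
    peak_frac: float = 0.1,
    n: int = 41,
    record_id: str = "tri",
) -> FlowVolumeCurve:
    """Piecewise-linear limb: rise to PEF at peak_frac*vc, straight descent to (vc, 0).

    The grid contains the exact peak so both legs are exactly linear in the
    samples.
    """
    v_peak = peak_frac * vc
    v = np.unique(np.concatenate([np.linspace(0, vc, n), [v_peak]]))
    f = np.where(v <= v_peak, pef * v / v_peak, pef * (vc - v) / (vc - v_peak))
    return FlowVolumeCurve(record_id, v, f)


@pytest.fixture
def triangle_curve() -> FlowVolumeCurve:
    return make_triangle_curve()
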