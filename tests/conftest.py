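import numpy as np
import pytest

from fawps import GroundTruthNeuronSpec, StimulusGrid


@pytest.fixture
def grid():
    return StimulusGrid()


@pytest.fixture
def flat_spec():
    """Untuned-direction spec peaked at a grid point (sf0=0.25 cpd, tf0=2 Hz)."""
    return GroundTruthNeuronSpec(tuning_params=(1.0, 0.25, 2.0, 1.0, 1.0, 0.0), osi_target=0.0)


def make_spec(A=1.0, sf0=0.25, tf0=2.0, ssf=1.0, stf=1.0, xi=0.0, osi=0.0, **kw):
    return GroundTruthNeuronSpec(tuning_params=(A, sf0, tf0, ssf, stf, xi), osi_target=osi, **kw)


@pytest.fixture
def two_region_boxes():
    """Two abutting 1 mm cubes along x: A = [0,1000), B = [1000,2000) µm."""
    return [
        (1, ((0.0, 0.0, 0.0), (1000.0, 1000.0, 1000.0))),
        (2, ((1000.0, 0.0, 0.0), (2000.0, 1000.0, 1000.0))),
    ]
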