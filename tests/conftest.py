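import numpy as np
import pytest

from polspike import (
    AnalysisConfig,
    PolarizerRotation,
    Recording,
    SpikeTrain,
    StimulusEpoch,
)


@pytest.fixture
def cfg():
    return AnalysisConfig()


def make_epoch(t_on=10.0, dop=0.99, speed=40.0, start_angle=0.0, pad=0.5):
    """A standard light-on epoch with one CW and one CCW 360-degree sweep."""
    cw = PolarizerRotation(t_start=t_on + pad, direction="CW",
                           start_angle=start_angle, speed=speed)
    ccw = PolarizerRotation(t_start=cw.t_end, direction="CCW",
                            start_angle=cw.end_angle, speed=speed)
    return StimulusEpoch(t_on=t_on, t_off=ccw.t_end + pad, dop=dop,
                         rotations=[cw, ccw], label=f"dop{dop:g}")


def make_recording(spike_times, epochs=None, duration=60.0, cell_type="TL2",
                   neuron_id="n1"):
    train = SpikeTrain(neuron_id=neuron_id, cell_type=cell_type,
                       spike_times=np.asarray(spike_times, dtype=float),
                       session_duration=duration)
    return Recording(spike_train=train, epochs=epochs or [])


@pytest.fixture
def simple_recording():
    epoch = make_epoch(t_on=10.0)
    return make_recording([1.0, 5.0, 12.0, 15.0, 20.0], [epoch], duration=60.0)
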