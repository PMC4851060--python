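import numpy as np
import pytest

from exitrec.io import (
    ROOM1,
    ROOM2,
    ActivityLabel,
    AnnotationInterval,
    SensorObservation,
)
from exitrec import crf


@pytest.fixture
def room1():
    return ROOM1


@pytest.fixture
def room2():
    return ROOM2


def make_obs(t, antenna_id="antenna1", a_v=1.0, a_l=0.0, a_f=0.0, rssi=-60.0,
             phase=0.0, channel=0, participant_id="p00", gender=0):
    return SensorObservation(
        t=t, a_v=a_v, a_l=a_l, a_f=a_f, rssi=rssi, antenna_id=antenna_id,
        phase=phase, channel=channel, participant_id=participant_id,
        gender=gender,
    )


@pytest.fixture
def obs_factory():
    return make_obs


@pytest.fixture
def simple_annotations():
    return [
        AnnotationInterval(0.0, 10.0, ActivityLabel.LYING),
        AnnotationInterval(10.0, 20.0, ActivityLabel.AMBULATING),
    ]


def random_crf_model(rng, d=3, vartheta=0.0, schema=None):
    return crf.CRFModel(
        unary_weights=rng.normal(size=(4, d)),
        bias=rng.normal(size=4),
        transition_weights=rng.normal(size=(4, 4)),
        class_weights=np.ones(4),
        tau=0,
        vartheta=vartheta,
        feature_schema=schema or [f"f{i}" for i in range(d)],
    )


@pytest.fixture
def crf_model_factory():
    return random_crf_model
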