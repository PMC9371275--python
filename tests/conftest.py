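import math

import numpy as np
import pytest

from scoliopred.geometry import VertebraLandmarks


class MeanPredictor:
    """Predicts the training-target mean regardless of features."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


@pytest.fixture
def mean_model_factory():
    return MeanPredictor


def rectangle_landmarks(level="T5", width=40.0, height=20.0, angle_deg=0.0,
                        centre=(0.0, 0.0)):
    """Width x height rectangle rotated by angle_deg about its centre,
    corners in SL,SR,IR,IL order (y-up)."""
    w, h = width / 2.0, height / 2.0
    base = np.array([[-w, h], [w, h], [w, -h], [-w, -h]])
    t = math.radians(angle_deg)
    rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    return VertebraLandmarks(level, base @ rot.T + np.asarray(centre))


@pytest.fixture
def make_rectangle():
    return rectangle_landmarks
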