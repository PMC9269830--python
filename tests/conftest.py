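"""Shared fixtures: cheap synthetic feature tensors and one small real corpus."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from eegtw import EMOTION_ORDER, EpochFeatureTensor

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: per-band feature-mean shifts per emotion class, used by the tensor factory;
#: theta is deliberately flat across classes (an uninformative band)
CLASS_SHIFTS = {
    1: np.array([0.0, 0.0, -0.5, 1.0, 1.5]),
    0: np.array([0.0, 0.0, 0.5, 0.0, 0.0]),
    -1: np.array([0.5, 0.0, 0.0, -0.5, -1.0]),
}


def make_epoch_tensor(rng, subject_id=0, experiment_id=0, trial_index=0,
                      label=None, separation=1.0, noise=1.0,
                      feature_type="de") -> EpochFeatureTensor:
    """A (58, 5, 180) Gaussian feature tensor with class-dependent band means.

    ``separation=0`` gives label-free noise; larger values make the three
    classes linearly separable at the trial level.
    """
    if label is None:
        label = EMOTION_ORDER[trial_index]
    mean = 5.0 + separation * CLASS_SHIFTS[label]
    values = rng.normal(mean[None, :, None], noise, size=(58, 5, 180))
    return EpochFeatureTensor(values=values, feature_type=feature_type,
                              subject_id=subject_id, experiment_id=experiment_id,
                              trial_index=trial_index, label=label)


def make_experiment_tensors(rng, subject_id=0, experiment_id=0, separation=1.0,
                            noise=1.0, feature_type="de"):
    """The 15 synthetic tensors of one experiment, labels in protocol order."""
    return [
        make_epoch_tensor(rng, subject_id, experiment_id, i,
                          separation=separation, noise=noise,
                          feature_type=feature_type)
        for i in range(15)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_experiments(rng):
    """30 separable synthetic epoch tensors from two experiments."""
    return (make_experiment_tensors(rng, 0, 0) +
            make_experiment_tensors(rng, 1, 0))
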