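"""HDF5 persistence: one file per experiment for signals and features.

Signal layout (``save_experiment``): dataset ``signal`` of shape
(15 trials, channels, samples), float32, with attributes ``subject_id``,
``experiment_id``, ``labels`` (15 ints) and ``fs``.  Pre-extracted
SEED-style arrays saved in the same layout load through the same reader.

Feature layout (``save_feature_experiment``): dataset ``values`` of shape
(15, 58, 5, n) with attributes ``feature_type``, ``smoothed`` (or
``tw_length``), ``band_edges``, plus the same provenance attributes.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .bands import BANDS, N_BANDS, N_CHANNELS
from .features import EpochFeatureTensor, N_EPOCHS
from .synth import EMOTION_ORDER, ExperimentBatch, N_TRIALS, RawTrial
from .windows import TWFeatureTensor

_BAND_EDGES = np.array([(lo, hi) for _, lo, hi in BANDS])


def experiment_filename(subject_id: int, experiment_id: int) -> str:
    return f"subject{subject_id:02d}_experiment{experiment_id}.h5"


def save_experiment(batch: ExperimentBatch, path) -> Path:
    path = Path(path)
    sig = np.stack([t.signal for t in batch.trials]).astype(np.float32)
    with h5py.File(path, "w") as f:
        d = f.create_dataset("signal", data=sig, chunks=(1,) + sig.shape[1:])
        d.attrs["units"] = "uV"
        f.attrs["subject_id"] = batch.subject_id
        f.attrs["experiment_id"] = batch.experiment_id
        f.attrs["labels"] = np.array([t.label for t in batch.trials])
        f.attrs["fs"] = batch.trials[0].sampling_rate
    return path


def load_experiment(path) -> ExperimentBatch:
    with h5py.File(path, "r") as f:
        if "signal" not in f:
            raise ValueError(f"{path}: missing 'signal' dataset")
        for attr in ("subject_id", "experiment_id", "labels", "fs"):
            if attr not in f.attrs:
                raise ValueError(f"{path}: missing required attribute '{attr}'")
        sig = f["signal"][()]
        labels = np.asarray(f.attrs["labels"])
        sub = int(f.attrs["subject_id"])
        exp = int(f.attrs["experiment_id"])
        fs = float(f.attrs["fs"])
    if sig.ndim != 3 or sig.shape[0] != N_TRIALS:
        raise ValueError(f"{path}: expected signal shape (15, channels, samples), "
                         f"got {sig.shape}")
    if len(labels) != N_TRIALS:
        raise ValueError(f"{path}: expected 15 labels, got {len(labels)}")
    trials = [
        RawTrial(signal=sig[i], label=int(labels[i]), subject_id=sub,
                 experiment_id=exp, trial_index=i, sampling_rate=fs)
        for i in range(N_TRIALS)
    ]
    return ExperimentBatch(trials=trials, subject_id=sub, experiment_id=exp)


def save_feature_experiment(tensors: Sequence, path) -> Path:
    """Persist the 15 feature tensors (epoch- or TW-level) of one experiment."""
    if len(tensors) != N_TRIALS:
        raise ValueError("expected the 15 tensors of one experiment")
    tensors = sorted(tensors, key=lambda t: t.trial_index)
    path = Path(path)
    values = np.stack([t.values for t in tensors]).astype(np.float32)
    ref = tensors[0]
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=values)
        f.attrs["subject_id"] = ref.subject_id
        f.attrs["experiment_id"] = ref.experiment_id
        f.attrs["labels"] = np.array([t.label for t in tensors])
        f.attrs["feature_type"] = ref.feature_type
        f.attrs["band_edges"] = _BAND_EDGES
        if isinstance(ref, TWFeatureTensor):
            f.attrs["tw_length"] = ref.tw_length
        else:
            f.attrs["smoothed"] = bool(ref.smoothed)
    return path


def load_feature_experiment(path) -> list:
    """Load one experiment's feature tensors; validates the documented layout."""
    with h5py.File(path, "r") as f:
        if "values" not in f:
            raise ValueError(f"{path}: missing 'values' dataset")
        if "labels" not in f.attrs:
            raise ValueError(f"{path}: missing 'labels' attribute")
        for attr in ("subject_id", "experiment_id", "feature_type"):
            if attr not in f.attrs:
                raise ValueError(f"{path}: missing required attribute '{attr}'")
        values = f["values"][()].astype(np.float64)
        labels = np.asarray(f.attrs["labels"])
        sub = int(f.attrs["subject_id"])
        exp = int(f.attrs["experiment_id"])
        ftype = str(f.attrs["feature_type"])
        tw_length = int(f.attrs["tw_length"]) if "tw_length" in f.attrs else None
        smoothed = bool(f.attrs.get("smoothed", False))
    if values.ndim != 4 or values.shape[0] != N_TRIALS:
        raise ValueError(f"{path}: expected values shape (15, 58, 5, n), "
                         f"got {values.shape}")
    if values.shape[1] != N_CHANNELS:
        raise ValueError(f"{path}: expected {N_CHANNELS} channels, "
                         f"got {values.shape[1]}")
    if values.shape[2] != N_BANDS:
        raise ValueError(f"{path}: expected {N_BANDS} bands, got {values.shape[2]}")
    out = []
    for i in range(N_TRIALS):
        if tw_length is not None:
            out.append(TWFeatureTensor(values=values[i], tw_length=tw_length,
                                       feature_type=ftype, subject_id=sub,
                                       experiment_id=exp, trial_index=i,
                                       label=int(labels[i])))
        else:
            if values.shape[3] != N_EPOCHS:
                raise ValueError(f"{path}: expected {N_EPOCHS} epochs, "
                                 f"got {values.shape[3]}")
            out.append(EpochFeatureTensor(values=values[i], feature_type=ftype,
                                          subject_id=sub, experiment_id=exp,
                                          trial_index=i, label=int(labels[i]),
                                          smoothed=smoothed))
    return out


def load_features_dir(directory) -> list:
    """Load and concatenate every experiment feature file in a directory."""
    files = sorted(Path(directory).glob("*.h5"))
    if not files:
        raise ValueError(f"no .h5 feature files found in {directory}")
    out = []
    for p in files:
        out.extend(load_feature_experiment(p))
    return out
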