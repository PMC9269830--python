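"""Sliding-window online emotion recognition.

A short window (default 2 s) slides over each trial with a 1-s step; the
window's mean epoch features (58 x 5 = 290 values, optionally ELBN-
normalized with the trial's own session stats) are scored by a logistic
regression trained on the window-level features of the training trials.
The output per test trial is a W x 3 class-probability trace (W = 179 at
the defaults); traces are summarized per true class as median / 25th /
75th-percentile probability trajectories.

The classifier is trained on window-level samples (each training trial
contributes all of its windows, labelled with the trial's emotion): a
trial-level model has a different feature dimension and cannot score a
single window, so window-level training is the only dimensionally
consistent protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import (ClassifierSpec, SplitSet, group_by_experiment,
                         split_sets)
from .features import EpochFeatureTensor, N_EPOCHS

CLASS_COLUMNS = {-1: "p_neg", 0: "p_neu", 1: "p_pos"}


@dataclass(frozen=True)
class OnlineConfig:
    window_length: int = 2   # seconds (= epochs)
    step: int = 1            # seconds
    classifier: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("LR"))
    elbn_on: bool = True
    elbn_mode: str = "faithful"  # or "causal"

    def __post_init__(self) -> None:
        if self.step > self.window_length:
            raise ValueError("step must be <= window_length")
        if self.window_length < 1 or self.step < 1:
            raise ValueError("window_length and step must be whole epochs >= 1")


def count_windows(duration_s: float, window_s: float, step_s: float) -> int:
    """Number of sliding windows: floor((duration - window)/step) + 1."""
    if window_s > duration_s:
        raise ValueError("window longer than the signal")
    return int(np.floor((duration_s - window_s) / step_s)) + 1


def sliding_window_features(tensor: EpochFeatureTensor, window: int = 2,
                            step: int = 1) -> np.ndarray:
    """(W, 58, 5) window-mean features; window w = mean of epochs [w*step, w*step+window)."""
    w = count_windows(N_EPOCHS, window, step)
    v = np.lib.stride_tricks.sliding_window_view(tensor.values, window, axis=2)
    return np.moveaxis(v[:, :, ::step].mean(axis=-1), 2, 0)[:w]


def _experiment_window_features(batch: Sequence[EpochFeatureTensor],
                                cfg: OnlineConfig,
                                fit_trials: Sequence[int] | None):
    """Per-trial sliding features of one session, optionally ELBN-normalized.

    ELBN stats (per channel/band min/max) are pooled over all windows of the
    fit trials — the session's 15 trials in the protocol-faithful mode, the
    split's train trials in causal mode.
    """
    feats = np.stack([
        sliding_window_features(t, cfg.window_length, cfg.step) for t in batch
    ])  # (15, W, 58, 5)
    if not cfg.elbn_on:
        return feats
    if fit_trials is None:
        fit = feats
    else:
        fit = feats[list(fit_trials)]
    f_min = fit.min(axis=(0, 1))
    f_max = fit.max(axis=(0, 1))
    span = f_max - f_min
    out = np.where(span == 0, 0.0, (feats - f_min) / np.where(span == 0, 1, span))
    return out


@dataclass
class OnlineResult:
    """Window-level probability traces and their per-class summaries."""

    traces: pd.DataFrame       # set_id, subject, experiment, trial, window, p_*, true
    summary: pd.DataFrame      # true_label, window_index, class column, p25/p50/p75
    mean_accuracy: float       # fraction of test windows whose argmax is correct


def summarize_traces(traces: pd.DataFrame) -> pd.DataFrame:
    """Median and quartile probability trajectories per true class."""
    rows = []
    for (lab, w), g in traces.groupby(["true_label", "window_index"]):
        for cls, col in CLASS_COLUMNS.items():
            q = np.percentile(g[col], [25, 50, 75])
            rows.append({"true_label": lab, "window_index": w,
                         "predicted_class": cls,
                         "p25": q[0], "p50": q[1], "p75": q[2]})
    return pd.DataFrame(rows)


def run_online(epoch_tensors: Sequence[EpochFeatureTensor],
               cfg: OnlineConfig | None = None,
               sets: Sequence[SplitSet] | None = None) -> OnlineResult:
    """Sliding-window recognition over all split sets.

    Per set: train the classifier on the pooled window-level features of the
    12 training trials of every experiment, then score every window of every
    test trial, yielding one probability trace per (set, test trial).
    """
    cfg = cfg or OnlineConfig()
    sets = sets if sets is not None else split_sets()
    groups = group_by_experiment(epoch_tensors)
    keys = sorted(groups)

    records = []
    n_correct = 0
    n_total = 0
    for split in sets:
        fit_trials = split.train_trials if cfg.elbn_mode == "causal" else None
        X_train, y_train = [], []
        test_feats = []  # (key, trial_index, label, (W, 58, 5))
        for key in keys:
            batch = groups[key]
            feats = _experiment_window_features(batch, cfg, fit_trials)
            for i in split.train_trials:
                X_train.append(feats[i].reshape(feats.shape[1], -1))
                y_train.append(np.full(feats.shape[1], batch[i].label))
            for i in split.test_trials:
                test_feats.append((key, i, batch[i].label, feats[i]))
        clf = cfg.classifier.build()
        clf.fit(np.concatenate(X_train), np.concatenate(y_train))
        classes = list(clf.classes_)

        for (sub, exp), trial_idx, label, feats in test_feats:
            proba = clf.predict_proba(feats.reshape(feats.shape[0], -1))
            pred = np.asarray(classes)[np.argmax(proba, axis=1)]
            n_correct += int(np.sum(pred == label))
            n_total += proba.shape[0]
            rec = {
                "set_id": split.set_id,
                "subject_id": sub,
                "experiment_id": exp,
                "trial_index": trial_idx,
                "true_label": label,
            }
            for w in range(proba.shape[0]):
                row = dict(rec, window_index=w)
                for cls, col in CLASS_COLUMNS.items():
                    row[col] = proba[w, classes.index(cls)]
                records.append(row)

    traces = pd.DataFrame(records)
    return OnlineResult(
        traces=traces,
        summary=summarize_traces(traces),
        mean_accuracy=n_correct / n_total,
    )
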