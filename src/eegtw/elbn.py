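"""Experiment-level batch normalization (ELBN).

Each (channel, band) feature is min-max rescaled to [0, 1] using the
extrema observed across the 15 trials of one recording session:

    F_norm = (F - F_min) / (F_max - F_min)

Because every session is normalized against its own extrema, any affine
distortion a*F + b (a > 0) applied uniformly to a session's features — e.g.
electrode-impedance gain or baseline shifts between sessions — cancels
exactly.  Normalization is strictly within-experiment; applying stats to a
tensor from a different session is an error.

Pooling granularity for multi-window tensors (N > 1): by default the
extrema are taken over all 15 x N window values of the session
(``pooling="all_windows"``), which reduces to the single-window rule at
N = 1; a per-window-index variant is available.  Degenerate ranges
(F_max == F_min) map to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .synth import N_TRIALS
from .windows import TWFeatureTensor

log = logging.getLogger(__name__)

POOLINGS = ("all_windows", "per_window_index")


@dataclass
class ElbnStats:
    """Per-(channel, band) extrema of one experiment's features."""

    f_min: np.ndarray  # (58, 5) or (58, 5, N) for per-window-index pooling
    f_max: np.ndarray
    subject_id: int
    experiment_id: int
    tw_length: int
    feature_type: str
    pooling: str = "all_windows"

    def __post_init__(self) -> None:
        if np.any(self.f_max < self.f_min):
            raise ValueError("F_max < F_min")


def fit_elbn(batch: Sequence[TWFeatureTensor], pooling: str = "all_windows",
             trial_indices: Sequence[int] | None = None) -> ElbnStats:
    """Extrema over the trials of one experiment.

    ``batch`` must be the 15 trials of a single session (same tw_length and
    feature type).  ``trial_indices`` restricts the fit to a subset (the
    "causal" mode that avoids using test-trial extrema); default is all 15,
    the protocol-faithful behaviour.
    """
    if len(batch) != N_TRIALS:
        raise ValueError(f"an experiment has exactly {N_TRIALS} trials, "
                         f"got {len(batch)}")
    if pooling not in POOLINGS:
        raise ValueError(f"pooling must be one of {POOLINGS}")
    ref = batch[0]
    for t in batch:
        if (t.subject_id, t.experiment_id) != (ref.subject_id, ref.experiment_id):
            raise ValueError("trials come from different experiments")
        if t.tw_length != ref.tw_length or t.feature_type != ref.feature_type:
            raise ValueError("trials mix tw_length or feature_type")
        if t.values.shape != ref.values.shape:
            raise ValueError("trial tensors have inconsistent shapes")

    fit_on = batch
    if trial_indices is not None:
        by_idx = {t.trial_index: t for t in batch}
        fit_on = [by_idx[i] for i in trial_indices]

    stacked = np.stack([t.values for t in fit_on])  # (n_fit, 58, 5, N)
    if pooling == "all_windows":
        f_min = stacked.min(axis=(0, 3))
        f_max = stacked.max(axis=(0, 3))
    else:
        f_min = stacked.min(axis=0)
        f_max = stacked.max(axis=0)
    return ElbnStats(
        f_min=f_min,
        f_max=f_max,
        subject_id=ref.subject_id,
        experiment_id=ref.experiment_id,
        tw_length=ref.tw_length,
        feature_type=ref.feature_type,
        pooling=pooling,
    )


def apply_elbn(tensor: TWFeatureTensor, stats: ElbnStats) -> TWFeatureTensor:
    """Min-max normalize one trial with its experiment's stats."""
    if (tensor.subject_id, tensor.experiment_id) != (
        stats.subject_id, stats.experiment_id
    ):
        raise ValueError(
            "ELBN is strictly within-experiment: stats fitted on "
            f"(subject {stats.subject_id}, experiment {stats.experiment_id}) "
            f"cannot normalize a trial from (subject {tensor.subject_id}, "
            f"experiment {tensor.experiment_id})"
        )
    if tensor.tw_length != stats.tw_length or tensor.feature_type != stats.feature_type:
        raise ValueError("stats tw_length/feature_type mismatch")

    f_min, f_max = stats.f_min, stats.f_max
    if stats.pooling == "all_windows":
        f_min = f_min[:, :, None]
        f_max = f_max[:, :, None]
    span = f_max - f_min
    degenerate = span == 0
    if np.any(degenerate):
        log.info("%d degenerate (zero-range) cells mapped to 0",
                 int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(degenerate, 0.0, (tensor.values - f_min) / span)
    new = replace(tensor)
    new.values = out
    return new


def normalize_experiment(batch: Sequence[TWFeatureTensor],
                         pooling: str = "all_windows",
                         mode: str = "faithful",
                         train_trials: Sequence[int] | None = None,
                         ) -> list[TWFeatureTensor]:
    """Fit on one experiment and normalize all its trials.

    ``mode="faithful"`` fits the extrema on all 15 trials (as the protocol
    prescribes; this leaks test-trial extrema into normalization).
    ``mode="causal"`` fits on ``train_trials`` only; outputs for held-out
    trials may then fall outside [0, 1].
    """
    if mode == "faithful":
        stats = fit_elbn(batch, pooling=pooling)
    elif mode == "causal":
        if train_trials is None:
            raise ValueError("causal mode requires train_trials")
        stats = fit_elbn(batch, pooling=pooling, trial_indices=train_trials)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [apply_elbn(t, stats) for t in batch]
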