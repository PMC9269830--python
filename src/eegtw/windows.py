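"""Time-window (TW) aggregation of epoch features.

The 180 per-epoch features of a trial are averaged within non-overlapping
contiguous windows of one of 11 canonical lengths (180, 90, 60, 30, 20, 10,
5, 4, 3, 2, 1 seconds), yielding per-trial tensors of shape (58, 5, N) with
N = 180 / length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import EpochFeatureTensor, N_EPOCHS

#: The 11 canonical TW lengths in seconds, longest first.
TW_LENGTHS: tuple[int, ...] = (180, 90, 60, 30, 20, 10, 5, 4, 3, 2, 1)


@dataclass(frozen=True)
class TWConfig:
    """One time-window scheme: length in seconds (= epochs per window)."""

    tw_length: int

    def __post_init__(self) -> None:
        if self.tw_length not in TW_LENGTHS:
            raise ValueError(
                f"tw_length must be one of {TW_LENGTHS}, got {self.tw_length}"
            )

    @property
    def epochs_per_window(self) -> int:
        return self.tw_length

    @property
    def n_windows(self) -> int:
        return N_EPOCHS // self.tw_length


def tw_table() -> list[tuple[int, int, int]]:
    """(tw_length, n_windows, epochs_per_window) for the 11 schemes."""
    return [(L, N_EPOCHS // L, L) for L in TW_LENGTHS]


@dataclass
class TWFeatureTensor:
    """Per-trial aggregated features, shape (58, 5, N)."""

    values: np.ndarray
    tw_length: int
    feature_type: str
    subject_id: int
    experiment_id: int
    trial_index: int
    label: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = N_EPOCHS // self.tw_length
        if self.values.shape[2] != n:
            raise ValueError(
                f"expected {n} windows for tw_length={self.tw_length}, "
                f"got {self.values.shape[2]}"
            )

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]


def aggregate_tw(tensor: EpochFeatureTensor, tw) -> TWFeatureTensor:
    """Average epochs within each window: window j = mean of epochs [jL, (j+1)L)."""
    cfg = tw if isinstance(tw, TWConfig) else TWConfig(int(tw))
    L, n = cfg.epochs_per_window, cfg.n_windows
    c, b, _ = tensor.values.shape
    values = tensor.values.reshape(c, b, n, L).mean(axis=3)
    return TWFeatureTensor(
        values=values,
        tw_length=cfg.tw_length,
        feature_type=tensor.feature_type,
        subject_id=tensor.subject_id,
        experiment_id=tensor.experiment_id,
        trial_index=tensor.trial_index,
        label=tensor.label,
    )
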