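"""Canonical frequency bands and the 62-channel montage.

The five bands (delta 1-3 Hz, theta 4-7 Hz, alpha 8-13 Hz, beta 14-30 Hz,
gamma 31-50 Hz) are the standard decomposition used throughout EEG affective
computing.  The montage is the 62-channel extended 10-20 layout used by the
SEED recordings; four parieto-occipital/cerebellar channels (PO5, PO6, CB1,
CB2) are conventionally dropped, leaving 58 analysis channels.
"""

from __future__ import annotations

import numpy as np

#: (name, low Hz, high Hz) — non-overlapping, ordered, gamma below Nyquist at 200 Hz.
BANDS: tuple[tuple[str, float, float], ...] = (
    ("delta", 1.0, 3.0),
    ("theta", 4.0, 7.0),
    ("alpha", 8.0, 13.0),
    ("beta", 14.0, 30.0),
    ("gamma", 31.0, 50.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b[0] for b in BANDS)
N_BANDS = len(BANDS)

#: Recording montage (62 channels, row-major over the scalp, front to back).
CHANNELS_62: tuple[str, ...] = (
    "FP1", "FPZ", "FP2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)

#: Channels excluded from analysis.
EXCLUDED_CHANNELS: tuple[str, ...] = ("PO5", "PO6", "CB1", "CB2")

#: The 58 retained analysis channels, in montage order.
CHANNELS_58: tuple[str, ...] = tuple(
    ch for ch in CHANNELS_62 if ch not in EXCLUDED_CHANNELS
)

N_CHANNELS_RAW = len(CHANNELS_62)
N_CHANNELS = len(CHANNELS_58)

assert N_CHANNELS_RAW == 62 and N_CHANNELS == 58


def retained_indices(channel_names=CHANNELS_62) -> np.ndarray:
    """Indices of the retained channels within ``channel_names``.

    Exclusions are matched by name; raises ``ValueError`` if any of the four
    excluded channel names is absent from the input list.
    """
    names = [str(c).upper() for c in channel_names]
    missing = [c for c in EXCLUDED_CHANNELS if c not in names]
    if missing:
        raise ValueError(
            f"channel list lacks expected excluded channels {missing}; "
            "cannot apply the 58-channel selection by name"
        )
    return np.array([i for i, c in enumerate(names) if c not in EXCLUDED_CHANNELS])


def select_channels(signal: np.ndarray, channel_names=CHANNELS_62) -> np.ndarray:
    """Drop the four excluded channels from a (channels, samples) array."""
    signal = np.asarray(signal)
    if signal.shape[0] != len(channel_names):
        raise ValueError(
            f"signal has {signal.shape[0]} rows but {len(channel_names)} "
            "channel names were given"
        )
    return signal[retained_indices(channel_names)]
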