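"""Epoch-level band-power (PSD) and differential-entropy (DE) features.

Each trial is cut into 180 non-overlapping 1-s epochs.  Per channel, band
and epoch two features are computed:

* PSD — the integral of the one-sided Hann-windowed periodogram over the
  band, i.e. the epoch's band power (signal units squared);
* DE — the differential entropy of a Gaussian whose variance equals that
  band power, ``DE = 0.5 * ln(2*pi*e*P)`` (nats), the standard log-power
  feature of the SEED literature.

A fixed-interval smoother for the random-walk-plus-noise state-space model
(``lds_smooth``) optionally denoises each (channel, band) feature sequence
across epochs before time-window aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .bands import BANDS, CHANNELS_62, N_BANDS, N_CHANNELS, select_channels
from .synth import RawTrial

log = logging.getLogger(__name__)

N_EPOCHS = 180
EPOCH_SECONDS = 1.0

#: floor applied to non-positive band powers before taking the DE logarithm
DE_POWER_FLOOR = float(np.finfo(np.float64).eps)


@dataclass
class EpochFeatureTensor:
    """Per-trial feature tensor, shape (58 channels, 5 bands, 180 epochs)."""

    values: np.ndarray
    feature_type: str  # "psd" | "de"
    subject_id: int
    experiment_id: int
    trial_index: int
    label: int
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (N_CHANNELS, N_BANDS, N_EPOCHS):
            raise ValueError(
                f"expected shape {(N_CHANNELS, N_BANDS, N_EPOCHS)}, "
                f"got {self.values.shape}"
            )
        if self.feature_type not in ("psd", "de"):
            raise ValueError(f"unknown feature_type {self.feature_type!r}")


def segment_epochs(trial: RawTrial, channel_names=CHANNELS_62) -> np.ndarray:
    """Split a trial into 180 1-s epochs after channel selection.

    Returns an array of shape (58, 180, fs_samples); epoch k covers samples
    [k*fs, (k+1)*fs) (0-based, half-open), surplus samples beyond 180 s are
    discarded.
    """
    fs = trial.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("sampling rate must be an integer number of Hz")
    fs = int(round(fs))
    sig = select_channels(trial.signal, channel_names)
    needed = N_EPOCHS * fs
    if sig.shape[1] < needed:
        raise ValueError(
            f"trial has {sig.shape[1]} samples (< {needed} = 180 s at {fs} Hz)"
        )
    return sig[:, :needed].reshape(N_CHANNELS, N_EPOCHS, fs)


def _periodogram(x: np.ndarray, fs: int):
    """One-sided Hann periodogram (density scaling) along the last axis."""
    return sps.periodogram(x, fs=fs, window="hann", scaling="density", axis=-1)


def band_mask(freqs: np.ndarray, band) -> np.ndarray:
    """Bins whose center frequency lies in [low, high], inclusive."""
    _, lo, hi = band if len(band) == 3 else ("", *band)
    return (freqs >= lo) & (freqs <= hi)


def epoch_band_power(epoch_signal: np.ndarray, band, fs: int = 200) -> float:
    """Band power of one 1-s epoch: integral of the PSD estimate over the band."""
    x = np.asarray(epoch_signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("epoch signal contains non-finite values")
    freqs, pxx = _periodogram(x, fs)
    df = freqs[1] - freqs[0]
    return float(np.sum(pxx[..., band_mask(freqs, band)], axis=-1) * df)


def de_from_power(power) -> np.ndarray:
    """Gaussian differential entropy (nats) from band power.

    Non-positive powers are clipped to a machine-epsilon floor (degenerate
    all-zero epochs) with a logged warning.
    """
    p = np.asarray(power, dtype=float)
    if np.any(p < DE_POWER_FLOOR):
        log.warning("band power at/below zero; clipping to %.3g before log",
                    DE_POWER_FLOOR)
        p = np.maximum(p, DE_POWER_FLOOR)
    return 0.5 * np.log(2.0 * np.pi * np.e * p)


def epoch_de(epoch_signal: np.ndarray, band, fs: int = 200) -> float:
    """DE of one epoch in one band: 0.5*ln(2*pi*e*P_band)."""
    return float(de_from_power(epoch_band_power(epoch_signal, band, fs)))


def lds_smooth(sequence: np.ndarray, q_over_r: float = 0.01,
               axis: int = -1) -> np.ndarray:
    """Fixed-interval (RTS) smoother for a random-walk-plus-noise model.

    State model x_t = x_{t-1} + w_t, observation y_t = x_t + v_t with
    var(w)/var(v) = ``q_over_r``.  Initialization: state = first
    observation, state variance = sample variance of the sequence.  Constant
    sequences are fixed points; q/r -> inf recovers the identity.
    """
    y = np.asarray(sequence, dtype=float)
    y = np.moveaxis(y, axis, -1)
    shape = y.shape
    T = shape[-1]
    Y = y.reshape(-1, T)
    if T < 2:
        return np.moveaxis(Y.reshape(shape), -1, axis).copy()

    q = float(q_over_r)
    r = 1.0
    p0 = Y.var(axis=1)
    p0 = np.where(p0 > 0, p0, r)

    xf = np.empty_like(Y)          # filtered means
    pf = np.empty_like(Y)          # filtered variances
    pp = np.empty_like(Y)          # predicted variances (for the backward pass)
    xf[:, 0] = Y[:, 0]
    pf[:, 0] = p0
    for t in range(1, T):
        pp[:, t] = pf[:, t - 1] + q
        k = pp[:, t] / (pp[:, t] + r)
        xf[:, t] = xf[:, t - 1] + k * (Y[:, t] - xf[:, t - 1])
        pf[:, t] = (1.0 - k) * pp[:, t]

    xs = xf.copy()
    for t in range(T - 2, -1, -1):
        c = pf[:, t] / pp[:, t + 1]
        xs[:, t] = xf[:, t] + c * (xs[:, t + 1] - xf[:, t])

    return np.moveaxis(xs.reshape(shape), -1, axis)


def extract_features(trial: RawTrial, feature_type: str = "de",
                     lds_on: bool = True, q_over_r: float = 0.01,
                     channel_names=CHANNELS_62) -> EpochFeatureTensor:
    """Channel selection -> segmentation -> band power / DE -> optional LDS.

    Returns a (58, 5, 180) tensor of the requested feature type.
    """
    epochs = segment_epochs(trial, channel_names)       # (58, 180, fs)
    fs = int(round(trial.sampling_rate))
    freqs, pxx = _periodogram(epochs, fs)               # (58, 180, fs//2+1)
    df = freqs[1] - freqs[0]
    powers = np.empty((N_CHANNELS, N_BANDS, N_EPOCHS))
    for b, band in enumerate(BANDS):
        powers[:, b, :] = pxx[..., band_mask(freqs, band)].sum(axis=-1) * df

    if feature_type == "psd":
        values = powers
    elif feature_type == "de":
        values = de_from_power(powers)
    else:
        raise ValueError(f"unknown feature_type {feature_type!r}")

    if lds_on:
        values = lds_smooth(values, q_over_r=q_over_r, axis=-1)

    return EpochFeatureTensor(
        values=values,
        feature_type=feature_type,
        subject_id=trial.subject_id,
        experiment_id=trial.experiment_id,
        trial_index=trial.trial_index,
        label=trial.label,
        smoothed=lds_on,
    )
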