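"""Synthetic SEED-structured EEG generator.

Emulates the structure of the SEED corpus — 15 subjects x 3 sessions
("experiments") x 15 film-clip trials, 62 channels at 200 Hz, >= 180 s per
trial, the fixed three-class emotion order — with a known, controllable
ground truth:

* class structure: each emotion class shifts per-band log power by a
  configurable offset (``class_band_effects``);
* session drift: every experiment draws one multiplicative power gain per
  band (log-normal) and one additive power offset (normal), shared by its
  15 trials — the nuisance structure experiment-level batch normalization
  is designed to remove;
* channel heterogeneity: a fixed per-channel gain profile drawn once per
  subject.

Signals are sums of five band-limited Gaussian processes.  By default each
band component is synthesized in the frequency domain (complex-Gaussian
rFFT coefficients confined to the band, normalized via Parseval so the
component's time-domain variance equals its target power exactly); a
Butterworth-filtered variant is available as ``synthesis="filtered"``.

All randomness is keyed: substreams are derived from (seed, role, subject,
experiment, trial) so generation order is irrelevant and any trial can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .bands import BANDS, N_CHANNELS_RAW

#: Fixed presentation order of the emotion classes within every experiment
#: (1 positive, 0 neutral, -1 negative); 5 trials per class.
EMOTION_ORDER: tuple[int, ...] = (1, 0, -1, -1, 0, 1, -1, 0, 1, 1, 0, -1, 0, 1, -1)

N_TRIALS = len(EMOTION_ORDER)

# Substream role tags (arbitrary distinct small ints, stable across versions).
_ROLE_TRIAL = 11
_ROLE_DRIFT = 13
_ROLE_CHANNEL = 17


def emotion_order() -> list[int]:
    """The fixed 15-trial emotion label sequence of one experiment."""
    return list(EMOTION_ORDER)


def _default_class_effects() -> dict[int, tuple[float, ...]]:
    # Per-band log-power offsets (delta, theta, alpha, beta, gamma).
    # Magnitudes 0.3-0.8 give clear but non-trivial class separability;
    # the profiles are pairwise distinct in every band pair.
    return {
        1: (0.0, 0.0, -0.3, 0.5, 0.8),
        0: (0.0, 0.0, 0.3, 0.0, 0.0),
        -1: (0.2, 0.3, 0.1, -0.2, -0.4),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic corpus.

    Defaults reproduce the SEED layout: 15 subjects x 3 experiments x 15
    trials of 180 s at 200 Hz over 62 channels.
    """

    n_subjects: int = 15
    n_experiments_per_subject: int = 3
    n_trials: int = N_TRIALS
    sampling_rate: float = 200.0
    trial_duration: float = 180.0
    n_channels: int = N_CHANNELS_RAW
    class_band_effects: Mapping[int, Sequence[float]] = field(
        default_factory=_default_class_effects
    )
    drift_gain_sd: float = 0.5
    drift_offset_sd: float = 0.3
    channel_gain_sd: float = 0.2
    noise_floor: float = 1.0
    synthesis: str = "spectral"  # or "filtered" (4th-order Butterworth)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials != N_TRIALS:
            raise ValueError("n_trials is fixed at 15 (hardwired emotion order)")
        n = self.trial_duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("trial_duration x sampling_rate must be an integer")
        if self.sampling_rate < 2 * BANDS[-1][2]:
            raise ValueError("sampling_rate must be >= 100 Hz (gamma below Nyquist)")
        if self.n_channels != N_CHANNELS_RAW:
            raise ValueError("n_channels is fixed at 62 (montage is hardwired)")
        if self.synthesis not in ("spectral", "filtered"):
            raise ValueError(f"unknown synthesis method {self.synthesis!r}")
        for lab in (1, 0, -1):
            if lab not in self.class_band_effects:
                raise ValueError(f"class_band_effects missing label {lab}")
            if len(self.class_band_effects[lab]) != len(BANDS):
                raise ValueError("class_band_effects entries must have 5 values")

    @property
    def n_samples(self) -> int:
        return round(self.trial_duration * self.sampling_rate)


@dataclass
class RawTrial:
    """One film-clip trial: (channels, samples) signal plus provenance."""

    signal: np.ndarray
    label: int
    subject_id: int
    experiment_id: int
    trial_index: int
    sampling_rate: float


@dataclass
class ExperimentBatch:
    """The 15 trials of one recording session — the unit of normalization."""

    trials: list
    subject_id: int
    experiment_id: int
    #: ground-truth (per-band gain vector, offset) drift of this session, for tests
    drift: tuple[np.ndarray, float] | None = None

    def __post_init__(self) -> None:
        if len(self.trials) != N_TRIALS:
            raise ValueError("an experiment holds exactly 15 trials")


def experiment_drift(config: GeneratorConfig, subject_id: int, experiment_id: int):
    """Ground-truth session drift, drawn once per (subject, experiment).

    Returns (gain, offset): ``gain`` is a per-band vector of log-normal
    multiplicative power gains (a session whose recording conditions favour
    some rhythms over others), ``offset`` a scalar additive power offset.
    Both are shared by all 15 trials of the session.
    """
    rng = np.random.default_rng(
        [config.seed, _ROLE_DRIFT, subject_id, experiment_id]
    )
    gain = np.exp(rng.normal(0.0, config.drift_gain_sd, size=len(BANDS)))
    offset = float(rng.normal(0.0, config.drift_offset_sd))
    return gain, offset


def channel_gains(config: GeneratorConfig, subject_id: int) -> np.ndarray:
    """Fixed per-channel power gain profile of one subject."""
    rng = np.random.default_rng([config.seed, _ROLE_CHANNEL, subject_id])
    return np.exp(rng.normal(0.0, config.channel_gain_sd, size=config.n_channels))


def _band_powers(config: GeneratorConfig, label: int, gain: np.ndarray,
                 offset: float, ch_gain: np.ndarray) -> np.ndarray:
    """Target (channels, bands) power matrix for one trial."""
    effects = np.asarray(config.class_band_effects[label], dtype=float)
    base = config.noise_floor * np.exp(effects)[None, :] * ch_gain[:, None]
    power = base * np.asarray(gain)[None, :] + config.noise_floor * offset
    # additive offsets can push a weak band negative; keep power physical
    return np.maximum(power, 1e-6 * config.noise_floor)


def _synth_spectral(rng, power, n, fs):
    """Sum of band-limited processes built directly in the frequency domain."""
    n_ch = power.shape[0]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.zeros((n_ch, freqs.size), dtype=complex)
    for b, (_, lo, hi) in enumerate(BANDS):
        mask = (freqs >= lo - 0.5) & (freqs < hi + 0.5)
        m = int(mask.sum())
        z = rng.standard_normal((n_ch, m)) + 1j * rng.standard_normal((n_ch, m))
        # Parseval: var(irfft(X, n)) = (2/n^2) * sum |X_k|^2 for interior bins
        energy = np.sum(np.abs(z) ** 2, axis=1)
        scale = np.sqrt(power[:, b] * n * n / (2.0 * energy))
        spec[:, mask] += z * scale[:, None]
    return np.fft.irfft(spec, n=n, axis=1)


def _synth_filtered(rng, power, n, fs):
    """Sum of Butterworth band-passed white-noise processes (zero-phase)."""
    n_ch = power.shape[0]
    out = np.zeros((n_ch, n))
    for b, (_, lo, hi) in enumerate(BANDS):
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n)), axis=-1)
        v = x.var(axis=-1)
        out += x * np.sqrt(power[:, b] / v)[:, None]
    return out


def generate_trial(config: GeneratorConfig, subject_id: int, experiment_id: int,
                   trial_index: int) -> RawTrial:
    """Synthesize one trial; deterministic in (config.seed, ids, trial_index)."""
    if not 0 <= trial_index < N_TRIALS:
        raise ValueError(f"trial_index must be in 0..14, got {trial_index}")
    label = EMOTION_ORDER[trial_index]
    gain, offset = experiment_drift(config, subject_id, experiment_id)
    ch_gain = channel_gains(config, subject_id)
    power = _band_powers(config, label, gain, offset, ch_gain)
    rng = np.random.default_rng(
        [config.seed, _ROLE_TRIAL, subject_id, experiment_id, trial_index]
    )
    synth = _synth_spectral if config.synthesis == "spectral" else _synth_filtered
    sig = synth(rng, power, config.n_samples, config.sampling_rate)
    return RawTrial(
        signal=sig.astype(np.float32),
        label=label,
        subject_id=subject_id,
        experiment_id=experiment_id,
        trial_index=trial_index,
        sampling_rate=config.sampling_rate,
    )


def generate_experiment(config: GeneratorConfig, subject_id: int,
                        experiment_id: int) -> ExperimentBatch:
    """All 15 trials of one session, with its ground-truth drift attached."""
    trials = [
        generate_trial(config, subject_id, experiment_id, t) for t in range(N_TRIALS)
    ]
    return ExperimentBatch(
        trials=trials,
        subject_id=subject_id,
        experiment_id=experiment_id,
        drift=experiment_drift(config, subject_id, experiment_id),
    )


def iter_experiments(config: GeneratorConfig) -> Iterator[ExperimentBatch]:
    """Yield experiments one at a time (memory-friendly at full scale)."""
    for s in range(config.n_subjects):
        for e in range(config.n_experiments_per_subject):
            yield generate_experiment(config, s, e)


def generate_dataset(config: GeneratorConfig) -> list[ExperimentBatch]:
    """Materialize the whole corpus.

    At full SEED scale this holds ~6 GB of float32 signal; prefer
    :func:`iter_experiments` and process per experiment when scaling up.
    """
    return list(iter_experiments(config))
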