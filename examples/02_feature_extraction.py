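"""Extract band-power (PSD) and differential-entropy (DE) epoch features.

Each 180-s trial becomes a (58 channels, 5 bands, 180 epochs) tensor.  DE
is the Gaussian closed form 0.5*ln(2*pi*e*P) of the epoch band power P, so
the two feature types are deterministically linked.
"""

import numpy as np

from eegtw import (GeneratorConfig, de_from_power, extract_features,
                   generate_trial, lds_smooth)

cfg = GeneratorConfig(n_subjects=1, n_experiments_per_subject=1, seed=42)
trial = generate_trial(cfg, 0, 0, 0)   # first trial: positive class

psd = extract_features(trial, "psd", lds_on=False)
de = extract_features(trial, "de", lds_on=False)

print("feature tensor shape:", psd.values.shape)
print("mean band power per band (delta..gamma):",
      np.round(psd.values.mean(axis=(0, 2)), 3))
print("DE equals closed form of PSD:",
      np.array_equal(de.values, de_from_power(psd.values)))

# LDS smoothing: a fixed-interval random-walk smoother across the epoch
# axis suppresses epoch-to-epoch estimation noise without changing shape.
seq = de.values[0, 2]                  # channel FP1, alpha band
smooth = lds_smooth(seq, q_over_r=0.01)
print(f"alpha-DE epoch-series variance raw {seq.var():.4f} "
      f"-> smoothed {smooth.var():.4f}")
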