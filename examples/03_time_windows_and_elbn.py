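"""Time-window aggregation and experiment-level batch normalization.

Epoch features are averaged within non-overlapping windows of 11 canonical
lengths; ELBN then min-max rescales every (channel, band) feature to [0, 1]
using the extrema of the 15 trials of the same session, cancelling any
affine session distortion exactly.
"""

import numpy as np

from eegtw import (GeneratorConfig, aggregate_tw, extract_features,
                   generate_experiment, normalize_experiment, tw_table)

print("TW length -> windows per trial (x epochs per window):")
for tw, n, epw in tw_table():
    print(f"  {tw:>3} s -> {n:>3} x {epw}")

cfg = GeneratorConfig(n_subjects=1, n_experiments_per_subject=1, seed=42)
batch = generate_experiment(cfg, 0, 0)
tensors = [extract_features(t, "de") for t in batch.trials]
agg = [aggregate_tw(t, 2) for t in tensors]
print("2-s aggregated tensor shape:", agg[0].values.shape)

norm = normalize_experiment(agg)
vals = np.stack([t.values for t in norm])
print(f"after ELBN: min {vals.min():.1f}, max {vals.max():.1f} "
      "(session extrema map to exactly 0 and 1)")

# affine session distortion (gain 5x, baseline +3) cancels exactly
distorted = [aggregate_tw(t, 2) for t in tensors]
for t in distorted:
    t.values = 5.0 * t.values + 3.0
norm_d = normalize_experiment(distorted)
diff = max(np.abs(a.values - b.values).max() for a, b in zip(norm, norm_d))
print(f"max |ELBN(F) - ELBN(5F+3)| = {diff:.2e}")
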