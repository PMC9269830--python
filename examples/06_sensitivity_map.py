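"""Kruskal-Wallis emotion-sensitivity map before and after ELBN.

Per (channel, band), the per-trial mean features are compared across the
three emotion groups with a rank-based H test.  Session drift dilutes the
pooled group differences; normalizing each session first aligns the scales
and typically increases the number of significant cells.
"""

from eegtw import (GeneratorConfig, extract_features, iter_experiments,
                   kw_table, prepare_tw_features, significance_count,
                   significance_wide)

cfg = GeneratorConfig(n_subjects=4, n_experiments_per_subject=1,
                      drift_gain_sd=1.5, seed=5)
tensors = [extract_features(t, "de")
           for b in iter_experiments(cfg) for t in b.trials]

for elbn_on, tag in ((False, "without ELBN"), (True, "with ELBN")):
    prepared = prepare_tw_features(tensors, 2, elbn_on=elbn_on)
    tab = kw_table(prepared, elbn_state=tag)
    n_sig = significance_count(tab, alpha=0.05)
    print(f"{tag}: {n_sig} / {len(tab)} channel x band cells with p <= 0.05")
    if elbn_on:
        wide = significance_wide(tab, channels=["FP1", "FPZ", "CZ", "PZ", "OZ"])
        print("\np-values (frontal/central/occipital sample, with ELBN):")
        print(wide.round(3).to_string())
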