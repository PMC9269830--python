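"""Kruskal-Wallis emotion-sensitivity maps over channels and bands.

For each (channel, band) cell the per-trial mean feature values are split
into the three emotion groups (pooled across all experiments) and compared
with the Kruskal-Wallis H test (tie-corrected, chi-square reference with
2 df).  Counting cells with p <= 0.05 before and after ELBN quantifies how
normalization changes the features' sensitivity to emotion.

No multiple-testing correction is applied (the map is descriptive).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .bands import BAND_NAMES, CHANNELS_58

log = logging.getLogger(__name__)


def trial_mean_features(tensor) -> np.ndarray:
    """Per-trial (58, 5) mean over the window (or epoch) axis.

    Because offline windows partition the epochs equally, this equals the
    mean over all 180 epoch values regardless of the TW length used.
    """
    return tensor.values.mean(axis=2)


def kruskal_cell(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected H and chi-square p for one cell's emotion groups.

    Degenerate cells (every observation identical) return (0, 1) with a
    logged warning instead of raising.
    """
    for g in groups:
        if len(g) < 2:
            raise ValueError("each emotion group needs >= 2 observations")
    pooled = np.concatenate([np.asarray(g) for g in groups])
    if np.all(pooled == pooled[0]):
        log.warning("degenerate Kruskal-Wallis cell (all values tied); p = 1")
        return 0.0, 1.0
    h, p = sstats.kruskal(*groups)
    if not np.isfinite(h):
        log.warning("non-finite Kruskal-Wallis statistic; treating as p = 1")
        return 0.0, 1.0
    return float(h), float(p)


def kw_table(tensors: Sequence, elbn_state: str | None = None) -> pd.DataFrame:
    """Kruskal-Wallis map over all 58 channels x 5 bands.

    ``tensors`` are per-trial feature tensors (epoch- or TW-level) carrying
    labels; per-trial means are pooled across experiments into three emotion
    groups per cell.  Returns a long DataFrame with columns channel, band,
    H, p (plus feature_type and the optional elbn tag).
    """
    means = np.stack([trial_mean_features(t) for t in tensors])  # (n, 58, 5)
    labels = np.array([t.label for t in tensors])
    feature_type = tensors[0].feature_type
    masks = [labels == lab for lab in (-1, 0, 1)]
    rows = []
    for c in range(means.shape[1]):
        for b in range(means.shape[2]):
            h, p = kruskal_cell([means[m, c, b] for m in masks])
            rows.append({
                "feature_type": feature_type,
                "band": BAND_NAMES[b],
                "channel": CHANNELS_58[c],
                "H": h,
                "p": p,
            })
    df = pd.DataFrame(rows)
    if elbn_state is not None:
        df["elbn"] = elbn_state
    return df


def significance_count(table: pd.DataFrame, alpha: float = 0.05) -> int:
    """Number of cells with p <= alpha."""
    if len(table) == 0:
        return 0
    return int((table["p"] <= alpha).sum())


def significance_wide(table: pd.DataFrame, alpha: float = 0.05,
                      channels: Sequence[str] | None = None) -> pd.DataFrame:
    """Wide (band x channel) rendering of p-values, optionally channel-subset."""
    df = table if channels is None else table[table["channel"].isin(channels)]
    wide = df.pivot_table(index="band", columns="channel", values="p")
    order = [c for c in CHANNELS_58 if c in wide.columns]
    return wide.reindex(index=[b for b in BAND_NAMES if b in wide.index],
                        columns=order)
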