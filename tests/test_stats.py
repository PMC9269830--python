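"""Kruskal-Wallis sensitivity maps: oracle equivalence and rank properties."""

from itertools import product

import numpy as np
import pytest

from eegtw import (aggregate_tw, kruskal_cell, kw_table, normalize_experiment,
                   significance_count, significance_wide, trial_mean_features)
from tests.conftest import make_epoch_tensor, make_experiment_tensors


def brute_force_kw(groups):
    """Independent tie-corrected H: direct rank computation from first principles."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    # mid-ranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    denom = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / denom if denom > 0 else np.nan


class TestTrialMeans:
    def test_known_two_window_mean(self, rng):
        t = aggregate_tw(make_epoch_tensor(rng), 90)
        t.values[0, 0] = [0.0, 1.0]
        assert trial_mean_features(t)[0, 0] == 0.5

    def test_single_window_is_value_itself(self, rng):
        t = aggregate_tw(make_epoch_tensor(rng), 180)
        np.testing.assert_array_equal(trial_mean_features(t),
                                      t.values[..., 0])

    def test_equals_epoch_level_mean_for_any_tw(self, rng):
        epoch = make_epoch_tensor(rng)
        for tw in (180, 20, 2):
            agg = aggregate_tw(epoch, tw)
            np.testing.assert_allclose(trial_mean_features(agg),
                                       epoch.values.mean(axis=2), rtol=1e-12)


class TestKruskalOracle:
    def test_identical_groups_degenerate(self):
        h, p = kruskal_cell([np.ones(4), np.ones(4), np.ones(4)])
        assert h == 0.0 and p == 1.0

    def test_clean_separation_example(self):
        h, _ = kruskal_cell([np.array([1., 2, 3]), np.array([4., 5, 6]),
                             np.array([7., 8, 9])])
        assert h == pytest.approx(brute_force_kw(
            [np.array([1., 2, 3]), np.array([4., 5, 6]), np.array([7., 8, 9])]))

    def test_exhaustive_small_instances_match_brute_force(self):
        """H agrees with the independent rank computation on every value
        assignment from a small alphabet (ties included), n = 6 and 9."""
        configs = [((2, 2, 2), (0.0, 1.0, 2.0)), ((3, 3, 3), (0.0, 1.0))]
        checked = 0
        for sizes, alphabet in configs:
            n = sum(sizes)
            for vals in product(alphabet, repeat=n):
                arr = np.array(vals)
                if np.all(arr == arr[0]):
                    continue  # degenerate; handled separately
                groups = []
                start = 0
                for s in sizes:
                    groups.append(arr[start:start + s])
                    start += s
                h, p = kruskal_cell(groups)
                assert h == pytest.approx(brute_force_kw(groups), abs=1e-10)
                assert 0.0 <= p <= 1.0
                checked += 1
        assert checked > 1000

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            kruskal_cell([np.array([1.0]), np.array([2.0, 3.0]),
                          np.array([4.0, 5.0])])


@pytest.fixture(scope="module")
def tensors():
    rng = np.random.default_rng(13)
    out = []
    for e in range(3):
        out += [aggregate_tw(t, 20) for t in
                make_experiment_tensors(rng, e, 0, separation=1.5)]
    return out


class TestKwTable:
    def test_full_map_dimensions(self, tensors):
        tab = kw_table(tensors)
        assert len(tab) == 58 * 5
        assert tab["p"].between(0, 1).all()

    def test_informative_bands_more_significant_than_flat_ones(self, tensors):
        """The factory shifts gamma strongly and theta weakly across classes,
        so gamma cells should dominate the significant set."""
        tab = kw_table(tensors)
        gamma = significance_count(tab[tab["band"] == "gamma"])
        theta = significance_count(tab[tab["band"] == "theta"])
        assert gamma > theta

    def test_counts_on_trivial_tables(self):
        import pandas as pd
        assert significance_count(pd.DataFrame(columns=["p"])) == 0
        assert significance_count(pd.DataFrame({"p": [1.0, 0.9, 0.06]})) == 0
        assert significance_count(pd.DataFrame({"p": [0.05, 0.01]})) == 2

    def test_p_invariant_to_monotone_transform(self, rng):
        """Rank test: a monotone transform of the per-trial feature values
        (single-window tensors, where the trial mean is the value itself)
        changes no H or p."""
        import copy
        batch = []
        for e in range(2):
            batch += [aggregate_tw(t, 180) for t in
                      make_experiment_tensors(rng, e, 0, separation=1.5)]
        tab = kw_table(batch)
        warped = copy.deepcopy(batch)
        for t in warped:
            t.values = np.exp(t.values / 10.0)
        tab_w = kw_table(warped)
        np.testing.assert_allclose(tab["H"], tab_w["H"], atol=1e-9)
        np.testing.assert_allclose(tab["p"], tab_w["p"], atol=1e-9)

    def test_within_experiment_elbn_preserves_ranks(self, rng):
        """For a single experiment, ELBN is a monotone affine map per cell, so
        the per-experiment KW map is unchanged exactly."""
        batch = [aggregate_tw(t, 20) for t in
                 make_experiment_tensors(rng, 0, 0, separation=1.5)]
        raw = kw_table(batch)
        norm = kw_table(normalize_experiment(batch))
        np.testing.assert_allclose(raw["H"], norm["H"], atol=1e-9)
        np.testing.assert_allclose(raw["p"], norm["p"], atol=1e-9)

    def test_wide_rendering_subsets_channels(self, tensors):
        wide = significance_wide(kw_table(tensors), channels=["FP1", "CZ", "PZ"])
        assert list(wide.columns) == ["FP1", "CZ", "PZ"]
        assert wide.shape == (5, 3)
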