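"""Offline emotion recognition across time-window lengths and classifiers.

Each trial contributes one sample: its (58, 5, N) time-window tensor
flattened in (channel, band, window) order.  Ten fixed train/test trial
splits — the same 12/3 partition of trial indices applied in every
experiment — are evaluated for six classical classifiers, and the mean and
standard deviation of overall accuracy over the ten splits is reported per
(TW length, classifier) cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .elbn import normalize_experiment
from .features import EpochFeatureTensor
from .synth import EMOTION_ORDER
from .windows import TW_LENGTHS, TWFeatureTensor, aggregate_tw

log = logging.getLogger(__name__)

CLASS_LABELS = (-1, 0, 1)  # negative, neutral, positive


@dataclass(frozen=True)
class SplitSet:
    """One of the ten fixed 12-train / 3-test trial-index partitions."""

    set_id: int
    train_trials: tuple[int, ...]
    test_trials: tuple[int, ...]

    def test_labels(self) -> tuple[int, ...]:
        return tuple(EMOTION_ORDER[i] for i in self.test_trials)


_SPLITS = (
    (1, (0, 1, 2, 4, 5, 6, 9, 10, 11, 12, 13, 14), (3, 7, 8)),
    (2, (0, 1, 2, 3, 6, 7, 8, 9, 10, 12, 13, 14), (4, 5, 11)),
    (3, (1, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 14), (0, 2, 12)),
    (4, (0, 1, 3, 4, 5, 6, 7, 8, 9, 10, 11, 14), (2, 12, 13)),
    (5, (0, 1, 2, 3, 4, 5, 7, 9, 10, 11, 13, 14), (6, 8, 12)),
    (6, (0, 1, 2, 5, 6, 7, 9, 10, 11, 12, 13, 14), (3, 4, 8)),
    (7, (0, 1, 2, 3, 4, 6, 7, 8, 9, 11, 12, 13), (5, 10, 14)),
    (8, (0, 2, 3, 4, 5, 7, 9, 10, 11, 12, 13, 14), (1, 6, 8)),
    (9, (0, 3, 4, 5, 6, 7, 8, 10, 11, 12, 13, 14), (1, 2, 9)),
    (10, (0, 1, 2, 3, 4, 5, 6, 8, 10, 11, 12, 13), (7, 9, 14)),
)


def split_sets() -> list[SplitSet]:
    """The ten fixed split sets, verbatim.

    Set 3 contains trial 12 in both its train and test lists; the overlap is
    part of the published protocol and is preserved (and logged) rather than
    repaired.
    """
    out = []
    for sid, train, test in _SPLITS:
        s = SplitSet(sid, train, test)
        overlap = set(train) & set(test)
        if overlap:
            log.info("split set %d train/test overlap on trials %s (kept verbatim)",
                     sid, sorted(overlap))
        out.append(s)
    return out


CLASSIFIER_NAMES = ("KNN", "LR", "SVM", "GNB", "MLP", "Bagging")


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier with optional hyperparameter overrides.

    With no overrides the six canonical configurations are used verbatim;
    overrides exist for scaled-down runs (e.g. fewer Bagging estimators).
    """

    name: str
    overrides: Mapping[str, object] = field(default_factory=dict)

    def build(self):
        return make_classifier(self.name, **self.overrides)


def make_classifier(name: str, **overrides):
    """Instantiate one of the six canonical classifiers.

    Defaults follow the published configuration: KNN(k=5, Euclidean),
    LR(liblinear, seed 10), SVC(RBF, seed 10), GaussianNB, MLP(lbfgs,
    alpha=1e-5, hidden (100, 3), seed 1, max_iter=1e5), and Bagging of 500
    liblinear logistic regressions (seed 1).
    """
    if name == "KNN":
        params = dict(n_neighbors=5, p=2, metric="minkowski")
        params.update(overrides)
        return KNeighborsClassifier(**params)
    if name == "LR":
        # liblinear handles three classes one-vs-rest; recent scikit-learn
        # requires the wrapper to be explicit
        params = dict(solver="liblinear", random_state=10)
        params.update(overrides)
        return OneVsRestClassifier(LogisticRegression(**params))
    if name == "SVM":
        params = dict(random_state=10)
        params.update(overrides)
        return SVC(**params)
    if name == "GNB":
        return GaussianNB(**overrides)
    if name == "MLP":
        params = dict(solver="lbfgs", alpha=1e-5, hidden_layer_sizes=(100, 3),
                      random_state=1, max_iter=int(1e5))
        params.update(overrides)
        return MLPClassifier(**params)
    if name == "Bagging":
        base = OneVsRestClassifier(
            LogisticRegression(solver="liblinear", random_state=1))
        # modern scikit-learn names the base learner `estimator`
        params = dict(estimator=base, n_estimators=500, max_samples=1.0,
                      max_features=1.0, bootstrap=True, bootstrap_features=False,
                      n_jobs=1, random_state=1)
        params.update(overrides)
        return BaggingClassifier(**params)
    raise ValueError(f"unknown classifier {name!r}")


def default_classifier_specs(
    overrides: Mapping[str, Mapping[str, object]] | None = None,
    names: Sequence[str] = CLASSIFIER_NAMES,
) -> list[ClassifierSpec]:
    overrides = overrides or {}
    return [ClassifierSpec(n, overrides.get(n, {})) for n in names]


# ---------------------------------------------------------------------------
# sample construction


def group_by_experiment(tensors) -> dict[tuple[int, int], list]:
    """Group feature tensors by (subject_id, experiment_id), trial-ordered."""
    groups: dict[tuple[int, int], list] = {}
    for t in tensors:
        groups.setdefault((t.subject_id, t.experiment_id), []).append(t)
    for key, ts in groups.items():
        ts.sort(key=lambda t: t.trial_index)
        idx = [t.trial_index for t in ts]
        if idx != list(range(len(ts))):
            raise ValueError(f"experiment {key} has trial indices {idx}")
    return groups


def prepare_tw_features(epoch_tensors: Sequence[EpochFeatureTensor],
                        tw_length: int, elbn_on: bool = False,
                        elbn_pooling: str = "all_windows",
                        elbn_mode: str = "faithful",
                        train_trials: Sequence[int] | None = None,
                        ) -> list[TWFeatureTensor]:
    """Aggregate all trials at one TW length, optionally ELBN per experiment."""
    groups = group_by_experiment(epoch_tensors)
    out: list[TWFeatureTensor] = []
    for key in sorted(groups):
        batch = [aggregate_tw(t, tw_length) for t in groups[key]]
        if elbn_on:
            batch = normalize_experiment(batch, pooling=elbn_pooling,
                                         mode=elbn_mode, train_trials=train_trials)
        out.extend(batch)
    return out


def build_samples(tw_tensors: Sequence[TWFeatureTensor]):
    """One flattened sample per trial.

    Returns (X, y, meta): X of shape (n_trials, 58*5*N) in fixed (channel,
    band, window) order, y the emotion labels, meta a DataFrame with
    subject_id / experiment_id / trial_index per row.
    """
    if not tw_tensors:
        raise ValueError("no tensors given")
    tw = tw_tensors[0].tw_length
    for t in tw_tensors:
        if t.tw_length != tw:
            raise ValueError("tensors mix tw lengths")
    X = np.stack([t.values.reshape(-1) for t in tw_tensors])
    y = np.array([t.label for t in tw_tensors])
    meta = pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in tw_tensors],
            "experiment_id": [t.experiment_id for t in tw_tensors],
            "trial_index": [t.trial_index for t in tw_tensors],
        }
    )
    return X, y, meta


# ---------------------------------------------------------------------------
# grid evaluation


@dataclass
class GridResult:
    """Per-(tw, classifier, split) accuracies plus summary tables."""

    per_set: pd.DataFrame
    confusions: dict = field(default_factory=dict)

    @property
    def mean_table(self) -> pd.DataFrame:
        """Mean accuracy (%) over split sets: rows = TW length, cols = classifier."""
        t = self.per_set.pivot_table(index="tw_length", columns="classifier",
                                     values="accuracy", aggfunc="mean") * 100
        return t.reindex(index=sorted(t.index, reverse=True))

    @property
    def std_table(self) -> pd.DataFrame:
        t = self.per_set.pivot_table(index="tw_length", columns="classifier",
                                     values="accuracy", aggfunc="std") * 100
        return t.reindex(index=sorted(t.index, reverse=True))

    def formatted(self) -> pd.DataFrame:
        """'mean(std)' strings, mirroring the published accuracy matrices."""
        m, s = self.mean_table, self.std_table
        out = m.copy().astype(object)
        for col in m.columns:
            out[col] = [f"{a:.2f}({b:.2f})" for a, b in zip(m[col], s[col])]
        return out


def _split_indices(meta: pd.DataFrame, split: SplitSet):
    train = meta.index[meta["trial_index"].isin(split.train_trials)].to_numpy()
    test = meta.index[meta["trial_index"].isin(split.test_trials)].to_numpy()
    return train, test


def evaluate_split(X, y, meta, split: SplitSet, clf):
    """Train on the split's 12 trials per experiment, test on the other 3."""
    tr, te = _split_indices(meta, split)
    clf.fit(X[tr], y[tr])
    pred = clf.predict(X[te])
    acc = float(np.mean(pred == y[te]))
    per_class = {
        lab: float(np.mean(pred[y[te] == lab] == lab)) if np.any(y[te] == lab)
        else np.nan
        for lab in CLASS_LABELS
    }
    cm = confusion_matrix(y[te], pred, labels=list(CLASS_LABELS))
    return acc, per_class, cm


def evaluate_grid(epoch_tensors: Sequence[EpochFeatureTensor],
                  tw_lengths: Sequence[int] = TW_LENGTHS,
                  classifiers: Sequence[ClassifierSpec] | None = None,
                  sets: Sequence[SplitSet] | None = None,
                  elbn_on: bool = False,
                  elbn_pooling: str = "all_windows",
                  elbn_mode: str = "faithful",
                  keep_confusions: bool = True) -> GridResult:
    """The full offline accuracy grid for one feature type.

    For every (TW length, classifier, split set): fit on the train-trial
    samples of all experiments, score on the test-trial samples.  ELBN, when
    enabled, is fitted per experiment before sample construction (in causal
    mode, on the split's train trials only).
    """
    classifiers = classifiers if classifiers is not None else default_classifier_specs()
    sets = sets if sets is not None else split_sets()
    rows = []
    confusions: dict = {}
    for tw in tw_lengths:
        if elbn_on and elbn_mode == "causal":
            prepared = None  # must be refitted per split below
        else:
            prepared = prepare_tw_features(epoch_tensors, tw, elbn_on=elbn_on,
                                           elbn_pooling=elbn_pooling)
            Xc, yc, metac = build_samples(prepared)
        for split in sets:
            if prepared is None:
                tensors = prepare_tw_features(
                    epoch_tensors, tw, elbn_on=True, elbn_pooling=elbn_pooling,
                    elbn_mode="causal", train_trials=split.train_trials)
                X, y, meta = build_samples(tensors)
            else:
                X, y, meta = Xc, yc, metac
            for spec in classifiers:
                try:
                    acc, per_class, cm = evaluate_split(X, y, meta, split,
                                                        spec.build())
                except Exception as err:  # surface full context
                    raise RuntimeError(
                        f"classifier {spec.name} failed at tw={tw}, "
                        f"set={split.set_id}: {err}"
                    ) from err
                rows.append({
                    "tw_length": tw,
                    "classifier": spec.name,
                    "set_id": split.set_id,
                    "accuracy": acc,
                    "acc_neg": per_class[-1],
                    "acc_neu": per_class[0],
                    "acc_pos": per_class[1],
                })
                if keep_confusions:
                    confusions[(tw, spec.name, split.set_id)] = cm
    return GridResult(per_set=pd.DataFrame(rows), confusions=confusions)


def elbn_contrast(table_without: pd.DataFrame,
                  table_with: pd.DataFrame) -> pd.DataFrame:
    """Elementwise accuracy improvement (percentage points) from ELBN."""
    if table_without.shape != table_with.shape:
        raise ValueError("accuracy tables have different shapes")
    return table_with - table_without


def improvement_argmax(improvement: pd.DataFrame):
    """(tw_length, classifier, value) of the largest improvement cell."""
    col = improvement.max().idxmax()
    row = improvement[col].idxmax()
    return row, col, float(improvement.loc[row, col])
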