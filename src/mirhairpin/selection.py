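"""Fisher F-score feature ranking and threshold selection.

For a feature with positive-class values :math:`x^+` and negative-class
values :math:`x^-`,

.. math::

    F = \\frac{(\\bar x^+ - \\bar x)^2 + (\\bar x^- - \\bar x)^2}
             {s^2_+ + s^2_-}

where :math:`\\bar x` is the pooled mean and :math:`s^2_\\pm` are the
unbiased within-class variances (the filter popularised with the LIBSVM
toolchain).  Larger is more discriminative.  When both within-class variances
vanish the score is 0 if the class means coincide (no separation) and
``inf`` otherwise (perfect separation).

Threshold selection is inclusive (``score >= threshold``): the published
compact model keeps a feature scoring exactly at the 0.60 cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .features import FEATURE_NAMES

__all__ = ["fscore", "FScoreTable", "rank_features", "select_by_threshold", "FScoreSelector"]


def fscore(values_pos, values_neg) -> float:
    """Fisher F-score of one feature between two classes (>= 2 values each)."""
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("each class needs at least 2 values")
    pooled = np.concatenate([pos, neg]).mean()
    numerator = (pos.mean() - pooled) ** 2 + (neg.mean() - pooled) ** 2
    denominator = pos.var(ddof=1) + neg.var(ddof=1)
    if denominator == 0.0:
        return 0.0 if numerator == 0.0 else math.inf
    return float(numerator / denominator)


@dataclass(frozen=True)
class FScoreTable:
    """Per-feature F-scores with a descending-score ordering.

    Ties are broken by canonical feature order, so the ordering is a
    deterministic function of the scores alone.
    """

    entries: dict[str, float]
    names: tuple[str, ...] = FEATURE_NAMES

    @property
    def ordering(self) -> list[str]:
        canonical_rank = {name: k for k, name in enumerate(self.names)}
        return sorted(self.entries, key=lambda n: (-self.entries[n], canonical_rank[n]))

    def to_frame(self) -> pd.DataFrame:
        order = self.ordering
        return pd.DataFrame(
            {"feature": order, "fscore": [self.entries[n] for n in order]}
        ).set_index("feature")


def rank_features(X, y=None, names: tuple[str, ...] = FEATURE_NAMES) -> FScoreTable:
    """F-score every feature of a labelled matrix.

    ``X``: (n, d) matrix, DataFrame (columns override ``names``), or a
    :class:`~mirhairpin.io.LabeledDataset` with extracted features (``y`` is
    then taken from its labels); ``y``: binary labels, 1/True = positive.
    """
    from .io import LabeledDataset

    if isinstance(X, LabeledDataset):
        if X.features is None:
            raise ValueError("dataset has no extracted feature matrix")
        X, y = X.features, X.y
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if X.shape[1] != len(names):
        raise ValueError(f"matrix has {X.shape[1]} columns for {len(names)} names")
    if y.all() or not y.any():
        raise ValueError("both classes must be populated")
    entries = {
        name: fscore(X[y, k], X[~y, k]) for k, name in enumerate(names)
    }
    return FScoreTable(entries=entries, names=names)


def select_by_threshold(table: FScoreTable | dict, threshold: float) -> list[str]:
    """Features scoring at or above ``threshold``, in canonical order.

    Accepts an :class:`FScoreTable` or a plain name->score mapping (scored
    against the canonical 54-feature order).
    """
    if isinstance(table, dict):
        table = FScoreTable(entries=table)
    return [n for n in table.names if table.entries.get(n, -math.inf) >= threshold]


class FScoreSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector keeping features with F-score >= ``threshold``."""

    def __init__(self, threshold: float = 0.6, feature_names=FEATURE_NAMES):
        self.threshold = threshold
        self.feature_names = feature_names

    def fit(self, X, y):
        table = rank_features(X, y, names=tuple(self.feature_names))
        self.scores_ = np.array([table.entries[n] for n in table.names])
        self.table_ = table
        self.n_features_in_ = len(table.names)
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.scores_ >= self.threshold

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        mask = self._get_support_mask()
        return np.array([n for n, keep in zip(self.table_.names, mask) if keep],
                        dtype=object)
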