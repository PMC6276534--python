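"""Mutual-information-based minimal-redundancy maximal-relevance selection.

Continuous features are discretized into equal-frequency (quantile) bins
— scale-invariant, so no standardization is needed beforehand — and
mutual information is computed by the plug-in estimator on the resulting
contingency table, in nats.  Selection is greedy forward search on the
criterion

    J(f) = I(f; c) - beta * sum_{s in S} I(f; s)

where S is the already-selected set; the default ``beta`` is 1/|S| (the
mean-redundancy "MID" scheme), step one picks the feature with maximal
relevance I(f; c), and ties are broken by column order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FeatureDataset:
    """Feature matrix, integer class labels and aligned feature names."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if y.shape != (X.shape[0],):
            raise ValueError("y must align with the rows of X")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names must align with the columns of X")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite entries")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.feature_names.index(name)]

    def subset(self, names: list[str] | tuple[str, ...]) -> "FeatureDataset":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureDataset(self.X[:, idx], self.y, tuple(names),
                              self.class_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["class"] = self.y
        return df


@dataclass(frozen=True)
class SelectionResult:
    """Greedy selection trace.

    ``order`` lists the selected feature names; ``scores[t]`` is the
    criterion value J at step t, ``redundancy[t]`` the redundancy term
    subtracted at that step, and ``relevance`` maps every feature to its
    I(f; c).
    """

    order: tuple[str, ...]
    scores: tuple[float, ...]
    redundancy: tuple[float, ...]
    relevance: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(1, len(self.order) + 1),
            "feature": list(self.order),
            "J": list(self.scores),
            "relevance": [self.relevance[f] for f in self.order],
            "redundancy": list(self.redundancy),
        })


def discretize(x: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Equal-frequency binning into at most ``n_bins`` integer codes.

    Duplicate quantile edges (heavily tied data) collapse into fewer
    bins; a constant vector yields a single code.
    """
    x = np.asarray(x, dtype=float)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="left")


def _discrete_mi(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete code vectors."""
    if a.shape != b.shape:
        raise ValueError("inputs must be aligned")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n_a = ai.max() + 1
    n_b = bi.max() + 1
    joint = np.zeros((n_a, n_b))
    np.add.at(joint, (ai, bi), 1.0)
    n = joint.sum()
    p = joint / n
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float(np.sum(p[mask] * np.log(p[mask] / (pa @ pb)[mask])))
    return max(mi, 0.0)


def mi_feature_class(x: np.ndarray, y: np.ndarray, n_bins: int = 3) -> float:
    """MI between a continuous feature (quantile-binned) and class labels."""
    x = np.asarray(x, dtype=float)
    if x.shape != np.shape(y):
        raise ValueError("x and y must be aligned")
    codes = discretize(x, n_bins)
    if codes.max() == codes.min():
        warnings.warn("constant feature: MI with class is 0")
        return 0.0
    return _discrete_mi(codes, np.asarray(y))


def mi_feature_feature(x1: np.ndarray, x2: np.ndarray,
                       n_bins: int = 3) -> float:
    """MI between two continuous features, both quantile-binned."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must be aligned")
    c1 = discretize(x1, n_bins)
    c2 = discretize(x2, n_bins)
    if c1.max() == c1.min() or c2.max() == c2.min():
        warnings.warn("constant feature: MI is 0")
        return 0.0
    return _discrete_mi(c1, c2)


def mrmr_select(ds: FeatureDataset, k: int = 5,
                beta: float | None = None, n_bins: int = 3) -> SelectionResult:
    """Greedy forward mRMR selection of ``k`` features.

    ``beta=None`` uses the mean-redundancy form 1/|S|; ``beta=0`` reduces
    to pure relevance ranking.  Ties break toward the earlier column.
    """
    if not 1 <= k <= ds.n_features:
        raise ValueError(
            f"k must be in [1, {ds.n_features}], got {k}")
    if np.unique(ds.y).size < 2:
        raise ValueError("selection needs at least 2 classes")
    names = ds.feature_names
    codes = [discretize(ds.X[:, j], n_bins) for j in range(ds.n_features)]
    y = np.asarray(ds.y)
    relevance = np.array([_discrete_mi(c, y) for c in codes])
    # pairwise feature MI, filled lazily
    pair_mi = np.full((ds.n_features, ds.n_features), np.nan)

    def pair(i: int, j: int) -> float:
        if np.isnan(pair_mi[i, j]):
            v = _discrete_mi(codes[i], codes[j])
            pair_mi[i, j] = pair_mi[j, i] = v
        return pair_mi[i, j]

    selected: list[int] = []
    scores: list[float] = []
    redundancies: list[float] = []
    remaining = list(range(ds.n_features))
    for _ in range(k):
        best_j = None
        best_score = -np.inf
        best_red = 0.0
        for j in remaining:
            if selected:
                red_sum = sum(pair(j, s) for s in selected)
                b = (1.0 / len(selected)) if beta is None else beta
                red = b * red_sum
            else:
                red = 0.0
            score = relevance[j] - red
            if score > best_score:  # strict: ties keep the earlier column
                best_score = score
                best_j = j
                best_red = red
        selected.append(best_j)
        remaining.remove(best_j)
        scores.append(float(best_score))
        redundancies.append(float(best_red))
    return SelectionResult(
        order=tuple(names[j] for j in selected),
        scores=tuple(scores),
        redundancy=tuple(redundancies),
        relevance={names[j]: float(relevance[j])
                   for j in range(ds.n_features)},
    )
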