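"""Mutual-information relevance, MaxRel ranking and the mRMR ordered list.

Continuous features are discretized into three bins at mean ± one
population standard deviation before any mutual information is computed
(the convention of the classic mRMR program).  Mutual information uses
the natural logarithm; the base only rescales scores and cannot change a
ranking.  The greedy mRMR criterion is relevance minus mean redundancy
(difference form); a quotient form is available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError


@dataclass
class DiscretizedTable:
    """Samples × features matrix of bin labels plus binary class labels."""

    bins: np.ndarray       # (m, N) int8, values in {-1, 0, +1}
    labels: np.ndarray     # (m,) int, 1 = positive, 0 = negative
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.bins.shape[0] != self.labels.shape[0]:
            raise ConfigurationError("bins and labels disagree on sample count")
        if self.bins.shape[1] != len(self.feature_names):
            raise ConfigurationError("bins and feature_names disagree on feature count")


def discretize(matrix: np.ndarray, feature_names: list[str], labels: np.ndarray) -> DiscretizedTable:
    """Three-bin μ ± σ discretization of each feature column.

    Values below μ − σ map to −1, above μ + σ to +1, otherwise 0 (so a
    constant column is all zeros).  μ and σ (population) are taken over
    all samples.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.isfinite(matrix).all():
        raise ConfigurationError("feature matrix contains non-finite values")
    mu = matrix.mean(axis=0)
    sigma = matrix.std(axis=0)
    bins = np.zeros(matrix.shape, dtype=np.int8)
    bins[matrix < mu - sigma] = -1
    bins[matrix > mu + sigma] = 1
    return DiscretizedTable(bins=bins, labels=np.asarray(labels, dtype=int), feature_names=list(feature_names))


def _mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in MI (natural log) from a joint count table."""
    total = joint.sum()
    if total == 0:
        return 0.0
    pxy = joint / total
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Empirical mutual information of two discrete vectors (nats)."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ConfigurationError("mutual_information requires two equal-length 1-D vectors")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx = xi.max() + 1
    ny = yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    return _mi_from_joint(joint)


def _mi_columns(codes: np.ndarray, y_codes: np.ndarray, n_x: int, n_y: int) -> np.ndarray:
    """MI of every column of ``codes`` against ``y_codes`` (all nonneg ints)."""
    m, n = codes.shape
    joint = np.empty((n, n_x, n_y))
    y_onehot = np.stack([(y_codes == b).astype(float) for b in range(n_y)], axis=1)  # (m, n_y)
    for a in range(n_x):
        joint[:, a, :] = ((codes == a).astype(float).T @ y_onehot)
    return np.array([_mi_from_joint(joint[j]) for j in range(n)])


@dataclass
class FeatureRanking:
    """MaxRel order (by relevance) and the greedy mRMR order."""

    feature_names: list[str]
    relevance: np.ndarray          # I(f, h) per feature, registry order
    maxrel_order: list[int]        # indices, relevance descending
    mrmr_order: list[int]          # indices, mRMR selection rounds
    mrmr_scores: list[float]       # criterion value at each selection round

    @property
    def maxrel_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.maxrel_order]

    @property
    def mrmr_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.mrmr_order]


def mrmr_rank(table: DiscretizedTable, criterion: str = "difference") -> FeatureRanking:
    """Rank features by MaxRel and by greedy mRMR.

    Round 1 selects the feature with maximum relevance I(f, h); each later
    round selects the remaining feature maximizing relevance minus the
    mean MI with the already-selected set (or relevance divided by it,
    under ``criterion="quotient"``).  Ties break toward the lower feature
    index.  Runs N rounds, producing a full ordering.
    """
    if criterion not in ("difference", "quotient"):
        raise ConfigurationError(f"unknown mRMR criterion {criterion!r}")
    m, n = table.bins.shape
    if n < 1:
        raise ConfigurationError("at least one feature required")
    codes = (table.bins + 1).astype(np.int64)          # {-1,0,1} -> {0,1,2}
    y = np.unique(table.labels, return_inverse=True)[1]
    n_y = y.max() + 1

    relevance = _mi_columns(codes, y, 3, n_y)
    maxrel_order = list(np.argsort(-relevance, kind="stable"))

    remaining = np.ones(n, dtype=bool)
    red_sum = np.zeros(n)
    mrmr_order: list[int] = []
    mrmr_scores: list[float] = []
    for round_no in range(n):
        if round_no == 0:
            score = np.where(remaining, relevance, -np.inf)
        else:
            mean_red = red_sum / round_no
            if criterion == "difference":
                score = relevance - mean_red
            else:
                score = relevance / np.maximum(mean_red, 1e-12)
            score = np.where(remaining, score, -np.inf)
        pick = int(np.argmax(score))     # first max -> lowest index on ties
        mrmr_order.append(pick)
        mrmr_scores.append(float(score[pick]))
        remaining[pick] = False
        if remaining.any():
            red_sum[remaining] += _mi_columns(
                codes[:, remaining], codes[:, pick], 3, 3
            )
    return FeatureRanking(
        feature_names=table.feature_names,
        relevance=relevance,
        maxrel_order=maxrel_order,
        mrmr_order=mrmr_order,
        mrmr_scores=mrmr_scores,
    )


def maxrel_slice(ranking: FeatureRanking, fraction: float = 0.10) -> list[str]:
    """Top ⌊fraction · N⌋ feature names of the MaxRel list."""
    if not (0 < fraction <= 1):
        raise ConfigurationError("fraction must be in (0, 1]")
    k = int(len(ranking.feature_names) * fraction)
    return ranking.maxrel_names[:k]
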