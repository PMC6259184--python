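"""Nearest-neighbor classification, jackknife cross-validation and the
incremental feature selection (IFS) loop.

The distance between two pathway feature vectors is 1 minus their cosine
similarity (the dot-product/modulus form); a true Euclidean metric is
available as a switch for sensitivity analysis.  Predictions and the
jackknife are fully deterministic: distance ties break toward the lower
sample index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError

POSITIVE, NEGATIVE = 1, 0


def distance(c1: np.ndarray, c2: np.ndarray, metric: str = "cosine") -> float:
    """Distance between two feature vectors.

    ``cosine``: 1 − c1·c2 / (‖c1‖‖c2‖), with distance 1 when either
    vector is all-zero.  ``euclidean``: the usual L2 norm of c1 − c2.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if c1.shape != c2.shape:
        raise ConfigurationError("distance requires equal-dimension vectors")
    if metric == "euclidean":
        return float(np.linalg.norm(c1 - c2))
    if metric != "cosine":
        raise ConfigurationError(f"unknown metric {metric!r}")
    n1 = np.linalg.norm(c1)
    n2 = np.linalg.norm(c2)
    if n1 == 0 or n2 == 0:
        return 1.0
    return float(1.0 - c1 @ c2 / (n1 * n2))


def _distance_matrix(a: np.ndarray, b: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise distances between rows of ``a`` and rows of ``b``."""
    if metric == "euclidean":
        aa = (a**2).sum(axis=1)[:, None]
        bb = (b**2).sum(axis=1)[None, :]
        return np.sqrt(np.maximum(aa + bb - 2 * a @ b.T, 0.0))
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = (a @ b.T) / np.outer(na, nb)
    sim[~np.isfinite(sim)] = 0.0
    return 1.0 - sim


def nn_predict(
    query: np.ndarray, train_x: np.ndarray, train_y: np.ndarray, metric: str = "cosine"
) -> int:
    """Label of the nearest training sample (ties → lower sample index)."""
    train_x = np.asarray(train_x, dtype=float)
    if train_x.shape[0] == 0:
        raise ConfigurationError("empty training set")
    dists = _distance_matrix(np.asarray(query, dtype=float)[None, :], train_x, metric)[0]
    return int(train_y[int(np.argmin(dists))])


def jackknife(
    x: np.ndarray,
    y: np.ndarray,
    feature_idx: np.ndarray | list[int] | None = None,
    metric: str = "cosine",
) -> tuple[float, float, float]:
    """Leave-one-out nearest-neighbor accuracies.

    Each sample is predicted by its nearest neighbor among all the others,
    over the restricted feature columns.  Returns (positive accuracy,
    negative accuracy, total accuracy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape[0] < 2:
        raise ConfigurationError("jackknife requires at least two samples")
    if set(np.unique(y)) != {POSITIVE, NEGATIVE}:
        raise ConfigurationError("jackknife requires both classes present")
    if feature_idx is not None:
        x = x[:, np.asarray(feature_idx, dtype=int)]
    d = _distance_matrix(x, x, metric)
    np.fill_diagonal(d, np.inf)
    pred = y[np.argmin(d, axis=1)]
    pos = y == POSITIVE
    return (
        float((pred[pos] == POSITIVE).mean()),
        float((pred[~pos] == NEGATIVE).mean()),
        float((pred == y).mean()),
    )


@dataclass
class IFSResult:
    """Per-prefix jackknife metrics along the mRMR ordering.

    ``optimal_size`` is the smallest prefix size maximizing the
    positive-class accuracy (the curve's y-axis).
    """

    prefix_sizes: np.ndarray
    positive_accuracy: np.ndarray
    negative_accuracy: np.ndarray
    total_accuracy: np.ndarray
    feature_order: list[str] = field(default_factory=list)

    @property
    def optimal_size(self) -> int:
        best = int(np.argmax(self.positive_accuracy))   # first max -> smallest prefix
        return int(self.prefix_sizes[best])

    @property
    def optimal_metrics(self) -> tuple[float, float, float]:
        i = int(np.argmax(self.positive_accuracy))
        return (
            float(self.positive_accuracy[i]),
            float(self.negative_accuracy[i]),
            float(self.total_accuracy[i]),
        )

    @property
    def optimal_features(self) -> list[str]:
        return self.feature_order[: self.optimal_size]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "prefix_size": self.prefix_sizes,
                "pos_acc": self.positive_accuracy,
                "neg_acc": self.negative_accuracy,
                "total_acc": self.total_accuracy,
            }
        )


def ifs(
    x: np.ndarray,
    y: np.ndarray,
    order: list[int],
    max_prefix: int | None = None,
    metric: str = "cosine",
    feature_names: list[str] | None = None,
) -> IFSResult:
    """Jackknife the NN classifier over growing prefixes of a feature order.

    Prefix sizes run from 1 to ``max_prefix`` (default: the full order).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    order = list(order)
    if max_prefix is None:
        max_prefix = len(order)
    max_prefix = min(max_prefix, len(order))
    if max_prefix < 1:
        raise ConfigurationError("max_prefix must be >= 1")

    rows = []
    for size in range(1, max_prefix + 1):
        rows.append(jackknife(x, y, feature_idx=order[:size], metric=metric))
    arr = np.array(rows)
    names = (
        [feature_names[i] for i in order[:max_prefix]] if feature_names is not None else []
    )
    return IFSResult(
        prefix_sizes=np.arange(1, max_prefix + 1),
        positive_accuracy=arr[:, 0],
        negative_accuracy=arr[:, 1],
        total_accuracy=arr[:, 2],
        feature_order=names,
    )
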