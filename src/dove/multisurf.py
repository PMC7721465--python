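"""MultiSURF feature scoring for a continuous endpoint.

MultiSURF is a Relief-based feature scorer.  Instead of a fixed number of
nearest neighbors it uses a per-instance dead-band: instance j is "near" i
when their distance is below mu_i - sigma_i/2, where mu_i and sigma_i are
the mean and standard deviation of i's distances to all other instances.
Distances are range-normalized Manhattan, the standard Relief choice:

    d(i, j) = mean_f |x_if - x_jf| / range(f)        (constant f contributes 0)

The classical algorithm is defined for discrete endpoints.  The continuous
adaptation used here declares a near pair (i, j) a *hit* when the responses
are close, |y_i - y_j| <= endpoint_tolerance * range(y), and a *miss*
otherwise.  Feature f's score accumulates + |x_if - x_jf| / range(f) over
miss pairs (differing on f while differing on y is evidence of relevance)
and the same quantity negatively over hit pairs, normalized by the total
number of near pairs over all instances.  Higher scores mean more relevant;
constant features score exactly 0.

``endpoint_tolerance`` defaults to 0.05 of the response range; it is a
documented design parameter of this package, not a universal constant.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["FeatureScores", "multisurf_scores", "select_top_k"]

DEFAULT_ENDPOINT_TOLERANCE = 0.05


@dataclass
class FeatureScores:
    """Per-feature relevance scores and the induced ranking.

    Ranking is by descending score; ties break by ascending feature name,
    so the order is deterministic.
    """

    scores: dict[str, float]
    ranking: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.ranking = sorted(self.scores, key=lambda f: (-self.scores[f], f))

    def top(self, k: int) -> list[str]:
        return select_top_k(self, k)


def multisurf_scores(
    X,
    y,
    endpoint_tolerance: float = DEFAULT_ENDPOINT_TOLERANCE,
    feature_names: list[str] | None = None,
) -> FeatureScores:
    """Score features of ``X`` against the continuous response ``y``.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        At least 3 instances; constant columns are allowed and score 0.
    y : (n,) array
        Continuous endpoint; must not be constant.
    endpoint_tolerance : float
        Hit threshold as a fraction of the response range.
    feature_names
        Names for array input; DataFrames use their columns.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValidationError("MultiSURF needs at least 3 instances")
    if len(feature_names) != p:
        raise ValidationError("feature_names length does not match X")
    y_range = float(np.ptp(y))
    if y_range == 0:
        raise ValidationError("constant endpoint: response range is 0")

    ranges = np.ptp(X, axis=0)
    informative = ranges > 0
    scale = np.where(informative, ranges, 1.0)  # constant cols divide by 1, diff is 0 anyway

    # Pairwise range-normalized Manhattan distances (mean over all p features).
    D = np.zeros((n, n))
    for j in range(p):
        if informative[j]:
            D += np.abs(X[:, j, None] - X[None, :, j]) / scale[j]
    D /= p
    if np.all(D == 0):
        raise ValidationError("degenerate geometry: all instances identical")

    # Per-instance neighborhood statistics over the n-1 distances to others.
    off = ~np.eye(n, dtype=bool)
    dists = D[off].reshape(n, n - 1)
    mu = dists.mean(axis=1)
    sigma = dists.std(axis=1)  # population std of i's distances
    threshold = mu - sigma / 2.0

    near = (D < threshold[:, None]) & off  # directed: j in near-set of i
    hit = np.abs(y[:, None] - y[None, :]) <= endpoint_tolerance * y_range
    weight = np.where(near, np.where(hit, -1.0, 1.0), 0.0)
    total_near = int(near.sum())

    scores = np.zeros(p)
    if total_near:
        for j in range(p):
            if informative[j]:
                diff = np.abs(X[:, j, None] - X[None, :, j]) / scale[j]
                scores[j] = float((weight * diff).sum()) / total_near
    return FeatureScores({name: float(s) for name, s in zip(feature_names, scores)})


def select_top_k(scores: FeatureScores, k: int) -> list[str]:
    """The k highest-scoring features (descending score, name breaks ties)."""
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(scores.scores):
        raise ValidationError(f"k={k} exceeds the number of features ({len(scores.scores)})")
    return scores.ranking[:k]
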