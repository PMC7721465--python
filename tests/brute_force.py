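"""Literal pair-enumeration oracle for the continuous-endpoint MultiSURF rule.

Independent of the vectorized implementation: plain Python loops over every
ordered instance pair, transcribing the scoring rule one clause at a time.
Used only by tests.
"""
import math


def brute_force_multisurf(X, y, endpoint_tolerance=0.05):
    """X: list of rows, y: list; returns list of per-feature scores."""
    n = len(X)
    p = len(X[0])
    ranges = []
    for f in range(p):
        col = [X[i][f] for i in range(n)]
        ranges.append(max(col) - min(col))
    y_range = max(y) - min(y)
    if y_range == 0:
        raise ValueError("constant endpoint")

    def diff(i, j, f):
        if ranges[f] == 0:
            return 0.0
        return abs(X[i][f] - X[j][f]) / ranges[f]

    def dist(i, j):
        return sum(diff(i, j, f) for f in range(p)) / p

    near_pairs = []
    for i in range(n):
        ds = [dist(i, j) for j in range(n) if j != i]
        mu = sum(ds) / len(ds)
        sigma = math.sqrt(sum((d - mu) ** 2 for d in ds) / len(ds))
        for j in range(n):
            if j != i and dist(i, j) < mu - sigma / 2.0:
                near_pairs.append((i, j))

    scores = [0.0] * p
    for (i, j) in near_pairs:
        hit = abs(y[i] - y[j]) <= endpoint_tolerance * y_range
        for f in range(p):
            scores[f] += -diff(i, j, f) if hit else diff(i, j, f)
    if near_pairs:
        scores = [s / len(near_pairs) for s in scores]
    return scores
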