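"""Deterministic one-dimensional two-means partitioning.

Both the DLL4-pattern binarization and the invasion-depth threshold rest on
the same primitive: split a set of scalar values into two clusters.  For
k = 2 in one dimension the optimal partition is a split of the sorted
values, so instead of iterative Lloyd updates we evaluate every sorted
split point exactly and keep the one with the smallest within-cluster sum
of squares.  This is deterministic (no initialization sensitivity) and
globally optimal.
"""

from __future__ import annotations

import numpy as np

__all__ = ["two_means_1d", "DegenerateValuesError"]


class DegenerateValuesError(ValueError):
    """All values identical (or numerically indistinguishable)."""


def two_means_1d(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Optimal 1-D 2-means: returns (labels, (low_centroid, high_centroid)).

    ``labels`` is a boolean array, True for membership in the
    higher-centroid cluster.  Raises :class:`DegenerateValuesError` if the
    values have no spread.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least two values to split")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    order = np.argsort(v, kind="stable")
    s = v[order]
    n = s.size
    if s[-1] - s[0] < 1e-9:
        raise DegenerateValuesError("values have no spread; no two-cluster split exists")

    # prefix sums give O(n) evaluation of all n-1 sorted splits
    c1 = np.cumsum(s)
    c2 = np.cumsum(s * s)
    k = np.arange(1, n)  # size of the lower cluster
    lo_mean = c1[:-1] / k
    hi_mean = (c1[-1] - c1[:-1]) / (n - k)
    # within-cluster SSE = sum(x^2) - n_c * mean_c^2, summed over clusters
    sse = c2[-1] - k * lo_mean**2 - (n - k) * hi_mean**2
    best = int(np.argmin(sse))

    labels = np.zeros(n, dtype=bool)
    labels[order[best + 1:]] = True
    return labels.reshape(np.asarray(values).shape), (float(lo_mean[best]), float(hi_mean[best]))
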