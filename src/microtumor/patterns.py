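"""Classification of equilibrium DLL4 patterns.

Two qualitative outcomes matter: the lateral-inhibition *checkerboard*
(isolated DLL4-high cells, each surrounded by NOTCH1-high neighbours) and
*DLL4 clusters* (connected patches of DLL4-high cells).  The readouts are

* a binarized DLL4-high mask (deterministic two-means split of the
  equilibrium DLL4 levels),
* the checkerboard score — the fraction of first-ring adjacent cell pairs
  in which both cells are DLL4-high (0 for a perfect checkerboard), and
* the connected-component size distribution of the mask under periodic
  8-connectivity, whose maximum is the cluster-transition readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cluster1d import DegenerateValuesError, two_means_1d

__all__ = [
    "PatternSummary",
    "binarize_dll4",
    "checkerboard_score",
    "cluster_sizes",
    "summarize_pattern",
]

# directed half of the 8-neighbour offsets: each undirected adjacent pair
# is counted exactly once when rolling over these
_HALF_RING1 = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class PatternSummary:
    dll4_high_mask: np.ndarray
    fraction_high: float
    checkerboard_score: float
    cluster_sizes: list[int]
    max_cluster: int
    mean_D_high: float
    mean_D_all: float
    degenerate: bool = False
    seed: int | None = None
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "fraction_high": self.fraction_high,
            "checkerboard_score": self.checkerboard_score,
            "cluster_sizes": list(map(int, self.cluster_sizes)),
            "max_cluster": int(self.max_cluster),
            "mean_D_high": self.mean_D_high,
            "mean_D_all": self.mean_D_all,
            "degenerate": self.degenerate,
            "seed": self.seed,
            "converged": self.converged,
            "dll4_high_mask": np.asarray(self.dll4_high_mask, dtype=int).tolist(),
        }


def binarize_dll4(D: np.ndarray) -> tuple[np.ndarray, bool]:
    """Split DLL4 levels into high/low by deterministic 1-D two-means.

    Returns ``(mask, degenerate)``.  A field with spread below 1e-9 has no
    meaningful split; it is flagged degenerate and all cells are low.
    """
    D = np.asarray(D, dtype=float)
    if D.size == 0:
        raise ValueError("empty DLL4 grid")
    if not np.all(np.isfinite(D)):
        raise ValueError("DLL4 grid contains non-finite values")
    try:
        labels, _ = two_means_1d(D)
    except DegenerateValuesError:
        return np.zeros(D.shape, dtype=bool), True
    return labels, False


def checkerboard_score(mask: np.ndarray) -> float:
    """Fraction of first-ring adjacent pairs (periodic) with both cells high.

    0 exactly when the high set is independent under 8-neighbour adjacency
    (a perfect checkerboard); 1 when every cell is high.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    both = 0
    for di, dj in _HALF_RING1:
        both += int((m & np.roll(np.roll(m, di, axis=0), dj, axis=1)).sum())
    total = 4 * m.size
    return both / total


def cluster_sizes(mask: np.ndarray) -> list[int]:
    """Connected-component sizes of the high mask under periodic
    8-connectivity, sorted descending.  Sizes sum to the high-cell count.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not m.any():
        return []
    labeled, n_lab = ndimage.label(m, structure=np.ones((3, 3), dtype=int))

    # merge components that touch across the periodic seams (union-find)
    parent = np.arange(n_lab + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    rows, cols = m.shape
    for di, dj in _HALF_RING1:
        shifted = np.roll(np.roll(labeled, di, axis=0), dj, axis=1)
        pairs = m & np.roll(np.roll(m, di, axis=0), dj, axis=1)
        for a, b in zip(labeled[pairs].ravel(), shifted[pairs].ravel()):
            union(int(a), int(b))

    roots = np.array([find(lab) for lab in range(n_lab + 1)])
    merged = roots[labeled]
    sizes = np.bincount(merged.ravel())[1:]
    sizes = sizes[sizes > 0]
    return sorted((int(s) for s in sizes), reverse=True)


def summarize_pattern(
    D: np.ndarray, seed: int | None = None, converged: bool = True
) -> PatternSummary:
    """Full pattern readout of an equilibrium DLL4 field."""
    D = np.asarray(D, dtype=float)
    mask, degenerate = binarize_dll4(D)
    sizes = cluster_sizes(mask)
    n_high = int(mask.sum())
    return PatternSummary(
        dll4_high_mask=mask,
        fraction_high=n_high / mask.size,
        checkerboard_score=checkerboard_score(mask),
        cluster_sizes=sizes,
        max_cluster=max(sizes) if sizes else 0,
        mean_D_high=float(D[mask].mean()) if n_high else 0.0,
        mean_D_all=float(D.mean()),
        degenerate=degenerate,
        seed=seed,
        converged=converged,
    )
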