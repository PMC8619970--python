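"""Replicate phase sweep over mean NOTCH1 production rate and variation.

For every grid point (mean R_N, sigma) the sweep runs at least five
independently seeded simulations — fresh R_N draws and fresh initial
noise — integrates each to equilibrium and summarizes the DLL4 pattern.
The transition readout is the median over replicates of the largest
DLL4-high cluster: 1 in the checkerboard phase, growing once variation
breaks the mosaic into clusters.  ``critical_sigma`` extracts, per mean
rate, the smallest variation at which that median reaches a cluster-size
threshold; this onset moves to larger sigma as the mean rate grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import generate_lattice_init
from .heterogeneity import HeterogeneitySpec, sample_production_rates
from .lattice import (
    CellField,
    KineticParams,
    LatticeConfig,
    build_neighborhood,
    integrate,
)
from .patterns import PatternSummary, summarize_pattern

__all__ = ["PhaseGrid", "run_sweep", "critical_sigma", "MIN_REPLICATES"]

#: replicate floor: a grid cell is only trusted with at least five
#: independent simulations
MIN_REPLICATES = 5

DEFAULT_R_AXIS = (1.0, 1.5, 2.0, 3.0)
DEFAULT_SIGMA_AXIS = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8)


@dataclass
class PhaseGrid:
    r_axis: tuple[float, ...]
    sigma_axis: tuple[float, ...]
    cells: list[list[list[PatternSummary]]]  # [i_r][i_sigma][replicate]

    def __post_init__(self):
        r = np.asarray(self.r_axis)
        s = np.asarray(self.sigma_axis)
        if len(r) == 0 or len(s) == 0:
            raise ValueError("axes must be non-empty")
        if np.any(np.diff(r) <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("axes must be strictly increasing")
        for row in self.cells:
            for cell in row:
                if len(cell) < MIN_REPLICATES:
                    raise ValueError(
                        f"every grid cell needs at least {MIN_REPLICATES} replicates"
                    )

    def median_max_cluster(self) -> np.ndarray:
        """(len(r_axis), len(sigma_axis)) array of replicate medians."""
        return np.array(
            [[float(np.median([p.max_cluster for p in cell])) for cell in row]
             for row in self.cells]
        )

    def mean_dll4(self, high_only: bool = False) -> np.ndarray:
        """Replicate-averaged DLL4 level per grid cell (the gray-scale
        transition-map analogue); ``high_only`` restricts to DLL4-high cells."""
        attr = "mean_D_high" if high_only else "mean_D_all"
        return np.array(
            [[float(np.mean([getattr(p, attr) for p in cell])) for cell in row]
             for row in self.cells]
        )

    def to_dict(self) -> dict:
        return {
            "r_axis": list(self.r_axis),
            "sigma_axis": list(self.sigma_axis),
            "cells": [[[p.to_dict() for p in cell] for cell in row]
                      for row in self.cells],
        }


def _replicate_seeds(base_seed: int, i: int, j: int, rep: int) -> tuple[int, int]:
    """Deterministic per-replicate seeds (rates, initial field)."""
    ss = np.random.SeedSequence((int(base_seed), i, j, rep))
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


def run_sweep(
    r_axis=DEFAULT_R_AXIS,
    sigma_axis=DEFAULT_SIGMA_AXIS,
    replicates: int = MIN_REPLICATES,
    config: LatticeConfig | None = None,
    params: KineticParams | None = None,
    base_seed: int = 0,
    dt: float = 0.05,
    tol: float = 1e-6,
    max_steps: int = 200_000,
) -> PhaseGrid:
    """Run the full replicate sweep; deterministic given ``base_seed``.

    A simulation that fails to converge within ``max_steps`` is recorded
    with ``converged=False`` rather than aborting the sweep.
    """
    if replicates < MIN_REPLICATES:
        raise ValueError(
            f"replicates must be >= {MIN_REPLICATES}, got {replicates}"
        )
    config = config if config is not None else LatticeConfig()
    params = params if params is not None else KineticParams()
    contacts = build_neighborhood(config)

    cells: list[list[list[PatternSummary]]] = []
    for i, r in enumerate(r_axis):
        row: list[list[list]] = []
        for j, sigma in enumerate(sigma_axis):
            reps: list[PatternSummary] = []
            for rep in range(replicates):
                seed_rates, seed_init = _replicate_seeds(base_seed, i, j, rep)
                spec = HeterogeneitySpec(R_N_mean=float(r), sigma=float(sigma),
                                         seed=seed_rates)
                rates = sample_production_rates(spec, config.n_cells)
                init = generate_lattice_init(config, seed_init)
                field_ = CellField(init.N, init.D, rates.reshape(config.shape))
                result = integrate(field_, params, config, dt=dt, tol=tol,
                                   max_steps=max_steps, contacts=contacts)
                summary = summarize_pattern(result.final_field.D,
                                            seed=seed_rates,
                                            converged=result.converged)
                reps.append(summary)
            row.append(reps)
        cells.append(row)
    return PhaseGrid(r_axis=tuple(r_axis), sigma_axis=tuple(sigma_axis), cells=cells)


def critical_sigma(grid: PhaseGrid, cluster_threshold: int = 3) -> list[float | None]:
    """Smallest sigma per mean rate at which the replicate-median largest
    cluster reaches ``cluster_threshold``; None where no sigma on the grid
    triggers the transition."""
    medians = grid.median_max_cluster()
    out: list[float | None] = []
    for i in range(len(grid.r_axis)):
        hit = np.nonzero(medians[i] >= cluster_threshold)[0]
        out.append(float(grid.sigma_axis[hit[0]]) if hit.size else None)
    return out
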