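"""NOTCH1–DLL4 lateral-inhibition dynamics on a periodic square lattice.

Each lattice site is one cell of a microtumor carrying a NOTCH1 level ``N``
and a DLL4 level ``D``.  Cells signal juxtacrinely: a cell's NOTCH1
production is activated (Hill kinetics) by the DLL4 presented by the cells
it touches, while its own DLL4 production is repressed by its NOTCH1
activity.  Receptor and ligand expressed in the same cell mutually
inactivate each other (cis-inhibition), modelled as a bilinear ``N·D`` sink
on both species.  Contact extends over the first and second Moore rings of
the lattice (8 + 16 cells) because filopodial protrusions reach past
immediate neighbours; the second ring contributes with a reduced weight.

The homogeneous steady state of these dynamics is unstable in the default
parameter regime, so small random perturbations grow into the classic
lateral-inhibition mosaic: isolated DLL4-high cells surrounded by
NOTCH1-high cells.  Per-cell variation of the maximum NOTCH1 production
rate ``R_N`` (see :mod:`microtumor.heterogeneity`) can break that mosaic
into DLL4-high clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LatticeConfig",
    "KineticParams",
    "CellField",
    "SimulationResult",
    "Neighborhood",
    "RingAliasingError",
    "DivergenceError",
    "build_neighborhood",
    "neighbor_signal",
    "derivatives",
    "integrate",
    "integrate_pair",
]


class RingAliasingError(ValueError):
    """Lattice too small for distinct first and second contact rings."""


class DivergenceError(RuntimeError):
    """Integration produced a non-finite state."""

    def __init__(self, step: int):
        super().__init__(f"non-finite state at integration step {step}")
        self.step = step


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and contact weights of the periodic cell lattice.

    ``w1`` and ``w2`` weight the DLL4 contribution of first-ring
    (touching) and second-ring (filopodial) contacts.  The second ring
    is kept at half the first-ring weight by default.
    """

    rows: int = 16
    cols: int = 16
    w1: float = 1.0
    w2: float = 0.25
    periodic: bool = True

    def __post_init__(self):
        if self.rows < 5 or self.cols < 5:
            raise RingAliasingError(
                f"lattice must be at least 5x5 so the two contact rings do not "
                f"alias under wrap-around, got {self.rows}x{self.cols}"
            )
        if not self.w1 > 0:
            raise ValueError("w1 must be positive")
        if self.w2 < 0:
            raise ValueError("w2 must be non-negative")
        if not self.periodic:
            raise ValueError("only periodic boundaries are supported")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the production/degradation/cis-inhibition ODEs.

    Concentrations and rates are in arbitrary units; degradation rates set
    the time scale.  ``K_act``/``h_act`` govern activation of NOTCH1
    production by neighbour DLL4, ``K_rep``/``h_rep`` the repression of
    DLL4 production by own NOTCH1, and ``k_cis`` the bilinear
    cis-inhibition sink.  Defaults are calibrated so that a uniform-``R_N``
    lattice settles into a checkerboard (every DLL4-high cell isolated).
    """

    R_D: float = 1.0
    gamma_N: float = 1.0
    gamma_D: float = 1.0
    k_cis: float = 0.1
    K_act: float = 0.1
    h_act: float = 4.0
    K_rep: float = 0.3
    h_rep: float = 4.0

    def __post_init__(self):
        for name in ("R_D", "gamma_N", "gamma_D", "K_act", "K_rep"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.h_act < 1 or self.h_rep < 1:
            raise ValueError("Hill exponents must be >= 1")
        if self.k_cis < 0:
            raise ValueError("k_cis must be non-negative")


@dataclass
class CellField:
    """Per-cell state: NOTCH1 ``N``, DLL4 ``D`` and the maximum NOTCH1
    production rate ``R_N_cell`` (the heterogeneity variable)."""

    N: np.ndarray
    D: np.ndarray
    R_N_cell: np.ndarray

    def __post_init__(self):
        self.N = np.asarray(self.N, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.R_N_cell = np.asarray(self.R_N_cell, dtype=float)
        if not (self.N.shape == self.D.shape == self.R_N_cell.shape):
            raise ValueError("N, D and R_N_cell must share the lattice shape")
        for name, grid in (("N", self.N), ("D", self.D), ("R_N_cell", self.R_N_cell)):
            if np.any(grid < 0):
                raise ValueError(f"{name} must be non-negative everywhere")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.N.shape

    def copy(self) -> "CellField":
        return CellField(self.N.copy(), self.D.copy(), self.R_N_cell.copy())


@dataclass
class SimulationResult:
    final_field: CellField
    steps_taken: int
    residual: float
    converged: bool


@dataclass(frozen=True)
class Neighborhood:
    """Flat-index contact lists: ``ring1[i]`` holds the 8 first-ring and
    ``ring2[i]`` the 16 second-ring neighbours of cell ``i``."""

    ring1: np.ndarray
    ring2: np.ndarray
    config: LatticeConfig = field(repr=False)


def _ring_offsets(r: int) -> list[tuple[int, int]]:
    return [
        (di, dj)
        for di in range(-r, r + 1)
        for dj in range(-r, r + 1)
        if max(abs(di), abs(dj)) == r
    ]


def build_neighborhood(config: LatticeConfig) -> Neighborhood:
    """Precompute periodic first- and second-ring (Moore) contact indices.

    Every cell has exactly 8 first-ring and 16 second-ring contacts; the
    relation is symmetric because ring offsets come in ± pairs.
    """
    rows, cols = config.rows, config.cols
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rings = []
    for r in (1, 2):
        offs = _ring_offsets(r)
        cols_idx = np.empty((rows * cols, len(offs)), dtype=np.intp)
        for k, (di, dj) in enumerate(offs):
            cols_idx[:, k] = (((ii + di) % rows) * cols + (jj + dj) % cols).ravel()
        rings.append(cols_idx)
    return Neighborhood(ring1=rings[0], ring2=rings[1], config=config)


def neighbor_signal(
    D: np.ndarray, contacts: Neighborhood, config: LatticeConfig | None = None
) -> np.ndarray:
    """Weighted mean DLL4 presented to each cell by its contacts.

    ``Dbar_i = (w1 * sum(D, ring1) + w2 * sum(D, ring2)) / (8 w1 + 16 w2)``.
    """
    cfg = config if config is not None else contacts.config
    D = np.asarray(D, dtype=float)
    if D.size != contacts.ring1.shape[0]:
        raise ValueError(
            f"field size {D.size} does not match contact structure "
            f"({contacts.ring1.shape[0]} cells)"
        )
    flat = D.ravel()
    wsum = 8.0 * cfg.w1 + 16.0 * cfg.w2
    dbar = (cfg.w1 * flat[contacts.ring1].sum(axis=1)
            + cfg.w2 * flat[contacts.ring2].sum(axis=1)) / wsum
    return dbar.reshape(D.shape)


def _hill_act(x: np.ndarray, K: float, h: float) -> np.ndarray:
    xh = np.power(x, h)
    return xh / (K**h + xh)


def _hill_rep(x: np.ndarray, K: float, h: float) -> np.ndarray:
    Kh = K**h
    return Kh / (Kh + np.power(x, h))


def derivatives(
    field: CellField, params: KineticParams, dbar: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the per-cell ODEs given the contact signal ``dbar``.

    dN/dt = R_N,i * Hill+(Dbar) - gamma_N * N - k_cis * N * D
    dD/dt = R_D   * Hill-(N)    - gamma_D * D - k_cis * N * D
    """
    N, D = field.N, field.D
    if np.any(N < 0) or np.any(D < 0):
        raise ValueError("state must be non-negative")
    cis = params.k_cis * N * D
    dN = field.R_N_cell * _hill_act(dbar, params.K_act, params.h_act) - params.gamma_N * N - cis
    dD = params.R_D * _hill_rep(N, params.K_rep, params.h_rep) - params.gamma_D * D - cis
    return dN, dD


def integrate(
    field: CellField,
    params: KineticParams,
    config: LatticeConfig,
    dt: float = 0.05,
    tol: float = 1e-6,
    max_steps: int = 200_000,
    contacts: Neighborhood | None = None,
) -> SimulationResult:
    """Integrate the lattice ODEs with fixed-step RK4 to equilibrium.

    Terminates when the max-norm of the time derivative drops below
    ``tol`` (an equilibrium pattern) or after ``max_steps`` steps.  The
    scheme is deterministic: identical inputs give bit-identical results.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if field.N.shape != config.shape:
        raise ValueError("field shape does not match lattice config")
    if contacts is None:
        contacts = build_neighborhood(config)

    N = field.N.ravel().copy()
    D = field.D.ravel().copy()
    R_N = field.R_N_cell.ravel()
    w1, w2 = config.w1, config.w2
    wsum = 8.0 * w1 + 16.0 * w2
    r1, r2 = contacts.ring1, contacts.ring2
    Ka, ha = params.K_act, params.h_act
    Kr, hr = params.K_rep, params.h_rep
    Krh = Kr**hr
    gN, gD, RD, kc = params.gamma_N, params.gamma_D, params.R_D, params.k_cis

    def rhs(N, D):
        # overflow in a diverging run produces non-finite values that the
        # step loop detects; silence the intermediate warnings
        with np.errstate(over="ignore", invalid="ignore"):
            dbar = (w1 * D[r1].sum(axis=1) + w2 * D[r2].sum(axis=1)) / wsum
            dbh = np.power(dbar, ha)
            cis = kc * N * D
            dN = R_N * dbh / (Ka**ha + dbh) - gN * N - cis
            dD = RD * Krh / (Krh + np.power(N, hr)) - gD * D - cis
        return dN, dD

    steps = 0
    k1n, k1d = rhs(N, D)
    residual = max(np.abs(k1n).max(), np.abs(k1d).max(), 0.0)
    if not np.isfinite(residual):
        raise DivergenceError(steps)
    while residual >= tol and steps < max_steps:
        k2n, k2d = rhs(N + 0.5 * dt * k1n, D + 0.5 * dt * k1d)
        k3n, k3d = rhs(N + 0.5 * dt * k2n, D + 0.5 * dt * k2d)
        k4n, k4d = rhs(N + dt * k3n, D + dt * k3d)
        N = N + (dt / 6.0) * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
        D = D + (dt / 6.0) * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)
        steps += 1
        if not (np.all(np.isfinite(N)) and np.all(np.isfinite(D))):
            raise DivergenceError(steps)
        k1n, k1d = rhs(N, D)
        residual = max(np.abs(k1n).max(), np.abs(k1d).max())
        if not np.isfinite(residual):
            raise DivergenceError(steps)

    shape = config.shape
    out = CellField(N.reshape(shape), D.reshape(shape), field.R_N_cell.copy())
    return SimulationResult(
        final_field=out,
        steps_taken=steps,
        residual=float(residual),
        converged=bool(residual < tol),
    )


def integrate_pair(
    params: KineticParams,
    n_init: tuple[float, float],
    d_init: tuple[float, float],
    r_n: tuple[float, float] = (2.0, 2.0),
    dt: float = 0.05,
    tol: float = 1e-9,
    max_steps: int = 500_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Two mutually-contacting cells: each cell's contact signal is the
    other cell's DLL4.  The minimal system exhibiting lateral-inhibition
    bistability — a small initial asymmetry resolves into one DLL4-high /
    NOTCH1-low cell and one DLL4-low / NOTCH1-high cell.
    Returns the equilibrium ``(N, D)`` arrays of length 2.
    """
    N = np.asarray(n_init, dtype=float).copy()
    D = np.asarray(d_init, dtype=float).copy()
    R_N = np.asarray(r_n, dtype=float)
    swap = np.array([1, 0])

    def rhs(N, D):
        dbar = D[swap]
        cis = params.k_cis * N * D
        dN = R_N * _hill_act(dbar, params.K_act, params.h_act) - params.gamma_N * N - cis
        dD = params.R_D * _hill_rep(N, params.K_rep, params.h_rep) - params.gamma_D * D - cis
        return dN, dD

    for step in range(max_steps):
        k1n, k1d = rhs(N, D)
        if max(np.abs(k1n).max(), np.abs(k1d).max()) < tol:
            break
        k2n, k2d = rhs(N + 0.5 * dt * k1n, D + 0.5 * dt * k1d)
        k3n, k3d = rhs(N + 0.5 * dt * k2n, D + 0.5 * dt * k2d)
        k4n, k4d = rhs(N + dt * k3n, D + dt * k3d)
        N = N + (dt / 6.0) * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
        D = D + (dt / 6.0) * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)
        if not (np.all(np.isfinite(N)) and np.all(np.isfinite(D))):
            raise DivergenceError(step + 1)
    return N, D
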