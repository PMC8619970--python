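import numpy as np
import pytest

from microtumor import (
    CellField,
    KineticParams,
    LatticeConfig,
    generate_lattice_init,
    integrate,
)


@pytest.fixture(scope="session")
def default_params():
    return KineticParams()


@pytest.fixture(scope="session")
def small_config():
    return LatticeConfig(rows=8, cols=8)


@pytest.fixture(scope="session")
def converged_8x8(small_config, default_params):
    """One 8x8 simulation at uniform R_N integrated to equilibrium."""
    init = generate_lattice_init(small_config, seed=11)
    field = CellField(init.N, init.D, np.full(small_config.shape, 2.0))
    return integrate(field, default_params, small_config)


def naive_reference_step(N, D, R_N, params, config, dt):
    """Slow per-cell RK4 step used as the vectorization oracle.

    Loops over every cell and enumerates its Moore rings by modular
    arithmetic; shares no code with the lattice implementation.
    """
    rows, cols = config.shape

    def rhs(N, D):
        dN = np.empty_like(N)
        dD = np.empty_like(D)
        for i in range(rows):
            for j in range(cols):
                s1 = 0.0
                s2 = 0.0
                for di in range(-2, 3):
                    for dj in range(-2, 3):
                        ring = max(abs(di), abs(dj))
                        if ring == 0:
                            continue
                        val = D[(i + di) % rows, (j + dj) % cols]
                        if ring == 1:
                            s1 += val
                        else:
                            s2 += val
                dbar = (config.w1 * s1 + config.w2 * s2) / (
                    8 * config.w1 + 16 * config.w2
                )
                act = dbar**params.h_act / (params.K_act**params.h_act + dbar**params.h_act)
                rep = params.K_rep**params.h_rep / (
                    params.K_rep**params.h_rep + N[i, j] ** params.h_rep
                )
                cis = params.k_cis * N[i, j] * D[i, j]
                dN[i, j] = R_N[i, j] * act - params.gamma_N * N[i, j] - cis
                dD[i, j] = params.R_D * rep - params.gamma_D * D[i, j] - cis
        return dN, dD

    k1n, k1d = rhs(N, D)
    k2n, k2d = rhs(N + 0.5 * dt * k1n, D + 0.5 * dt * k1d)
    k3n, k3d = rhs(N + 0.5 * dt * k2n, D + 0.5 * dt * k2d)
    k4n, k4d = rhs(N + dt * k3n, D + dt * k3d)
    N2 = N + dt / 6.0 * (k1n + 2 * k2n + 2 * k3n + k4n)
    D2 = D + dt / 6.0 * (k1d + 2 * k2d + 2 * k3d + k4d)
    return N2, D2
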