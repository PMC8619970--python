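"""Lattice geometry, ODE right-hand side and integrator behavior."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from microtumor import (
    CellField,
    KineticParams,
    LatticeConfig,
    build_neighborhood,
    derivatives,
    generate_lattice_init,
    integrate,
    integrate_pair,
    neighbor_signal,
)
from microtumor.lattice import DivergenceError, RingAliasingError

from conftest import naive_reference_step


class TestNeighborhood:
    @pytest.mark.parametrize("rows,cols", [(8, 8), (16, 16), (5, 9)])
    def test_ring_cardinalities(self, rows, cols):
        cfg = LatticeConfig(rows=rows, cols=cols)
        nb = build_neighborhood(cfg)
        assert nb.ring1.shape == (rows * cols, 8)
        assert nb.ring2.shape == (rows * cols, 16)
        # no duplicates within a cell's rings, and the two rings are disjoint
        for i in range(rows * cols):
            contacts = np.concatenate([nb.ring1[i], nb.ring2[i]])
            assert len(set(contacts.tolist())) == 24
            assert i not in contacts

    def test_symmetry(self):
        cfg = LatticeConfig(rows=6, cols=7)
        nb = build_neighborhood(cfg)
        for ring in (nb.ring1, nb.ring2):
            for i in range(cfg.n_cells):
                for j in ring[i]:
                    assert i in ring[j]

    def test_too_small_lattice_raises(self):
        with pytest.raises(RingAliasingError):
            LatticeConfig(rows=4, cols=8)


class TestNeighborSignal:
    def test_uniform_field_is_fixed_point_of_averaging(self):
        cfg = LatticeConfig(rows=8, cols=8)
        nb = build_neighborhood(cfg)
        dbar = neighbor_signal(np.full(cfg.shape, 0.7), nb)
        assert np.allclose(dbar, 0.7, atol=1e-15)
        assert np.all(neighbor_signal(np.zeros(cfg.shape), nb) == 0)

    def test_single_source_weight_sum(self):
        # one cell with D=1 in a zero background, w1=1, w2=0.5:
        # first-ring neighbors see 1/(8*1 + 16*0.5) = 0.0625
        cfg = LatticeConfig(rows=8, cols=8, w1=1.0, w2=0.5)
        nb = build_neighborhood(cfg)
        D = np.zeros(cfg.shape)
        D[3, 3] = 1.0
        dbar = neighbor_signal(D, nb)
        assert dbar[3, 4] == pytest.approx(0.0625)
        assert dbar[2, 2] == pytest.approx(0.0625)
        # second-ring neighbors see w2/(8 w1 + 16 w2)
        assert dbar[3, 5] == pytest.approx(0.5 / 16.0)
        assert dbar[3, 3] == 0.0

    def test_signal_bounded_by_field_range(self):
        cfg = LatticeConfig(rows=6, cols=6)
        nb = build_neighborhood(cfg)
        rng = np.random.default_rng(0)
        D = rng.uniform(0.2, 1.7, cfg.shape)
        dbar = neighbor_signal(D, nb)
        assert dbar.min() >= D.min() - 1e-12
        assert dbar.max() <= D.max() + 1e-12


class TestDerivatives:
    def test_origin_values(self, default_params):
        cfg = LatticeConfig(rows=5, cols=5)
        f = CellField(np.zeros(cfg.shape), np.zeros(cfg.shape), np.full(cfg.shape, 2.0))
        dN, dD = derivatives(f, default_params, np.zeros(cfg.shape))
        assert np.all(dN == 0.0)
        assert np.allclose(dD, default_params.R_D)

    def test_negative_state_rejected(self, default_params):
        cfg = LatticeConfig(rows=5, cols=5)
        with pytest.raises(ValueError):
            CellField(np.full(cfg.shape, -0.1), np.zeros(cfg.shape), np.ones(cfg.shape))

    def test_converged_field_has_small_derivatives(self, converged_8x8,
                                                   default_params, small_config):
        assert converged_8x8.converged
        nb = build_neighborhood(small_config)
        dbar = neighbor_signal(converged_8x8.final_field.D, nb)
        dN, dD = derivatives(converged_8x8.final_field, default_params, dbar)
        assert max(np.abs(dN).max(), np.abs(dD).max()) < 1e-6

    def test_two_cell_fixed_point_matches_root_finder(self, default_params):
        """Independent oracle: solve the 4-dim algebraic system directly."""
        p = default_params
        r_n = (2.0, 2.0)

        def system(x):
            n1, d1, n2, d2 = x
            out = []
            for (n, d, dbar, rn) in ((n1, d1, d2, r_n[0]), (n2, d2, d1, r_n[1])):
                act = dbar**p.h_act / (p.K_act**p.h_act + dbar**p.h_act)
                rep = p.K_rep**p.h_rep / (p.K_rep**p.h_rep + n**p.h_rep)
                out.append(rn * act - p.gamma_N * n - p.k_cis * n * d)
                out.append(p.R_D * rep - p.gamma_D * d - p.k_cis * n * d)
            return out

        N, D = integrate_pair(p, (0.02, 0.0), (0.0, 0.02), r_n=r_n)
        root = fsolve(system, [N[0], D[0], N[1], D[1]], full_output=False)
        assert np.max(np.abs(system(root))) < 1e-8
        # the integrator landed on the same equilibrium the root finder refines
        assert np.allclose([N[0], D[0], N[1], D[1]], root, atol=1e-6)


class TestIntegrate:
    def test_uniform_initial_state_stays_uniform(self, default_params):
        cfg = LatticeConfig(rows=6, cols=6)
        f = CellField(np.full(cfg.shape, 0.05), np.full(cfg.shape, 0.07),
                      np.full(cfg.shape, 2.0))
        res = integrate(f, default_params, cfg, tol=1e-300, max_steps=1000)
        # symmetry of the dynamics: spatial uniformity is exactly preserved
        assert np.ptp(res.final_field.N) == 0.0
        assert np.ptp(res.final_field.D) == 0.0

    def test_states_remain_nonnegative(self, converged_8x8):
        assert res_min(converged_8x8) >= 0.0

    def test_step_halving_oracle(self, default_params):
        """Fine-step integration reproduces the dt=0.05 equilibrium."""
        cfg = LatticeConfig(rows=8, cols=8)
        init = generate_lattice_init(cfg, seed=5)
        f = CellField(init.N, init.D, np.full(cfg.shape, 2.0))
        coarse = integrate(f, default_params, cfg, dt=0.05)
        fine = integrate(f, default_params, cfg, dt=0.005)
        assert coarse.converged and fine.converged
        scale = np.abs(fine.final_field.D).max()
        assert np.abs(coarse.final_field.D - fine.final_field.D).max() / scale < 1e-6
        assert np.abs(coarse.final_field.N - fine.final_field.N).max() / scale < 1e-6

    def test_matches_naive_per_cell_loop(self, default_params):
        """Vectorized integration equals a per-cell Python loop, 100 steps."""
        cfg = LatticeConfig(rows=5, cols=5)
        rng = np.random.default_rng(3)
        N = rng.uniform(0, 0.1, cfg.shape)
        D = rng.uniform(0, 0.1, cfg.shape)
        R_N = rng.uniform(1.0, 3.0, cfg.shape)
        dt = 0.05

        Nn, Dn = N.copy(), D.copy()
        for _ in range(100):
            Nn, Dn = naive_reference_step(Nn, Dn, R_N, default_params, cfg, dt)

        res = integrate(CellField(N, D, R_N), default_params, cfg,
                        dt=dt, tol=1e-300, max_steps=100)
        assert res.steps_taken == 100
        assert np.abs(res.final_field.N - Nn).max() < 1e-12
        assert np.abs(res.final_field.D - Dn).max() < 1e-12

    def test_bit_reproducible(self, default_params):
        cfg = LatticeConfig(rows=8, cols=8)
        init = generate_lattice_init(cfg, seed=9)
        f = CellField(init.N, init.D, np.full(cfg.shape, 2.0))
        a = integrate(f, default_params, cfg)
        b = integrate(f, default_params, cfg)
        assert np.array_equal(a.final_field.N, b.final_field.N)
        assert np.array_equal(a.final_field.D, b.final_field.D)
        assert a.steps_taken == b.steps_taken

    def test_divergence_reports_step(self):
        # an enormous step size blows the scheme up quickly
        cfg = LatticeConfig(rows=5, cols=5)
        params = KineticParams(R_D=1e3)
        init = generate_lattice_init(cfg, seed=1)
        f = CellField(init.N, init.D, np.full(cfg.shape, 1e3))
        with pytest.raises(DivergenceError) as exc:
            integrate(f, params, cfg, dt=1e6, tol=1e-300, max_steps=1000)
        assert exc.value.step >= 1

    def test_invalid_controls_rejected(self, default_params, small_config):
        init = generate_lattice_init(small_config, seed=0)
        f = CellField(init.N, init.D, np.ones(small_config.shape))
        with pytest.raises(ValueError):
            integrate(f, default_params, small_config, dt=0.0)
        with pytest.raises(ValueError):
            integrate(f, default_params, small_config, tol=-1.0)


class TestTwoCellLateralInhibition:
    def test_asymmetry_resolves_and_mirrors(self, default_params):
        N, D = integrate_pair(default_params, (0.01, 0.0), (0.0, 0.01))
        # cell 0 wins the NOTCH1 fate, cell 1 the DLL4 fate
        assert N[0] > 10 * N[1]
        assert D[1] > 10 * D[0]
        Nm, Dm = integrate_pair(default_params, (0.0, 0.01), (0.01, 0.0))
        assert np.array_equal(N, Nm[::-1])
        assert np.array_equal(D, Dm[::-1])


def res_min(result):
    return min(result.final_field.N.min(), result.final_field.D.min())
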