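"""Steady-state solvers against independent oracles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

import wusham as wm
from wusham.core import SPECIES, ModelState, model_rhs
from wusham.equilibrium import (
    SolverError,
    SolverSettings,
    gene_equilibrium,
    newton_dimer_equilibrium,
    solve_diffusion_equilibrium,
)

from _oracles import full_system_jacobian, integrate_to_steady_state


class TestDiffusionEquilibrium:
    def test_zero_production_gives_zero(self, template10):
        out = solve_diffusion_equilibrium(
            np.zeros(template10.n_cells), 0.0, 1.0, 1.0, template10
        )
        np.testing.assert_array_equal(out, 0.0)

    def test_isolated_cell_scalar_balance(self):
        t = wm.build_1d_template(2)
        # disconnect the two cells: scalar balance p/(g + D*S) per cell
        t.neighbor_weights = t.neighbor_weights * 0.0
        out = solve_diffusion_equilibrium(np.ones(2), 2.0, 0.5, 1.0, t)
        np.testing.assert_allclose(out, [2.0 / (0.5 + 1.0), 2.0 / 0.5])

    def test_singular_system_raises(self):
        t = wm.build_1d_template(5)
        t.S = np.zeros(5, dtype=int)  # no sink, no degradation: singular
        with pytest.raises(SolverError):
            solve_diffusion_equilibrium(t.L.astype(float), 1.0, 0.0, 1.0, t)

    def test_matches_stiff_integration(self, template10):
        """Sparse solve vs long-time integration of the same linear ODE."""
        t = template10
        p_, g_, D_ = 1.2, 0.15, 0.8
        x = solve_diffusion_equilibrium(t.L.astype(float), p_, g_, D_, t)

        M = wm.core.transport_matrix(t, D_).toarray() - g_ * np.eye(t.n_cells)

        def rhs(_t, y):
            return p_ * t.L + M @ y

        y_inf = integrate_to_steady_state(rhs, np.zeros(t.n_cells))
        np.testing.assert_allclose(x, y_inf, atol=1e-8 * max(1, x.max()))


class TestNewtonDimer:
    def test_no_ham_decouples(self, template10, default_params):
        W = np.ones(template10.n_cells)
        H = np.zeros(template10.n_cells)
        w, h, d = newton_dimer_equilibrium(W, H, default_params, template10)
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(d, 0.0)
        expected = solve_diffusion_equilibrium(
            W, default_params.p_w, default_params.g_w, default_params.D_w,
            template10,
        )
        np.testing.assert_allclose(w, expected, atol=1e-9)

    def test_single_cell_matches_bisection_oracle(self, default_params):
        """On one isolated cell the steady state reduces to a scalar root."""
        t = wm.build_1d_template(2)
        t.neighbor_weights = t.neighbor_weights * 0.0
        t.S = np.zeros(2, dtype=int)
        p = default_params.copy(p_w=1.0, p_h=0.7, g_w=0.9, g_h=1.1,
                                f=2.0, b=0.3, g_d=0.5)
        W = np.array([1.0, 1.0])
        H = np.array([0.8, 0.8])
        w, h, d = newton_dimer_equilibrium(W, H, p, t)

        # scalar oracle: eliminate h and d, bisect on w
        def residual(wv):
            # at steady state: d = f h w/(g_d + b); and
            # p_h H - g_h h - f h w + b d = 0 -> h = p_h H/(g_h + f w g_d/(g_d+b))
            hv = p.p_h * H[0] / (p.g_h + p.f * wv * p.g_d / (p.g_d + p.b))
            dv = p.f * hv * wv / (p.g_d + p.b)
            return p.p_w * W[0] - p.g_w * wv - p.f * hv * wv + p.b * dv

        w_star = bisect(residual, 1e-12, 1e6, xtol=1e-13)
        np.testing.assert_allclose(w[0], w_star, rtol=1e-8)

    def test_matches_integration_oracle(self, template10, default_params):
        rng = np.random.default_rng(2)
        n = template10.n_cells
        W = rng.uniform(0.1, 2.0, n)
        H = rng.uniform(0.1, 2.0, n)
        p = default_params.copy(f=1.7, b=0.4, g_d=0.6, D_d=0.2)
        w, h, d = newton_dimer_equilibrium(W, H, p, template10)

        st0 = ModelState.zeros(n)

        def rhs(_t, y):
            st = ModelState.zeros(n)
            st.W, st.H = W, H
            st.w = np.maximum(y[:n], 0)
            st.h = np.maximum(y[n:2 * n], 0)
            st.d = np.maximum(y[2 * n:], 0)
            r = model_rhs(st, p, template10)
            return np.concatenate([r.w, r.h, r.d])

        y_inf = integrate_to_steady_state(rhs, np.zeros(3 * n), t_end=5000.0)
        scale = max(w.max(), h.max(), d.max())
        np.testing.assert_allclose(
            np.concatenate([w, h, d]), y_inf, atol=1e-6 * scale, rtol=1e-6
        )


class TestFullEquilibrium:
    def test_open_loop_composition_when_no_clv3(self, template10, default_params):
        """V_C = 0 removes the feedback: the state is the staged composition."""
        p = default_params.copy(V_C=0.0)
        st = wm.full_equilibrium(p, template10)
        L = template10.L.astype(float)
        L_c = solve_diffusion_equilibrium(L, p.p_Lc, p.g_Lc, p.D_Lc, template10)
        L_a = solve_diffusion_equilibrium(L, p.p_La, p.g_La, p.D_La, template10)
        W0 = gene_equilibrium(
            [(L_c, p.k_LcW, p.n_LcW)], [(L_a, p.k_LaW, p.n_LaW)],
            p.V_W, p.g_W, template10.n_cells,
        )
        np.testing.assert_allclose(st.W, W0, rtol=1e-12)
        np.testing.assert_array_equal(st.C, 0.0)

    def test_printed_stopping_criterion_reached(self, template10, default_params):
        st = wm.full_equilibrium(default_params, template10)
        r = model_rhs(st, default_params, template10)
        signed = float(r.w.sum() + r.h.sum() + r.d.sum() + r.c.sum())
        assert abs(signed) <= 1e-10

    def test_matches_full_system_integration(self, optimized10, template10):
        """Relaxation equilibrium vs stiff integration of all ten species."""
        p = optimized10.params
        st = wm.full_equilibrium(p, template10)
        n = template10.n_cells

        def rhs(_t, y):
            state = ModelState.from_vector(np.maximum(y, 0.0), n)
            return model_rhs(state, p, template10).to_vector()

        # start from the composed open-loop sub-equilibria (the clavata
        # state), the same entry point the relaxation uses
        y = wm.full_equilibrium(
            p.copy(clv3_feedback=False), template10
        ).to_vector()
        jac = full_system_jacobian(template10, p)
        t_end = 1e5
        for _ in range(6):
            y = integrate_to_steady_state(
                rhs, y, t_end=t_end, rtol=1e-8, atol=1e-10, jac=jac,
            )
            if np.abs(rhs(0.0, y)).max() < 1e-7 * max(1.0, y.max()):
                break
            t_end *= 10
        ref = ModelState.from_vector(np.maximum(y, 0.0), n)
        scale = st.to_vector().max()
        np.testing.assert_allclose(
            st.to_vector(), ref.to_vector(), atol=1e-5 * scale, rtol=1e-5
        )

    def test_feedback_reduces_total_wus(self, template10, default_params):
        with_fb = wm.full_equilibrium(default_params, template10)
        without = wm.full_equilibrium(
            default_params.copy(clv3_feedback=False), template10
        )
        assert with_fb.W.sum() <= without.W.sum() + 1e-9

    def test_deterministic(self, template10, default_params):
        a = wm.full_equilibrium(default_params, template10)
        b = wm.full_equilibrium(default_params, template10)
        assert np.array_equal(a.to_vector(), b.to_vector())

    def test_homodimer_variant_equilibrium(self, template10, default_params):
        """The WUS-WUS homodimer variant reaches equilibrium with the HAM
        species identically zero and a non-trivial dimer field."""
        p = default_params.copy(variant="homodimer")
        st = wm.full_equilibrium(p, template10)
        np.testing.assert_array_equal(st.H, 0.0)
        np.testing.assert_array_equal(st.h, 0.0)
        assert st.d.sum() > 0
        assert st.W.sum() > 0

    def test_state_round_trip(self, template10, default_params, tmp_path):
        st = wm.full_equilibrium(default_params, template10)
        path = tmp_path / "state.tsv"
        st.save(path)
        back = ModelState.load(path)
        np.testing.assert_allclose(back.to_vector(), st.to_vector())
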