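"""Shared oracle helpers: stiff integration of the model equations.

The integration oracles deliberately re-derive nothing from the equilibrium
solvers: they step the model's right-hand side with an implicit integrator.
Only the *sparsity pattern* of the Jacobian is provided (BDF then
finite-differences the entries in grouped columns), which keeps the oracle
numerically independent while avoiding dense 10n x 10n factorisations.
"""

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from wusham.core import SPECIES, laplacian_matrix


def integrate_to_steady_state(rhs, y0, t_end=2000.0, rtol=1e-12, atol=1e-13,
                              jac=None, jac_sparsity=None):
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="BDF", rtol=rtol, atol=atol,
                    jac=jac, jac_sparsity=jac_sparsity)
    assert sol.success
    return sol.y[:, -1]


def full_system_sparsity(template) -> sp.csr_matrix:
    """Structural Jacobian of the ten-species system (blocks of n_cells)."""
    n = template.n_cells
    lap = (laplacian_matrix(template) != 0) + sp.identity(n, format="csr")
    eye = sp.identity(n, format="csr")
    zero = sp.csr_matrix((n, n))
    idx = {s: i for i, s in enumerate(SPECIES)}
    blocks = [[zero] * len(SPECIES) for _ in SPECIES]

    def dep(row, col, pattern):
        blocks[idx[row]][idx[col]] = pattern

    dep("W", "W", eye)
    for reg in ("L_c", "L_a", "c", "w", "d"):  # incl. variant couplings
        dep("W", reg, eye)
    dep("H", "H", eye)
    dep("H", "L_H", eye)
    dep("C", "C", eye)
    dep("C", "w", eye)
    dep("C", "d", eye)
    dep("w", "W", eye)
    dep("w", "w", lap)
    dep("w", "h", eye)
    dep("w", "d", eye)
    dep("h", "H", eye)
    dep("h", "h", lap)
    dep("h", "w", eye)
    dep("h", "d", eye)
    dep("d", "d", lap)
    dep("d", "w", eye)
    dep("d", "h", eye)
    dep("c", "C", eye)
    dep("c", "c", lap)
    dep("L_c", "L_c", lap)
    dep("L_a", "L_a", lap)
    dep("L_H", "L_H", lap)
    return sp.bmat(blocks, format="csr")


def full_system_jacobian(template, params):
    """Analytic Jacobian of the ten-species right-hand side at a state.

    Returns a callable ``jac(t, y) -> sparse matrix`` for implicit
    integrators. Derivatives are re-derived from the model equations here,
    independently of the package's adjoint machinery.
    """
    import wusham.core as core

    n = template.n_cells
    p = params
    lap = laplacian_matrix(template)
    S = sp.diags(template.S.astype(float))
    eye = sp.identity(n, format="csr")
    zero = sp.csr_matrix((n, n))

    def T(D, name):
        sink = zero if name in p.sink_free_species else D * S
        return D * lap - sink

    Tw, Th, Td, Tc = T(p.D_w, "w"), T(p.D_h, "h"), T(p.D_d, "d"), T(p.D_c, "c")
    TLc, TLa, TLH = T(p.D_Lc, "L_c"), T(p.D_La, "L_a"), T(p.D_LH, "L_H")

    def act(x, k, nn):
        a = core.hill_activation(x, k, nn)
        with np.errstate(divide="ignore", invalid="ignore"):
            da = np.where(x > 0, nn * a * (1 - a) / np.maximum(x, 1e-300), 0.0)
        return a, da

    def rep(x, k, nn):
        r = core.hill_repression(x, k, nn)
        with np.errstate(divide="ignore", invalid="ignore"):
            dr = np.where(x > 0, -nn * r * (1 - r) / np.maximum(x, 1e-300), 0.0)
        return r, dr

    idx = {s: i for i, s in enumerate(SPECIES)}

    def jac(_t, y):
        blocks = [[zero] * len(SPECIES) for _ in SPECIES]
        st = {s: np.maximum(y[i * n:(i + 1) * n], 0.0)
              for i, s in enumerate(SPECIES)}

        def D(row, col, val):
            blocks[idx[row]][idx[col]] = (
                sp.diags(val) if isinstance(val, np.ndarray) else val
            )

        aLc, daLc = act(st["L_c"], p.k_LcW, p.n_LcW)
        rLa, drLa = rep(st["L_a"], p.k_LaW, p.n_LaW)
        rc, drc = rep(st["c"], p.k_c, p.n_c)
        D("W", "W", -p.g_W * np.ones(n))
        D("W", "L_c", p.V_W * daLc * rLa * rc)
        D("W", "L_a", p.V_W * aLc * drLa * rc)
        D("W", "c", p.V_W * aLc * rLa * drc)
        rLH, drLH = rep(st["L_H"], p.k_LH, p.n_LH)
        D("H", "H", -p.g_H * np.ones(n))
        D("H", "L_H", p.V_H * drLH)
        den = 1.0 + p.k_w * st["w"] + p.k_d * st["d"]
        D("C", "C", -p.g_C * np.ones(n))
        D("C", "w", p.V_C * p.k_w * (1 + p.k_d * st["d"]) / den**2)
        D("C", "d", -p.V_C * p.k_w * st["w"] * p.k_d / den**2)
        D("w", "W", p.p_w * np.ones(n))
        D("w", "w", Tw - sp.diags(p.g_w + p.f * st["h"]))
        D("w", "h", -p.f * st["w"])
        D("w", "d", p.b * np.ones(n))
        D("h", "H", p.p_h * np.ones(n))
        D("h", "h", Th - sp.diags(p.g_h + p.f * st["w"]))
        D("h", "w", -p.f * st["h"])
        D("h", "d", p.b * np.ones(n))
        D("d", "d", Td - (p.g_d + p.b) * eye)
        D("d", "w", p.f * st["h"])
        D("d", "h", p.f * st["w"])
        D("c", "C", p.p_c * np.ones(n))
        D("c", "c", Tc - p.g_c * eye)
        D("L_c", "L_c", TLc - p.g_Lc * eye)
        D("L_a", "L_a", TLa - p.g_La * eye)
        D("L_H", "L_H", TLH - p.g_LH * eye)
        return sp.bmat(blocks, format="csc")

    return jac
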