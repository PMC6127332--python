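"""Analytic gradients of the stage cost functions.

Every stage cost is a smooth composition of (a) sparse linear solves for
diffusing species, (b) elementwise Hill / Shea-Ackers kinetics and (c) the
Newton solution of the monomer/dimer subsystem.  The gradient with respect
to the optimised parameters is assembled by the adjoint method:

* linear solve ``x = A(g, D)^-1 (p P)`` with ``A = g I - D T1`` (``T1`` the
  unit-rate transport operator): given the downstream sensitivity ``v =
  dE/dx``, the adjoint ``lam = A^-T v`` yields ``dE/dp = lam . P``,
  ``dE/dg = -lam . x`` and ``dE/dD = lam . (T1 x)``.
* implicit Newton solution ``F(x, theta) = 0``: with ``lam = J^-T dE/dx``,
  ``dE/dtheta = -lam . dF/dtheta``.

Gradients are returned with respect to log10-parameters, matching the
optimiser's search space.  Finite-difference checks live in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse.linalg as spla

import scipy.sparse as sp

from .core import hill_activation, hill_repression, transport_matrix
from .equilibrium import _dimer_jacobian, newton_dimer_equilibrium
from .parameters import STAGE_PARAMS


def _solve_T(A, v):
    return spla.spsolve(A.T.tocsc(), v)


class _LinSolve:
    """One diffusing-species equilibrium with its adjoint bookkeeping."""

    def __init__(self, P, p, g, D, template, sink_free=False):
        self.P = np.asarray(P, dtype=float)
        self.p, self.g, self.D = p, g, D
        n = template.n_cells
        self.T1 = transport_matrix(template, 1.0, sink_free=sink_free)
        self.A = (sp.identity(n) * g - D * self.T1).tocsc()
        self.x = np.maximum(spla.spsolve(self.A, p * self.P), 0.0)

    def grads(self, v):
        """dE/d(p, g, D) given the sensitivity v = dE/dx."""
        lam = _solve_T(self.A, v)
        return (
            float(lam @ self.P),
            float(-(lam @ self.x)),
            float(lam @ (self.T1 @ self.x)),
        )


def _act_terms(x, k, n):
    """Activation a = x^n/(x^n+k^n) with da/dx and da/dk."""
    a = hill_activation(x, k, n)
    core = a * (1.0 - a)
    with np.errstate(divide="ignore", invalid="ignore"):
        da_dx = np.where(x > 0, n * core / np.maximum(x, 1e-300), 0.0)
    da_dk = -n * core / k
    return a, da_dx, da_dk


def _rep_terms(x, k, n):
    """Repression r = k^n/(x^n+k^n) with dr/dx and dr/dk."""
    r = hill_repression(x, k, n)
    core = r * (1.0 - r)
    with np.errstate(divide="ignore", invalid="ignore"):
        dr_dx = np.where(x > 0, -n * core / np.maximum(x, 1e-300), 0.0)
    dr_dk = n * core / k
    return r, dr_dx, dr_dk


def _to_log10(grads, names, params):
    out = np.zeros(len(names))
    ln10 = math.log(10.0)
    for i, name in enumerate(names):
        out[i] = grads.get(name, 0.0) * getattr(params, name) * ln10
    return out


def stage_w1_value_and_grad(theta, params, template, targets):
    names = STAGE_PARAMS[1]
    p = params.copy(**{n: 10.0 ** t for n, t in zip(names, theta)})
    L = template.L.astype(float)
    sc = _LinSolve(L, p.p_Lc, p.g_Lc, p.D_Lc, template)
    sa = _LinSolve(L, p.p_La, p.g_La, p.D_La, template)
    a, da_dx, da_dk = _act_terms(sc.x, p.k_LcW, p.n_LcW)
    r, dr_dx, dr_dk = _rep_terms(sa.x, p.k_LaW, p.n_LaW)
    scale = p.V_W / p.g_W
    W1 = scale * a * r
    resid = W1 - 1.5 * targets.W_t
    E = float(np.sum(resid**2))
    u = 2.0 * resid * scale
    g = {
        "k_LcW": float(np.sum(u * r * da_dk)),
        "k_LaW": float(np.sum(u * a * dr_dk)),
    }
    g["p_Lc"], g["g_Lc"], g["D_Lc"] = sc.grads(u * r * da_dx)
    g["p_La"], g["g_La"], g["D_La"] = sa.grads(u * a * dr_dx)
    return E, _to_log10(g, names, p), {"W": W1, "p": p}


def stage_w2_value_and_grad(theta, params, template, targets, W1):
    names = STAGE_PARAMS[2]
    p = params.copy(**{n: 10.0 ** t for n, t in zip(names, theta)})
    ct_solve = _LinSolve(
        targets.C_t.astype(float), p.p_c, 1.0, p.D_c, template
    )  # g_c = 1 fixed in this stage
    c_t = ct_solve.x
    r, dr_dx, dr_dk = _rep_terms(c_t, p.k_c, p.n_c)
    W = W1 * r
    resid = W - targets.W_t
    E = float(np.sum(resid**2))
    u = 2.0 * resid * W1
    g = {"k_c": float(np.sum(u * dr_dk))}
    g["p_c"], _, g["D_c"] = ct_solve.grads(u * dr_dx)
    return E, _to_log10(g, names, p), {"W": W, "c_t": c_t, "p": p}


def stage_c_value_and_grad(theta, params, template, targets, C4):
    names = STAGE_PARAMS[5]
    p = params.copy(**{n: 10.0 ** t for n, t in zip(names, theta)})
    solve = _LinSolve(C4, p.p_c, p.g_c, p.D_c, template,
                      sink_free="c" in p.sink_free_species)
    resid = solve.x - targets.c_t
    E = float(np.sum(resid**2))
    g = {}
    g["p_c"], g["g_c"], g["D_c"] = solve.grads(2.0 * resid)
    return E, _to_log10(g, names, p), {"c": solve.x, "p": p}


class _NewtonBlock:
    """One (w, h, d) equilibrium at given RNA fields, with its adjoint."""

    def __init__(self, W, H, p, template, solver, x0, pw_factor=1.0, ham=False):
        self.p_eff = p.copy(p_w=p.p_w * pw_factor, p_h=0.0 if ham else p.p_h)
        self.pw_factor = pw_factor
        self.ham = ham
        self.W, self.H = W, H
        self.w, self.h, self.d = newton_dimer_equilibrium(
            W, H, self.p_eff, template, solver, x0=x0
        )
        Tw = transport_matrix(template, self.p_eff.D_w,
                              sink_free="w" in p.sink_free_species)
        Th = transport_matrix(template, self.p_eff.D_h,
                              sink_free="h" in p.sink_free_species)
        Td = transport_matrix(template, self.p_eff.D_d,
                              sink_free="d" in p.sink_free_species)
        self.T1w = transport_matrix(template, 1.0,
                                    sink_free="w" in p.sink_free_species)
        self.T1h = transport_matrix(template, 1.0,
                                    sink_free="h" in p.sink_free_species)
        self.T1d = transport_matrix(template, 1.0,
                                    sink_free="d" in p.sink_free_species)
        self.J = _dimer_jacobian(
            self.w, self.h, self.d, self.p_eff, Tw, Th, Td, homo=False
        )

    def accumulate(self, Ew, Eh, Ed, g, p):
        """Add -lam . dF/dtheta for every free parameter; returns dE/dH."""
        n = len(self.w)
        lam = _solve_T(self.J, np.concatenate([Ew, Eh, Ed]))
        lw, lh, ld = lam[:n], lam[n: 2 * n], lam[2 * n:]
        w, h, d = self.w, self.h, self.d
        wh = w * h
        g["p_w"] = g.get("p_w", 0.0) - self.pw_factor * float(lw @ self.W)
        g["g_w"] = g.get("g_w", 0.0) + float(lw @ w)
        g["D_w"] = g.get("D_w", 0.0) - float(lw @ (self.T1w @ w))
        if not self.ham:
            g["p_h"] = g.get("p_h", 0.0) - float(lh @ self.H)
        g["g_h"] = g.get("g_h", 0.0) + float(lh @ h)
        g["D_h"] = g.get("D_h", 0.0) - float(lh @ (self.T1h @ h))
        g["g_d"] = g.get("g_d", 0.0) + float(ld @ d)
        g["D_d"] = g.get("D_d", 0.0) - float(ld @ (self.T1d @ d))
        g["f"] = g.get("f", 0.0) + float((lw + lh - ld) @ wh)
        g["b"] = g.get("b", 0.0) - float((lw + lh - ld) @ d)
        # dE/dH: F_h carries the production p_h * H
        if self.ham:
            return np.zeros(n)
        return -self.p_eff.p_h * lh


def _clv3_terms(w, d, p):
    """C and its partial derivatives with respect to w, d, k_w, k_d, V_C."""
    den = 1.0 + p.k_w * w + p.k_d * d
    C = (p.V_C / p.g_C) * p.k_w * w / den
    dC_dw = (p.V_C / p.g_C) * p.k_w * (1.0 + p.k_d * d) / den**2
    dC_dd = -(p.V_C / p.g_C) * p.k_w * w * p.k_d / den**2
    dC_dkw = (p.V_C / p.g_C) * w * (1.0 + p.k_d * d) / den**2
    dC_dkd = -(p.V_C / p.g_C) * p.k_w * w * d / den**2
    dC_dVC = C / p.V_C if p.V_C > 0 else np.zeros_like(C)
    return C, dC_dw, dC_dd, dC_dkw, dC_dkd, dC_dVC


def stage_ch_value_and_grad(
    stage, theta, params, template, targets, W2, solver, guesses=None,
    omega=0.08, omega1=0.04, omega2=0.2,
):
    """Value and gradient of E_CH1 or E_CH2 over the 16 stage parameters."""
    names = STAGE_PARAMS[3]
    p = params.copy(**{n: 10.0 ** t for n, t in zip(names, theta)})
    L = template.L.astype(float)
    lh_solve = _LinSolve(L, p.p_LH, p.g_LH, p.D_LH, template)
    L_H = lh_solve.x
    rH, drH_dx, drH_dk = _rep_terms(L_H, p.k_LH, p.n_LH)
    Hscale = p.V_H / p.g_H
    H = Hscale * rH
    guesses = guesses or {}
    wt = _NewtonBlock(W2, H, p, template, solver, guesses.get("wt"))
    C = _clv3_terms(wt.w, wt.d, p)[0]
    g: dict = {}
    dE_dH = np.zeros(template.n_cells)

    if stage == "CH1":
        residC = C - targets.C_t
        residH = H - targets.H_t
        E = float(np.sum(residC**2) + omega * np.sum(residH**2))
        uC = 2.0 * residC
        dE_dH += 2.0 * omega * residH
        blocks = [(wt, uC)]
        extras = {"C": C, "H": H}
    else:
        cl = _NewtonBlock(W2, H, p, template, solver,
                          guesses.get("cl") or (wt.w, wt.h, wt.d),
                          pw_factor=1.5)
        hm = _NewtonBlock(W2, H, p, template, solver, guesses.get("hm"),
                          ham=True)
        C_c = _clv3_terms(cl.w, cl.d, p)[0]
        C_h = _clv3_terms(hm.w, hm.d, p)[0]
        sum_C = float(np.sum(C))
        if sum_C <= 0:
            raise FloatingPointError("zero total CLV3 in E_CH2")
        ratio = float(np.sum(C_c)) / sum_C
        residC = C - targets.C_t
        residH = H - targets.H_t
        ham_resid = W2 - C_h
        ham_sq = max(float(np.sum(ham_resid**2)), 1e-30)
        E = float(
            np.sum(residC**2) + omega1 * np.sum(residH**2)
            + omega2 * (ratio - 1.5) ** 2 + math.log(ham_sq)
        )
        uC = 2.0 * residC - 2.0 * omega2 * (ratio - 1.5) * ratio / sum_C
        uCc = np.full_like(C, 2.0 * omega2 * (ratio - 1.5) / sum_C)
        uCh = -2.0 * ham_resid / ham_sq
        dE_dH += 2.0 * omega1 * residH
        blocks = [(wt, uC), (cl, uCc), (hm, uCh)]
        extras = {"C": C, "H": H, "C_c": C_c, "C_h": C_h}

    for block, u in blocks:
        Cb, dCw, dCd, dCkw, dCkd, dCVC = _clv3_terms(block.w, block.d, p)
        g["k_w"] = g.get("k_w", 0.0) + float(u @ dCkw)
        g["k_d"] = g.get("k_d", 0.0) + float(u @ dCkd)
        g["V_C"] = g.get("V_C", 0.0) + float(u @ dCVC)
        dE_dH += block.accumulate(u * dCw, np.zeros_like(u), u * dCd, g, p)

    # chain through H = (V_H/g_H) rep(L_H)
    g["k_LH"] = float(np.sum(dE_dH * Hscale * drH_dk))
    v_LH = dE_dH * Hscale * drH_dx
    g["p_LH"], g["g_LH"], g["D_LH"] = lh_solve.grads(v_LH)

    guesses_out = {"wt": (wt.w, wt.h, wt.d)}
    if stage == "CH2":
        guesses_out["cl"] = (cl.w, cl.h, cl.d)
        guesses_out["hm"] = (hm.w, hm.h, hm.d)
    return E, _to_log10(g, names, p), extras, guesses_out
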