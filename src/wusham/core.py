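"""Reaction kinetics and transport for the ten-species SAM network.

Species, per cell: three RNAs (*W* WUS, *H* HAM, *C* CLV3), WUS and HAM
monomer proteins (*w*, *h*), the HAM-WUS heterodimer (*d*), the CLV3 peptide
(*c*) and three epidermis-produced morphogens (*L_c* cytokinin proxy, *L_a*
AHK-repressor proxy, *L_H* HAM repressor).

Transcription uses Hill kinetics for WUS and HAM and a Shea-Ackers promoter
(single site bound by WUS monomers as activators or HAM-WUS dimers as
competitive non-productive binders) for CLV3.  Transport is a discrete
Laplacian on the cell graph; in the sink cells every diffusing species takes
an extra degradation equal to its diffusion rate, abstracting flux into the
stem.  The mirror (symmetry) boundary gives each axis cell a phantom
neighbour -- the reflection of its inward neighbour -- so symmetric fields
behave exactly as on the full mirrored tissue and a constant field has a
zero Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .parameters import ModelParameters
from .templates import TissueTemplate

SPECIES = ("W", "H", "C", "w", "h", "d", "c", "L_c", "L_a", "L_H")

#: species that diffuse (RNAs are cell-autonomous)
DIFFUSING = ("w", "h", "d", "c", "L_c", "L_a", "L_H")


@dataclass
class ModelState:
    """Per-cell concentration vectors of the ten species."""

    W: np.ndarray
    H: np.ndarray
    C: np.ndarray
    w: np.ndarray
    h: np.ndarray
    d: np.ndarray
    c: np.ndarray
    L_c: np.ndarray
    L_a: np.ndarray
    L_H: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.W.shape[0]

    @classmethod
    def zeros(cls, n: int) -> "ModelState":
        return cls(**{s: np.zeros(n) for s in SPECIES})

    def to_vector(self) -> np.ndarray:
        """Concatenate species blocks in the frozen (W,H,C,w,h,d,c,L_c,L_a,L_H) order."""
        return np.concatenate([getattr(self, s) for s in SPECIES])

    @classmethod
    def from_vector(cls, v: np.ndarray, n: int) -> "ModelState":
        blocks = v.reshape(len(SPECIES), n)
        return cls(**{s: blocks[i].copy() for i, s in enumerate(SPECIES)})

    def copy(self) -> "ModelState":
        return ModelState(**{s: getattr(self, s).copy() for s in SPECIES})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({s: getattr(self, s) for s in SPECIES})
        df.insert(0, "cell", np.arange(self.n_cells))
        return df

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ModelState":
        df = pd.read_csv(path, sep="\t")
        return cls(**{s: df[s].to_numpy(dtype=float) for s in SPECIES})


# ---------------------------------------------------------------------------
# gene expression


def _pow_ratio(num: np.ndarray, den: float, n: float) -> np.ndarray:
    """(num/den)**n computed in log space; overflow-safe for large n."""
    num = np.asarray(num, dtype=float)
    out = np.zeros_like(num)
    pos = num > 0
    with np.errstate(over="ignore"):
        out[pos] = np.exp(np.clip(n * (np.log(num[pos]) - np.log(den)), -700, 700))
    return out


def hill_activation(A: np.ndarray, k: float, n: float) -> np.ndarray:
    """A^n / (A^n + k^n), elementwise; 0 where A == 0."""
    x = _pow_ratio(A, k, n)
    return x / (1.0 + x)


def hill_repression(I: np.ndarray, k: float, n: float) -> np.ndarray:
    """k^n / (I^n + k^n), elementwise; 1 where I == 0."""
    x = _pow_ratio(I, k, n)
    return 1.0 / (1.0 + x)


def hill_gene_production(
    activators: list[tuple[np.ndarray, float, float]],
    inhibitors: list[tuple[np.ndarray, float, float]],
    V: float,
) -> np.ndarray:
    """Hill-regulated production rate V * prod(act) * prod(rep).

    Each regulator is a ``(concentration_vector, k, n)`` triple with Hill
    constant ``k > 0`` and coefficient ``n > 0``.  Empty regulator lists
    contribute a factor of one, so with no regulators the production is the
    constant ``V``.
    """
    vecs = [a[0] for a in activators] + [i[0] for i in inhibitors]
    for v in vecs:
        if np.any(np.asarray(v) < 0):
            raise ValueError("negative regulator concentration")
    for _, k, n in activators + inhibitors:
        if k <= 0 or n <= 0:
            raise ValueError("Hill constants and coefficients must be positive")
    n_cells = len(vecs[0]) if vecs else 1
    out = np.full(n_cells, float(V))
    for A, k, n in activators:
        out = out * hill_activation(np.asarray(A, dtype=float), k, n)
    for I, k, n in inhibitors:
        out = out * hill_repression(np.asarray(I, dtype=float), k, n)
    return out


def shea_ackers_clv3(w: np.ndarray, d: np.ndarray, params: ModelParameters) -> np.ndarray:
    """CLV3 production V_C * k_w w / (1 + k_w w + k_d d), elementwise."""
    w = np.asarray(w, dtype=float)
    d = np.asarray(d, dtype=float)
    if np.any(w < 0) or np.any(d < 0):
        raise ValueError("negative concentrations in Shea-Ackers promoter")
    return params.V_C * params.k_w * w / (1.0 + params.k_w * w + params.k_d * d)


# ---------------------------------------------------------------------------
# transport


def laplacian_matrix(template: TissueTemplate) -> sp.csr_matrix:
    """Graph Laplacian L with (L x)_i = sum_j w_ij (x_j - x_i).

    For 1D/2D templates the weights are unit adjacency; a mirror-boundary
    cell additionally exchanges with the reflection of its inward neighbour
    (an extra copy of the (1, y) edge).  For 3D templates the volume-scaled
    contact-surface form ``(1/V_i) sum_j C_ij (x_j - x_i)`` is used.
    """
    cached = getattr(template, "_laplacian", None)
    if cached is not None:
        return cached
    W = template.neighbor_weights
    rowsum = np.asarray(W.sum(axis=1)).ravel()
    lap = (W - sp.diags(rowsum)).tolil()
    if template.kind == "3d":
        lap = (sp.diags(1.0 / template.volumes) @ lap.tocsr()).tocsr()
    else:
        # mirror boundary: the phantom neighbour of an axis cell reflects
        # the (1, y) neighbour, so its exchange term duplicates that edge
        partner = template.mirror_partner
        for k in np.flatnonzero(partner >= 0):
            m = partner[k]
            lap[k, m] += 1.0
            lap[k, k] -= 1.0
        lap = lap.tocsr()
    # templates are treated as immutable once built
    object.__setattr__(template, "_laplacian", lap)
    return lap


def transport_operator(x: np.ndarray, D: float, template: TissueTemplate) -> np.ndarray:
    """Diffusive exchange D * (Laplacian x); sink degradation not included."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != template.n_cells:
        raise ValueError("state vector length does not match the template")
    return D * (laplacian_matrix(template) @ x)


def transport_matrix(
    template: TissueTemplate, D: float, sink_free: bool = False
) -> sp.csr_matrix:
    """Full linear transport operator D*Laplacian - D*diag(S).

    ``sink_free=True`` drops the sink degradation (no-flux lower boundary).
    """
    M = D * laplacian_matrix(template)
    if not sink_free:
        M = M - D * sp.diags(template.S.astype(float))
    return M.tocsr()


# ---------------------------------------------------------------------------
# full right-hand side


def wus_production(
    state: ModelState, params: ModelParameters, include_feedback: bool | None = None
) -> np.ndarray:
    """WUS transcription rate under the active variant flags."""
    if params.pclv3_wus:
        # WUS driven by the CLV3 promoter (pCLV3::WUS mutant)
        return params.V_W * params.k_w * state.w / (
            1.0 + params.k_w * state.w + params.k_d * state.d
        )
    if include_feedback is None:
        include_feedback = params.clv3_feedback
    inhibitors = [(state.L_a, params.k_LaW, params.n_LaW)]
    if include_feedback:
        inhibitors.append((state.c, params.k_c, params.n_c))
    return hill_gene_production(
        [(state.L_c, params.k_LcW, params.n_LcW)], inhibitors, params.V_W
    )


def model_rhs(
    state: ModelState, params: ModelParameters, template: TissueTemplate
) -> ModelState:
    """Time derivatives of all ten species (eight for the homodimer variant).

    In the ``homodimer`` variant the HAM equations are removed (H and h stay
    identically zero) and the dimer is the WUS-WUS homodimer with association
    flux ``f w^2``.
    """
    for s in SPECIES:
        v = getattr(state, s)
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise ValueError(f"state species {s} contains negative or non-finite values")
    n = template.n_cells
    lap = laplacian_matrix(template)
    S = template.S.astype(float)
    Lmask = template.L.astype(float)
    p = params
    free = set(p.sink_free_species)

    def tr(x, D, name):
        sink = 0.0 if name in free else D * S * x
        return D * (lap @ x) - sink

    homo = p.variant == "homodimer"
    dW = wus_production(state, p) - p.g_W * state.W
    dC = shea_ackers_clv3(state.w, state.d, p) - p.g_C * state.C
    if homo:
        dH = np.zeros(n)
        dh = np.zeros(n)
        assoc = p.f * state.w * state.w
    else:
        dH = (
            hill_gene_production([], [(state.L_H, p.k_LH, p.n_LH)], p.V_H)
            - p.g_H * state.H
        )
        assoc = p.f * state.h * state.w
        dh = (
            p.p_h * state.H - p.g_h * state.h + tr(state.h, p.D_h, "h")
            - assoc + p.b * state.d
        )
    dw = (
        p.p_w * state.W - p.g_w * state.w + tr(state.w, p.D_w, "w")
        - assoc + p.b * state.d
    )
    dd = -p.g_d * state.d + tr(state.d, p.D_d, "d") + assoc - p.b * state.d
    dc = p.p_c * state.C - p.g_c * state.c + tr(state.c, p.D_c, "c")
    dLc = p.p_Lc * Lmask - p.g_Lc * state.L_c + tr(state.L_c, p.D_Lc, "L_c")
    dLa = p.p_La * Lmask - p.g_La * state.L_a + tr(state.L_a, p.D_La, "L_a")
    dLH = p.p_LH * Lmask - p.g_LH * state.L_H + tr(state.L_H, p.D_LH, "L_H")
    return ModelState(
        W=dW, H=dH, C=dC, w=dw, h=dh, d=dd, c=dc, L_c=dLc, L_a=dLa, L_H=dLH
    )
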