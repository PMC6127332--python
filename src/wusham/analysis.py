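"""Mobility profiles, behaviour categorisation and axis expression profiles.

At equilibrium, the range of a diffusing species is set by its *mobility* --
the ratio of its diffusion rate to its total consumption rate.  For the
HAM-WUS dimer both consumption channels (degradation, dissociation) are
concentration independent, so its mobility ``D_d / (g_d + b)`` is uniform.
A monomer is additionally consumed by dimer recruitment at a rate set by the
local concentration of its partner: WUS monomer mobility is
``D_w / (g_w + f [h])`` and HAM monomer mobility ``D_h / (g_h + f [w])``,
and both therefore vary across the tissue.

Optimised parameter sets fall into three behaviour classes read off the
radius-30 equilibrium: when the epidermal dimer concentration peaks at the
apex the set is *central axis*; otherwise a dimer pocket surrounds the stem
cell domain and the height of the WUS-monomer maximum on the central axis
separates *pocket activator* (y >= 21, peak inside the pocket) from *pocket
repressor* (y <= 17).  Heights in the open interval (17, 21) are reported as
``boundary`` and excluded from category statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ModelState
from .parameters import ModelParameters
from .templates import TemplateError, TissueTemplate

POCKET_ACTIVATOR_MIN_Y = 21
POCKET_REPRESSOR_MAX_Y = 17


@dataclass
class MobilityProfile:
    """Species mobilities along the central axis (stem to apex)."""

    y: np.ndarray
    wus_monomer: np.ndarray
    ham_monomer: np.ndarray
    dimer: np.ndarray


@dataclass
class Category:
    """Behaviour class of a parameter set."""

    label: str                 # central_axis | pocket_activator | pocket_repressor | boundary
    plus_flag: bool | None = None   # pocket repressor +/- (set separately)

    def __post_init__(self):
        if self.plus_flag is not None and self.label != "pocket_repressor":
            raise ValueError("plus_flag is only meaningful for pocket_repressor")


def compute_mobility(
    params: ModelParameters, state: ModelState, template: TissueTemplate
) -> MobilityProfile:
    """Mobility of the two monomers and the dimer along the central axis.

    Zero consumption gives an explicit infinite mobility.
    """
    axis = template.central_axis
    y = template.coords[axis, 1] if template.kind != "3d" else template.coords[axis, 2]
    p = params
    with np.errstate(divide="ignore"):
        dimer = np.full(len(axis), np.divide(p.D_d, p.g_d + p.b)
                        if (p.g_d + p.b) > 0 else np.inf)
        wus = np.divide(p.D_w, p.g_w + p.f * state.h[axis])
        ham = np.divide(p.D_h, p.g_h + p.f * state.w[axis])
    return MobilityProfile(y=np.asarray(y), wus_monomer=wus, ham_monomer=ham,
                           dimer=dimer)


def _apex_l1_cell(template: TissueTemplate) -> int:
    """The L1 cell at the top of the central axis; ties resolved towards the axis."""
    l1 = np.flatnonzero(template.L == 1)
    ymax = template.coords[l1, 1].max()
    top = l1[template.coords[l1, 1] == ymax]
    return int(top[np.argmin(template.coords[top, 0])])


def categorize(state: ModelState, template: TissueTemplate) -> Category:
    """Behaviour class of an equilibrium on the standard radius-30 dome."""
    if template.kind != "2d":
        raise TemplateError("categorisation is defined on the 2D dome template")
    axis = template.central_axis
    top_y = template.coords[axis, 1].max()
    if not (28 <= top_y + 1 <= 30):
        raise TemplateError(
            "categorisation thresholds assume the radius-30 dome "
            f"(axis reaches y={top_y})"
        )
    l1 = np.flatnonzero(template.L == 1)
    d_l1 = state.d[l1]
    peak_cells = l1[d_l1 == d_l1.max()]
    # ties towards the axis: highest, then closest to x = 0
    order = np.lexsort((template.coords[peak_cells, 0],
                        -template.coords[peak_cells, 1]))
    peak = int(peak_cells[order[0]])
    if peak == _apex_l1_cell(template):
        return Category("central_axis")
    w_axis = state.w[axis]
    y_peak = int(template.coords[axis, 1][np.argmax(w_axis)])
    if y_peak >= POCKET_ACTIVATOR_MIN_Y:
        return Category("pocket_activator")
    if y_peak <= POCKET_REPRESSOR_MAX_Y:
        return Category("pocket_repressor")
    return Category("boundary")


def select_pocket_repressor_plus(
    state: ModelState, template45: TissueTemplate
) -> bool:
    """Pocket-repressor +/- split from the pCLV3::WUS equilibrium.

    On the radius-45 dome (apex labelled (0,45)), WUS and CLV3 are
    max-normalised to [0, 1] (the maxima sit in the L1 for this mutant); a
    set is "pocket repressor +" when normalised WUS stays below 0.5 in axis
    cells (0,20) and (0,30) and normalised CLV3 below 0.5 in (0,30) -- low
    central expression, matching the outer-layer phenotype seen in planta.
    """
    w_max = state.W.max()
    c_max = state.C.max()
    if w_max <= 0 or c_max <= 0:
        raise ValueError("degenerate pCLV3::WUS state: zero maxima")
    Wn = state.W / w_max
    Cn = state.C / c_max
    i20 = template45.axis_cell(20)
    i30 = template45.axis_cell(30)
    return bool(Wn[i20] < 0.5 and Wn[i30] < 0.5 and Cn[i30] < 0.5)


def central_axis_profile(
    state: ModelState,
    template: TissueTemplate,
    species: str,
    normalise: bool = False,
) -> np.ndarray:
    """Expression of one species along the central axis, stem to apex."""
    axis = template.central_axis
    values = getattr(state, species)[axis].astype(float)
    if normalise:
        m = values.max()
        if m > 0:
            values = values / m
    return values
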