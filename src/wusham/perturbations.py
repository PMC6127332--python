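"""In-silico mutants and boundary-condition variants.

Each perturbation is a pure transform of a (parameters, template) pair:

* ``clavata`` -- the CLV3 -| WUS feedback is abolished (the peptide-repression
  Hill factor is removed, i.e. the open-loop WUS regulation) and the tissue
  becomes a laterally expanded, fasciated half-stadium.
* ``ham`` -- HAM transcription is silenced (``V_H = 0``).
* ``pclv3_wus`` -- WUS transcription is driven by the CLV3 promoter logic on
  an enlarged (radius 45) dome.
* ``large_meristem`` -- radius-45 dome, parameters untouched.
* ``ham_dose`` -- ``V_H`` scaled by a dose in [0, 1]; dose 1 is wild type.
* ``no_flux_boundary`` -- the sink degradation is removed for the mobile
  proteins and peptide (w, h, d, c by default) while the epidermal morphogen
  gradients keep the sink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .equilibrium import SolverError, SolverSettings, full_equilibrium
from .parameters import ModelParameters
from .templates import TissueTemplate, build_2d_template

PERTURBATION_NAMES = (
    "wild_type", "clavata", "ham", "pclv3_wus", "large_meristem",
    "ham_dose", "no_flux_boundary",
)


@dataclass
class Perturbation:
    """A named mutant/condition with its knobs."""

    name: str
    dose: float | None = None            # ham_dose only
    large_radius: int = 45               # pclv3_wus / large_meristem
    fasciated_width: int = 20            # clavata cap width
    sink_free_species: tuple = ("w", "h", "d", "c")
    template_override: TissueTemplate | None = None

    def __post_init__(self):
        if self.name not in PERTURBATION_NAMES:
            raise ValueError(f"unknown perturbation {self.name!r}")
        if self.name == "ham_dose":
            if self.dose is None or not (0.0 <= self.dose <= 1.0):
                raise ValueError("ham_dose requires a dose in [0, 1]")


def apply_perturbation(
    params: ModelParameters,
    template: TissueTemplate,
    perturbation: Perturbation | str,
) -> tuple[ModelParameters, TissueTemplate]:
    """Return the perturbed (parameters, template) pair; inputs are not mutated."""
    if isinstance(perturbation, str):
        perturbation = Perturbation(name=perturbation)
    pert = perturbation
    if pert.name == "wild_type":
        return params.copy(), template
    if pert.name == "ham":
        return params.copy(V_H=0.0), template
    if pert.name == "ham_dose":
        return params.copy(V_H=params.V_H * pert.dose), template
    if pert.name == "clavata":
        t = pert.template_override or build_2d_template(
            30, shape="fasciated", width=pert.fasciated_width
        )
        return params.copy(clv3_feedback=False), t
    if pert.name == "pclv3_wus":
        t = pert.template_override or build_2d_template(pert.large_radius)
        return params.copy(pclv3_wus=True), t
    if pert.name == "large_meristem":
        t = pert.template_override or build_2d_template(pert.large_radius)
        return params.copy(), t
    if pert.name == "no_flux_boundary":
        return params.copy(sink_free_species=tuple(pert.sink_free_species)), template
    raise ValueError(f"unknown perturbation {pert.name!r}")


def ham_dose_series(
    params: ModelParameters,
    template: TissueTemplate,
    doses,
    settings: SolverSettings | None = None,
):
    """Equilibria over an ascending series of HAM production doses.

    Returns ``(states, table)`` where ``table`` has one row per dose with the
    height (y) of the CLV3 maximum along the central axis and the summed CLV3
    and WUS expression.  Solver failures are recorded with NaN rows and the
    series continues.
    """
    doses = list(doses)
    if any(b < a for a, b in zip(doses, doses[1:])):
        raise ValueError("doses must be sorted ascending")
    axis = template.central_axis
    ys = template.coords[axis, 1]
    states, rows = [], []
    for dose in doses:
        p, t = apply_perturbation(params, template, Perturbation("ham_dose", dose=dose))
        try:
            st = full_equilibrium(p, t, settings)
        except SolverError:
            states.append(None)
            rows.append({"dose": dose, "argmax_y": np.nan,
                         "sum_C": np.nan, "sum_W": np.nan})
            continue
        states.append(st)
        k = int(np.argmax(st.C[axis]))
        rows.append({
            "dose": dose,
            "argmax_y": int(ys[k]),
            "sum_C": float(st.C.sum()),
            "sum_W": float(st.W.sum()),
        })
    return states, pd.DataFrame(rows)
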