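"""Multi-stage parameter fitting for the SAM model.

The pipeline mirrors the structure of the network: each stage fits one layer
of the model against binary target expression domains, then freezes it.

1. Open-loop (clavata) WUS against an inflated target ``1.5 * W_t``;
   fits the two epidermal morphogen gradients and their Hill thresholds.
2. CLV3-peptide repression closing WUS onto ``W_t``; the peptide gradient
   ``c_t`` is produced by the *target* CLV3 domain.
3. HAM plus the monomer/dimer subsystem and the CLV3 promoter against
   ``C_t``/``H_t`` (cost ``E_CH1``).
4. Re-optimisation of the same parameters adding clavata (``p_w * 1.5``) and
   ham (``p_h = 0``) phenotype terms (cost ``E_CH2``).
5. CLV3-peptide parameters refitted so the peptide produced by the optimised
   CLV3 domain matches the stage-2 gradient ``c_t``.
6. Full-model equilibrium; a parameter set is accepted when
   ``sum((C - C_t)**2) < 15``.

All stages use L-BFGS-B on log10-transformed parameters bounded in
``[-8, 8]`` (i.e. rates in ``[1e-8, 1e8]``), initialised uniformly in
``[-2, 2]`` from the run's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import ModelState, shea_ackers_clv3
from .equilibrium import (
    SolverError,
    SolverSettings,
    full_equilibrium,
    gene_equilibrium,
    newton_dimer_equilibrium,
    solve_diffusion_equilibrium,
)
from .gradients import (
    stage_c_value_and_grad,
    stage_ch_value_and_grad,
    stage_w1_value_and_grad,
    stage_w2_value_and_grad,
)
from .parameters import FIXED_3D_HILL, STAGE_PARAMS, ModelParameters
from .templates import TargetDomains, TissueTemplate

LOG_BOUNDS = (-8.0, 8.0)
INIT_RANGE = (-2.0, 2.0)
ACCEPTANCE_THRESHOLD = 15.0
BAD_COST = 1e9

STAGES = ("W1", "W2", "CH1", "CH2", "c")
_STAGE_INDEX = {"W1": 1, "W2": 2, "CH1": 3, "CH2": 4, "c": 5}


@dataclass
class OptimizerSettings:
    """Budget and solver knobs for one pipeline run."""

    solver: SolverSettings = field(default_factory=SolverSettings)
    maxiter: dict = field(default_factory=lambda: {
        "W1": 300, "W2": 300, "CH1": 150, "CH2": 50, "c": 200,
    })
    maxfun: dict = field(default_factory=lambda: {
        "W1": 800, "W2": 500, "CH1": 450, "CH2": 250, "c": 500,
    })
    # random starting points screened per stage (best initial cost wins);
    # stages 4 and 5 instead continue from the previous stage's optimum
    screen: dict = field(default_factory=lambda: {
        "W1": 100, "W2": 30, "CH1": 100, "CH2": 0, "c": 0,
    })
    # finite-difference step for L-BFGS-B gradients, in log10-parameter
    # units; the default 1e-8 is swamped by solver noise on this model
    fd_step: float = 1e-4
    # independent screen+minimise restarts per stage (best final cost wins);
    # remaining restarts are skipped once the cost drops below restart_stop
    restarts: dict = field(default_factory=lambda: {
        "W1": 3, "W2": 1, "CH1": 3, "CH2": 1, "c": 1,
    })
    restart_stop: dict = field(default_factory=lambda: {
        "W1": 60.0, "CH1": 20.0,
    })
    # adjoint gradients for L-BFGS-B (finite differences when False)
    analytic_gradients: bool = True


@dataclass
class OptimizationResult:
    """Outcome of one seeded pipeline run."""

    params: ModelParameters
    stage_costs: dict
    final_clv3_error: float
    accepted: bool
    seed: int
    category: str | None = None
    failure_stage: str | None = None
    state: ModelState | None = None
    targets: TargetDomains | None = None


def evaluate_cost(
    stage: str,
    computed: dict,
    targets: TargetDomains,
    weights: dict | None = None,
) -> float:
    """Stage cost functions.

    ``computed`` carries the stage's equilibrium fields: ``W1`` needs ``W``;
    ``W2`` needs ``W``; ``CH1`` needs ``C`` and ``H``; ``CH2`` needs ``C``,
    ``H``, ``C_c`` (clavata CLV3), ``C_h`` (ham CLV3) and ``W``; ``c`` needs
    ``c`` and the cached target gradient ``targets.c_t``.
    """
    w = {"omega": 0.08, "omega1": 0.04, "omega2": 0.2}
    if weights:
        w.update(weights)
    if stage == "W1":
        return float(np.sum((computed["W"] - 1.5 * targets.W_t) ** 2))
    if stage == "W2":
        return float(np.sum((computed["W"] - targets.W_t) ** 2))
    if stage == "CH1":
        return float(
            np.sum((computed["C"] - targets.C_t) ** 2)
            + w["omega"] * np.sum((computed["H"] - targets.H_t) ** 2)
        )
    if stage == "CH2":
        sum_C = float(np.sum(computed["C"]))
        if sum_C <= 0:
            return math.inf
        ratio = float(np.sum(computed["C_c"])) / sum_C
        ham_sq = float(np.sum((computed["W"] - computed["C_h"]) ** 2))
        return float(
            np.sum((computed["C"] - targets.C_t) ** 2)
            + w["omega1"] * np.sum((computed["H"] - targets.H_t) ** 2)
            + w["omega2"] * (ratio - 1.5) ** 2
            + math.log(max(ham_sq, 1e-30))
        )
    if stage == "c":
        if targets.c_t is None:
            raise ValueError("stage 'c' requires the cached target gradient c_t")
        return float(np.sum((computed["c"] - targets.c_t) ** 2))
    raise ValueError(f"unknown stage {stage!r}")


class _PipelineState:
    """Intermediate fields carried between stages of one run."""

    def __init__(self):
        self.W1 = None       # open-loop WUS domain (stage 1)
        self.W2 = None       # wild-type WUS domain (stage 2)
        self.c_t = None      # peptide gradient of the target CLV3 domain
        self.C4 = None       # optimised CLV3 domain (stage 4)
        self.guess = None    # Newton warm start within a stage
        self.guess_ham = None  # warm start for the ham (p_h = 0) sub-solve
        self.grad_guesses = None  # warm starts inside the adjoint evaluations


def _stage_cost_fn(stage, params, template, targets, carry, settings):
    """Build the scalar cost function of ``stage`` over its free parameters."""
    names = STAGE_PARAMS[_STAGE_INDEX[stage]]
    # cost evaluations fail fast on hard Newton problems instead of paying
    # for the stiff-integration rescue; a draw that needs it scores BAD_COST
    base_solver = (settings or OptimizerSettings()).solver
    eval_solver = _dc_replace(
        base_solver,
        integrator_fallback=False,
        newton_max_iter=min(base_solver.newton_max_iter, 25),
        newton_linesearch=min(base_solver.newton_linesearch, 12),
    )

    def with_theta(theta):
        vals = {name: 10.0 ** t for name, t in zip(names, theta)}
        return params.copy(**vals)

    # the best evaluation seen so far is tracked here, together with the
    # fields and warm-start state that produced it, so later stages never
    # need to re-solve at the optimum (a cold solve may not even converge
    # in the regimes the optimiser reaches through its warm-start chain)
    tracker = {"cost": np.inf, "theta": None, "extras": None, "guesses": None}

    def _record(E, theta, extras, guesses):
        if E < tracker["cost"]:
            tracker.update(
                cost=E, theta=np.array(theta, dtype=float, copy=True),
                extras=extras, guesses=guesses,
            )

    def cost(theta):
        p = with_theta(theta)
        try:
            computed = _stage_fields(stage, p, template, targets, carry,
                                     solver=eval_solver)
        except (SolverError, FloatingPointError, ValueError):
            return BAD_COST
        c = evaluate_cost(stage, computed, targets)
        if not np.isfinite(c):
            return BAD_COST
        _record(c, theta, computed,
                {"wt": carry.guess, "hm": carry.guess_ham})
        return c

    def value_and_grad(theta):
        try:
            if stage == "W1":
                E, grad, extras = stage_w1_value_and_grad(
                    theta, params, template, targets
                )
            elif stage == "W2":
                E, grad, extras = stage_w2_value_and_grad(
                    theta, params, template, targets, carry.W1
                )
            elif stage in ("CH1", "CH2"):
                E, grad, extras, gout = stage_ch_value_and_grad(
                    stage, theta, params, template, targets, carry.W2,
                    eval_solver, guesses=carry.grad_guesses,
                )
                carry.grad_guesses = gout
            else:
                E, grad, extras = stage_c_value_and_grad(
                    theta, params, template, targets, carry.C4
                )
        except (SolverError, FloatingPointError, ValueError):
            return BAD_COST, np.zeros(len(names))
        if not np.isfinite(E):
            return BAD_COST, np.zeros(len(names))
        _record(E, theta, extras, carry.grad_guesses)
        return E, grad

    return names, with_theta, cost, value_and_grad, tracker


def _stage_fields(stage, p, template, targets, carry, solver=None):
    """Equilibrium fields entering the cost of one stage."""
    L = template.L.astype(float)
    n = template.n_cells
    if stage == "W1":
        L_c = solve_diffusion_equilibrium(L, p.p_Lc, p.g_Lc, p.D_Lc, template)
        L_a = solve_diffusion_equilibrium(L, p.p_La, p.g_La, p.D_La, template)
        W1 = gene_equilibrium(
            [(L_c, p.k_LcW, p.n_LcW)], [(L_a, p.k_LaW, p.n_LaW)], p.V_W, p.g_W, n
        )
        return {"W": W1}
    if stage == "W2":
        c_t = solve_diffusion_equilibrium(
            targets.C_t.astype(float), p.p_c, p.g_c, p.D_c, template
        )
        rep = gene_equilibrium([], [(c_t, p.k_c, p.n_c)], 1.0, 1.0, n)
        return {"W": carry.W1 * rep, "c_t": c_t}
    if stage in ("CH1", "CH2"):
        L_H = solve_diffusion_equilibrium(L, p.p_LH, p.g_LH, p.D_LH, template)
        H = gene_equilibrium([], [(L_H, p.k_LH, p.n_LH)], p.V_H, p.g_H, n)
        w, h, d = newton_dimer_equilibrium(
            carry.W2, H, p, template, solver, x0=carry.guess
        )
        carry.guess = (w, h, d)
        C = shea_ackers_clv3(w, d, p) / p.g_C
        if stage == "CH1":
            return {"C": C, "H": H}
        wc, hc, dc = newton_dimer_equilibrium(
            carry.W2, H, p.copy(p_w=p.p_w * 1.5), template, solver, x0=(w, h, d)
        )
        C_c = shea_ackers_clv3(wc, dc, p) / p.g_C
        wh, hh, dh = newton_dimer_equilibrium(
            carry.W2, H, p.copy(p_h=0.0), template, solver, x0=carry.guess_ham
        )
        carry.guess_ham = (wh, hh, dh)
        C_h = shea_ackers_clv3(wh, dh, p) / p.g_C
        return {"C": C, "H": H, "C_c": C_c, "C_h": C_h, "W": carry.W2}
    if stage == "c":
        c = solve_diffusion_equilibrium(carry.C4, p.p_c, p.g_c, p.D_c, template)
        return {"c": c}
    raise ValueError(f"unknown stage {stage!r}")


def run_stage(
    stage: str,
    params: ModelParameters,
    template: TissueTemplate,
    targets: TargetDomains,
    settings: OptimizerSettings | None = None,
    carry: _PipelineState | None = None,
    theta0: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ModelParameters, float]:
    """Optimise one stage's parameter subset; returns updated params and cost.

    ``theta0`` overrides the log10 starting point; otherwise it is drawn
    uniformly from ``[-2, 2]`` with ``rng`` (or taken from the current
    parameter values when no generator is given).
    """
    settings = settings or OptimizerSettings()
    carry = carry if carry is not None else _prime_carry(params, template, targets)
    names, with_theta, cost, value_and_grad, tracker = _stage_cost_fn(
        stage, params, template, targets, carry, settings
    )
    n_restarts = max(1, settings.restarts.get(stage, 1)) if theta0 is None else 1
    for _restart in range(n_restarts):
        if theta0 is not None:
            start = theta0
        elif rng is not None:
            n_screen = max(1, settings.screen.get(stage, 1))
            cands = rng.uniform(*INIT_RANGE, size=(n_screen, len(names)))
            start = min(cands, key=cost)
        else:
            start = np.log10(
                np.clip([getattr(params, v) for v in names], 1e-8, 1e8)
            )
        carry.guess = None
        carry.guess_ham = None
        carry.grad_guesses = None
        if settings.analytic_gradients:
            minimize(
                value_and_grad,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=[LOG_BOUNDS] * len(names),
                options={
                    "maxiter": settings.maxiter[stage],
                    "maxfun": settings.maxfun[stage],
                },
            )
        else:
            minimize(
                cost,
                start,
                method="L-BFGS-B",
                bounds=[LOG_BOUNDS] * len(names),
                options={
                    "maxiter": settings.maxiter[stage],
                    "maxfun": settings.maxfun[stage],
                    "eps": settings.fd_step,
                },
            )
        if tracker["cost"] < settings.restart_stop.get(stage, -np.inf):
            break
    if tracker["theta"] is None:
        raise SolverError(f"stage {stage}: no feasible evaluation found")
    new_params = with_theta(tracker["theta"])
    extras = tracker["extras"]
    if stage == "W1":
        carry.W1 = extras["W"]
    elif stage == "W2":
        carry.W2 = extras["W"]
        carry.c_t = extras["c_t"]
        targets.c_t = carry.c_t
    elif stage == "CH2":
        carry.C4 = extras["C"]
    # hand the winning warm-start state to the next stage's first solve
    carry.grad_guesses = tracker["guesses"]
    carry.guess = None
    carry.guess_ham = None
    return new_params, float(tracker["cost"])


def _prime_carry(params, template, targets):
    carry = _PipelineState()
    fields = _stage_fields("W1", params, template, targets, carry)
    carry.W1 = fields["W"]
    return carry


def run_pipeline(
    seed: int,
    template: TissueTemplate,
    targets: TargetDomains,
    settings: OptimizerSettings | None = None,
    base_params: ModelParameters | None = None,
    keep_state: bool = True,
) -> OptimizationResult:
    """One seeded run of the six-stage fitting pipeline."""
    settings = settings or OptimizerSettings()
    rng = np.random.default_rng(seed)
    params = (base_params or ModelParameters()).copy()
    targets = TargetDomains(
        W_t=targets.W_t.copy(), C_t=targets.C_t.copy(), H_t=targets.H_t.copy(),
        c_t=None if targets.c_t is None else targets.c_t.copy(),
    )
    carry = _PipelineState()
    stage_costs: dict = {}
    theta0 = None
    for stage in STAGES:
        try:
            if stage == "CH2":
                theta0 = np.log10(
                    np.clip(
                        [getattr(params, v) for v in STAGE_PARAMS[4]], 1e-8, 1e8
                    )
                )
            elif stage == "c":
                theta0 = np.log10(
                    np.clip(
                        [getattr(params, v) for v in STAGE_PARAMS[5]], 1e-8, 1e8
                    )
                )
            else:
                theta0 = None
            params, stage_costs[stage] = run_stage(
                stage, params, template, targets, settings,
                carry=carry, theta0=theta0, rng=rng,
            )
        except (SolverError, ValueError) as exc:
            return OptimizationResult(
                params=params, stage_costs=stage_costs,
                final_clv3_error=math.inf, accepted=False, seed=seed,
                failure_stage=f"{stage}: {exc}",
            )
    try:
        state = full_equilibrium(params, template, settings.solver)
    except SolverError as exc:
        return OptimizationResult(
            params=params, stage_costs=stage_costs, final_clv3_error=math.inf,
            accepted=False, seed=seed, failure_stage=f"equilibrium: {exc}",
        )
    err = float(np.sum((state.C - targets.C_t) ** 2))
    return OptimizationResult(
        params=params,
        stage_costs=stage_costs,
        final_clv3_error=err,
        accepted=err < ACCEPTANCE_THRESHOLD,
        seed=seed,
        state=state if keep_state else None,
        targets=targets,
    )


def run_pipeline_3d(
    seed: int,
    template: TissueTemplate,
    targets: TargetDomains,
    settings: OptimizerSettings | None = None,
) -> OptimizationResult:
    """Pipeline on a 3D (volume/contact-surface) template.

    The four Hill coefficients are held at the values carried over from
    earlier optimisations of the epidermis-driven WUS model
    (n_LcW = 7.25968619416, n_LaW = 1.99109438845, n_c = 6.66419523049,
    n_LH = 6); transport uses the volume-scaled contact-surface operator.
    """
    if template.kind != "3d":
        raise ValueError("run_pipeline_3d requires a 3D template")
    base = ModelParameters().copy(**FIXED_3D_HILL)
    return run_pipeline(seed, template, targets, settings, base_params=base)


def clavata_ratio(result: OptimizationResult, template: TissueTemplate) -> float:
    """Sum(C_clavata)/Sum(C) with the induced clavata construction (p_w * 1.5).

    This is the quantity the stage-4 cost steers towards 1.5, evaluated at
    the run's final parameters on the open-loop WUS field.
    """
    p = result.params
    carry = _prime_carry(p, template, result.targets)
    fields = _stage_fields("W2", p, template, result.targets, carry)
    carry.W2 = fields["W"]
    out = _stage_fields("CH2", p, template, result.targets, carry)
    return float(np.sum(out["C_c"]) / np.sum(out["C"]))


# ---------------------------------------------------------------------------
# result tables


def results_to_frame(results: list[OptimizationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"seed": r.seed}
        row.update({k: v for k, v in r.params.to_dict().items()
                    if isinstance(v, (int, float))})
        row.update({f"cost_{k}": v for k, v in r.stage_costs.items()})
        row["final_clv3_error"] = r.final_clv3_error
        row["accepted"] = r.accepted
        row["category"] = r.category
        row["failure_stage"] = r.failure_stage
        rows.append(row)
    return pd.DataFrame(rows)
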