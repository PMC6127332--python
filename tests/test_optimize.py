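"""Cost functions and the staged fitting pipeline."""

import numpy as np
import pytest

import wusham as wm
from wusham.optimize import (
    ACCEPTANCE_THRESHOLD,
    OptimizerSettings,
    evaluate_cost,
    results_to_frame,
    run_pipeline,
    run_pipeline_3d,
    run_stage,
)
from wusham.parameters import FIXED_3D_HILL, STAGE_PARAMS
from wusham.templates import TargetDomains


def small_targets(n, rng):
    W_t = (rng.uniform(size=n) < 0.3).astype(int)
    C_t = (rng.uniform(size=n) < 0.3).astype(int)
    H_t = (rng.uniform(size=n) < 0.5).astype(int)
    for v in (W_t, C_t, H_t):
        v[0] = 1  # never empty
    return TargetDomains(W_t=W_t, C_t=C_t, H_t=H_t)


class TestEvaluateCost:
    def test_w1_perfect_fit_is_zero(self):
        rng = np.random.default_rng(0)
        td = small_targets(20, rng)
        cost = evaluate_cost("W1", {"W": 1.5 * td.W_t}, td)
        assert cost == 0.0

    def test_w1_zero_prediction_closed_form(self):
        rng = np.random.default_rng(1)
        td = small_targets(50, rng)
        m = td.W_t.sum()
        cost = evaluate_cost("W1", {"W": np.zeros(50)}, td)
        np.testing.assert_allclose(cost, 2.25 * m)

    def test_ch2_matches_independent_evaluation(self):
        """E_CH2 against a by-hand spreadsheet-style computation."""
        rng = np.random.default_rng(2)
        n = 12
        td = small_targets(n, rng)
        computed = {
            "C": rng.uniform(0, 2, n),
            "H": rng.uniform(0, 2, n),
            "C_c": rng.uniform(0, 2, n),
            "C_h": rng.uniform(0, 2, n),
            "W": rng.uniform(0, 2, n),
        }
        got = evaluate_cost("CH2", computed, td)
        # independent evaluation, term by term
        exp = 0.0
        for i in range(n):
            exp += (computed["C"][i] - td.C_t[i]) ** 2
            exp += 0.04 * (computed["H"][i] - td.H_t[i]) ** 2
        ratio = sum(computed["C_c"]) / sum(computed["C"])
        exp += 0.2 * (ratio - 1.5) ** 2
        exp += np.log(sum((computed["W"][i] - computed["C_h"][i]) ** 2
                          for i in range(n)))
        np.testing.assert_allclose(got, exp, rtol=1e-12)

    def test_ch2_zero_total_clv3_is_infinite(self):
        rng = np.random.default_rng(3)
        td = small_targets(5, rng)
        computed = {"C": np.zeros(5), "H": np.zeros(5), "C_c": np.zeros(5),
                    "C_h": np.zeros(5), "W": np.zeros(5)}
        assert evaluate_cost("CH2", computed, td) == np.inf

    def test_unknown_stage_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            evaluate_cost("W9", {}, small_targets(4, rng))


class TestStages:
    def test_stage2_only_touches_its_parameters(self, template10, targets10):
        rng = np.random.default_rng(0)
        params = wm.ModelParameters()
        from wusham.optimize import _PipelineState, _prime_carry

        carry = _prime_carry(params, template10, targets10)
        p1, _ = run_stage("W1", params, template10, targets10,
                          carry=carry, rng=rng)
        p2, _ = run_stage("W2", p1, template10, targets10,
                          carry=carry, rng=rng)
        changed = {
            name for name in p2.to_dict()
            if isinstance(getattr(p2, name), float)
            and getattr(p2, name) != getattr(p1, name)
        }
        assert changed <= set(STAGE_PARAMS[2])

    def test_stage_restarted_at_optimum_keeps_cost(self, template10, targets10):
        rng = np.random.default_rng(1)
        params = wm.ModelParameters()
        from wusham.optimize import _prime_carry

        carry = _prime_carry(params, template10, targets10)
        p1, c1 = run_stage("W1", params, template10, targets10,
                           carry=carry, rng=rng)
        theta0 = np.log10([getattr(p1, v) for v in STAGE_PARAMS[1]])
        p2, c2 = run_stage("W1", p1, template10, targets10,
                           carry=carry, theta0=theta0)
        assert c2 <= c1 + 1e-9

    def test_stage1_on_chain_gives_monotone_cytokinin_gradient(self):
        """The fitted long-range activator falls monotonically from the L1."""
        t = wm.build_1d_template(30)
        td = wm.make_target_domains(t)
        rng = np.random.default_rng(3)
        params = wm.ModelParameters()
        from wusham.optimize import _prime_carry

        carry = _prime_carry(params, t, td)
        p1, c1 = run_stage("W1", params, t, td, carry=carry, rng=rng)
        assert c1 < 2.25 * td.W_t.sum() - 1e-6  # beats the all-zero plateau
        L_c = wm.solve_diffusion_equilibrium(
            t.L.astype(float), p1.p_Lc, p1.g_Lc, p1.D_Lc, t
        )
        diffs = np.diff(L_c)  # cell 0 = sink ... cell 29 = L1
        assert np.all(diffs > -1e-12)


class TestPipeline:
    def test_same_seed_reproduces_bitwise(self, template10, targets10):
        a = run_pipeline(5, template10, targets10, keep_state=False)
        b = run_pipeline(5, template10, targets10, keep_state=False)
        assert a.stage_costs == b.stage_costs
        assert a.final_clv3_error == b.final_clv3_error
        assert a.params.to_dict() == b.params.to_dict()

    def test_parameters_within_bounds(self, optimized10):
        for name, value in optimized10.params.to_dict().items():
            if isinstance(value, float) and not name.startswith("n_"):
                assert 1e-8 - 1e-12 <= value <= 1e8 + 1e-4 or value == 0.0

    def test_accepted_flag_matches_threshold(self, pipeline_batch):
        for res in pipeline_batch:
            assert res.accepted == (res.final_clv3_error < ACCEPTANCE_THRESHOLD)

    def test_results_table_round_trip(self, pipeline_batch, tmp_path):
        frame = results_to_frame(pipeline_batch)
        assert {"seed", "final_clv3_error", "accepted"} <= set(frame.columns)
        assert len(frame) == len(pipeline_batch)


class TestPipeline3D:
    def test_fixed_hill_coefficients_survive(self, synthetic3d_run):
        res = synthetic3d_run
        for name, value in FIXED_3D_HILL.items():
            assert getattr(res.params, name) == value

    def test_completes_with_finite_error(self, synthetic3d_run):
        assert np.isfinite(synthetic3d_run.final_clv3_error)

    def test_uniform_3d_reduces_to_graph_laplacian(self):
        """With unit volumes and unit contacts, 3D transport equals the
        plain graph Laplacian on the same adjacency."""
        t3 = wm.generate_synthetic_3d_template(60, seed=3)
        t3.volumes = np.ones(t3.n_cells)
        W = (t3.neighbor_weights > 0).astype(float)
        t3.neighbor_weights = W.tocsr()
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, t3.n_cells)
        out = wm.transport_operator(x, 1.0, t3)
        A = W.toarray()
        expected = A @ x - A.sum(axis=1) * x
        np.testing.assert_allclose(out, expected, rtol=1e-12)
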