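"""Tissue-template construction, targets and serialisation."""

import numpy as np
import pytest
import scipy.sparse as sp

import wusham as wm
from wusham.templates import TemplateError, TargetSpec, mirrored_full_template


def brute_force_quarter_disk_count(radius):
    """Independent enumeration of lattice points with i^2 + j^2 < r^2."""
    return sum(
        1
        for i in range(radius + 1)
        for j in range(radius + 1)
        if i * i + j * j < radius * radius
    )


class TestBuild2D:
    @pytest.mark.parametrize("radius,expected", [(30, 732), (1, 1)])
    def test_printed_cell_counts(self, radius, expected):
        assert wm.build_2d_template(radius).n_cells == expected

    @pytest.mark.parametrize("radius", [5, 10, 17])
    def test_counts_match_enumeration_oracle(self, radius):
        assert (
            wm.build_2d_template(radius).n_cells
            == brute_force_quarter_disk_count(radius)
        )

    def test_cell_count_increases_with_radius(self):
        counts = [wm.build_2d_template(r).n_cells for r in range(2, 13)]
        assert all(b > a for a, b in zip(counts, counts[1:]))

    def test_boundary_masks(self, template30):
        t = template30
        # bottom row is the sink; masks disjoint; arc marked epidermal
        assert t.S.sum() == 30
        assert np.all(t.coords[t.S == 1, 1] == 0)
        assert not np.any((t.L == 1) & (t.S == 1))
        assert t.L.sum() > 0
        # every epidermal cell sits near the circle edge
        r = np.hypot(*t.coords[t.L == 1].T)
        assert r.min() > 28.0
        # mirror column cells are not epidermal (the phantom neighbour
        # across the axis is tissue, not outside)
        on_axis = t.coords[:, 0] == 0
        assert not np.any(t.L[on_axis & (t.coords[:, 1] < 29)])

    def test_mirror_bonus_on_degree(self, template30):
        t = template30
        adj = np.asarray(t.neighbor_weights.sum(axis=1)).ravel()
        mirror = t.coords[:, 0] == 0
        assert np.all(t.degree[mirror] == adj[mirror] + 1)
        assert np.all(t.degree[~mirror] == adj[~mirror])

    def test_connected(self, template30):
        assert template30.is_connected()

    def test_invalid_geometry(self):
        with pytest.raises(TemplateError):
            wm.build_2d_template(0)
        with pytest.raises(TemplateError):
            wm.build_2d_template(10, shape="fasciated")  # missing width
        with pytest.raises(TemplateError):
            wm.build_2d_template(10, shape="hexagon")

    def test_fasciated_is_wider_not_taller(self):
        dome = wm.build_2d_template(12)
        fas = wm.build_2d_template(12, shape="fasciated", width=8)
        assert fas.n_cells > dome.n_cells
        assert fas.coords[:, 1].max() == dome.coords[:, 1].max()
        assert fas.coords[:, 0].max() == dome.coords[:, 0].max() + 8


class TestBuild1D:
    def test_minimal_chain(self):
        t = wm.build_1d_template(2)
        assert t.n_cells == 2
        assert t.neighbor_weights.nnz == 2
        assert list(t.S) == [1, 0] and list(t.L) == [0, 1]

    def test_chain_degrees(self):
        assert list(wm.build_1d_template(5).degree) == [1, 2, 2, 2, 1]

    def test_too_short(self):
        with pytest.raises(TemplateError):
            wm.build_1d_template(1)

    def test_cytokinin_equilibrium_matches_dense_solve(self):
        t = wm.build_1d_template(50)
        p_, g_, D_ = 1.3, 0.02, 2.5
        x = wm.solve_diffusion_equilibrium(t.L.astype(float), p_, g_, D_, t)
        # dense oracle assembled from scratch
        n = t.n_cells
        A = np.zeros((n, n))
        for i in range(n):
            A[i, i] = g_ + D_ * t.S[i]
            for j in (i - 1, i + 1):
                if 0 <= j < n:
                    A[i, j] -= D_
                    A[i, i] += D_
        expected = np.linalg.solve(A, p_ * t.L)
        np.testing.assert_allclose(x, expected, rtol=1e-10)


class TestSynthetic3D:
    def test_deterministic_given_seed(self):
        a = wm.generate_synthetic_3d_template(60, seed=4)
        b = wm.generate_synthetic_3d_template(60, seed=4)
        assert np.array_equal(a.coords, b.coords)
        assert (a.neighbor_weights != b.neighbor_weights).nnz == 0

    def test_structure_invariants(self):
        t = wm.generate_synthetic_3d_template(80, seed=1)
        W = t.neighbor_weights
        assert (abs(W - W.T)).max() < 1e-12
        assert np.all(t.volumes > 0)
        assert t.is_connected()
        assert t.L.sum() > 0 and t.S.sum() > 0
        assert not np.any((t.L == 1) & (t.S == 1))

    def test_too_small(self):
        with pytest.raises(TemplateError):
            wm.generate_synthetic_3d_template(10, seed=0)

    def test_transport_conserves_volume_weighted_total(self):
        # no degradation, no production, no sink: sum V_i x_i is invariant
        t = wm.generate_synthetic_3d_template(120, seed=1)
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 2.0, t.n_cells)
        flux = wm.transport_operator(x, D=0.7, template=t)
        assert abs(np.sum(t.volumes * flux)) < 1e-8 * np.sum(np.abs(x))


class TestSerialisation:
    def test_round_trip_2d(self, tmp_path):
        t = wm.build_2d_template(7)
        path = tmp_path / "t.tsv"
        wm.save_template(t, path)
        back = wm.load_template(path)
        assert back.n_cells == t.n_cells
        assert np.array_equal(back.coords, t.coords)
        assert (back.neighbor_weights != t.neighbor_weights).nnz == 0
        for field in ("L", "S", "mirror", "degree", "volumes"):
            np.testing.assert_array_equal(getattr(back, field), getattr(t, field))

    def test_round_trip_3d(self, tmp_path):
        t = wm.generate_synthetic_3d_template(40, seed=2)
        path = tmp_path / "t3.tsv"
        wm.save_template(t, path)
        back = wm.load_template(path)
        assert back.kind == "3d"
        np.testing.assert_allclose(back.volumes, t.volumes)
        np.testing.assert_allclose(
            back.neighbor_weights.toarray(), t.neighbor_weights.toarray()
        )

    def test_malformed_file_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#KIND\t3d\n#CELLS\tid\tx\ty\tz\tvolume\tL\tS\tmirror\n"
            "0\t0\t0\t0\t1\t0\t0\t0\n"
            "1\t1\t0\tnot_a_number\t1\t0\t0\t0\n"
        )
        with pytest.raises(TemplateError, match="line 4"):
            wm.load_template(path)

    def test_hand_written_three_cell_chain(self, tmp_path):
        path = tmp_path / "chain.tsv"
        path.write_text(
            "#KIND\t1d\n"
            "#CELLS\tid\tx\ty\tvolume\tL\tS\tmirror\n"
            "0\t0\t0\t1\t0\t1\t0\n"
            "1\t0\t1\t1\t0\t0\t0\n"
            "2\t0\t2\t1\t1\t0\t0\n"
            "#EDGES\tid_a\tid_b\tweight\n"
            "0\t1\t1\n"
            "1\t2\t1\n"
        )
        t = wm.load_template(path)
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        np.testing.assert_array_equal(t.neighbor_weights.toarray(), expected)
        assert list(t.S) == [1, 0, 0] and list(t.L) == [0, 0, 1]


class TestTargets:
    def test_default_domains_structure(self, template30, targets30):
        t, td = template30, targets30
        assert not np.any(td.W_t * t.L)
        assert td.C_t[t.axis_cell(29)] == 1  # cap contains the apex cell
        assert not np.any(td.H_t * t.L)
        for v in (td.W_t, td.C_t, td.H_t):
            assert set(np.unique(v)) <= {0, 1} and v.sum() > 0

    def test_frozen_default_counts(self, targets30):
        # regression lock on the frozen default geometry
        assert int(targets30.W_t.sum()) == 120
        assert int(targets30.C_t.sum()) == 136
        assert int(targets30.H_t.sum()) == 640

    def test_degenerate_spec_raises(self, template30):
        with pytest.raises(TemplateError):
            wm.make_target_domains(
                template30, TargetSpec(wus_depth=40.0)
            )


class TestMirrorBoundary:
    def test_half_equals_full_mirrored_equilibrium(self):
        """Zero-flux mirror: the half-template solve equals the restriction
        of the equilibrium on an explicitly mirrored full template."""
        half = wm.build_2d_template(6)
        full, half_to_full = mirrored_full_template(half)
        p_, g_, D_ = 1.0, 0.4, 1.7
        x_half = wm.solve_diffusion_equilibrium(half.L.astype(float), p_, g_, D_, half)
        x_full = wm.solve_diffusion_equilibrium(full.L.astype(float), p_, g_, D_, full)
        np.testing.assert_allclose(x_half, x_full[half_to_full], rtol=1e-9)
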