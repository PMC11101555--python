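"""Finite-element Reynolds solver: element level, fields, flow rates."""

import dataclasses

import numpy as np
import pytest

from helpers import network_flow_rate
from pvleak import (
    assemble,
    build_midgap_mesh,
    compute_flow_rate,
    solve_pressure,
    synthetic,
)
from pvleak.geometry import ShellMesh
from pvleak.reynolds import cross_section_flow_rate
from pvleak.vtu import write_vtu

MU = 0.0035
DP_VERIF = 13.32e3  # 100 mmHg as used in the die verification


def uniform_strip(n_x=31, n_y=11, W=10e-3, L=30e-3, h=0.5e-3):
    return synthetic.make_pocket_channel(
        W, L, h, h, (L / 3, 2 * L / 3, W / 3, 2 * W / 3), 1e-3, n_x=n_x, n_y=n_y
    )


class TestAssembly:
    def test_single_element_matches_hand_assembled_matrix(self, blood):
        # unit right triangle, uniform h: c * P1 Laplacian
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        mesh = ShellMesh(points=pts, triangles=[[0, 1, 2]], h=np.full(3, 2.0),
                         inlet=[1], outlet=[2])
        K = assemble(mesh, blood).toarray()
        c = 2.0**3 / (12 * blood.mu)
        K_hand = c * 0.5 * np.array([[2.0, -1, -1], [-1, 1, 0], [-1, 0, 1]])
        assert np.allclose(K, K_hand, rtol=1e-12)

    def test_rigid_rotation_leaves_matrix_unchanged(self, blood, rng):
        stack = synthetic.make_eccentric_annulus(10e-3, 11e-3, 0.5e-3, 10e-3, 16, 5)
        mesh = build_midgap_mesh(stack)
        K0 = assemble(mesh, blood).toarray()
        # random rotation via QR of a gaussian matrix
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = ShellMesh(points=mesh.points @ q.T, triangles=mesh.triangles,
                            h=mesh.h, inlet=mesh.inlet, outlet=mesh.outlet)
        K1 = assemble(rotated, blood).toarray()
        assert np.allclose(K0, K1, atol=1e-12 * np.abs(K0).max())

    def test_row_sums_vanish(self, die_stack, blood):
        K = assemble(build_midgap_mesh(die_stack), blood)
        sums = np.asarray(abs(K @ np.ones(K.shape[0])))
        assert sums.max() < 1e-12 * abs(K.diagonal()).max()

    def test_midedge_quadrature_close_to_centroid(self, blood):
        stack = synthetic.make_eccentric_annulus(10e-3, 11e-3, 0.8e-3, 30e-3, 64, 17)
        mesh = build_midgap_mesh(stack)
        q1 = solve_pressure(mesh, blood, DP_VERIF, 0.0, quadrature="centroid").Q_in
        q3 = solve_pressure(mesh, blood, DP_VERIF, 0.0, quadrature="midedge").Q_in
        assert q3 == pytest.approx(q1, rel=5e-3)


class TestSolvePressure:
    def test_uniform_strip_pressure_is_linear(self, blood):
        mesh = uniform_strip()
        sol = solve_pressure(mesh, blood, 1000.0, 0.0)
        x = mesh.points[:, 0]
        expected = 1000.0 * (1 - x / 30e-3)
        assert np.allclose(sol.p, expected, atol=1e-8 * 1000)

    def test_zero_pressure_difference(self, blood):
        mesh = uniform_strip()
        sol = solve_pressure(mesh, blood, 50.0, 50.0)
        assert np.allclose(sol.p, 50.0)
        assert np.allclose(sol.q_global, 0.0)
        assert sol.Q_in == pytest.approx(0.0, abs=1e-20)

    def test_two_gap_series_resistance(self, blood):
        # axial halves with gaps h1, h2: interface pressure follows R ~ L_i/h_i^3
        h1, h2, L = 0.4e-3, 0.8e-3, 30e-3
        n_x = 241
        mesh = uniform_strip(n_x=n_x, n_y=9)
        x = mesh.points[:, 0]
        h = np.where(x <= L / 2, h1, h2)
        mesh = ShellMesh(points=mesh.points, triangles=mesh.triangles, h=h,
                         inlet=mesh.inlet, outlet=mesh.outlet)
        dp = 1000.0
        sol = solve_pressure(mesh, blood, dp, 0.0)
        r1, r2 = (L / 2) / h1**3, (L / 2) / h2**3
        p_interface = dp * r2 / (r1 + r2)  # inlet at x=0 has the h1 half
        mid = np.isclose(x, L / 2)
        assert sol.p[mid] == pytest.approx(p_interface, rel=0.02)

    def test_maximum_principle(self, blood):
        stack = synthetic.make_eccentric_annulus(10e-3, 11e-3, 0.9e-3, 20e-3, 48, 13)
        sol = solve_pressure(build_midgap_mesh(stack), blood, 900.0, 100.0)
        assert sol.p.min() >= 100.0 - 1e-9 * 900
        assert sol.p.max() <= 900.0 + 1e-9 * 900

    def test_cg_matches_direct(self, blood, die_stack):
        mesh = build_midgap_mesh(die_stack)
        q_direct = solve_pressure(mesh, blood, DP_VERIF, 0.0, solver="direct").Q_in
        q_cg = solve_pressure(mesh, blood, DP_VERIF, 0.0, solver="cg").Q_in
        assert q_cg == pytest.approx(q_direct, rel=1e-9)


class TestFlux:
    def test_plane_poiseuille_flux_magnitude(self, blood):
        W, L, h, dp = 10e-3, 30e-3, 0.5e-3, 1000.0
        mesh = uniform_strip(W=W, L=L, h=h)
        sol = solve_pressure(mesh, blood, dp, 0.0)
        q_expected = h**3 * dp / (12 * blood.mu * L)  # ~9.92e-5 m^2/s
        qmag = np.linalg.norm(sol.q_global, axis=1)
        assert qmag == pytest.approx(q_expected, rel=1e-10)
        # axially directed: toward the outlet (+x)
        assert np.allclose(sol.q_global[:, 0], q_expected, rtol=1e-10)
        assert np.allclose(sol.q_global[:, 1:], 0.0, atol=1e-12 * q_expected)

    def test_flux_vanishes_in_clamped_regions(self, blood):
        # a partial obstruction: flow detours around it, and the dead-end
        # (ε-clamped) elements carry essentially no flux
        import warnings

        mesh = uniform_strip(n_x=61, n_y=21)
        h = mesh.h.copy()
        patch = ((mesh.points[:, 0] > 12e-3) & (mesh.points[:, 0] < 18e-3)
                 & (mesh.points[:, 1] < 6e-3))
        h[patch] = 0.0
        mesh = ShellMesh(points=mesh.points, triangles=mesh.triangles, h=h,
                         inlet=mesh.inlet, outlet=mesh.outlet)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sol = solve_pressure(mesh, blood, 1000.0, 0.0)
        clamped = np.all(patch[mesh.triangles], axis=1)
        assert clamped.any() and not clamped.all()
        open_q = np.linalg.norm(sol.q_global[~clamped], axis=1).max()
        assert np.linalg.norm(sol.q_global[clamped], axis=1).max() < 1e-6 * open_q

    def test_interior_divergence_vanishes(self, blood):
        stack = synthetic.make_eccentric_annulus(10e-3, 11e-3, 0.6e-3, 20e-3, 32, 9)
        mesh = build_midgap_mesh(stack)
        sol = solve_pressure(mesh, blood, 1000.0, 0.0)
        interior = np.setdiff1d(np.arange(mesh.n_points),
                                np.concatenate([mesh.inlet, mesh.outlet]))
        assert np.abs(sol.residual[interior]).max() < 1e-10 * abs(sol.Q_in)


class TestFlowRate:
    def test_uniform_strip_closed_form(self, blood):
        W, L, h, dp = 10e-3, 30e-3, 0.5e-3, 1000.0
        mesh = uniform_strip(W=W, L=L, h=h)
        sol = solve_pressure(mesh, blood, dp, 0.0)
        Q_expected = W * h**3 * dp / (12 * blood.mu * L)  # ~9.92e-7 m^3/s
        assert compute_flow_rate(mesh, sol, "inlet") == pytest.approx(Q_expected, rel=1e-10)

    def test_annular_die_verification(self, blood):
        stack = synthetic.make_annular_die(10e-3, 11e-3, 30e-3, 256, 64)
        sol = solve_pressure(build_midgap_mesh(stack), blood, DP_VERIF, 0.0)
        assert sol.Q_in * 1e6 == pytest.approx(697.2, rel=0.01)

    def test_linearity_in_pressure(self, blood, die_stack):
        mesh = build_midgap_mesh(die_stack)
        q1 = solve_pressure(mesh, blood, 500.0, 0.0).Q_in
        q2 = solve_pressure(mesh, blood, 1000.0, 0.0).Q_in
        assert q2 == pytest.approx(2 * q1, rel=1e-12)

    def test_cross_section_integration_agrees(self, blood, die_stack):
        mesh = build_midgap_mesh(die_stack)
        sol = solve_pressure(mesh, blood, DP_VERIF, 0.0)
        assert cross_section_flow_rate(mesh, sol) == pytest.approx(sol.Q_in, rel=1e-6)


class TestProperties:
    def test_conservation_inlet_outlet(self, blood):
        for stack in (
            synthetic.make_annular_die(10e-3, 11e-3, 30e-3, 48, 13),
            synthetic.make_eccentric_annulus(10e-3, 11e-3, 0.9e-3, 30e-3, 48, 13),
            synthetic.make_nodule_annulus(
                10e-3, 11e-3, 30e-3, [synthetic.iso5840_nodule(axial_center=15e-3)],
                48, 13),
        ):
            sol = solve_pressure(build_midgap_mesh(stack), blood, DP_VERIF, 0.0)
            assert abs(sol.Q_in - sol.Q_out) <= 1e-8 * abs(sol.Q_in)

    def test_cubed_gap_scaling(self, blood, die_stack):
        mesh = build_midgap_mesh(die_stack)
        q1 = solve_pressure(mesh, blood, 1000.0, 0.0).Q_in
        scaled = ShellMesh(points=mesh.points, triangles=mesh.triangles,
                           h=2.0 * mesh.h, inlet=mesh.inlet, outlet=mesh.outlet)
        q2 = solve_pressure(scaled, blood, 1000.0, 0.0).Q_in
        assert q2 == pytest.approx(8 * q1, rel=1e-12)

    def test_matches_finite_volume_oracle(self, blood):
        stack = synthetic.make_eccentric_annulus(10e-3, 11e-3, 0.6e-3, 30e-3, 192, 49)
        Q_fe = solve_pressure(build_midgap_mesh(stack), blood, DP_VERIF, 0.0).Q_in
        fine = synthetic.make_eccentric_annulus(10e-3, 11e-3, 0.6e-3, 30e-3, 384, 97)
        Q_fv = network_flow_rate(fine, blood.mu, DP_VERIF)
        assert Q_fe == pytest.approx(Q_fv, rel=0.005)

    def test_thin_film_error_bound_for_die(self, blood):
        # closed-form annular flow vs FE on the mid-gap shell: < 1% for h/r ~ 0.1
        from pvleak import annular_die_flow
        stack = synthetic.make_annular_die(10e-3, 11e-3, 30e-3, 128, 32)
        Q_fe = solve_pressure(build_midgap_mesh(stack), blood, DP_VERIF, 0.0).Q_in
        Q_cf = annular_die_flow(DP_VERIF, blood.mu, 30e-3,
                                stack.inner_radius[0], stack.outer_radius[0])
        assert abs(Q_fe - Q_cf) / Q_cf < 0.01

    def test_pointwise_gap_increase_never_decreases_flow(self, blood, rng):
        stack = synthetic.make_nodule_annulus(
            10e-3, 11e-3, 30e-3,
            [synthetic.NoduleSpec(0.0, 0.8e-3, 6e-3, 15e-3, 10e-3)], 48, 13)
        mesh = build_midgap_mesh(stack)
        q0 = solve_pressure(mesh, blood, 1000.0, 0.0).Q_in
        for _ in range(5):
            bump = rng.uniform(0.0, 0.2e-3, size=mesh.h.size)
            bigger = ShellMesh(points=mesh.points, triangles=mesh.triangles,
                               h=mesh.h + bump, inlet=mesh.inlet, outlet=mesh.outlet)
            q1 = solve_pressure(bigger, blood, 1000.0, 0.0).Q_in
            assert q1 >= q0 * (1 - 1e-12)

    def test_blocked_channel_below_epsilon_ceiling(self, blood):
        eps = 1e-9
        stack = synthetic.make_annular_die(10e-3, 11e-3, 30e-3, 48, 16)
        inner = stack.inner_radius.copy()
        inner[7:9] = stack.outer_radius[7:9]  # full-circumference contact band
        blocked = dataclasses.replace(stack, inner_radius=inner)
        mesh = build_midgap_mesh(blocked)
        dp = DP_VERIF
        with pytest.warns(RuntimeWarning, match="blocked|under-resolved"):
            sol = solve_pressure(mesh, blood, dp, 0.0, eps=eps)
        # series-resistance bound: the contact band alone limits the flow
        w_band = blocked.z[8] - blocked.z[7]
        perimeter = 2 * np.pi * 11e-3  # contact band sits at r = R_i = R_o
        ceiling = perimeter * eps**3 / (12 * blood.mu) * dp / w_band
        assert 0 < sol.Q <= ceiling * (1 + 1e-9)

    def test_disconnected_component_detected(self, blood):
        # two strips, one floating without boundary conditions
        m1 = uniform_strip(n_x=5, n_y=3)
        pts2 = m1.points + np.array([0.1, 0.1, 0.0])
        n1 = m1.n_points
        mesh = ShellMesh(
            points=np.vstack([m1.points, pts2]),
            triangles=np.vstack([m1.triangles, m1.triangles + n1]),
            h=np.concatenate([m1.h, m1.h]),
            inlet=m1.inlet, outlet=m1.outlet,
        )
        with pytest.raises(ValueError, match="neither inlet nor outlet"):
            solve_pressure(mesh, blood, 1000.0, 0.0)


class TestVtuExport:
    def test_written_file_contains_fields(self, tmp_path, blood, die_stack):
        mesh = build_midgap_mesh(die_stack)
        sol = solve_pressure(mesh, blood, 1000.0, 0.0)
        path = write_vtu(mesh, tmp_path / "out.vtu",
                         point_data={"p": sol.p, "h": mesh.h},
                         cell_data={"q": sol.q_global})
        text = path.read_text()
        assert text.startswith("<?xml")
        for name in ("p", "h", "q", "connectivity", "offsets", "types"):
            assert f'Name="{name}"' in text
        assert f'NumberOfPoints="{mesh.n_points}"' in text

    def test_deterministic_output(self, tmp_path, blood, die_stack):
        mesh = build_midgap_mesh(die_stack)
        sol = solve_pressure(mesh, blood, 1000.0, 0.0)
        a = write_vtu(mesh, tmp_path / "a.vtu", point_data={"p": sol.p})
        b = write_vtu(mesh, tmp_path / "b.vtu", point_data={"p": sol.p})
        assert a.read_bytes() == b.read_bytes()
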