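"""Corotational dynamics: assembly oracles, invariants, instrumentation."""

from __future__ import annotations

import numpy as np
import pytest

import lungfem as lf
from conftest import regular_tet_nodes
from simcheck import assemble_global_stiffness, static_tip_displacement


def materials_parenchyma(**overrides) -> dict:
    return lf.default_materials(overrides={1: overrides} if overrides else None)


# --------------------------------------------------------------------------
# materials and assembly
# --------------------------------------------------------------------------


class TestMaterials:
    def test_default_stiffness_ordering(self):
        mats = lf.default_materials()
        assert mats[1].young_modulus < mats[7].young_modulus  # parenchyma < vein
        assert mats[7].young_modulus < mats[6].young_modulus  # vein < artery
        assert mats[6].young_modulus < mats[8].young_modulus  # artery < bronchus

    def test_poisson_ratios_valid(self):
        for m in lf.default_materials().values():
            assert 0.0 <= m.poisson_ratio < 0.5

    def test_override_reaches_assembly(self, unit_tet_mesh):
        base = lf.assemble(unit_tet_mesh, materials_parenchyma())
        tripled = lf.assemble(unit_tet_mesh, materials_parenchyma(young_modulus=15.0))
        assert np.allclose(tripled.Ke, 3.0 * base.Ke)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            lf.MaterialParams(young_modulus=-1.0, poisson_ratio=0.3, density=1000.0)
        with pytest.raises(ValueError):
            lf.MaterialParams(young_modulus=5.0, poisson_ratio=0.6, density=1000.0)


class TestAssembly:
    def test_single_tet_stiffness_has_six_rigid_modes(self, unit_tet_mesh):
        """Symmetric PSD element stiffness with exactly 6 zero eigenvalues."""
        asm = lf.assemble(
            unit_tet_mesh, materials_parenchyma(young_modulus=1.0, poisson_ratio=0.0)
        )
        Ke = asm.Ke[0]
        assert np.allclose(Ke, Ke.T, atol=1e-9)
        w = np.linalg.eigvalsh(Ke)
        scale = np.abs(w).max()
        assert (w > -1e-10 * scale).all()
        assert (np.abs(w) < 1e-9 * scale).sum() == 6

    def test_total_lumped_mass_conserved(self, small_cage, small_assembly):
        mats = lf.default_materials()
        rho = np.array([mats[int(c)].density * 1e-6 for c in small_cage.tissue])
        expected = float((rho * small_cage.volumes()).sum())
        assert np.isclose(small_assembly.mass.sum(), expected, rtol=1e-12)

    def test_stiffness_linear_in_young_modulus(self, unit_tet_mesh):
        a = lf.assemble(unit_tet_mesh, materials_parenchyma(young_modulus=2.0))
        b = lf.assemble(unit_tet_mesh, materials_parenchyma(young_modulus=10.0))
        assert np.allclose(b.Ke, 5.0 * a.Ke)

    def test_unknown_tissue_label_named_in_error(self, unit_tet_mesh):
        mats = lf.default_materials()
        mats.pop(1)
        with pytest.raises(KeyError, match="1"):
            lf.assemble(unit_tet_mesh, mats)

    def test_element_stiffness_matches_energy_gradient_oracle(self, unit_tet_mesh):
        """Ke u equals the gradient of an independently coded strain energy.

        The oracle fits the affine displacement field through the four
        nodes, forms the small-strain tensor and the isotropic energy
        density directly, and differentiates by central differences
        (exact for a quadratic).
        """
        E_int, nu = 1.0e3, 0.0  # 1 kPa in internal units
        lam = E_int * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E_int / (2 * (1 + nu))
        nodes = unit_tet_mesh.nodes[unit_tet_mesh.tets[0]]  # element dof order
        vol = unit_tet_mesh.volumes()[0]

        def energy(u_flat: np.ndarray) -> float:
            u = u_flat.reshape(4, 3)
            A = np.column_stack([np.ones(4), nodes])
            coeff = np.linalg.solve(A, u)  # affine field: u(x) = c0 + H^T x
            H = coeff[1:].T
            eps = 0.5 * (H + H.T)
            psi = 0.5 * lam * np.trace(eps) ** 2 + mu * np.sum(eps * eps)
            return vol * psi

        asm = lf.assemble(
            unit_tet_mesh, materials_parenchyma(young_modulus=1.0, poisson_ratio=0.0)
        )
        rng = np.random.default_rng(0)
        u = 0.01 * rng.standard_normal(12)
        grad = np.empty(12)
        h = 1e-5
        for i in range(12):
            d = np.zeros(12)
            d[i] = h
            grad[i] = (energy(u + d) - energy(u - d)) / (2 * h)
        assert np.allclose(asm.Ke[0] @ u, grad, rtol=1e-7, atol=1e-10)


# --------------------------------------------------------------------------
# corotational forces
# --------------------------------------------------------------------------


class TestInternalForces:
    def test_zero_at_rest(self, small_cage, small_assembly):
        f, info = lf.internal_forces(small_cage, small_assembly, small_cage.nodes)
        scale = np.abs(small_assembly.Ke).max()  # force per mm of displacement
        assert np.abs(f).max() <= 1e-10 * scale
        assert info["inverted"] == 0

    def test_rigid_rotation_produces_no_force(self, small_cage, small_assembly):
        th = np.pi / 2
        Q = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        c = small_cage.nodes.mean(axis=0)
        rotated = (small_cage.nodes - c) @ Q.T + c + np.array([5.0, -3.0, 2.0])
        f, _ = lf.internal_forces(small_cage, small_assembly, rotated)
        scale = np.abs(small_assembly.Ke).max()
        assert np.abs(f).max() <= 1e-6 * scale

    def test_forces_sum_to_zero_at_arbitrary_configuration(self, small_cage, small_assembly):
        rng = np.random.default_rng(3)
        pos = small_cage.nodes + 5.0 * rng.standard_normal(small_cage.nodes.shape)
        f, _ = lf.internal_forces(small_cage, small_assembly, pos)
        assert np.abs(f.sum(axis=0)).max() <= 1e-8 * np.abs(f).max()

    def test_small_displacement_matches_linear_stiffness(self, unit_tet_mesh):
        """One node nudged by a small delta: f = -Ke u to 1e-6 relative."""
        asm = lf.assemble(
            unit_tet_mesh, materials_parenchyma(young_modulus=1.0, poisson_ratio=0.0)
        )
        u = np.zeros((4, 3))
        u[2] = (1e-6, -5e-7, 2e-7)
        f, _ = lf.internal_forces(unit_tet_mesh, asm, unit_tet_mesh.nodes + u)
        order = unit_tet_mesh.tets[0]  # element dof order, not node order
        fe = -(asm.Ke[0] @ u[order].ravel()).reshape(4, 3)
        expected = np.zeros((4, 3))
        expected[order] = fe
        assert np.linalg.norm(f - expected) <= 1e-6 * np.linalg.norm(expected)

    def test_corotational_tracks_linear_model_at_small_strain(self, small_cage, small_assembly):
        """Within 1% of the linear FEM force at 0.1%-of-diameter displacements."""
        K = assemble_global_stiffness(small_cage, small_assembly)
        diam = np.linalg.norm(np.ptp(small_cage.nodes, axis=0))
        rng = np.random.default_rng(5)
        u = 1e-3 * diam * rng.standard_normal(small_cage.nodes.shape)
        u /= np.abs(u).max() / (1e-3 * diam)
        f, _ = lf.internal_forces(small_cage, small_assembly, small_cage.nodes + u)
        f_lin = -(K @ u.ravel()).reshape(-1, 3)
        assert np.linalg.norm(f - f_lin) <= 0.01 * np.linalg.norm(f_lin)

    def test_inverted_element_flagged_not_fatal(self, unit_tet_mesh):
        asm = lf.assemble(unit_tet_mesh, materials_parenchyma())
        pos = unit_tet_mesh.nodes.copy()
        pos[0] = pos[1:].mean(axis=0) * 2 - pos[0]  # reflect through the far face
        f, info = lf.internal_forces(unit_tet_mesh, asm, pos)
        assert info["inverted"] == 1
        assert np.all(np.isfinite(f))


# --------------------------------------------------------------------------
# time stepping
# --------------------------------------------------------------------------


class TestStep:
    def test_rest_is_a_fixed_point(self, small_cage, small_assembly):
        state = lf.rest_state(small_cage)
        after = lf.step(state, 1e-3, small_cage, small_assembly)
        assert np.array_equal(after.positions, state.positions)
        assert np.array_equal(after.velocities, state.velocities)
        assert after.time == pytest.approx(1e-3)

    def test_free_fall_velocity_increment_exact(self, unit_tet_mesh):
        """Undamped uniform force: dv = f/m dt and dx = dt v', exactly."""
        mats = materials_parenchyma(rayleigh_alpha=0.0, rayleigh_beta=0.0)
        asm = lf.assemble(unit_tet_mesh, mats)
        force = np.tile([0.0, 0.0, -2.5], (4, 1))
        dt = 1e-3
        state = lf.rest_state(unit_tet_mesh)
        after = lf.step(state, dt, unit_tet_mesh, asm, external_forces=force)
        dv_expected = force / asm.mass[:, None] * dt
        assert np.allclose(after.velocities, dv_expected, rtol=0, atol=0)
        assert np.allclose(after.positions, state.positions + dt * after.velocities)

    def test_energy_non_increasing_with_damping(self, cube_volume):
        mesh = lf.build_tet_mesh(cube_volume, {1}, 5)
        asm = lf.assemble(mesh, lf.default_materials())
        dt = lf.stable_timestep(mesh, asm)
        rng = np.random.default_rng(2)
        state = lf.rest_state(mesh)
        state.positions = state.positions + 0.05 * rng.standard_normal(state.positions.shape)
        prev = lf.mechanical_energy(mesh, asm, state)
        for _ in range(400):
            state = lf.step(state, dt, mesh, asm)
            e = lf.mechanical_energy(mesh, asm, state)
            assert e <= prev * (1 + 1e-9)
            prev = e

    def test_fixed_nodes_stay_pinned(self, small_cage, small_assembly):
        fixed = np.array([0, 1, 2])
        state = lf.rest_state(small_cage, fixed_nodes=fixed)
        state.velocities += 1.0
        state.velocities[fixed] = 0.0
        after = lf.step(state, 1e-3, small_cage, small_assembly)
        assert np.array_equal(after.positions[fixed], small_cage.nodes[fixed])
        assert np.array_equal(after.velocities[fixed], np.zeros((3, 3)))

    def test_blow_up_raises_actionable_error(self, unit_tet_mesh):
        asm = lf.assemble(unit_tet_mesh, materials_parenchyma())
        state = lf.rest_state(unit_tet_mesh)
        state.velocities += 1e6
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(lf.SimulationDiverged, match="dt"):
                for _ in range(2000):
                    state = lf.step(state, 1.0, unit_tet_mesh, asm)


# --------------------------------------------------------------------------
# deformation inputs
# --------------------------------------------------------------------------


def cube_surface(center, size) -> lf.SurfaceMesh:
    c = np.asarray(center, float)
    h = size / 2.0
    verts = c + h * np.array(
        [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
         [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], dtype=float
    )
    faces = np.array(
        [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7], [0, 1, 5], [0, 5, 4],
         [2, 3, 7], [2, 7, 6], [1, 2, 6], [1, 6, 5], [3, 0, 4], [3, 4, 7]]
    )
    return lf.SurfaceMesh(vertices=verts, faces=faces)


class TestFissureDeformations:
    @pytest.fixture()
    def five_lobes(self) -> dict[int, lf.SurfaceMesh]:
        return {
            1: cube_surface((0, 0, 30), 10),
            2: cube_surface((0, 0, 0), 20),  # same shape as 1, scaled 2x
            3: cube_surface((100, 0, 40), 12),
            4: cube_surface((100, 0, 0), 12),
            5: cube_surface((100, 40, 0), 12),
        }

    def test_magnitude_proportional_to_lobe_size(self, five_lobes):
        defs = {d.lobe: d for d in lf.default_fissure_deformations(five_lobes)}
        m1 = np.linalg.norm(defs[1].displacement_vector)
        m2 = np.linalg.norm(defs[2].displacement_vector)
        assert m2 == pytest.approx(2.0 * m1, rel=1e-9)

    def test_displacement_points_away_from_adjacent_lobe(self, five_lobes):
        centroids = {c: m.centroid() for c, m in five_lobes.items()}
        partners = {1: [2], 2: [1], 3: [4, 5], 4: [3, 5], 5: [3, 4]}
        for d in lf.default_fissure_deformations(five_lobes):
            others = [centroids[p] for p in partners[d.lobe]]
            nearest = min(others, key=lambda c: np.linalg.norm(c - centroids[d.lobe]))
            toward = nearest - centroids[d.lobe]
            assert float(d.displacement_vector @ toward) < 0

    def test_duration_defaults_to_tenth_of_a_second(self, five_lobes):
        for d in lf.default_fissure_deformations(five_lobes):
            assert d.duration == pytest.approx(0.1)

    def test_missing_lobes_rejected_with_inventory(self, five_lobes):
        five_lobes.pop(4)
        with pytest.raises(ValueError, match=r"\[1, 2, 3, 5\]"):
            lf.default_fissure_deformations(five_lobes)

    def test_handles_sit_on_fissure_facing_side(self, lobe_surfaces):
        defs = {d.lobe: d for d in lf.default_fissure_deformations(lobe_surfaces)}
        for code, d in defs.items():
            mesh = lobe_surfaces[code]
            handle_centroid = mesh.vertices[d.handle_vertices].mean(axis=0)
            # handles lie on the side the displacement pulls away from
            away = d.displacement_vector / np.linalg.norm(d.displacement_vector)
            assert float((handle_centroid - mesh.centroid()) @ away) < 0


# --------------------------------------------------------------------------
# simulation driver and instrumentation
# --------------------------------------------------------------------------


class TestRunSimulation:
    @pytest.fixture()
    def small_deformation(self, small_cage) -> lf.DeformationInput:
        x = small_cage.nodes[:, 0]
        handles = np.flatnonzero(x >= np.quantile(x, 0.9))
        return lf.DeformationInput(
            handle_vertices=handles, displacement_vector=np.array([1.0, 0.0, 0.0]), lobe=2
        )

    def test_zero_magnitude_input_leaves_model_still(self, small_cage, small_assembly):
        d = lf.DeformationInput(
            handle_vertices=np.array([0]), displacement_vector=np.zeros(3)
        )
        trace = lf.run_simulation(
            small_cage, small_assembly, d, t_max=0.3, dt=0.05, substeps=2
        )
        assert np.all(trace.mean_displacement == 0.0)

    def test_trace_time_grid(self, small_cage, small_assembly, small_deformation):
        trace = lf.run_simulation(
            small_cage, small_assembly, small_deformation, t_max=0.5, dt=0.05, substeps=2
        )
        assert np.allclose(trace.times, np.arange(11) * 0.05)
        assert trace.input_end_time == pytest.approx(0.1)

    def test_identical_inputs_give_bit_identical_traces(
        self, small_cage, small_assembly, small_deformation
    ):
        kwargs = dict(t_max=0.3, dt=0.05, substeps=3, record_positions=True)
        a = lf.run_simulation(small_cage, small_assembly, small_deformation, **kwargs)
        b = lf.run_simulation(small_cage, small_assembly, small_deformation, **kwargs)
        assert np.array_equal(a.mean_displacement, b.mean_displacement)
        for pa, pb in zip(a.positions, b.positions):
            assert np.array_equal(pa, pb)

    def test_tmax_must_exceed_input_duration(self, small_cage, small_assembly, small_deformation):
        with pytest.raises(ValueError, match="t_max"):
            lf.run_simulation(small_cage, small_assembly, small_deformation, t_max=0.05)

    def test_handles_resolve_through_embedding(self, small_cage, small_embedding):
        d = lf.DeformationInput(
            handle_vertices=np.array([0, 1]), displacement_vector=np.ones(3)
        )
        nodes = lf.simulation.resolve_handles(d, small_embedding)
        expected = np.unique(small_embedding.node_indices[[0, 1]])
        assert np.array_equal(nodes, expected)


class TestConvergenceTime:
    def hand_trace(self, disp, dt=0.1, end=0.5) -> lf.SimTrace:
        disp = np.asarray(disp, float)
        times = np.arange(len(disp)) * dt
        return lf.SimTrace(
            times=times, mean_displacement=disp,
            wall_s=np.full(len(disp), 1e-3), input_end_time=end,
        )

    def test_zero_deformation_converges_immediately(self):
        trace = self.hand_trace(np.zeros(30))
        assert lf.convergence_time(trace) == 0.0

    def test_monotone_decay_crossing_eps_at_known_frame(self):
        """Displacement drops below eps at t=1.2 -> 0.7 s after input end."""
        disp = np.where(np.arange(30) * 0.1 < 1.2, 1.0, 1e-4)
        trace = self.hand_trace(disp)
        assert lf.convergence_time(trace, eps=1e-3) == pytest.approx(1.2 - 0.5)

    def test_larger_eps_never_slower(self):
        disp = 1.0 * np.exp(-np.arange(60) * 0.1 * 2.0)
        trace = self.hand_trace(disp, dt=0.1, end=0.5)
        t_tight = lf.convergence_time(trace, eps=1e-3)
        t_loose = lf.convergence_time(trace, eps=1e-1)
        assert t_loose <= t_tight

    def test_never_settling_returns_infinity(self):
        trace = self.hand_trace(np.ones(30))
        assert lf.convergence_time(trace) == np.inf


class TestFrameStats:
    def make_trace(self, durations) -> lf.SimTrace:
        n = len(durations) + 1
        return lf.SimTrace(
            times=np.arange(n) / 90.0,
            mean_displacement=np.zeros(n),
            wall_s=np.concatenate([[0.0], durations]),
            input_end_time=0.1,
        )

    def test_uniform_durations_give_exact_mean(self):
        stats = lf.frame_stats(self.make_trace(np.full(20, 1.0 / 90.0)))
        assert stats.mean_fps == pytest.approx(90.0)
        assert stats.min_fps == pytest.approx(90.0)

    def test_min_fps_from_slowest_frame(self):
        stats = lf.frame_stats(self.make_trace(np.array([1 / 100, 1 / 50])))
        assert stats.min_fps == pytest.approx(50.0)

    def test_series_length_is_frames_minus_one(self):
        trace = self.make_trace(np.full(33, 1e-2))
        stats = lf.frame_stats(trace)
        assert len(stats.fps_series) == len(trace.times) - 1
        assert np.all(stats.fps_series > 0)
        assert stats.min_fps <= stats.mean_fps


class TestStaticResponse:
    def test_doubling_stiffness_halves_tip_displacement(self, bar_volume):
        """Linear-regime parameter recovery through the dynamics path."""
        d1 = static_tip_displacement(bar_volume, young_kpa=5.0)
        d2 = static_tip_displacement(bar_volume, young_kpa=10.0)
        assert d1 > 0.01  # the load visibly bends the bar
        assert d2 == pytest.approx(d1 / 2.0, rel=0.02)
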