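"""Shared simulation checks used by both the unit and acceptance suites."""

from __future__ import annotations

import numpy as np

import lungfem as lf


def assemble_global_stiffness(mesh: lf.TetMesh, assembly: lf.Assembly) -> np.ndarray:
    """Dense global stiffness from the per-element blocks (test-side)."""
    n = len(mesh.nodes)
    K = np.zeros((3 * n, 3 * n))
    for e, tet in enumerate(mesh.tets):
        dof = np.concatenate([[3 * i, 3 * i + 1, 3 * i + 2] for i in tet])
        K[np.ix_(dof, dof)] += assembly.Ke[e]
    return K


def settle_under_load(
    mesh: lf.TetMesh,
    assembly: lf.Assembly,
    fixed: np.ndarray,
    load: np.ndarray,
    v_tol: float = 1e-7,
    max_steps: int = 60000,
) -> np.ndarray:
    """Dynamic relaxation to static equilibrium under a constant load."""
    dt = lf.stable_timestep(mesh, assembly)
    state = lf.rest_state(mesh, fixed_nodes=fixed)
    for _ in range(max_steps):
        state = lf.step(state, dt, mesh, assembly, external_forces=load)
        if np.abs(state.velocities).max() < v_tol:
            break
    return state.positions - mesh.nodes


def static_tip_displacement(bar_volume: lf.LabelVolume, young_kpa: float) -> float:
    """Mean tip deflection of a clamped parenchyma bar under a small end load."""
    mesh = lf.build_tet_mesh(bar_volume, {1}, 60)
    mats = lf.default_materials(
        overrides={1: {"young_modulus": young_kpa, "rayleigh_alpha": 40.0, "rayleigh_beta": 2e-3}}
    )
    assembly = lf.assemble(mesh, mats)
    x = mesh.nodes[:, 0]
    fixed = np.flatnonzero(x <= x.min() + 1e-6)
    tip = np.flatnonzero(x >= x.max() - 1e-6)
    load = np.zeros_like(mesh.nodes)
    load[tip, 1] = 40.0 / len(tip)  # micronewtons, keeps the response linear
    disp = settle_under_load(mesh, assembly, fixed, load)
    return float(np.linalg.norm(disp[tip], axis=1).mean())
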