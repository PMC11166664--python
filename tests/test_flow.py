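"""Flow solver verification: rest states, Poiseuille limits, conservation,
boundary handling, viscous scaling, and time-scheme self-convergence."""
import dataclasses
import math

import numpy as np
import pytest

from sacflow.flow import (FlowBCs, FlowSolver, FlowSolverConfig, FlowState,
                          boundary_flux, divergence_norm)
from sacflow.geometry import rectangle_mesh
from sacflow.postprocess import sample_line
from sacflow.properties import EffectiveProperties


def make_props(rho=1063.0, mu=0.003):
    return EffectiveProperties(rho=rho, rho_cp=rho * 3746, mu=mu, k=0.52,
                               nu=mu / rho, alpha=0.52 / (rho * 3746))


H, L, U = 0.09, 0.7, 0.08


@pytest.fixture(scope="module")
def poiseuille():
    mesh = rectangle_mesh(L, H, 28, 8)
    solver = FlowSolver(mesh, make_props(), FlowBCs(v0=U, inlet_profile="parabolic"))
    return mesh, solver, solver.solve_steady()


def centerline_dpdz(mesh, state, x_line):
    p = sample_line(state.pressure, mesh, (0.1 * L, x_line), (0.9 * L, x_line), 2)
    return (p.values[0] - p.values[1]) / (0.8 * L)


def test_rest_state_is_fixed_point():
    """Zero inflow with equal boundary pressures reproduces rest exactly."""
    mesh = rectangle_mesh(L, H, 10, 4)
    bcs = FlowBCs(v0=0.0, p_out=13000.0, p_rupture=13000.0)
    solver = FlowSolver(mesh, make_props(), bcs)
    st = solver.step(solver.initial_state())
    # velocity roundoff floor is set by the 1.3e4 Pa pressure scale
    assert np.abs(st.velocity).max() <= 1e-10
    assert np.abs(st.pressure - 13000.0).max() <= 1e-9 * 13000


def test_plug_inlet_nodal_speeds():
    mesh = rectangle_mesh(L, H, 10, 4)
    solver = FlowSolver(mesh, make_props(), FlowBCs(v0=U, inlet_profile="plug"))
    inlet = solver.space.nodes_on("INLET")
    st = solver.step(solver.initial_state())
    assert np.allclose(st.velocity[inlet, 0], U, atol=1e-12)
    assert np.allclose(st.velocity[inlet, 1], 0.0, atol=1e-12)
    # inlet flux magnitude is exactly v0 * H
    assert abs(solver.boundary_flux(st, "INLET")) == pytest.approx(U * H, rel=1e-12)


def test_parabolic_profile_peak():
    mesh = rectangle_mesh(L, H, 10, 8)
    solver = FlowSolver(mesh, make_props(), FlowBCs(v0=U, inlet_profile="parabolic"))
    inlet = solver.space.nodes_on("INLET")
    prof = solver.inlet_profile_values(solver.space.nodes2[inlet])
    assert prof.max() == pytest.approx(1.5 * U, rel=1e-12)


def test_zero_viscosity_rejected():
    # bypass the dataclass guard to exercise the solver's own precondition
    p = EffectiveProperties(rho=1, rho_cp=1, mu=1, k=1, nu=1, alpha=1)
    object.__setattr__(p, "mu", 0.0)
    with pytest.raises(ValueError):
        FlowSolver(rectangle_mesh(L, H, 4, 2), p, FlowBCs())


def test_closed_cavity_pins_pressure_nullspace():
    """All-wall domain: the solver detects the pressure nullspace and pins
    one value instead of failing on a singular system."""
    mesh = rectangle_mesh(0.1, 0.1, 4, 4)
    mesh.boundary_tags[:] = "WALL"
    solver = FlowSolver(mesh, make_props(), FlowBCs(v0=0.0))
    assert solver.pin_pressure
    st = solver.solve_steady()
    assert np.abs(st.velocity).max() <= 1e-10
    assert np.abs(st.pressure - 13000.0).max() <= 1e-6


def test_divergence_norm_examples():
    mesh = rectangle_mesh(1.0, 1.0, 6, 6)
    sp_nodes = FlowSolver(mesh, make_props(), FlowBCs()).space.nodes2
    uniform = FlowState(0.0, np.tile([0.3, -0.2], (len(sp_nodes), 1)),
                        np.zeros(mesh.n_nodes))
    assert divergence_norm(uniform, mesh) <= 1e-12
    # v = (z, -x): analytically divergence-free
    v = np.column_stack([sp_nodes[:, 0], -sp_nodes[:, 1]])
    assert divergence_norm(FlowState(0, v, np.zeros(mesh.n_nodes)), mesh) <= 1e-12
    # v = (z, x): constant divergence 2 over unit area
    v = sp_nodes.copy()
    assert divergence_norm(FlowState(0, v, np.zeros(mesh.n_nodes)), mesh) \
        == pytest.approx(2.0, rel=1e-12)


def test_uniform_flow_flux_antisymmetry():
    mesh = rectangle_mesh(L, H, 8, 4)
    sp = FlowSolver(mesh, make_props(), FlowBCs()).space
    v = np.tile([0.1, 0.0], (sp.n2, 1))
    st = FlowState(0.0, v, np.zeros(mesh.n_nodes))
    fin = boundary_flux(st, mesh, "INLET")
    fout = boundary_flux(st, mesh, "OUTLET")
    assert fin == pytest.approx(-fout, rel=1e-12)
    with pytest.raises(KeyError):
        boundary_flux(st, mesh, "BOGUS")


# ------------------------------------------------------- Poiseuille limits --

def test_plane_poiseuille_closed_form(poiseuille):
    mesh, solver, st = poiseuille
    assert st.speed().max() / U == pytest.approx(1.5, rel=0.01)
    exact = 12 * 0.003 * U / H**2
    assert centerline_dpdz(mesh, st, H / 2) == pytest.approx(exact, rel=0.02)
    # pointwise profile at mid-length matches the parabola within 1%
    # (sampled at vertex-aligned stations: the linear sampling of the
    # quadratic profile is exact there)
    xs = np.linspace(0.0, H, 9)
    prof = sample_line(st.speed()[:mesh.n_nodes], mesh, (L / 2, 0.0), (L / 2, H), 9)
    exact_prof = 6 * U * xs * (H - xs) / H**2
    assert np.abs(prof.values - exact_prof).max() <= 0.01 * (1.5 * U)
    # symmetry about the midline
    assert np.abs(prof.values - prof.values[::-1]).max() <= 0.01 * (1.5 * U)


def test_hagen_poiseuille_axisymmetric():
    R = 0.045
    mesh = rectangle_mesh(L, R, 28, 8, mode="axisymmetric")
    solver = FlowSolver(mesh, make_props(), FlowBCs(v0=U, inlet_profile="parabolic"))
    st = solver.solve_steady()
    assert st.speed().max() / U == pytest.approx(2.0, rel=0.01)
    exact = 8 * 0.003 * U / R**2
    assert centerline_dpdz(mesh, st, 0.0) == pytest.approx(exact, rel=0.02)


def test_stokes_limit_matches_full_solver_at_small_inflow():
    """With convection disabled the Stokes solve agrees with the full solver
    as v0 -> 0 (identical to leading order)."""
    mesh = rectangle_mesh(L, H, 10, 4)
    v0 = 1e-6
    bcs = FlowBCs(v0=v0, inlet_profile="parabolic")
    full = FlowSolver(mesh, make_props(), bcs).solve_steady()
    stokes = FlowSolver(mesh, make_props(), bcs,
                        FlowSolverConfig(include_convection=False)).solve_steady()
    denom = np.abs(full.velocity).max()
    assert np.abs(full.velocity - stokes.velocity).max() <= 1e-6 * denom


def test_stokes_pressure_drop_scaling():
    """Delta-p scales linearly in mu and in v0 in the Stokes regime."""
    mesh = rectangle_mesh(L, H, 14, 6)
    cfg = FlowSolverConfig(include_convection=False)

    def dpdz(mu, v0):
        st = FlowSolver(mesh, make_props(mu=mu),
                        FlowBCs(v0=v0, inlet_profile="parabolic"), cfg).solve_steady()
        return centerline_dpdz(mesh, st, H / 2)

    base = dpdz(0.003, U)
    assert dpdz(0.03, U) == pytest.approx(10 * base, rel=1e-6)
    assert dpdz(0.03, U / 10) == pytest.approx(base, rel=1e-6)


def test_effective_viscosity_couples_to_pressure_drop(blood_props, hnf_props):
    """Replacing blood by the hybrid mixture rescales the Poiseuille
    pressure drop by exactly mu_hnf / mu_f (within 0.5%)."""
    mesh = rectangle_mesh(L, H, 14, 6)
    # modest inflow keeps outlet-defect convective feedback negligible
    bcs = FlowBCs(v0=U / 10, inlet_profile="parabolic")
    d_f = centerline_dpdz(mesh, FlowSolver(mesh, blood_props, bcs).solve_steady(), H / 2)
    d_h = centerline_dpdz(mesh, FlowSolver(mesh, hnf_props, bcs).solve_steady(), H / 2)
    assert d_h / d_f == pytest.approx(hnf_props.mu / blood_props.mu, rel=0.005)


# -------------------------------------------------------- time integration --

def test_bdf2_self_convergence():
    """Halving dt on a smooth forced transient drops the time error ~4x."""
    mesh = rectangle_mesh(1.0, 1.0, 8, 8)
    props = EffectiveProperties(rho=1.0, rho_cp=1.0, mu=0.05, k=1.0,
                                nu=0.05, alpha=1.0)
    t_final = 0.4

    def solve(dt):
        bcs = FlowBCs(v0=0.0, p_out=0.0, p_rupture=0.0, backflow_beta=0.0)
        cfg = FlowSolverConfig(dt=dt, t_end=t_final, picard_tol=1e-11,
                               picard_max=40)
        solver = FlowSolver(mesh, props, bcs, cfg,
                            dirichlet_velocity=lambda z, x: (0.0 * z, 0.0 * x))
        st, prev = solver.initial_state(), None
        st = dataclasses.replace(st, pressure=np.zeros(mesh.n_nodes))
        n = int(round(t_final / dt))
        for k in range(n):
            t_new = (k + 1) * dt
            amp = math.sin(math.pi * t_new / (2 * t_final))

            def force(z, x, a=amp):
                return (a * np.sin(np.pi * x) * np.ones_like(z),
                        a * np.sin(np.pi * z) * np.ones_like(x))

            solver.body_force = force
            new = solver.step(st, prev)
            prev, st = st, new
        return st.velocity

    u1, u2, u3 = solve(0.05), solve(0.025), solve(0.0125)
    e12 = np.linalg.norm(u1 - u2)
    e23 = np.linalg.norm(u2 - u3)
    ratio = e12 / e23
    assert 3.0 <= ratio <= 6.0  # second-order: ~4
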