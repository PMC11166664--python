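"""Energy-equation verification: dissipation closed forms, insulation
invariants, conduction limits, the maximum principle, and energy audits."""
import numpy as np
import pytest

from sacflow.flow import FlowBCs, FlowSolver, FlowState
from sacflow.geometry import rectangle_mesh
from sacflow.properties import EffectiveProperties
from sacflow.thermal import (ThermalBCs, ThermalConfig, ThermalSolver,
                             ThermalState, thermal_energy,
                             viscous_dissipation_field)

H, L, U = 0.09, 0.7, 0.08


def make_props(rho=1063.0, mu=0.003, k=0.52, cp=3746.0):
    return EffectiveProperties(rho=rho, rho_cp=rho * cp, mu=mu, k=k,
                               nu=mu / rho, alpha=k / (rho * cp))


@pytest.fixture(scope="module")
def channel_flow():
    mesh = rectangle_mesh(L, H, 28, 8)
    solver = FlowSolver(mesh, make_props(), FlowBCs(v0=U, inlet_profile="parabolic"))
    return mesh, solver, solver.solve_steady()


# ----------------------------------------------------------- dissipation ----

def test_dissipation_zero_for_uniform_velocity(channel_flow):
    mesh, solver, _ = channel_flow
    v = np.tile([0.2, -0.1], (solver.space.n2, 1))
    st = FlowState(0.0, v, np.zeros(mesh.n_nodes))
    d = viscous_dissipation_field(st, make_props(), mesh, space=solver.space)
    assert np.abs(d).max() <= 1e-12


def test_dissipation_pure_shear_closed_form(channel_flow):
    """u_axial = gamma * x gives mu * gamma^2 everywhere."""
    mesh, solver, _ = channel_flow
    gamma = 7.0
    v = np.zeros((solver.space.n2, 2))
    v[:, 0] = gamma * solver.space.nodes2[:, 1]
    st = FlowState(0.0, v, np.zeros(mesh.n_nodes))
    d = viscous_dissipation_field(st, make_props(), mesh, space=solver.space)
    assert d == pytest.approx(0.003 * gamma**2, rel=1e-12)


def test_poiseuille_dissipation_equals_pressure_work(channel_flow):
    """Integrated mu*Phi equals Delta-p times the volumetric flux within 2%
    (mechanical energy balance of fully developed channel flow)."""
    mesh, solver, st = channel_flow
    d = viscous_dissipation_field(st, make_props(), mesh, space=solver.space)
    total = float((d * mesh.areas()).sum())
    exact = (12 * 0.003 * U / H**2) * L * (U * H)
    assert total == pytest.approx(exact, rel=0.02)


def test_axisymmetric_dissipation_includes_hoop_term():
    """Uniform radial velocity u_r = c: planar invariant vanishes except the
    2(u_r/r)^2 hoop contribution."""
    mesh = rectangle_mesh(1.0, 1.0, 6, 6, mode="axisymmetric")
    mesh.nodes[:, 1] += 1.0  # shift off the axis so r in [1, 2]
    solver = FlowSolver(mesh, make_props(), FlowBCs(v0=0.0))
    c = 0.3
    v = np.zeros((solver.space.n2, 2))
    v[:, 1] = c
    st = FlowState(0.0, v, np.zeros(mesh.n_nodes))
    d = viscous_dissipation_field(st, make_props(), mesh, space=solver.space)
    r_mid = solver.space.rq.mean()
    assert d.min() >= 2 * 0.003 * (c / 2.0) ** 2 * 0.99
    assert d.max() <= 2 * 0.003 * (c / 1.0) ** 2 * 1.01


# ------------------------------------------------------------ invariants ----

def test_uniform_temperature_invariance(channel_flow):
    """T = T_inlet with dissipation off is exactly preserved by insulated
    walls and advective outflow."""
    mesh, fsolver, flow = channel_flow
    ts = ThermalSolver(mesh, make_props(), ThermalBCs(),
                       ThermalConfig(include_dissipation=False),
                       space=fsolver.space)
    T, prev = ts.initial_state(), None
    for _ in range(25):
        new = ts.step(T, flow, prev)
        prev, T = T, new
    assert np.abs(T.temperature - 310.0).max() <= 1e-9


def test_insulated_diffusion_conserves_energy_and_reaches_mean():
    """Closed insulated domain, zero flow: energy is conserved and a
    two-level initial strip relaxes to its uniform mean."""
    mesh = rectangle_mesh(L, H, 20, 4)
    props = make_props(k=0.52 * 1e5)  # fast-diffusing variant
    ts = ThermalSolver(mesh, props, ThermalBCs(inlet_dirichlet=False),
                       ThermalConfig(include_dissipation=False, dt=0.5))
    T0 = np.where(mesh.nodes[:, 0] < L / 2, 311.0, 309.0)
    T = ThermalState(0.0, T0.astype(float))
    e0 = ts.energy(T)
    mean0 = e0 / (props.rho_cp * L * H)
    prev = None
    for _ in range(60):
        new = ts.step(T, None, prev)
        prev, T = T, new
    assert ts.energy(T) == pytest.approx(e0, rel=1e-8)
    assert np.abs(T.temperature - mean0).max() <= 1e-3


def test_maximum_principle_smooth_pulse():
    """With dissipation off, temperatures stay inside the analytic
    initial/inlet range [310, 311] K (tolerance 1e-6 K) while a resolved
    smooth pulse diffuses and advects."""
    mesh = rectangle_mesh(L, H, 60, 10)
    props = make_props(k=52.0)
    fsolver = FlowSolver(mesh, props, FlowBCs(v0=0.01, inlet_profile="parabolic"))
    flow = fsolver.solve_steady()
    ts = ThermalSolver(mesh, props, ThermalBCs(T_inlet=310.0),
                       ThermalConfig(include_dissipation=False),
                       space=fsolver.space)
    r2 = (mesh.nodes[:, 0] - 0.3) ** 2
    T = ThermalState(0.0, 310.0 + 1.0 * np.exp(-r2 / 0.08**2))
    lo, hi = 310.0, 311.0  # analytic range of the initial + inlet data
    prev = None
    for _ in range(30):
        new = ts.step(T, flow, prev)
        prev, T = T, new
        assert T.temperature.min() >= lo - 1e-6
        assert T.temperature.max() <= hi + 1e-6


def test_steady_conduction_linear_profile():
    """Pinned end temperatures, zero flow: the steady profile is linear."""
    mesh = rectangle_mesh(L, H, 20, 4)
    ts = ThermalSolver(mesh, make_props(),
                       ThermalBCs(T_inlet=310.0, pinned={"OUTLET": 300.0}),
                       ThermalConfig(include_dissipation=False, supg=False))
    T = ts.solve_steady()
    exact = 310.0 + (300.0 - 310.0) * mesh.nodes[:, 0] / L
    assert np.abs(T.temperature - exact).max() / 310.0 <= 1e-6


# ---------------------------------------------------------- energy audit ----

def test_energy_constant_while_interior_pulse_advects(channel_flow):
    """Fully insulated open channel: while a compactly supported pulse stays
    interior, no energy crosses the boundary, so the total is conserved
    within 1% (exercises the discrete budget including SUPG)."""
    mesh, fsolver, flow = channel_flow
    props = make_props()
    ts = ThermalSolver(mesh, props, ThermalBCs(inlet_dirichlet=False),
                       ThermalConfig(include_dissipation=False,
                                     time_scheme="euler"),
                       space=fsolver.space)
    r2 = (mesh.nodes[:, 0] - 0.2) ** 2 + (mesh.nodes[:, 1] - H / 2) ** 2
    T = ThermalState(0.0, np.exp(-r2 / 0.03**2))
    base = props.rho_cp * L * H * 0.0  # zero background
    e0 = ts.energy(T) - base
    prev = None
    for _ in range(20):
        new = ts.step(T, flow, prev)
        prev, T = T, new
    assert ts.energy(T) - base == pytest.approx(e0, rel=0.01)


def test_dissipation_heats_insulated_domain(channel_flow):
    """With dissipation on, energy is nondecreasing and grows at the rate of
    the integrated viscous heating."""
    mesh, fsolver, flow = channel_flow
    props = make_props()
    ts = ThermalSolver(mesh, props, ThermalBCs(inlet_dirichlet=False),
                       ThermalConfig(include_dissipation=True,
                                     time_scheme="euler"),
                       space=fsolver.space)
    T = ThermalState(0.0, np.full(mesh.n_nodes, 310.0))
    e0 = ts.energy(T)
    new = ts.step(T, flow)
    de_dt = (ts.energy(new) - e0) / ts.config.dt
    d = viscous_dissipation_field(flow, props, mesh, space=fsolver.space)
    expected = float((d * mesh.areas()).sum())
    assert de_dt > 0
    assert de_dt == pytest.approx(expected, rel=0.05)


def test_thermal_energy_wrapper(channel_flow):
    mesh, _, _ = channel_flow
    props = make_props()
    st = ThermalState(0.0, np.full(mesh.n_nodes, 2.0))
    assert thermal_energy(st, props, mesh) == pytest.approx(
        props.rho_cp * 2.0 * L * H, rel=1e-12)


def test_nonpositive_inlet_temperature_rejected():
    with pytest.raises(ValueError):
        ThermalBCs(T_inlet=-1.0)
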