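"""Transient energy transport on the flow solution.

Solves (rho Cp)_hnf (dT/dt + v . grad T) = k_hnf laplace(T) + mu_hnf * Phi
with linear (P1) temperature elements, one-way coupled to the Taylor-Hood
velocity.  Walls are thermally insulated (homogeneous natural condition), the
inlet carries a Dirichlet temperature, and open boundaries (outlet, rupture
orifice) are advective: zero diffusive flux.  Blood conductivity makes the
transport strongly advection dominated, so the Galerkin operator is
stabilized with streamline upwinding (SUPG); the stabilization is residual
based and therefore vanishes on exact solutions (in particular it leaves a
uniform temperature field exactly invariant).

The viscous-dissipation source mu * Phi uses the velocity-gradient invariant
of the planar or swirl-free cylindrical strain rate; the pressure-work term
of the compressible energy equation is excluded by default (incompressible
model) but can be enabled with a standard Boussinesq-type expansivity.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from ._fem import EDGE_S, FEMSpace
from .flow import AXIAL, TRANSVERSE, FlowState, SolverError
from .geometry import INLET, OUTLET, Mesh
from .properties import EffectiveProperties

__all__ = [
    "ThermalBCs",
    "ThermalConfig",
    "ThermalState",
    "ThermalSolver",
    "viscous_dissipation_field",
    "step_thermal",
    "thermal_energy",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThermalBCs:
    """Inlet temperature (K) and the insulated-boundary convention.

    ``pinned``: optional {tag: temperature} Dirichlet overrides used by the
    steady-conduction verification variant (e.g. pin OUTLET as well).
    """

    T_inlet: float = 310.0
    insulated_walls: bool = True
    inlet_dirichlet: bool = True  # False: fully insulated domain (energy audits)
    pinned: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.T_inlet <= 0:
            raise ValueError("T_inlet must be positive (absolute temperature)")


@dataclass(frozen=True)
class ThermalConfig:
    include_dissipation: bool = True
    include_pressure_work: bool = False
    alpha_p: float = 3.0e-4  # volumetric expansivity for the optional Q_p, 1/K
    dt: float = 0.01
    time_scheme: str = "bdf2"
    supg: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class ThermalState:
    t: float
    temperature: np.ndarray  # (nv,) K at vertices


def _dissipation_quad(space: FEMSpace, velocity: np.ndarray) -> np.ndarray:
    """Strain-rate invariant Phi at quadrature points (M, nq), 1/s^2."""
    guz = space.grad2(velocity[:, 0])       # (M, nq, 2): d u_axial / d(z, x)
    gux = space.grad2(velocity[:, 1])
    phi = (2.0 * gux[:, :, TRANSVERSE] ** 2 + 2.0 * guz[:, :, AXIAL] ** 2
           + (gux[:, :, AXIAL] + guz[:, :, TRANSVERSE]) ** 2)
    if space.axisym:
        ur = space.eval2(velocity[:, 1])
        phi = phi + 2.0 * (ur / space.rq) ** 2
    return phi


def viscous_dissipation_field(flow_state: FlowState, props: EffectiveProperties,
                              mesh: Mesh, space: Optional[FEMSpace] = None
                              ) -> np.ndarray:
    """Element-averaged viscous heating mu * Phi, W m^-3 (one value per
    triangle; nonnegative by construction)."""
    sp = space if space is not None else FEMSpace(mesh)
    phi = _dissipation_quad(sp, flow_state.velocity)
    # area-weighted average over the element's quadrature points
    w = sp.wdet_plane
    return props.mu * (w * phi).sum(axis=1) / w.sum(axis=1)


class ThermalSolver:
    """P1 SUPG advection-diffusion stepper sharing the flow solver's mesh."""

    def __init__(self, mesh: Mesh, props: EffectiveProperties,
                 bcs: ThermalBCs = ThermalBCs(),
                 config: ThermalConfig = ThermalConfig(),
                 space: Optional[FEMSpace] = None):
        self.mesh = mesh
        self.space = space if space is not None else FEMSpace(mesh)
        self.props = props
        self.bcs = bcs
        self.config = config
        self.nv = mesh.n_nodes
        self.alpha = props.alpha
        sp = self.space
        # Dirichlet nodes: inlet always; optional pinned tags for verification
        pin: dict[int, float] = {}
        if bcs.inlet_dirichlet:
            for n in np.unique(mesh.boundary_edges[mesh.boundary_tags == INLET]):
                pin[int(n)] = bcs.T_inlet
        for tag, val in (bcs.pinned or {}).items():
            for n in np.unique(mesh.boundary_edges[mesh.boundary_tags == tag]):
                pin[int(n)] = float(val)
        self.dir_idx = np.array(sorted(pin), dtype=np.int64)
        self.dir_val = np.array([pin[i] for i in self.dir_idx])
        self.free = np.ones(self.nv, dtype=bool)
        self.free[self.dir_idx] = False
        # constant Galerkin blocks
        w = sp.wdet
        self.Me = np.einsum("mq,qa,qb->mab", w, sp.N1, sp.N1)
        self.Ke = self.alpha * np.einsum("mq,mqad,mqbd->mab", w, sp.dphi1, sp.dphi1)

    def initial_state(self, T0: Optional[float] = None) -> ThermalState:
        T = np.full(self.nv, self.bcs.T_inlet if T0 is None else T0)
        T[self.dir_idx] = self.dir_val
        return ThermalState(t=0.0, temperature=T)

    # ------------------------------------------------------------------
    def _system(self, vel_quad: np.ndarray, coeff: float, newmark_rhs,
                source_quad: Optional[np.ndarray]):
        """Assemble (A, b) for one implicit step divided through by
        (rho Cp): dT-part coeff*T - rhs_hist = -v.grad T + alpha lap T + s."""
        sp = self.space
        nq = sp.N1.shape[0]
        adv = np.einsum("mqd,mqbd->mqb", vel_quad, sp.dphi1)  # v.grad N_b
        Ce = np.einsum("mq,qa,mqb->mab", sp.wdet, sp.N1, adv)
        Ae = self.Ke + Ce + coeff * self.Me
        rhs_q = np.zeros((len(sp.detJ), nq))
        if newmark_rhs is not None:
            rhs_q += sp.eval1(newmark_rhs)
        if source_quad is not None:
            rhs_q += source_quad
        be = np.einsum("mq,qa->ma", sp.wdet * rhs_q, sp.N1)
        if self.config.supg:
            speed = np.sqrt((vel_quad ** 2).sum(-1)) + 1e-300
            h = sp.h_elem[:, None]
            tau = 1.0 / np.sqrt((2.0 * coeff) ** 2 + (2.0 * speed / h) ** 2
                                + (12.0 * self.alpha / h**2) ** 2)
            # test-function perturbation tau * v.grad N_a against the strong
            # residual (P1: element Laplacian vanishes)
            wts = sp.wdet * tau
            Ae = Ae + np.einsum("mq,mqa,mqb->mab", wts, adv, adv)
            Ae = Ae + coeff * np.einsum("mq,mqa,qb->mab", wts, adv, sp.N1)
            be = be + np.einsum("mq,mqa->ma", wts * rhs_q, adv)
        tris = self.mesh.triangles
        A = sp.assemble(Ae, tris, tris, (self.nv, self.nv))
        b = np.zeros(self.nv)
        np.add.at(b, tris, be)
        # Dirichlet rows
        keep = sparse.diags(self.free.astype(float))
        fix = sparse.coo_matrix((np.ones(len(self.dir_idx)),
                                 (self.dir_idx, self.dir_idx)), shape=A.shape)
        A = (keep @ A + fix).tocsr()
        b[self.dir_idx] = self.dir_val
        return A, b

    def _source(self, flow_state: Optional[FlowState],
                prev_flow: Optional[FlowState]) -> Optional[np.ndarray]:
        """Heat sources divided by (rho Cp), at quadrature points."""
        cfg, sp = self.config, self.space
        if flow_state is None:
            return None
        s = None
        if cfg.include_dissipation:
            phi = _dissipation_quad(sp, flow_state.velocity)
            s = self.props.mu * phi / self.props.rho_cp
        if cfg.include_pressure_work and prev_flow is not None:
            # alpha_p T Dp/Dt with the stored temperature approximated by the
            # inlet level (the field stays within a fraction of a kelvin)
            dpdt = sp.eval1((flow_state.pressure - prev_flow.pressure) / cfg.dt)
            vq = sp.eval2(flow_state.velocity)
            gp = sp.grad1(flow_state.pressure)
            conv = np.einsum("mqd,mqd->mq", vq, gp)
            qp = cfg.alpha_p * self.bcs.T_inlet * (dpdt + conv) / self.props.rho_cp
            s = qp if s is None else s + qp
        return s

    def step(self, state: ThermalState, flow_state: Optional[FlowState] = None,
             prev: Optional[ThermalState] = None,
             prev_flow: Optional[FlowState] = None) -> ThermalState:
        """Advance temperature by one step using the (new-time) velocity."""
        cfg, sp = self.config, self.space
        dt = cfg.dt
        if flow_state is not None:
            vel_quad = sp.eval2(flow_state.velocity)
        else:
            vel_quad = np.zeros((len(sp.detJ), sp.N1.shape[0], 2))
        courant = float((np.sqrt((vel_quad ** 2).sum(-1)).max(initial=0.0)
                         * dt / sp.h_elem.min()))
        if courant > 5.0:
            log.warning("advective Courant number %.1f > 5 at t=%.3f", courant, state.t)
        if cfg.time_scheme == "bdf2" and prev is not None:
            coeff = 1.5 / dt
            hist = (2.0 * state.temperature - 0.5 * prev.temperature) / dt
        else:
            coeff = 1.0 / dt
            hist = state.temperature / dt
        A, b = self._system(vel_quad, coeff, hist, self._source(flow_state, prev_flow))
        T = spsolve(A.tocsc(), b)
        if not np.isfinite(T).all():
            raise SolverError(f"non-finite temperature at t={state.t + dt}")
        return ThermalState(t=state.t + dt, temperature=T)

    def solve_steady(self, flow_state: Optional[FlowState] = None) -> ThermalState:
        """Steady advection-diffusion solve (verification aid)."""
        sp = self.space
        if flow_state is not None:
            vel_quad = sp.eval2(flow_state.velocity)
        else:
            vel_quad = np.zeros((len(sp.detJ), sp.N1.shape[0], 2))
        A, b = self._system(vel_quad, 0.0, None, self._source(flow_state, None))
        T = spsolve(A.tocsc(), b)
        if not np.isfinite(T).all():
            raise SolverError("non-finite steady temperature")
        return ThermalState(t=math.inf, temperature=T)

    def energy(self, state: ThermalState) -> float:
        """Thermal energy integral (rho Cp) T dOmega, J per unit depth."""
        return self.props.rho_cp * self.space.integrate(
            self.space.eval1(state.temperature))

    def boundary_advective_flux(self, state: ThermalState,
                                flow_state: FlowState, tag: str) -> float:
        """Outward advected energy rate through a tagged boundary, W."""
        sp = self.space
        total = 0.0
        for e in sp.boundary_edge_ids(tag):
            nodes = sp.bedge_nodes[e]
            vq = sp.bedge_N @ flow_state.velocity[nodes]
            T0, T1 = state.temperature[nodes[0]], state.temperature[nodes[1]]
            Tq = (1.0 - EDGE_S) * T0 + EDGE_S * T1  # P1 trace is linear
            vn = vq @ sp.bedge_normal[e]
            total += float((sp.bedge_w[e] * vn * Tq).sum())
        return self.props.rho_cp * total


# functional wrappers -------------------------------------------------------

def step_thermal(solver: ThermalSolver, state: ThermalState,
                 flow_state: Optional[FlowState] = None,
                 prev: Optional[ThermalState] = None) -> ThermalState:
    return solver.step(state, flow_state, prev)


def thermal_energy(state: ThermalState, props: EffectiveProperties,
                   mesh: Mesh) -> float:
    sp = FEMSpace(mesh)
    return props.rho_cp * sp.integrate(sp.eval1(state.temperature))
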