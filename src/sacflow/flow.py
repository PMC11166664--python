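"""Transient incompressible Navier-Stokes solver on Taylor-Hood triangles.

Momentum and continuity are discretized with quadratic velocity / linear
pressure (inf-sup stable), the full symmetric-gradient viscous stress
``mu (grad v + grad v^T)``, Picard-linearized convection, and BDF2 time
stepping (implicit-Euler startup).  Boundary conditions follow the arterial
scenario: no-slip walls, a prescribed inlet speed, and traction (pressure)
outlets with backflow suppression at the outlet and the rupture orifice.

Planar mode solves the 2D Cartesian cut; axisymmetric mode solves the
swirl-free r-z reduction with the ``1/r`` metric terms (hoop stress, the
``u_r / r`` divergence contribution) under r-weighted integration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from ._fem import EDGE_W, FEMSpace
from .geometry import AXIS, INLET, OUTLET, RUPTURE, WALL, Mesh
from .properties import EffectiveProperties

__all__ = [
    "FlowBCs",
    "FlowSolverConfig",
    "FlowState",
    "FlowSolver",
    "SolverError",
    "assemble_flow_system",
    "apply_flow_bcs",
    "step_flow",
    "solve_steady_flow",
    "divergence_norm",
    "boundary_flux",
]

# velocity component indices in nodal arrays: column 0 axial (u3), column 1
# transverse/radial (u1); the azimuthal component u2 is identically zero.
AXIAL, TRANSVERSE = 0, 1


class SolverError(RuntimeError):
    """Linear/nonlinear solve failure (non-convergence, NaN, singularity)."""


@dataclass(frozen=True)
class FlowBCs:
    """Boundary data for the arterial flow problem.

    ``v0``: inlet speed (m/s); ``p_out``: outlet traction magnitude (Pa);
    ``p_rupture``: external pressure at the rupture orifice (Pa, must not
    exceed ``p_out`` so leakage is outward); ``backflow_beta``: coefficient of
    the re-entrant-flow boundary penalty at open boundaries.
    """

    v0: float = 0.08
    p_out: float = 13000.0
    p_rupture: float = 12990.0
    inlet_profile: str = "plug"  # plug | parabolic
    backflow_beta: float = 0.5

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError("v0 must be nonnegative")
        if self.p_rupture > self.p_out:
            raise ValueError("p_rupture must not exceed p_out")
        if self.inlet_profile not in ("plug", "parabolic"):
            raise ValueError(f"unknown inlet profile {self.inlet_profile!r}")


@dataclass(frozen=True)
class FlowSolverConfig:
    dt: float = 0.01
    t_end: float = 2.4
    time_scheme: str = "bdf2"  # bdf2 (implicit-Euler startup) | euler
    picard_tol: float = 1e-8
    picard_max: int = 25
    include_convection: bool = True
    # "newton" augments the Picard-lagged convection with its Jacobian after
    # one fixed-point startup iteration (far faster contraction at arterial
    # Reynolds numbers); "picard" is the plain lagged-convection iteration.
    linearization: str = "newton"

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end < self.dt:
            raise ValueError("need dt > 0 and t_end >= dt")
        if self.time_scheme not in ("bdf2", "euler"):
            raise ValueError(f"unknown time scheme {self.time_scheme!r}")
        if self.linearization not in ("newton", "picard"):
            raise ValueError(f"unknown linearization {self.linearization!r}")


@dataclass
class FlowState:
    """Discrete flow fields at one time level.

    ``velocity``: (n2, 2) at P2 nodes, columns (axial, transverse);
    ``pressure``: (nv,) at vertices.
    """

    t: float
    velocity: np.ndarray
    pressure: np.ndarray
    picard_iters: int = 0
    residual: float = 0.0

    def speed(self) -> np.ndarray:
        return np.hypot(self.velocity[:, 0], self.velocity[:, 1])


@dataclass
class StepLog:
    t: float
    picard_iters: int
    residual: float
    div_norm: float
    flux_balance: float  # |sum of open-boundary fluxes| / |inlet flux|


class FlowSolver:
    """Assembles and advances the mixed Navier-Stokes system on one mesh."""

    def __init__(self, mesh: Mesh, props: EffectiveProperties, bcs: FlowBCs,
                 config: FlowSolverConfig = FlowSolverConfig(),
                 body_force: Optional[Callable] = None,
                 dirichlet_velocity: Optional[Callable] = None):
        if props.mu <= 0:
            raise ValueError("viscosity must be positive")
        self.mesh = mesh
        self.space = FEMSpace(mesh)
        self.props = props
        self.bcs = bcs
        self.config = config
        self.body_force = body_force
        # optional override: prescribe velocity on ALL boundaries (used by
        # manufactured-solution verification); callable (z, x) -> (uz, ux)
        self.dirichlet_velocity = dirichlet_velocity
        sp = self.space
        self.n2, self.nv = sp.n2, sp.nv
        self.ndof = 2 * self.n2 + self.nv
        self._build_constant_blocks()
        self._build_dirichlet()
        self._build_traction_rhs()

    # ------------------------------------------------------------------ setup
    def _build_constant_blocks(self) -> None:
        sp, mu = self.space, self.props.mu
        w = sp.wdet
        d = sp.dphi2
        lap = np.einsum("mq,mqad,mqbd->mab", w, d, d)
        self.K = [[None, None], [None, None]]
        shape2 = (self.n2, self.n2)
        for I in (0, 1):
            for J in (0, 1):
                blk = mu * np.einsum("mq,mqa,mqb->mab", w, d[:, :, :, J], d[:, :, :, I])
                if I == J:
                    blk = blk + mu * lap
                if sp.axisym and I == 1 and J == 1:
                    # hoop stress 2 mu (u_r / r)(w_r / r) under r-weighting
                    blk = blk + 2.0 * mu * np.einsum(
                        "mq,qa,qb->mab", sp.wdet_plane / sp.rq, sp.N2, sp.N2)
                self.K[I][J] = sp.assemble(blk, sp.tri2, sp.tri2, shape2)
        Bz = np.einsum("mq,qa,mqb->mab", w, sp.N1, d[:, :, :, AXIAL])
        Bx = np.einsum("mq,qa,mqb->mab", w, sp.N1, d[:, :, :, TRANSVERSE])
        if sp.axisym:
            Bx = Bx + np.einsum("mq,qa,qb->mab", sp.wdet_plane, sp.N1, sp.N2)
        shapeB = (self.nv, self.n2)
        self.B = [sp.assemble(Bz, sp.mesh.triangles, sp.tri2, shapeB),
                  sp.assemble(Bx, sp.mesh.triangles, sp.tri2, shapeB)]
        self.G = [(-self.B[0]).T.tocsr(), (-self.B[1]).T.tocsr()]
        self.M2 = sp.assemble(sp.mass2(), sp.tri2, sp.tri2, shape2)
        if self.dirichlet_velocity is not None:
            self.open_tags = []  # fully velocity-constrained boundary
        else:
            self.open_tags = [t for t in (OUTLET, RUPTURE)
                              if len(sp.boundary_edge_ids(t)) > 0]
        self.pin_pressure = len(self.open_tags) == 0

    def inlet_profile_values(self, coords: np.ndarray) -> np.ndarray:
        """Axial inlet speed at given (z, x) points (inflow along +z)."""
        bcs, mesh = self.bcs, self.mesh
        x = coords[:, 1]
        if bcs.inlet_profile == "plug":
            return np.full(len(coords), bcs.v0)
        H = float(mesh.nodes[:, 1].max())
        if self.space.axisym:
            return 2.0 * bcs.v0 * (1.0 - (x / H) ** 2)
        return 6.0 * bcs.v0 * x * (H - x) / H**2

    def _build_dirichlet(self) -> None:
        sp = self.space
        idx: list[int] = []
        val: list[float] = []
        if self.dirichlet_velocity is not None:
            nodes = np.unique(sp.bedge_nodes.ravel())
            uz, ux = self.dirichlet_velocity(sp.nodes2[nodes, 0], sp.nodes2[nodes, 1])
            idx.extend(nodes.tolist() + (nodes + self.n2).tolist())
            val.extend(np.concatenate([np.atleast_1d(uz) * np.ones(len(nodes)),
                                       np.atleast_1d(ux) * np.ones(len(nodes))]))
        else:
            wall = sp.nodes_on(WALL)
            inlet = sp.nodes_on(INLET)
            axis = sp.nodes_on(AXIS)
            wall_only = np.setdiff1d(wall, inlet)  # inlet keeps its plug value
            for n in wall_only:
                idx += [n, n + self.n2]
                val += [0.0, 0.0]
            prof = self.inlet_profile_values(sp.nodes2[inlet])
            for n, u in zip(inlet, prof):
                idx += [n, n + self.n2]
                val += [float(u), 0.0]
            axis_only = np.setdiff1d(axis, np.concatenate([wall_only, inlet]))
            for n in axis_only:
                idx += [n + self.n2]  # u_r = 0 on the symmetry axis
                val += [0.0]
        if self.pin_pressure:
            idx.append(2 * self.n2)
            val.append(self.bcs.p_out)
        self.dir_idx = np.array(idx, dtype=np.int64)
        self.dir_val = np.array(val)
        self.free_mask = np.ones(self.ndof, dtype=bool)
        self.free_mask[self.dir_idx] = False

    def _build_traction_rhs(self) -> None:
        """Constant natural-BC load: -p_bar n on OUTLET and RUPTURE."""
        sp = self.space
        rhs = np.zeros(self.ndof)
        if not self.open_tags:
            self.traction_rhs = rhs
            return
        for tag, pbar in ((OUTLET, self.bcs.p_out), (RUPTURE, self.bcs.p_rupture)):
            for e in sp.boundary_edge_ids(tag):
                nodes = sp.bedge_nodes[e]
                n = sp.bedge_normal[e]
                wN = sp.bedge_w[e] @ sp.bedge_N  # (3,) integrals of shapes
                rhs[nodes] += -pbar * n[AXIAL] * wN
                rhs[nodes + self.n2] += -pbar * n[TRANSVERSE] * wN
        self.traction_rhs = rhs

    # ------------------------------------------------------------- assembly
    def _convection_matrix(self, vel: np.ndarray) -> sparse.csr_matrix:
        sp, rho = self.space, self.props.rho
        a = sp.eval2(vel)  # (M, nq, 2)
        adv = np.einsum("mqd,mqbd->mqb", a, sp.dphi2)
        C = rho * np.einsum("mq,qa,mqb->mab", sp.wdet, sp.N2, adv)
        return sp.assemble(C, sp.tri2, sp.tri2, (self.n2, self.n2))

    def _backflow_matrix(self, vel: np.ndarray) -> Optional[sparse.csr_matrix]:
        """Penalty -beta rho min(v.n, 0) u on open boundaries (SPD addition)."""
        sp = self.space
        beta, rho = self.bcs.backflow_beta, self.props.rho
        if beta == 0.0 or not self.open_tags:
            return None
        rows, cols, data = [], [], []
        for tag in self.open_tags:
            for e in sp.boundary_edge_ids(tag):
                nodes = sp.bedge_nodes[e]
                n = sp.bedge_normal[e]
                vq = sp.bedge_N @ vel[nodes]  # (nq_e, 2)
                m = np.minimum(vq @ n, 0.0)
                Me = np.einsum("q,qa,qb->ab", -beta * rho * m * sp.bedge_w[e],
                               sp.bedge_N, sp.bedge_N)
                rows.append(np.repeat(nodes, 3))
                cols.append(np.tile(nodes, 3))
                data.append(Me.ravel())
        if not rows:
            return None
        return sparse.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n2, self.n2)).tocsr()

    def assemble_system(self, vel_iter: np.ndarray,
                        mass_coeff: float = 0.0,
                        mass_rhs: Optional[np.ndarray] = None,
                        newton: bool = False
                        ) -> tuple[sparse.csr_matrix, np.ndarray]:
        """Oseen system linearized about ``vel_iter``.

        ``mass_coeff`` multiplies the transient term rho/dt M (0 for steady);
        ``mass_rhs`` is the (n2, 2) velocity history combination entering the
        right-hand side as rho/dt M * mass_rhs.  With ``newton`` the
        convection Jacobian term rho (u . grad) a is added (with the matching
        rho (a . grad) a right-hand-side correction).
        """
        rho = self.props.rho
        A = [[self.K[0][0].copy(), self.K[0][1]], [self.K[1][0], self.K[1][1].copy()]]
        newton_rhs = None
        if self.config.include_convection:
            C = self._convection_matrix(vel_iter)
            A[0][0] = A[0][0] + C
            A[1][1] = A[1][1] + C
            if newton:
                sp = self.space
                aq = sp.eval2(vel_iter)                     # (M, nq, 2)
                ga = np.stack([sp.grad2(vel_iter[:, 0]),
                               sp.grad2(vel_iter[:, 1])], axis=2)  # (M,nq,comp I,J)
                for I in (0, 1):
                    for J in (0, 1):
                        blk = rho * np.einsum("mq,qa,qb->mab",
                                              sp.wdet * ga[:, :, I, J], sp.N2, sp.N2)
                        A[I][J] = A[I][J] + sp.assemble(
                            blk, sp.tri2, sp.tri2, (self.n2, self.n2))
                conv_a = np.einsum("mqd,mqid->mqi", aq, ga)  # (a.grad)a
                newton_rhs = (sp.load2(rho * conv_a[:, :, 0]),
                              sp.load2(rho * conv_a[:, :, 1]))
            BF = self._backflow_matrix(vel_iter)
            if BF is not None:
                A[0][0] = A[0][0] + BF
                A[1][1] = A[1][1] + BF
        if mass_coeff:
            T = (rho * mass_coeff) * self.M2
            A[0][0] = A[0][0] + T
            A[1][1] = A[1][1] + T
        S = sparse.bmat([[A[0][0], A[0][1], self.G[0]],
                         [A[1][0], A[1][1], self.G[1]],
                         [self.B[0], self.B[1], None]], format="csr")
        b = self.traction_rhs.copy()
        if newton_rhs is not None:
            b[:self.n2] += newton_rhs[0]
            b[self.n2:2 * self.n2] += newton_rhs[1]
        if mass_rhs is not None:
            b[:self.n2] += rho * (self.M2 @ mass_rhs[:, 0])
            b[self.n2:2 * self.n2] += rho * (self.M2 @ mass_rhs[:, 1])
        if self.body_force is not None:
            sp = self.space
            fz, fx = self.body_force(sp.xq[:, :, 0], sp.xq[:, :, 1])
            b[:self.n2] += sp.load2(np.broadcast_to(fz, sp.xq[:, :, 0].shape))
            b[self.n2:2 * self.n2] += sp.load2(np.broadcast_to(fx, sp.xq[:, :, 0].shape))
        return S, b

    def apply_bcs(self, S: sparse.csr_matrix, b: np.ndarray
                  ) -> tuple[sparse.csr_matrix, np.ndarray]:
        """Impose Dirichlet rows (identity row, prescribed value)."""
        keep = sparse.diags(self.free_mask.astype(float))
        fix = sparse.coo_matrix(
            (np.ones(len(self.dir_idx)), (self.dir_idx, self.dir_idx)),
            shape=S.shape)
        S = (keep @ S + fix).tocsr()
        b = b.copy()
        b[self.dir_idx] = self.dir_val
        return S, b

    # --------------------------------------------------------------- solves
    def _pack(self, state: FlowState) -> np.ndarray:
        return np.concatenate([state.velocity[:, 0], state.velocity[:, 1],
                               state.pressure])

    def _unpack(self, u: np.ndarray, t: float, iters: int, res: float) -> FlowState:
        vel = np.column_stack([u[:self.n2], u[self.n2:2 * self.n2]])
        return FlowState(t=t, velocity=vel, pressure=u[2 * self.n2:],
                         picard_iters=iters, residual=res)

    def _picard(self, u0: np.ndarray, mass_coeff: float,
                mass_rhs: Optional[np.ndarray], t: float) -> FlowState:
        cfg = self.config
        u = u0.copy()
        res = math.inf
        history = []
        for it in range(cfg.picard_max):
            vel = np.column_stack([u[:self.n2], u[self.n2:2 * self.n2]])
            newton = cfg.linearization == "newton" and it > 0
            S, b = self.assemble_system(vel, mass_coeff, mass_rhs, newton=newton)
            S, b = self.apply_bcs(S, b)
            bnorm = float(np.linalg.norm(b))
            res = float(np.linalg.norm(b - S @ u)) / max(bnorm, 1e-300)
            history.append(res)
            if res < cfg.picard_tol and it > 0:
                return self._unpack(u, t, it, res)
            u = spsolve(S.tocsc(), b)
            if not np.isfinite(u).all():
                raise SolverError(f"non-finite solution at t={t} (NaN/Inf detected)")
        # converged on the last allowed iterate?
        vel = np.column_stack([u[:self.n2], u[self.n2:2 * self.n2]])
        S, b = self.assemble_system(vel, mass_coeff, mass_rhs)
        S, b = self.apply_bcs(S, b)
        res = float(np.linalg.norm(b - S @ u)) / max(float(np.linalg.norm(b)), 1e-300)
        if res < cfg.picard_tol:
            return self._unpack(u, t, cfg.picard_max, res)
        raise SolverError(
            f"Picard iteration did not converge at t={t}: residual history "
            f"{[f'{r:.2e}' for r in history + [res]]}")

    def initial_state(self) -> FlowState:
        """Start from rest at the outlet pressure level."""
        return FlowState(t=0.0, velocity=np.zeros((self.n2, 2)),
                         pressure=np.full(self.nv, self.bcs.p_out))

    def solve_steady(self, initial: Optional[FlowState] = None) -> FlowState:
        u0 = self._pack(initial) if initial is not None else np.zeros(self.ndof)
        return self._picard(u0, mass_coeff=0.0, mass_rhs=None, t=math.inf)

    def step(self, state: FlowState,
             prev: Optional[FlowState] = None) -> FlowState:
        """Advance one time step: BDF2 when a second history level is
        available (and the scheme allows), implicit Euler otherwise."""
        dt = self.config.dt
        if self.config.time_scheme == "bdf2" and prev is not None:
            coeff = 1.5 / dt
            hist = (2.0 * state.velocity - 0.5 * prev.velocity) / dt
        else:
            coeff = 1.0 / dt
            hist = state.velocity / dt
        out = self._picard(self._pack(state), coeff, hist, state.t + dt)
        return out

    # ------------------------------------------------------------ diagnostics
    def divergence_field(self, state: FlowState) -> np.ndarray:
        """Discrete divergence at quadrature points (M, nq)."""
        sp = self.space
        gz = np.einsum("mqa,ma->mq", sp.dphi2[:, :, :, AXIAL],
                       state.velocity[sp.tri2, 0])
        gx = np.einsum("mqa,ma->mq", sp.dphi2[:, :, :, TRANSVERSE],
                       state.velocity[sp.tri2, 1])
        div = gz + gx
        if sp.axisym:
            div = div + sp.eval2(state.velocity[:, 1]) / sp.rq
        return div

    def divergence_norm(self, state: FlowState) -> float:
        return math.sqrt(max(self.space.integrate(
            self.divergence_field(state) ** 2), 0.0))

    def boundary_flux(self, state: FlowState, tag: str) -> float:
        """Outward volumetric flux through the tagged boundary (per unit
        depth in planar mode; per radian-weighted measure in axisymmetric)."""
        sp = self.space
        ids = sp.boundary_edge_ids(tag)
        if tag not in (INLET, OUTLET, WALL, RUPTURE, AXIS):
            raise KeyError(f"unknown boundary tag {tag!r}")
        total = 0.0
        for e in ids:
            vq = sp.bedge_N @ state.velocity[sp.bedge_nodes[e]]
            total += float((sp.bedge_w[e] * (vq @ sp.bedge_normal[e])).sum())
        return total

    def flux_balance(self, state: FlowState) -> float:
        """|sum of all boundary fluxes| relative to the inlet flux."""
        tags = {t for t in self.mesh.boundary_tags}
        total = sum(self.boundary_flux(state, t) for t in tags)
        inlet = abs(self.boundary_flux(state, INLET))
        return abs(total) / max(inlet, 1e-300)

    def step_log(self, state: FlowState) -> StepLog:
        return StepLog(t=state.t, picard_iters=state.picard_iters,
                       residual=state.residual,
                       div_norm=self.divergence_norm(state),
                       flux_balance=self.flux_balance(state))


# ---------------------------------------------------------------------------
# thin functional wrappers matching the module surface
# ---------------------------------------------------------------------------

def assemble_flow_system(mesh: Mesh, props: EffectiveProperties, bcs: FlowBCs,
                         state: FlowState, dt: float, mode: str | None = None):
    """One Oseen system (pre-BC) linearized about ``state`` with an implicit
    time term at step size ``dt``; returns (solver, matrix, rhs)."""
    solver = FlowSolver(mesh, props, bcs, FlowSolverConfig(dt=dt, t_end=dt))
    S, b = solver.assemble_system(state.velocity, 1.0 / dt, state.velocity / dt)
    return solver, S, b


def apply_flow_bcs(solver: FlowSolver, S, b):
    return solver.apply_bcs(S, b)


def step_flow(solver: FlowSolver, state: FlowState,
              prev: Optional[FlowState] = None) -> FlowState:
    return solver.step(state, prev)


def solve_steady_flow(mesh: Mesh, props: EffectiveProperties, bcs: FlowBCs,
                      config: FlowSolverConfig = FlowSolverConfig(),
                      **kwargs) -> FlowState:
    return FlowSolver(mesh, props, bcs, config, **kwargs).solve_steady()


def divergence_norm(state: FlowState, mesh: Mesh) -> float:
    solver_space = FEMSpace(mesh)
    gz = np.einsum("mqa,ma->mq", solver_space.dphi2[:, :, :, AXIAL],
                   state.velocity[solver_space.tri2, 0])
    gx = np.einsum("mqa,ma->mq", solver_space.dphi2[:, :, :, TRANSVERSE],
                   state.velocity[solver_space.tri2, 1])
    div = gz + gx
    if solver_space.axisym:
        div = div + solver_space.eval2(state.velocity[:, 1]) / solver_space.rq
    return math.sqrt(max(solver_space.integrate(div ** 2), 0.0))


def boundary_flux(state: FlowState, mesh: Mesh, tag: str) -> float:
    sp = FEMSpace(mesh)
    if tag not in (INLET, OUTLET, WALL, RUPTURE, AXIS):
        raise KeyError(f"unknown boundary tag {tag!r}")
    total = 0.0
    for e in sp.boundary_edge_ids(tag):
        vq = sp.bedge_N @ state.velocity[sp.bedge_nodes[e]]
        total += float((sp.bedge_w[e] * (vq @ sp.bedge_normal[e])).sum())
    return total
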