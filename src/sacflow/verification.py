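"""Method-of-manufactured-solutions (MMS) verification for the flow solver.

A divergence-free velocity field (the curl of a stream function) and a
pressure field are substituted into the steady incompressible momentum
equation; the residual becomes the body force that makes the pair an exact
solution.  Solving with exact-velocity Dirichlet data on uniformly refined
structured meshes then measures the spatial convergence order of the
discretization (formal: 3 for the quadratic velocity in L2, 2 for the linear
pressure).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import sympy as sp

from ._fem import FEMSpace
from .flow import FlowBCs, FlowSolver, FlowSolverConfig
from .geometry import rectangle_mesh

__all__ = ["manufactured_solution", "convergence_study", "MMSResult"]


@lru_cache(maxsize=4)
def manufactured_solution(rho: float = 1.0, mu: float = 0.05):
    """Return callables (u, p, f) of (z, x) for a steady Navier-Stokes MMS.

    u(z, x) -> (uz, ux) from the stream function sin(pi z) sin(pi x) (hence
    exactly divergence free and zero on the unit-square boundary is NOT
    imposed — the boundary carries the exact nonzero trace);
    p = cos(pi z) cos(pi x); f is the momentum residual including convection
    and the symmetric-gradient viscous stress.
    """
    z, x = sp.symbols("z x")
    psi = sp.sin(sp.pi * z) * sp.sin(sp.pi * x)
    uz = sp.diff(psi, x)
    ux = -sp.diff(psi, z)
    p = sp.cos(sp.pi * z) * sp.cos(sp.pi * x)
    u = sp.Matrix([uz, ux])
    coords = [z, x]
    conv = sp.Matrix([sum(u[j] * sp.diff(u[i], coords[j]) for j in range(2))
                      for i in range(2)])
    gradp = sp.Matrix([sp.diff(p, c) for c in coords])
    # div of mu (grad u + grad u^T)
    stress_div = sp.Matrix([
        sum(sp.diff(mu * (sp.diff(u[i], coords[j]) + sp.diff(u[j], coords[i])),
                    coords[j]) for j in range(2))
        for i in range(2)])
    f = rho * conv + gradp - stress_div
    u_fn = sp.lambdify((z, x), [uz, ux], "numpy")
    p_fn = sp.lambdify((z, x), p, "numpy")
    f_fn = sp.lambdify((z, x), [f[0], f[1]], "numpy")
    return u_fn, p_fn, f_fn


@dataclass
class MMSResult:
    ns: list[int]
    h: list[float]
    err_u: list[float]       # velocity L2 errors
    err_p: list[float]       # pressure L2 errors (mean-adjusted)
    orders_u: list[float]
    order_u: float           # least-squares slope over all levels


def _solve_level(n: int, rho: float, mu: float):
    u_fn, p_fn, f_fn = manufactured_solution(rho, mu)
    mesh = rectangle_mesh(1.0, 1.0, n, n)
    bcs = FlowBCs(v0=0.0, p_out=0.0, p_rupture=0.0, backflow_beta=0.0)
    cfg = FlowSolverConfig(dt=1.0, t_end=1.0, picard_tol=1e-11, picard_max=40)
    solver = FlowSolver(mesh, _props(rho, mu), bcs, cfg,
                        body_force=lambda zz, xx: f_fn(zz, xx),
                        dirichlet_velocity=lambda zz, xx: u_fn(zz, xx))
    st = solver.solve_steady()
    space = solver.space
    # L2 errors by quadrature
    uz_ex, ux_ex = u_fn(space.xq[:, :, 0], space.xq[:, :, 1])
    du = (space.eval2(st.velocity[:, 0]) - uz_ex) ** 2 \
        + (space.eval2(st.velocity[:, 1]) - ux_ex) ** 2
    err_u = math.sqrt(space.integrate(du))
    p_ex = p_fn(space.xq[:, :, 0], space.xq[:, :, 1])
    dp = space.eval1(st.pressure) - p_ex
    dp = dp - space.integrate(dp)  # pressure defined up to a constant (area 1)
    err_p = math.sqrt(space.integrate(dp ** 2))
    return err_u, err_p


def _props(rho: float, mu: float):
    from .properties import EffectiveProperties
    return EffectiveProperties(rho=rho, rho_cp=rho * 1000.0, mu=mu, k=1.0,
                               nu=mu / rho, alpha=1.0 / (rho * 1000.0))


def convergence_study(ns=(8, 16, 32), rho: float = 1.0, mu: float = 0.05
                      ) -> MMSResult:
    """Velocity/pressure L2 errors and observed orders over uniformly
    refined unit-square meshes."""
    errs_u, errs_p = [], []
    for n in ns:
        eu, ep = _solve_level(n, rho, mu)
        errs_u.append(eu)
        errs_p.append(ep)
    h = [1.0 / n for n in ns]
    orders = [math.log(errs_u[i] / errs_u[i + 1]) / math.log(h[i] / h[i + 1])
              for i in range(len(ns) - 1)]
    slope = float(np.polyfit(np.log(h), np.log(errs_u), 1)[0])
    return MMSResult(ns=list(ns), h=h, err_u=errs_u, err_p=errs_p,
                     orders_u=orders, order_u=slope)
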