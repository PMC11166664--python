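"""Finite-element machinery on triangle meshes: quadratic (P2) and linear
(P1) Lagrange spaces, quadrature, and vectorized assembly helpers.

Used by the flow solver (Taylor-Hood P2 velocity / P1 pressure) and the
thermal solver (P1 temperature).  In axisymmetric mode every volume integral
carries the radial weight ``r`` (the transverse coordinate); the extra
``1/r``-type terms of the cylindrical operators are assembled by the solvers
from the unweighted measures this class also exposes.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import sparse

from .geometry import Mesh

# 7-point degree-5 quadrature on the reference triangle (weights sum to 1/2)
_A1 = (6.0 - math.sqrt(15.0)) / 21.0
_A2 = (6.0 + math.sqrt(15.0)) / 21.0
_W0 = 9.0 / 40.0
_W1 = (155.0 - math.sqrt(15.0)) / 1200.0
_W2 = (155.0 + math.sqrt(15.0)) / 1200.0
QP = np.array([
    [1 / 3, 1 / 3],
    [_A1, _A1], [1 - 2 * _A1, _A1], [_A1, 1 - 2 * _A1],
    [_A2, _A2], [1 - 2 * _A2, _A2], [_A2, 1 - 2 * _A2],
])
QW = 0.5 * np.array([_W0, _W1, _W1, _W1, _W2, _W2, _W2])

# 3-point Gauss on [0, 1] (degree 5) for boundary edges
EDGE_S = 0.5 + 0.5 * np.array([-math.sqrt(3.0 / 5.0), 0.0, math.sqrt(3.0 / 5.0)])
EDGE_W = 0.5 * np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def p1_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P1 shape values (nq, 3) and reference gradients (nq, 3, 2)."""
    l1, l2 = xi[:, 0], xi[:, 1]
    l0 = 1.0 - l1 - l2
    N = np.stack([l0, l1, l2], axis=1)
    dN = np.broadcast_to(
        np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]]), (len(xi), 3, 2)
    ).copy()
    return N, dN


def p2_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P2 shape values (nq, 6) and reference gradients (nq, 6, 2).

    Node order: vertices 0,1,2 then midpoints of edges (0,1), (1,2), (2,0).
    """
    l1, l2 = xi[:, 0], xi[:, 1]
    l0 = 1.0 - l1 - l2
    N = np.stack([
        l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
        4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0,
    ], axis=1)
    z = np.zeros_like(l1)
    dl0 = np.stack([-np.ones_like(l1), -np.ones_like(l1)], axis=1)
    dl1 = np.stack([np.ones_like(l1), z], axis=1)
    dl2 = np.stack([z, np.ones_like(l1)], axis=1)
    dN = np.stack([
        (4 * l0 - 1)[:, None] * dl0,
        (4 * l1 - 1)[:, None] * dl1,
        (4 * l2 - 1)[:, None] * dl2,
        4 * (l1[:, None] * dl0 + l0[:, None] * dl1),
        4 * (l2[:, None] * dl1 + l1[:, None] * dl2),
        4 * (l0[:, None] * dl2 + l2[:, None] * dl0),
    ], axis=1)
    return N, dN


def edge_p2_shape(s: np.ndarray) -> np.ndarray:
    """Quadratic shape values on an edge (nq, 3); nodes (end0, end1, mid)."""
    return np.stack([(1 - s) * (1 - 2 * s), s * (2 * s - 1), 4 * s * (1 - s)], axis=1)


class FEMSpace:
    """P2/P1 function spaces and precomputed assembly data on one mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.axisym = mesh.mode == "axisymmetric"
        nv = mesh.n_nodes
        tris = mesh.triangles

        # unique-edge midpoint nodes for P2
        edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        edges_sorted = np.sort(edges, axis=1)
        uniq, inverse = np.unique(edges_sorted, axis=0, return_inverse=True)
        self.nv = nv
        self.ne = len(uniq)
        self.n2 = nv + self.ne
        mid_ids = nv + inverse.reshape(3, -1).T  # (M, 3) midpoints of (01,12,20)
        self.tri2 = np.hstack([tris, mid_ids])
        mid_coords = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
        self.nodes2 = np.vstack([mesh.nodes, mid_coords])
        self._edge_lookup = {tuple(e): nv + i for i, e in enumerate(map(tuple, uniq))}

        # reference shapes at volume quadrature
        self.N2, dN2 = p2_shape(QP)
        self.N1, dN1 = p1_shape(QP)

        # affine element geometry
        p = mesh.nodes[tris]
        J = np.empty((len(tris), 2, 2))
        J[:, :, 0] = p[:, 1] - p[:, 0]
        J[:, :, 1] = p[:, 2] - p[:, 0]
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            raise ValueError("mesh contains degenerate or inverted triangles")
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1] / detJ
        invJ[:, 0, 1] = -J[:, 0, 1] / detJ
        invJ[:, 1, 0] = -J[:, 1, 0] / detJ
        invJ[:, 1, 1] = J[:, 0, 0] / detJ
        self.detJ = detJ
        # physical gradients: (M, nq, ndof, 2)
        self.dphi2 = np.einsum("qad,mde->mqae", dN2, invJ)
        self.dphi1 = np.einsum("qad,mde->mqae", dN1, invJ)
        # physical quadrature coordinates (M, nq, 2)
        self.xq = np.einsum("qa,mad->mqd", self.N1, p)
        self.wdet_plane = QW[None, :] * detJ[:, None]       # plain 2D measure
        if self.axisym:
            self.rq = self.xq[:, :, 1]
            if np.any(self.rq <= 0):
                raise ValueError("axisymmetric mesh must lie in r >= 0 with "
                                 "quadrature points at r > 0")
            self.wdet = self.wdet_plane * self.rq
        else:
            self.rq = np.ones_like(self.xq[:, :, 1])
            self.wdet = self.wdet_plane
        self.areas = 0.5 * detJ
        self.h_elem = np.sqrt(4.0 * self.areas / math.sqrt(3.0))

        self._build_boundary()

    # -- boundary -----------------------------------------------------------
    def _build_boundary(self) -> None:
        mesh = self.mesh
        be = mesh.boundary_edges
        mids = np.array([self._edge_lookup[(min(u, v), max(u, v))] for u, v in be])
        self.bedge_nodes = np.column_stack([be[:, 0], be[:, 1], mids])  # (B, 3)
        p0 = mesh.nodes[be[:, 0]]
        p1 = mesh.nodes[be[:, 1]]
        tvec = p1 - p0
        self.bedge_len = np.hypot(tvec[:, 0], tvec[:, 1])
        that = tvec / self.bedge_len[:, None]
        # boundary loop is CCW (interior on the left) -> outward normal
        self.bedge_normal = np.column_stack([that[:, 1], -that[:, 0]])
        self.bedge_N = edge_p2_shape(EDGE_S)  # (nq_e, 3)
        # quadrature coords along each (straight) edge: (B, nq_e, 2)
        self.bedge_xq = p0[:, None, :] + EDGE_S[None, :, None] * tvec[:, None, :]
        w = EDGE_W[None, :] * self.bedge_len[:, None]
        if self.axisym:
            w = w * self.bedge_xq[:, :, 1]
        self.bedge_w = w  # (B, nq_e)

    def boundary_edge_ids(self, tag: str) -> np.ndarray:
        return np.nonzero(self.mesh.boundary_tags == tag)[0]

    def nodes_on(self, tag: str) -> np.ndarray:
        """All P2 node indices (vertices + midpoints) on edges with this tag."""
        ids = self.boundary_edge_ids(tag)
        return np.unique(self.bedge_nodes[ids].ravel())

    # -- evaluation ---------------------------------------------------------
    def eval2(self, U: np.ndarray) -> np.ndarray:
        """P2 nodal field (n2,) or (n2, k) at volume quad points: (M, nq[, k])."""
        Ue = U[self.tri2]
        return np.einsum("qa,ma...->mq...", self.N2, Ue)

    def grad2(self, U: np.ndarray) -> np.ndarray:
        """Gradient of a scalar P2 field at quad points: (M, nq, 2)."""
        return np.einsum("mqad,ma->mqd", self.dphi2, U[self.tri2])

    def eval1(self, U: np.ndarray) -> np.ndarray:
        Ue = U[self.mesh.triangles]
        return np.einsum("qa,ma...->mq...", self.N1, Ue)

    def grad1(self, U: np.ndarray) -> np.ndarray:
        return np.einsum("mqad,ma->mqd", self.dphi1, U[self.mesh.triangles])

    # -- assembly -----------------------------------------------------------
    def assemble(self, elem: np.ndarray, conn_row: np.ndarray, conn_col: np.ndarray,
                 shape: tuple[int, int]) -> sparse.csr_matrix:
        """Scatter per-element blocks ``elem`` (M, a, b) into a CSR matrix."""
        M, na, nb = elem.shape
        rows = np.repeat(conn_row, nb, axis=1).ravel()
        cols = np.tile(conn_col, (1, na)).ravel()
        return sparse.coo_matrix((elem.ravel(), (rows, cols)), shape=shape).tocsr()

    def mass2(self, coeff=None, weighted: bool = True) -> np.ndarray:
        """Element P2 mass blocks (M, 6, 6); ``coeff`` is per-(M, nq)."""
        w = self.wdet if weighted else self.wdet_plane
        if coeff is not None:
            w = w * coeff
        return np.einsum("mq,qa,qb->mab", w, self.N2, self.N2)

    def load2(self, values: np.ndarray) -> np.ndarray:
        """P2 load vector from quad-point values (M, nq) -> (n2,)."""
        fe = np.einsum("mq,qa->ma", self.wdet * values, self.N2)
        out = np.zeros(self.n2)
        np.add.at(out, self.tri2, fe)
        return out

    def load1(self, values: np.ndarray) -> np.ndarray:
        fe = np.einsum("mq,qa->ma", self.wdet * values, self.N1)
        out = np.zeros(self.nv)
        np.add.at(out, self.mesh.triangles, fe)
        return out

    def integrate(self, values: np.ndarray, weighted: bool = True) -> float:
        """Integral of quad-point values (M, nq) over the domain."""
        w = self.wdet if weighted else self.wdet_plane
        return float((w * values).sum())
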