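"""Reporting surfaces: line sampling, per-time extremes tables, and
standard-format exports (legacy-ASCII VTK unstructured grids + CSV).

Vector and quadratic fields are reported through their vertex values (the
quadratic velocity interpolant is exact at vertices), so every sampled or
exported field is a piecewise-linear nodal field on the triangulation.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from matplotlib.tri import Triangulation

from .geometry import Mesh

__all__ = [
    "LineSample",
    "ExtremesTable",
    "Snapshot",
    "sample_line",
    "extremes",
    "export_fields",
    "read_vtk_fields",
]

EXTREMES_COLUMNS = ["t", "v_max", "v_min", "p_max", "p_min", "T_max", "T_min"]


@dataclass
class Snapshot:
    """Vertex-valued fields stored at one output time."""

    t: float
    velocity: np.ndarray           # (nv, 2) columns (axial, transverse)
    pressure: np.ndarray           # (nv,)
    temperature: Optional[np.ndarray] = None  # (nv,)
    dissipation: Optional[np.ndarray] = None  # (M,) per element, W/m^3

    def speed(self) -> np.ndarray:
        return np.hypot(self.velocity[:, 0], self.velocity[:, 1])


@dataclass
class LineSample:
    points: np.ndarray   # (n, 2) equispaced along the segment
    values: np.ndarray   # (n,)
    t: float
    name: str = "field"

    @property
    def arclength(self) -> np.ndarray:
        d = np.hypot(*(self.points - self.points[0]).T)
        return d


@dataclass
class ExtremesTable:
    """Per-output-time field extremes (Table-style reporting)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.frame["t"].to_numpy()
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("output times must be strictly increasing")
        if (self.frame["v_min"] > self.frame["v_max"]).any() or \
           (self.frame["p_min"] > self.frame["p_max"]).any():
            raise ValueError("extremes rows violate min <= max")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")


def _interpolator(mesh: Mesh):
    tri = Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1],
                        triangles=mesh.triangles)
    return tri, tri.get_trifinder()


def sample_line(values: np.ndarray, mesh: Mesh, start, end, n: int,
                t: float = 0.0, name: str = "field") -> LineSample:
    """Sample a vertex-nodal field at ``n`` equispaced points on a segment
    via barycentric interpolation.  Raises if a point falls outside the mesh,
    naming the offending point."""
    if n < 2:
        raise ValueError("need at least 2 sample points")
    values = np.asarray(values, dtype=float)
    if values.shape != (mesh.n_nodes,):
        raise ValueError("values must be a vertex-nodal scalar field")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    pts = start[None, :] + np.linspace(0.0, 1.0, n)[:, None] * (end - start)
    tri, finder = _interpolator(mesh)
    cells = finder(pts[:, 0], pts[:, 1])
    if (cells < 0).any():
        bad = pts[np.argmax(cells < 0)]
        raise ValueError(f"sample point ({bad[0]:.6g}, {bad[1]:.6g}) lies outside the mesh")
    verts = mesh.triangles[cells]
    p = mesh.nodes[verts]  # (n, 3, 2)
    # barycentric coordinates w.r.t. each containing triangle
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    den = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    d = pts - p[:, 0]
    l1 = (d[:, 0] * v1[:, 1] - d[:, 1] * v1[:, 0]) / den
    l2 = (v0[:, 0] * d[:, 1] - v0[:, 1] * d[:, 0]) / den
    l0 = 1.0 - l1 - l2
    out = (values[verts] * np.stack([l0, l1, l2], axis=1)).sum(axis=1)
    return LineSample(points=pts, values=out, t=t, name=name)


def extremes(trajectory: Sequence[Snapshot], times: Sequence[float],
             dt_tol: Optional[float] = None,
             line: Optional[tuple] = None, mesh: Optional[Mesh] = None
             ) -> ExtremesTable:
    """Extremes of speed, pressure (and temperature when stored) at the
    requested times.

    Default: domain-wide nodal extremes.  With ``line=(start, end, n)`` (and
    ``mesh``) the scan is restricted to samples on that segment — the
    reporting-line variant (a domain minimum of speed is always 0 at no-slip
    walls, so line-restricted minima are the meaningful analog of reported
    line-graph minima).
    """
    if not trajectory:
        raise ValueError("empty trajectory")
    stored = np.array([s.t for s in trajectory])
    if dt_tol is None:
        dt_tol = 0.5 * float(np.diff(np.sort(stored)).min()) if len(stored) > 1 else np.inf
    rows = []
    for t in times:
        i = int(np.argmin(np.abs(stored - t)))
        if abs(stored[i] - t) > dt_tol + 1e-12:
            raise ValueError(f"no stored snapshot within {dt_tol} of t={t}")
        snap = trajectory[i]
        if line is not None:
            start, end, n = line
            speed = sample_line(snap.speed(), mesh, start, end, n).values
            pres = sample_line(snap.pressure, mesh, start, end, n).values
            temp = (sample_line(snap.temperature, mesh, start, end, n).values
                    if snap.temperature is not None else None)
        else:
            speed, pres, temp = snap.speed(), snap.pressure, snap.temperature
        row = {
            "t": snap.t,
            "v_max": float(speed.max()), "v_min": float(speed.min()),
            "p_max": float(pres.max()), "p_min": float(pres.min()),
            "T_max": float(temp.max()) if temp is not None else np.nan,
            "T_min": float(temp.min()) if temp is not None else np.nan,
        }
        rows.append(row)
    return ExtremesTable(pd.DataFrame(rows, columns=EXTREMES_COLUMNS))


# ---------------------------------------------------------------------------
# VTK legacy-ASCII export
# ---------------------------------------------------------------------------

def _write_vtk(snap: Snapshot, mesh: Mesh, path: str) -> None:
    nv, M = mesh.n_nodes, mesh.n_triangles
    lines = ["# vtk DataFile Version 3.0",
             f"sacflow fields t={snap.t!r}", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {nv} double"]
    for z, x in mesh.nodes:
        lines.append(f"{float(z)!r} {float(x)!r} 0")
    lines.append(f"CELLS {M} {4 * M}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {M}")
    lines.extend(["5"] * M)
    lines.append(f"POINT_DATA {nv}")
    lines.append("VECTORS velocity double")
    for uz, ux in snap.velocity:
        lines.append(f"{float(uz)!r} {float(ux)!r} 0")
    lines.append("SCALARS pressure double 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(repr(float(v)) for v in snap.pressure)
    if snap.temperature is not None:
        lines.append("SCALARS temperature double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(repr(float(v)) for v in snap.temperature)
    lines.append(f"CELL_DATA {M}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(r) for r in mesh.region_id)
    if snap.dissipation is not None:
        lines.append("SCALARS dissipation double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(repr(float(v)) for v in snap.dissipation)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk_fields(path) -> dict[str, np.ndarray]:
    """Read back point/cell data arrays from a legacy-ASCII VTK file written
    by :func:`export_fields` (round-trip aid)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    out: dict[str, np.ndarray] = {}
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("POINTS"):
            n = int(ln.split()[1])
            pts = [tuple(map(float, lines[i + 1 + k].split()[:2])) for k in range(n)]
            out["points"] = np.array(pts)
            i += n
        elif ln.startswith("VECTORS"):
            name = ln.split()[1]
            n = len(out["points"])
            out[name] = np.array(
                [tuple(map(float, lines[i + 1 + k].split()[:2])) for k in range(n)])
            i += n
        elif ln.startswith("SCALARS"):
            name = ln.split()[1]
            count = _pending_count(lines, i, out)
            vals = []
            k = i + 2  # skip LOOKUP_TABLE
            while len(vals) < count:
                vals.extend(float(v) for v in lines[k].split())
                k += 1
            out[name] = np.array(vals)
            i = k - 1
        elif ln.startswith("CELLS "):
            ncell = int(ln.split()[1])
            out["cells"] = np.array(
                [list(map(int, lines[i + 1 + k].split()[1:])) for k in range(ncell)])
            out["_ncells"] = np.array([ncell])
            i += ncell
        i += 1
    return out


def _pending_count(lines, i, out) -> int:
    for j in range(i, -1, -1):
        if lines[j].startswith("CELL_DATA"):
            return int(lines[j].split()[1])
        if lines[j].startswith("POINT_DATA"):
            return int(lines[j].split()[1])
    raise ValueError("malformed VTK file: SCALARS outside data section")


def export_fields(trajectory: Sequence[Snapshot], mesh: Mesh, outdir,
                  line: Optional[tuple] = None,
                  basename: str = "fields") -> list[str]:
    """Write one VTK file per stored time plus the extremes CSV (and line
    samples CSV when a reporting line is given).  Returns written paths."""
    os.makedirs(outdir, exist_ok=True)
    written = []
    for k, snap in enumerate(trajectory):
        p = os.path.join(outdir, f"{basename}_{k:04d}.vtk")
        _write_vtk(snap, mesh, p)
        written.append(p)
    times = [s.t for s in trajectory]
    table = extremes(trajectory, times)
    p = os.path.join(outdir, "extremes.csv")
    table.to_csv(p)
    written.append(p)
    if line is not None:
        table_line = extremes(trajectory, times, line=line, mesh=mesh)
        p = os.path.join(outdir, "extremes_line.csv")
        table_line.to_csv(p)
        written.append(p)
        rows = []
        start, end, n = line
        for snap in trajectory:
            for fname, vals in (("speed", snap.speed()), ("pressure", snap.pressure),
                                ("temperature", snap.temperature)):
                if vals is None:
                    continue
                ls = sample_line(vals, mesh, start, end, n, t=snap.t, name=fname)
                for s, (z, x), v in zip(ls.arclength, ls.points, ls.values):
                    rows.append((snap.t, fname, s, z, x, v))
        df = pd.DataFrame(rows, columns=["t", "field", "s", "z", "x", "value"])
        p = os.path.join(outdir, "line_samples.csv")
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)
    return written
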