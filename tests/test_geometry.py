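"""Vessel geometry construction, graded meshing, quality metrics, and
mesh-file round trips."""
import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from sacflow.geometry import (GeometryError, Mesh, MeshingError, MeshSizing,
                              VesselGeometry, build_geometry, generate_mesh,
                              quality_report, read_mesh, rectangle_mesh,
                              sac_area, triangle_quality, write_mesh)


def test_rectangle_boundary_tags_and_perimeter():
    vg = VesselGeometry(has_sac=False, has_orifice=False)
    b = build_geometry(vg)
    assert b.tags == {"INLET", "OUTLET", "WALL"}
    perim = sum(pc.length for pc in b.pieces)
    assert perim == pytest.approx(2 * (0.7 + 0.09), rel=1e-12)


def test_default_geometry_has_single_rupture_arc():
    b = build_geometry(VesselGeometry())
    rupture = [pc for pc in b.pieces if pc.tag == "RUPTURE"]
    assert len(rupture) == 1
    assert rupture[0].kind == "arc"
    # the orifice straddles the sac apex
    mid = rupture[0].point(0.5)
    apex = VesselGeometry().orifice_center
    assert mid == pytest.approx(apex, abs=1e-12)


def test_sac_area_matches_circular_segment_closed_form():
    """Polygon area of the sac bulge converges to the analytic major
    circular-segment area."""
    vg = VesselGeometry()
    poly = build_geometry(vg).polygon(pts_per_arc=4096)
    rect = 0.7 * 0.09
    analytic = sac_area(vg.sac_radius, vg.neck_width)
    assert poly.area - rect == pytest.approx(analytic, rel=1e-4)


@pytest.mark.parametrize("bad", [
    dict(length=-1.0),
    dict(has_sac=False, has_orifice=True),
    dict(mode="axisymmetric"),                      # sac breaks axisymmetry
    dict(neck_width=0.06, sac_radius=0.025),        # neck exceeds diameter
    dict(sac_center_z=0.01),                        # neck overhangs the inlet
])
def test_invalid_geometry_rejected(bad):
    with pytest.raises(GeometryError):
        VesselGeometry(**bad)


def test_mesh_sizing_validation():
    with pytest.raises(GeometryError):
        MeshSizing(h_min=0.2, h_max=0.1)
    with pytest.raises(GeometryError):
        MeshSizing(growth_rate=0.9)


# --------------------------------------------------------------- meshing ----

@pytest.fixture(scope="module")
def rupture_mesh():
    return generate_mesh(build_geometry(VesselGeometry()), MeshSizing(), seed=0)


def test_generated_mesh_area_matches_shoelace(rupture_mesh):
    """Triangle areas sum to the polygonal boundary area (shoelace)."""
    loop = []
    for u, _ in _ordered_loop(rupture_mesh):
        loop.append(rupture_mesh.nodes[u])
    shoelace = Polygon(loop).area
    assert rupture_mesh.total_area() == pytest.approx(shoelace, rel=1e-8)


def _ordered_loop(mesh):
    nxt = {u: (u, v) for u, v in mesh.boundary_edges}
    start = mesh.boundary_edges[0][0]
    out, u = [], start
    while True:
        e = nxt[u]
        out.append(e)
        u = e[1]
        if u == start:
            return out


def test_boundary_edges_form_closed_tagged_loop(rupture_mesh):
    mesh = rupture_mesh
    mesh.check()  # hull edges == tagged edges
    loop = _ordered_loop(mesh)
    assert len(loop) == len(mesh.boundary_edges)
    for tag in ("INLET", "OUTLET", "WALL", "RUPTURE"):
        assert len(mesh.edges_by_tag(tag)) > 0


def test_rupture_neighborhood_is_refined(rupture_mesh):
    """Median edge length near the orifice is below the far-field median."""
    vg = VesselGeometry()
    center = np.array(vg.orifice_center)
    mesh = rupture_mesh
    p = mesh.nodes[mesh.triangles]
    edges = np.concatenate([p[:, 1] - p[:, 0], p[:, 2] - p[:, 1], p[:, 0] - p[:, 2]])
    mids = np.concatenate([(p[:, 1] + p[:, 0]) / 2, (p[:, 2] + p[:, 1]) / 2,
                           (p[:, 0] + p[:, 2]) / 2])
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    d = np.hypot(mids[:, 0] - center[0], mids[:, 1] - center[1])
    near = lengths[d < 3 * vg.orifice_width]
    far = lengths[d > 10 * vg.orifice_width]
    assert np.median(near) < 0.5 * np.median(far)
    assert near.max() <= 2.5 * MeshSizing().h_min


def test_mesh_determinism_and_refinement_monotonicity():
    b = build_geometry(VesselGeometry(has_sac=False, has_orifice=False))
    m1 = generate_mesh(b, MeshSizing(h_max=0.02, h_min=0.01), seed=3)
    m2 = generate_mesh(b, MeshSizing(h_max=0.02, h_min=0.01), seed=3)
    assert np.array_equal(m1.nodes, m2.nodes)
    assert np.array_equal(m1.triangles, m2.triangles)
    counts = []
    for hmax in (0.03, 0.02, 0.012):
        m = generate_mesh(b, MeshSizing(h_max=hmax, h_min=0.006), seed=3)
        counts.append(m.n_triangles)
    assert counts[0] <= counts[1] <= counts[2]


def test_unit_square_mesh_area_conservation():
    vg = VesselGeometry(length=1.0, height=1.0, has_sac=False, has_orifice=False)
    m = generate_mesh(build_geometry(vg), MeshSizing(h_max=0.3, h_min=0.1), seed=0)
    assert m.total_area() == pytest.approx(1.0, abs=1e-10)


def test_structured_rectangle_mesh(channel_mesh):
    qr = quality_report(channel_mesh)
    assert qr.total_area == pytest.approx(0.7 * 0.09, rel=1e-12)
    assert qr.n_elements == 2 * 28 * 8
    axi = rectangle_mesh(0.7, 0.045, 4, 2, mode="axisymmetric")
    assert set(axi.boundary_tags) == {"INLET", "OUTLET", "WALL", "AXIS"}


# --------------------------------------------------------------- quality ----

def test_quality_metric_closed_forms():
    eq = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]])
    q = triangle_quality(eq, np.array([[0, 1, 2]]))
    assert q[0] == pytest.approx(1.0, abs=1e-12)
    right = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    q = triangle_quality(right, np.array([[0, 1, 2]]))
    assert q[0] == pytest.approx(math.sqrt(3) / 2, abs=1e-12)


def test_quality_report_bounds(rupture_mesh):
    qr = quality_report(rupture_mesh)
    assert 0 < qr.min_quality <= qr.avg_quality <= 1
    assert qr.n_elements == rupture_mesh.n_triangles


def test_degenerate_triangle_reported_not_dropped():
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [0.5, 1.0]])
    tris = np.array([[0, 1, 3], [1, 2, 0]])  # second is zero-area
    q = triangle_quality(nodes, tris)
    assert len(q) == 2 and q[1] == 0.0


# ------------------------------------------------------------------- I/O ----

def test_mesh_roundtrip_msh(tmp_path, rupture_mesh):
    p = tmp_path / "mesh.msh"
    write_mesh(rupture_mesh, p)
    back = read_mesh(p)
    assert np.allclose(back.nodes, rupture_mesh.nodes, rtol=0, atol=1e-15)
    assert np.array_equal(back.triangles, rupture_mesh.triangles)
    assert list(back.boundary_tags) == list(rupture_mesh.boundary_tags)
    assert np.array_equal(back.region_id, rupture_mesh.region_id)
    assert back.mode == rupture_mesh.mode


def test_read_untagged_mesh_errors(tmp_path):
    p = tmp_path / "plain.msh"
    p.write_text("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n"
                 "$Nodes\n3\n1 0 0 0\n2 1 0 0\n3 0 1 0\n$EndNodes\n"
                 "$Elements\n1\n1 2 2 100 0 1 2 3\n$EndElements\n")
    with pytest.raises(ValueError, match="tag"):
        read_mesh(p)


def test_unknown_format_rejected(tmp_path, rupture_mesh):
    with pytest.raises(ValueError, match="format"):
        write_mesh(rupture_mesh, tmp_path / "mesh.xyz")
    with pytest.raises(ValueError, match="format"):
        read_mesh(tmp_path / "mesh.xyz")
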