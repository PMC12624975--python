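"""Mesh generation: conformity, refinement constraint, tags, determinism."""

import numpy as np
import pytest

from arraystrain.geometry import ArraySpec, TissueSpec, build_geometry
from arraystrain.meshing import (
    Mesh,
    MeshSpec,
    MeshingError,
    box_mesh,
    generate_local_mesh,
    generate_mesh,
    max_edge_in_sphere,
    write_msh,
    write_vtu,
)


@pytest.fixture(scope="module")
def single_shank_model():
    arr = ArraySpec(rows=1, cols=1, base_lx=400, base_ly=400, base_lz=100)
    tis = TissueSpec(margin_below_tips=250, margin_lateral=250)
    return build_geometry(arr, tis)


@pytest.fixture(scope="module")
def coarse_mesh(single_shank_model):
    spec = MeshSpec(sphere_of_influence_radius=3.0, tip_max_edge=6.0,
                    global_target_edge=192.0, shank_refine_factor=5.0)
    return generate_mesh(single_shank_model, spec)


def test_all_elements_are_10_node_tetrahedra(coarse_mesh):
    assert coarse_mesh.tets.shape[1] == 10
    # midside nodes sit exactly at the edge midpoints (straight elements)
    p = coarse_mesh.points
    t = coarse_mesh.tets
    from arraystrain.meshing import TET10_EDGES

    for k, (i, j) in enumerate(TET10_EDGES):
        mid = 0.5 * (p[t[:, i]] + p[t[:, j]])
        assert np.allclose(p[t[:, 4 + k]], mid)


def test_positive_jacobians(coarse_mesh):
    assert coarse_mesh.volumes().min() > 0


def test_tip_sphere_edge_constraint(single_shank_model):
    spec = MeshSpec(sphere_of_influence_radius=5.0, tip_max_edge=3.0,
                    global_target_edge=192.0, shank_refine_factor=5.0)
    mesh = generate_mesh(single_shank_model, spec)
    tip = single_shank_model.tips[0]
    assert max_edge_in_sphere(mesh, tip, 5.0) <= 3.0 + 1e-9


def test_mesh_is_conforming(coarse_mesh):
    """Every interior corner face is shared by exactly two elements."""
    t4 = coarse_mesh.tet4
    faces = np.concatenate([t4[:, f] for f in
                            [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]])
    key = np.sort(faces, axis=1)
    _, counts = np.unique(key, axis=0, return_counts=True)
    assert counts.max() == 2
    assert set(np.unique(counts)) <= {1, 2}


def test_boundary_tags_nonempty_and_located(coarse_mesh, single_shank_model):
    lo, hi = single_shank_model.bounds
    for tag in ("tissue_bottom", "array_top", "interface"):
        assert len(coarse_mesh.faces[tag]) > 0
    zb = coarse_mesh.points[np.unique(coarse_mesh.faces["tissue_bottom"]), 2]
    assert np.allclose(zb, lo[2])
    zt = coarse_mesh.points[np.unique(coarse_mesh.faces["array_top"]), 2]
    assert np.allclose(zt, hi[2])


def test_region_tags_cover_both_materials(coarse_mesh):
    counts = np.bincount(coarse_mesh.region, minlength=2)
    assert counts[0] > 0 and counts[1] > 0
    # interface nodes are shared between tissue and array elements
    flags = coarse_mesh.node_regions()
    assert np.sum(flags == 3) > 0  # bonded contact: shared nodes


def test_determinism_same_spec_same_mesh(single_shank_model):
    spec = MeshSpec(sphere_of_influence_radius=3.0, tip_max_edge=8.0,
                    global_target_edge=192.0, shank_refine_factor=6.0)
    m1 = generate_mesh(single_shank_model, spec)
    m2 = generate_mesh(single_shank_model, spec)
    assert m1.n_elements == m2.n_elements
    assert m1.n_nodes == m2.n_nodes
    assert np.array_equal(m1.tets, m2.tets)
    assert np.allclose(m1.points, m2.points)


def test_multi_tip_refinement_constraint():
    arr = ArraySpec(rows=2, cols=2, base_lx=800, base_ly=800, base_lz=100)
    tis = TissueSpec(margin_below_tips=200, margin_lateral=200)
    model = build_geometry(arr, tis)
    spec = MeshSpec(sphere_of_influence_radius=3.0, tip_max_edge=6.0,
                    global_target_edge=192.0, shank_refine_factor=6.0)
    mesh = generate_mesh(model, spec)
    for tip in model.tips:
        assert max_edge_in_sphere(mesh, tip, 3.0) <= 6.0 + 1e-9


def test_spec_validation():
    with pytest.raises(MeshingError):
        MeshSpec(tip_max_edge=5.0, global_target_edge=2.0).validate()
    with pytest.raises(MeshingError):
        MeshSpec(element_order=1).validate()


def test_element_budget_enforced(single_shank_model):
    spec = MeshSpec(sphere_of_influence_radius=3.0, tip_max_edge=1.0,
                    global_target_edge=192.0, max_elements=5000)
    with pytest.raises(MeshingError):
        generate_mesh(single_shank_model, spec)


def test_local_mesh_refines_only_near_tip(single_shank_model):
    spec = MeshSpec(sphere_of_influence_radius=2.5, tip_max_edge=4.0,
                    global_target_edge=192.0, shank_refine_factor=4.0)
    tip = single_shank_model.tips[0]
    mesh = generate_local_mesh(single_shank_model, tip, 60.0, spec)
    assert mesh.volumes().min() > 0
    assert max_edge_in_sphere(mesh, tip, 2.5) <= 4.0 + 1e-9
    lo, hi = mesh.provenance["bounds"]
    assert np.all(mesh.points.min(axis=0) >= lo - 1e-6)
    assert np.all(mesh.points.max(axis=0) <= hi + 1e-6)


def test_box_mesh_structure():
    mesh = box_mesh([0, 0, 0], [2, 1, 1], (4, 2, 2))
    assert mesh.n_elements == 6 * 4 * 2 * 2
    assert mesh.volumes().min() > 0
    assert len(mesh.faces["tissue_bottom"]) == 2 * 4 * 2


def test_export_vtu_and_msh(tmp_path, coarse_mesh):
    vtu = tmp_path / "m.vtu"
    msh = tmp_path / "m.msh"
    write_vtu(coarse_mesh, vtu,
              point_data={"vm": np.zeros(coarse_mesh.n_nodes)})
    write_msh(coarse_mesh, msh)
    text = vtu.read_text()
    assert "QUADRATIC" not in text  # type code 24 is numeric
    assert f'NumberOfCells="{coarse_mesh.n_elements}"' in text
    head = msh.read_text().splitlines()
    assert head[0] == "$MeshFormat"
    assert any("$Elements" in line for line in head)
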