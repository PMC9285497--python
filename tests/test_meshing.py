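"""Mesh generation: conformity, grading, determinism, probe lookup."""

import numpy as np
import pytest

from ooablate.geometry import build_scenario
from ooablate.meshing import (
    RESOLUTION_LADDER,
    check_mesh,
    generate_mesh,
    probe_indices,
    structured_rectangle_mesh,
)


@pytest.fixture(scope="module")
def meshes(geom_a):
    return {lvl: generate_mesh(geom_a, lvl) for lvl in RESOLUTION_LADDER}


def test_mesh_invariants_hold_for_every_scenario_and_level(meshes):
    for mesh in meshes.values():
        check_mesh(mesh)  # positive areas, orientation, tags, region areas
    for sid in ("b", "c", "validation"):
        check_mesh(generate_mesh(build_scenario(sid), "medium"))


def test_region_areas_match_analytic_within_one_percent(meshes):
    for mesh in meshes.values():
        analytic = mesh.geometry.region_areas()
        for name, a_mesh in mesh.region_areas_mm2().items():
            assert a_mesh == pytest.approx(analytic[name], rel=0.01)


def test_refinement_increases_node_count_monotonically(meshes):
    counts = [meshes[lvl].n_nodes for lvl in RESOLUTION_LADDER]
    assert counts == sorted(counts)
    assert counts[0] < counts[-1] / 2


def test_finest_level_reaches_tenth_millimetre_at_the_tip(meshes):
    mesh = meshes["finest"]
    tip_edges = mesh.boundary_edges["electrode_active_tip"]
    assert len(tip_edges) > 0
    lengths = np.hypot(
        *(mesh.nodes[tip_edges[:, 0]] - mesh.nodes[tip_edges[:, 1]]).T
    )
    assert lengths.min() * 1e3 <= 0.105
    # grading: elements near the tip are the smallest in the mesh
    areas = mesh.triangle_areas()
    cent = mesh.nodes[mesh.triangles].mean(axis=1)
    near = np.hypot(cent[:, 0], cent[:, 1]) < 5e-3
    assert np.median(areas[near]) < 0.1 * np.median(areas[~near])


def test_mesh_generation_is_deterministic(geom_a):
    m1 = generate_mesh(geom_a, "coarse", seed=3)
    m2 = generate_mesh(geom_a, "coarse", seed=3)
    assert m1.nodes.tobytes() == m2.nodes.tobytes()
    assert np.array_equal(m1.triangles, m2.triangles)
    assert np.array_equal(m1.labels, m2.labels)


def test_boundary_tags_partition_the_exterior(mesh_a_coarse):
    mesh = mesh_a_coarse
    axis = mesh.boundary_edges["symmetry_axis"]
    outer = mesh.boundary_edges["outer_boundary"]
    assert np.abs(mesh.nodes[axis, 0]).max() < 1e-12
    rmax = mesh.geometry.r_max * 1e-3
    zmax = mesh.geometry.z_max * 1e-3
    mid = mesh.nodes[outer].mean(axis=1)
    on_rim = (
        (np.abs(mid[:, 0] - rmax) < 1e-9)
        | (np.abs(np.abs(mid[:, 1]) - zmax) < 1e-9)
    )
    assert on_rim.all()
    # an edge never carries two tags
    sets = [set(map(tuple, np.sort(e, axis=1))) for e in (axis, outer)]
    assert not sets[0] & sets[1]


def test_unknown_level_rejected(geom_a):
    with pytest.raises(ValueError, match="resolution level"):
        generate_mesh(geom_a, "ultra")


class TestProbeIndices:
    def test_probe_at_a_node_returns_that_node(self, mesh_a_coarse):
        node = 37
        r, z = mesh_a_coarse.nodes[node] * 1e3
        assert probe_indices(mesh_a_coarse, [(r, z)])[0] == node

    def test_validation_probes_are_distinct(self):
        mesh = generate_mesh(build_scenario("validation"), "coarse")
        idx = probe_indices(mesh, mesh.geometry.probe_points)
        assert len(set(idx.tolist())) == 3

    def test_probe_outside_domain_raises(self, mesh_a_coarse):
        with pytest.raises(ValueError, match="outside the domain"):
            probe_indices(mesh_a_coarse, [(400.0, 0.0)])


def test_structured_rectangle_mesh_geometry():
    mesh = structured_rectangle_mesh(0.001, 0.01, 0.0, 0.01, 9, 10)
    assert mesh.n_nodes == 10 * 11
    assert mesh.triangle_areas().sum() == pytest.approx(0.009 * 0.01, rel=1e-12)
    check_mesh(mesh)
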