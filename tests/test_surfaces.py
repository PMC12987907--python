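"""Derived surfaces: ROI crop, outer-surface wrap, skull base, sigmoid
reconstruction and the entry region."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from canalplan.errors import CoverageError, GeometryError
from canalplan.geometry import MeshDistance, points_in_mesh
from canalplan.surfaces import (
    EntryRegion,
    build_entry_region,
    build_sigmoid_surface,
    crop_roi,
    extract_outer_surface,
    extract_skull_base,
    normalize_side,
)


class TestCropRoi:
    def test_prism_containing_mesh_is_identity(self):
        mesh = trimesh.creation.box(extents=[10, 10, 10])
        out = crop_roi(mesh, [0, 0, 0], circumradius=100.0)
        assert len(out.faces) == len(mesh.faces)

    def test_disjoint_prism_raises(self):
        mesh = trimesh.creation.box(extents=[10, 10, 10])
        with pytest.raises(GeometryError):
            crop_roi(mesh, [0, 4.9, 0], circumradius=0.1, posterior_offset=100.0)

    def test_output_vertices_satisfy_half_planes(self, default_case):
        bone = default_case.meshes["temporal_bone"]
        out = crop_roi(bone, default_case.inner_ear_centre, circumradius=30.0)
        assert len(out.faces) > 0
        # re-derive the three half-planes and check every vertex
        apex = np.array([0.0, -10.0])
        ang = np.radians([90.0, 210.0, 330.0])
        v2d = apex + 30.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        pts = out.vertices.view(np.ndarray)[:, :2]
        for i in range(3):
            a, b = v2d[i], v2d[(i + 1) % 3]
            e = b - a
            n = np.array([-e[1], e[0]])
            n = n / np.linalg.norm(n)
            if np.dot(apex - a, n) < 0:
                n = -n
            assert ((pts - a) @ n).min() >= -1e-6


class TestOuterSurface:
    def test_convex_input_reproduces_itself(self):
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
        out = extract_outer_surface(sphere, target_face_area=0.5)
        md = MeshDistance(sphere)
        d, _, _ = md.closest(out.vertices)
        assert d.max() < 0.05

    def test_interior_cavity_is_never_reached(self):
        box = trimesh.creation.box(extents=[10, 10, 10]).subdivide_to_size(1.0)
        cavity = trimesh.creation.icosphere(subdivisions=2, radius=2.0)
        cavity.invert()
        soup = trimesh.util.concatenate([box, cavity])
        out = extract_outer_surface(soup, target_face_area=0.5)
        # nearest original face of every output vertex must be a box face
        md = MeshDistance(soup)
        _, _, tri = md.closest(out.vertices)
        assert tri.max() < len(box.faces)  # cavity faces are appended last

    def test_displacement_trace_decreases_and_median_area_near_target(self):
        box = trimesh.creation.box(extents=[8, 8, 8])
        target = 0.5
        out = extract_outer_surface(box, target_face_area=target)
        med = np.median(out.area_faces)
        assert target / 2 <= med <= target * 2
        # idempotence: wrapping the wrap moves vertices below tolerance
        again = extract_outer_surface(out, target_face_area=target)
        md = MeshDistance(out)
        d, _, _ = md.closest(again.vertices)
        assert d.max() < 0.05


class TestSkullBase:
    def test_flat_plate_component_is_recovered_exactly(self):
        """On the synthetic block the skull base is the sloped superior
        plate: every returned face must face upward and pass over the
        inner-ear centre region."""
        plate = trimesh.creation.box(extents=[20, 20, 1])
        plate.apply_translation([0, 0, 10])
        base = extract_skull_base(plate, np.zeros(3), clip_depth=0.4)
        assert len(base.faces) > 0
        assert (base.face_normals[:, 2] > 0.99).all()
        assert base.bounds[0][2] >= 10.4  # only the top side of the plate

    def test_seed_face_is_member_and_connected(self, default_case):
        bone = default_case.meshes["temporal_bone"]
        centre = default_case.inner_ear_centre
        base = extract_skull_base(bone, centre)
        from canalplan.geometry import ray_mesh

        t, tri = ray_mesh(centre[None], np.array([[0.0, 0.0, 1.0]]), bone)
        hit = centre + t[0] * np.array([0, 0, 1.0])
        md = MeshDistance(base)
        d, _, _ = md.closest(hit[None])
        assert d[0] < 1e-6  # the seed face is part of the output
        assert len(base.split(only_watertight=False)) == 1  # edge-connected

    def test_no_superior_face_raises(self):
        plate = trimesh.creation.box(extents=[4, 4, 1])
        plate.apply_translation([0, 0, -5])  # everything below the centre
        with pytest.raises(GeometryError):
            extract_skull_base(plate, np.zeros(3))


class TestSigmoidSurface:
    def test_cylindrical_channel_volume_oracle(self):
        """A straight centreline inside a cylindrical channel of radius
        4 mm reconstructs the analytic cylinder volume within 15%."""
        length = 30.0
        shell = trimesh.creation.cylinder(radius=4.0, height=length, sections=64)
        shell = shell.subdivide_to_size(1.0)
        centreline = np.column_stack(
            [np.zeros(31), np.zeros(31), np.linspace(-length / 2, length / 2, 31)]
        )
        surf = build_sigmoid_surface(centreline, shell, n_directions=128)
        inner = centreline[2:-2]
        assert points_in_mesh(inner, surf).all()
        expected = np.pi * 16.0 * length
        assert surf.metadata["complex_volume"] == pytest.approx(expected, rel=0.15)

    def test_subtraction_removes_contained_faces(self, case_artifacts):
        _, art = case_artifacts
        skull_base = art["skull_base"]
        sigmoid = art["sigmoid"]
        inside = points_in_mesh(skull_base.triangles_center, sigmoid)
        assert not inside.any()

    def test_too_short_centreline_raises(self, default_case):
        with pytest.raises(GeometryError):
            build_sigmoid_surface(
                np.zeros((1, 3)), default_case.meshes["temporal_bone"]
            )


class TestEntryRegion:
    def test_planar_area_is_1000_mm2(self):
        region = EntryRegion(
            points=np.zeros((1, 3)),
            normals=np.zeros((1, 3)),
            uv=np.zeros((1, 2)),
            eac_centre=np.zeros(3),
        )
        assert region.planar_area == 1000.0

    def test_default_returns_exactly_5000_surface_points(self, default_case):
        """The full-resolution entry region places 5000 points, all on the
        outer surface, all inside the planar domain."""
        bone = default_case.meshes["temporal_bone"]
        outer = extract_outer_surface(bone, target_face_area=1.0)
        region = build_entry_region(outer, default_case.eac_centre, n_points=5000)
        assert len(region) == 5000
        md = MeshDistance(outer)
        d, _, _ = md.closest(region.points)
        assert d.max() < 1e-6
        assert region.contains_uv(region.uv).all()

    def test_even_spacing_on_flat_phantom(self):
        """Nearest-neighbour spacing CV < 0.2 on a flat lateral surface."""
        plate = trimesh.creation.box(extents=[1.0, 60, 60])
        plate.apply_translation([10, -10, 0])
        region = build_entry_region(plate, [10.5, 8.0, 0.0], n_points=2000)
        tree = cKDTree(region.uv)
        d, _ = tree.query(region.uv, k=2)
        nn = d[:, 1]
        assert nn.std() / nn.mean() < 0.2

    def test_projection_misses_raise_coverage_error(self):
        tiny = trimesh.creation.box(extents=[1, 2, 2])
        with pytest.raises(CoverageError):
            build_entry_region(tiny, [0.5, 0.0, 0.0], n_points=500)

    def test_json_roundtrip(self, tmp_path, default_case):
        bone = default_case.meshes["temporal_bone"]
        outer = extract_outer_surface(bone, target_face_area=2.0)
        region = build_entry_region(outer, default_case.eac_centre, n_points=100)
        region.to_json(tmp_path / "region.json")
        back = EntryRegion.from_json(tmp_path / "region.json")
        assert np.allclose(back.points, region.points)
        assert np.allclose(back.uv, region.uv)


class TestNormalizeSide:
    def test_right_case_unchanged(self, default_case):
        out = normalize_side(default_case)
        assert out is default_case

    def test_mirror_twice_restores_coordinates(self):
        from canalplan.anatomy import AnatomyParams, generate_case, mirror_case

        left = generate_case(AnatomyParams(side="left"))
        back = mirror_case(mirror_case(left))
        for name in left.meshes:
            assert np.allclose(
                back.meshes[name].vertices, left.meshes[name].vertices, atol=1e-9
            )

    def test_left_case_normalizes_to_right_twin(self, default_case):
        from canalplan.anatomy import AnatomyParams, generate_case

        left = generate_case(AnatomyParams(side="left"))
        norm = normalize_side(left)
        assert norm.side == "right"
        for name in default_case.meshes:
            assert np.allclose(
                norm.meshes[name].vertices,
                default_case.meshes[name].vertices,
                atol=1e-12,
            )
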