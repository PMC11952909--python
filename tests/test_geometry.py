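"""Phantom generation, endplate annotation, and mesh/surface I/O."""

import numpy as np
import pytest
import trimesh

from spinepinn.geometry import (
    MeshResolutionError,
    PhantomSpec,
    SurfaceMesh,
    analytic_volume,
    annotate_endplates,
    build_phantom,
    extract_surface,
    permute_mesh,
    tet_volumes,
)
from spinepinn.stl_io import STLParseError, read_stl, write_stl
from spinepinn.vtk_io import read_vtk, write_vtk


class TestBuildPhantom:
    def test_default_stack_has_five_vertebrae_four_discs(self, phantom_mesh):
        names = phantom_mesh.region_names
        assert sum(n.startswith("vertebra") for n in names) == 5
        assert sum(n.startswith("disc") for n in names) == 4
        # alternating along +z
        assert names[0] == "vertebra_1" and names[1] == "disc_1"
        assert names[-1] == "vertebra_5"

    def test_single_vertebra_degenerate_stack(self):
        mesh = build_phantom(PhantomSpec(n_vertebrae=1, mesh_resolution=8.0))
        assert mesh.region_names == ["vertebra_1"]
        tops = [k for k in mesh.endplate_sets if k.endswith("_upper")]
        assert tops == ["vertebra_1_upper"]
        assert len(mesh.endplate_sets["top"]) > 0
        assert len(mesh.endplate_sets["bottom"]) > 0

    @pytest.mark.parametrize("cross_section", ["cylinder", "box"])
    def test_volume_matches_generating_solid(self, cross_section):
        spec = PhantomSpec(cross_section=cross_section, mesh_resolution=6.0)
        mesh = build_phantom(spec)
        total = tet_volumes(mesh.nodes, mesh.tets).sum()
        assert total == pytest.approx(analytic_volume(spec), rel=1e-9)

    def test_region_volumes_partition_total(self, phantom_mesh):
        per_region = sum(
            phantom_mesh.region_volume(n) for n in phantom_mesh.region_names
        )
        assert per_region == pytest.approx(phantom_mesh.total_volume(), rel=1e-9)

    def test_all_tets_positive_volume(self, phantom_mesh):
        from spinepinn.geometry import _signed_tet_volumes

        assert np.all(_signed_tet_volumes(phantom_mesh.nodes, phantom_mesh.tets) > 0)

    def test_conforming_interfaces_share_nodes(self, phantom_mesh):
        # a conforming mesh has no duplicated node coordinates
        unique = np.unique(np.round(phantom_mesh.nodes, 9), axis=0)
        assert len(unique) == len(phantom_mesh.nodes)

    def test_surface_watertight(self, phantom_mesh):
        surf = extract_surface(phantom_mesh)
        assert surf.watertight
        np.testing.assert_allclose(np.linalg.norm(surf.normals, axis=1), 1.0, atol=1e-9)

    def test_bit_reproducible(self, phantom_spec, phantom_mesh):
        again = build_phantom(phantom_spec)
        assert np.array_equal(again.nodes, phantom_mesh.nodes)
        assert np.array_equal(again.tets, phantom_mesh.tets)
        assert np.array_equal(again.region_labels, phantom_mesh.region_labels)

    def test_too_coarse_resolution_raises(self):
        with pytest.raises(MeshResolutionError):
            build_phantom(PhantomSpec(mesh_resolution=500.0))

    def test_vertebra_scale_surface_resolution(self):
        # a single vertebra at ~1.6 mm target edge length lands in the
        # 6000-7000 surface-triangle range typical of segmented vertebrae
        mesh = build_phantom(PhantomSpec(n_vertebrae=1, mesh_resolution=1.6))
        n_tri = len(extract_surface(mesh).triangles)
        assert 6000 <= n_tri <= 7000


def _cube_surface():
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(vertices=np.asarray(box.vertices), triangles=np.asarray(box.faces))


class TestAnnotateEndplates:
    def test_cube_top_and_bottom_faces(self):
        surf = _cube_surface()
        upper, lower = annotate_endplates(surf, max_angle_deg=10.0, distance_band=(0.4, 0.6))
        assert np.allclose(surf.normals[upper], [0, 0, 1])
        assert np.allclose(surf.normals[lower], [0, 0, -1])
        assert len(upper) == 2 and len(lower) == 2
        assert not set(upper) & set(lower)

    def test_sphere_zero_angle_selects_nothing(self):
        ico = trimesh.creation.icosphere(subdivisions=2)
        surf = SurfaceMesh(vertices=np.asarray(ico.vertices), triangles=np.asarray(ico.faces))
        with pytest.warns(UserWarning):
            upper, lower = annotate_endplates(surf, max_angle_deg=0.0, distance_band=(0.0, 1.0))
        assert len(upper) == 0 and len(lower) == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_per_triangle_filter(self, seed):
        rng = np.random.default_rng(seed)
        ico = trimesh.creation.icosphere(subdivisions=2)
        verts = np.asarray(ico.vertices) * rng.uniform(0.5, 2.0, size=3)
        surf = SurfaceMesh(vertices=verts, triangles=np.asarray(ico.faces))
        max_angle = rng.uniform(5.0, 60.0)
        band = tuple(np.sort(rng.uniform(0.0, 1.5, size=2)))
        axis = np.array([0.0, 0.0, 1.0])
        upper, lower = annotate_endplates(surf, max_angle, band, axis)

        cos_max = np.cos(np.deg2rad(max_angle))
        s0 = float(np.mean(surf.vertices @ axis))
        exp_upper, exp_lower = [], []
        for i in range(len(surf.triangles)):
            n = surf.normals[i] / np.linalg.norm(surf.normals[i])
            d = surf.vertices[surf.triangles[i]].mean(axis=0) @ axis - s0
            if n @ axis >= cos_max and band[0] <= d <= band[1]:
                exp_upper.append(i)
            if -(n @ axis) >= cos_max and band[0] <= -d <= band[1]:
                exp_lower.append(i)
        assert upper.tolist() == exp_upper
        assert lower.tolist() == exp_lower

    def test_pure_predicate_is_order_independent(self):
        surf = _cube_surface()
        perm = np.random.default_rng(3).permutation(len(surf.triangles))
        shuffled = SurfaceMesh(vertices=surf.vertices, triangles=surf.triangles[perm])
        u1, _ = annotate_endplates(surf, 10.0, (0.4, 0.6))
        u2, _ = annotate_endplates(shuffled, 10.0, (0.4, 0.6))
        assert sorted(perm[u2].tolist()) == sorted(u1.tolist())

    def test_invalid_parameters_rejected(self):
        surf = _cube_surface()
        with pytest.raises(ValueError):
            annotate_endplates(surf, max_angle_deg=95.0)
        with pytest.raises(ValueError):
            annotate_endplates(surf, axis=(0.0, 0.0, 0.0))


class TestSTL:
    def test_single_triangle_ascii(self, tmp_path):
        p = tmp_path / "tri.stl"
        p.write_text(
            "solid tri\n"
            " facet normal 0 0 1\n"
            "  outer loop\n"
            "   vertex 0 0 0\n"
            "   vertex 1 0 0\n"
            "   vertex 0 1 0\n"
            "  endloop\n"
            " endfacet\n"
            "endsolid tri\n"
        )
        surf = read_stl(p)
        assert len(surf.triangles) == 1
        assert len(np.unique(surf.vertices, axis=0)) == 3

    @pytest.mark.parametrize("binary", [True, False])
    def test_phantom_surface_roundtrip(self, tmp_path, phantom_mesh, binary):
        surf = extract_surface(phantom_mesh)
        p = tmp_path / "phantom.stl"
        write_stl(surf, p, binary=binary)
        back = read_stl(p)
        assert len(back.triangles) == len(surf.triangles)
        # vertex coordinates survive to float32 precision
        orig = np.sort(surf.vertices[surf.triangles].reshape(-1, 3), axis=0)
        got = np.sort(back.vertices[back.triangles].reshape(-1, 3), axis=0)
        np.testing.assert_allclose(got, orig, rtol=1e-6, atol=1e-5)

    def test_truncated_binary_names_offset(self, tmp_path):
        p = tmp_path / "bad.stl"
        p.write_bytes(b"\x00" * 90)  # header claims triangles that are missing
        with pytest.raises(STLParseError, match="byte"):
            read_stl(p)

    def test_malformed_ascii_names_line(self, tmp_path):
        p = tmp_path / "bad.stl"
        p.write_text("solid x\n facet normal 0 0 1\n  outer loop\n   vertex 0 0\n")
        with pytest.raises(STLParseError, match="line"):
            read_stl(p)


class TestVTK:
    def test_mesh_roundtrip(self, tmp_path, phantom_mesh):
        p = tmp_path / "mesh.vtk"
        write_vtk(phantom_mesh, p)
        back = read_vtk(p)
        np.testing.assert_array_equal(back.nodes, phantom_mesh.nodes)
        np.testing.assert_array_equal(back.tets, phantom_mesh.tets)
        np.testing.assert_array_equal(back.region_labels, phantom_mesh.region_labels)
        assert back.region_names == phantom_mesh.region_names
        for k, v in phantom_mesh.endplate_sets.items():
            np.testing.assert_array_equal(np.sort(back.endplate_sets[k]), np.sort(v))

    def test_non_vtk_rejected(self, tmp_path):
        p = tmp_path / "x.vtk"
        p.write_text("not a vtk file\n")
        with pytest.raises(ValueError):
            read_vtk(p)


class TestPermuteMesh:
    def test_permutation_preserves_geometry(self, phantom_mesh):
        perm = permute_mesh(phantom_mesh, np.random.default_rng(0))
        assert perm.total_volume() == pytest.approx(phantom_mesh.total_volume(), rel=1e-12)
        assert len(perm.endplate_sets["top"]) == len(phantom_mesh.endplate_sets["top"])
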