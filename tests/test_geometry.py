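"""Mesh metrics against closed forms and independent oracles; exposure
classification against brute-force ray casting and analytic constructions."""

import numpy as np
import pytest
import trimesh

from digembryo import geometry
from digembryo.model import Blastomere, EmbryoFrame
from digembryo.raycast import OcclusionScene, ray_triangle_any
from digembryo.synthetic import sphere_mesh

from conftest import (
    make_blastomere,
    naive_classify,
    random_rotation,
    transform_frame,
)


def unit_cube(centre=(0.0, 0.0, 0.0)):
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    box.apply_translation(centre)
    return trimesh.Trimesh(box.vertices, box.faces, process=False)


class TestMeshMetrics:
    def test_cube_closed_forms(self):
        cube = unit_cube((5.0, 0.0, 0.0))
        assert geometry.surface_area(cube) == pytest.approx(6.0, rel=1e-12)
        assert geometry.enclosed_volume(cube) == pytest.approx(1.0, rel=1e-12)
        assert geometry.centre_of_mass(cube) == pytest.approx([5.0, 0.0, 0.0], abs=1e-12)

    def test_icosphere_analytic_limits(self):
        s = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        assert geometry.surface_area(s) == pytest.approx(4 * np.pi, rel=0.01)
        s2 = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        assert geometry.enclosed_volume(s2) == pytest.approx(
            4 * np.pi * 8 / 3, rel=0.015
        )

    def test_area_equals_per_face_cross_product_sum(self):
        rng = np.random.default_rng(7)
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=3.0)
        mesh = trimesh.Trimesh(
            mesh.vertices + rng.normal(0, 0.05, mesh.vertices.shape),
            mesh.faces,
            process=False,
        )
        tris = mesh.triangles
        oracle = sum(
            0.5 * np.linalg.norm(np.cross(t[1] - t[0], t[2] - t[0])) for t in tris
        )
        assert geometry.surface_area(mesh) == pytest.approx(oracle, rel=1e-9)

    def test_l_prism_volume_and_centroid_vs_voxel_oracle(self):
        # L-shaped cross-section in (x, y), extruded along z, built by hand
        loop = [(0, 0), (4, 0), (4, 2), (2, 2), (2, 4), (0, 4), (0, 2)]
        cap = [(0, 1, 2), (0, 2, 3), (0, 3, 6), (6, 3, 4), (6, 4, 5)]
        nb = len(loop)
        verts = [(x, y, 0.0) for x, y in loop] + [(x, y, 2.0) for x, y in loop]
        faces = []
        for a, b, c in cap:
            faces.append((a, c, b))                      # bottom, faces -z
            faces.append((a + nb, b + nb, c + nb))       # top, faces +z
        for i in range(nb):                              # side walls
            j = (i + 1) % nb
            faces.append((i, j, j + nb))
            faces.append((i, j + nb, i + nb))
        mesh = trimesh.Trimesh(np.array(verts, float), np.array(faces), process=False)
        assert mesh.is_watertight

        # voxel-counting oracle with analytic insideness of the L solid
        h = 0.02
        ax = np.arange(h / 2, 4, h)
        az = np.arange(h / 2, 2, h)
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        inside_xy = (Y <= 2) | (X <= 2)
        n_xy = inside_xy.sum()
        vol_oracle = n_xy * len(az) * h**3
        cx = (X[inside_xy].sum() * len(az)) * h**3 / vol_oracle
        cy = (Y[inside_xy].sum() * len(az)) * h**3 / vol_oracle
        cz = 1.0

        vol = geometry.enclosed_volume(mesh)
        com = geometry.centre_of_mass(mesh)
        assert vol == pytest.approx(vol_oracle, rel=0.01)
        diag = np.linalg.norm(mesh.bounds[1] - mesh.bounds[0])
        assert np.linalg.norm(com - [cx, cy, cz]) < 0.005 * diag

    def test_centroid_translation_equivariance(self):
        cube = unit_cube()
        shifted = unit_cube((5.0, 0.0, 0.0))
        assert geometry.centre_of_mass(shifted) - geometry.centre_of_mass(
            cube
        ) == pytest.approx([5.0, 0.0, 0.0], abs=1e-12)

    def test_validation_rejects_open_and_degenerate_meshes(self):
        open_mesh = trimesh.Trimesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            faces=[[0, 1, 2]],
            process=False,
        )
        with pytest.raises(geometry.MeshValidationError):
            geometry.validate_mesh(open_mesh, "open")
        with pytest.raises(geometry.MeshValidationError):
            geometry.enclosed_volume(open_mesh)

    def test_inward_winding_auto_reoriented(self):
        cube = unit_cube()
        cube.invert()
        fixed = geometry.validate_mesh(cube, "inverted")
        assert fixed.volume > 0


class TestRayCast:
    def test_any_hit_matches_naive_oracle_on_random_frames(self):
        rng = np.random.default_rng(11)
        for _ in range(12):
            n_cells = rng.integers(2, 5)
            cells = [
                make_blastomere(
                    f"C{i}",
                    rng.uniform(-12, 12, 3),
                    rng.uniform(4.0, 9.0),
                    subdivisions=1,
                )
                for i in range(n_cells)
            ]
            frame = EmbryoFrame(frame=0, cells=cells)
            for cell in cells:
                got = geometry.classify_faces(cell, frame).external
                want = naive_classify(cell, frame)
                assert np.array_equal(got, want)

    def test_rays_cannot_slip_through_shared_edges(self):
        # two triangles sharing an edge; a ray aimed exactly at the shared
        # edge must register a hit
        tris = np.array(
            [
                [[0, -1, 5], [0, 1, 5], [2, 0, 5]],
                [[0, -1, 5], [-2, 0, 5], [0, 1, 5]],
            ],
            dtype=float,
        )
        hit = ray_triangle_any(
            np.array([[0.0, 0.0, 0.0]]), np.array([[0.0, 0.0, 1.0]]), tris
        )
        assert bool(hit[0])

    def test_tangent_spheres_match_oracle(self):
        a = make_blastomere("A", (0, 0, 0), 5.0, subdivisions=2)
        b = make_blastomere("B", (10.0, 0, 0), 5.0, subdivisions=2)
        frame = EmbryoFrame(frame=0, cells=[a, b])
        for cell in (a, b):
            got = geometry.classify_faces(cell, frame).external
            want = naive_classify(cell, frame)
            assert np.array_equal(got, want)


class TestExposure:
    def test_lone_cell_fully_exposed(self, lone_cell_frame):
        rec = geometry.surface_exposure(lone_cell_frame.cells[0], lone_cell_frame)
        assert rec.exposure == 1.0
        assert rec.external_area == pytest.approx(rec.total_area)

    def test_enclosed_cell_zero_exposure(self, enclosed_frame):
        rec = geometry.surface_exposure(enclosed_frame.cell("INNER"), enclosed_frame)
        assert rec.exposure == 0.0

    def test_hemisphere_occluder_half_exposure(self):
        sph = Blastomere("S", 0, sphere_mesh(np.zeros(3), 10.0, 3))
        slab = trimesh.creation.box(extents=[2000, 2000, 2.0])
        slab.apply_translation([0, 0, 15.0])
        occ = Blastomere(
            "SLAB", 0, trimesh.Trimesh(slab.vertices, slab.faces, process=False)
        )
        frame = EmbryoFrame(0, [sph, occ])
        rec = geometry.surface_exposure(sph, frame)
        # outward rays with a +z component are blocked: half the area, up to
        # mesh discretisation of the equator
        assert rec.exposure == pytest.approx(0.5, abs=0.02)

    def test_exposure_invariant_under_rigid_motion_and_scale(self):
        rng = np.random.default_rng(3)
        cells = [
            make_blastomere("A", (0, 0, 0), 6.0, subdivisions=1),
            make_blastomere("B", (9.0, 2.0, 0), 5.0, subdivisions=1),
            make_blastomere("C", (-4.0, -7.0, 3.0), 4.0, subdivisions=1),
        ]
        frame = EmbryoFrame(frame=0, cells=cells)
        base = {
            cid: rec.exposure for cid, rec in geometry.frame_exposures(frame).items()
        }
        moved = transform_frame(
            frame,
            rotation=random_rotation(rng),
            translation=np.array([100.0, -50.0, 8.0]),
            scale=3.7,
        )
        after = {
            cid: rec.exposure for cid, rec in geometry.frame_exposures(moved).items()
        }
        for cid in base:
            assert after[cid] == pytest.approx(base[cid], abs=1e-12)

    def test_adding_occluder_never_increases_exposure(self):
        target = make_blastomere("T", (0, 0, 0), 6.0, subdivisions=2)
        other = make_blastomere("O1", (10.0, 0, 0), 5.0, subdivisions=1)
        extra = make_blastomere("O2", (0, 10.0, 0), 5.0, subdivisions=1)
        small = EmbryoFrame(frame=0, cells=[target, other])
        big = EmbryoFrame(frame=0, cells=[target, other, extra])
        e_small = geometry.surface_exposure(small.cell("T"), small).exposure
        e_big = geometry.surface_exposure(big.cell("T"), big).exposure
        assert e_big <= e_small
        ext_small = geometry.classify_faces(small.cell("T"), small).external
        ext_big = geometry.classify_faces(big.cell("T"), big).external
        assert not np.any(ext_big & ~ext_small)

    def test_exposure_converges_under_subdivision(self):
        values = []
        for sub in (2, 3):
            cells = [
                make_blastomere("A", (0, 0, 0), 6.0, subdivisions=sub),
                make_blastomere("B", (9.0, 0, 0), 6.0, subdivisions=sub),
            ]
            frame = EmbryoFrame(frame=0, cells=cells)
            values.append(geometry.surface_exposure(frame.cell("A"), frame).exposure)
        assert abs(values[1] - values[0]) < 0.02


class TestNearestFace:
    def test_matches_dense_surface_sampling(self):
        rng = np.random.default_rng(5)
        mesh = sphere_mesh(np.array([1.0, 2.0, 3.0]), 5.0, 2)
        pts = rng.uniform(-6, 10, size=(200, 3))
        dist, face = geometry.nearest_face(pts, mesh)
        # oracle: dense barycentric sampling of every triangle
        u = np.linspace(0, 1, 25)
        uu, vv = np.meshgrid(u, u)
        keep = (uu + vv) <= 1.0
        bary = np.stack([1 - uu[keep] - vv[keep], uu[keep], vv[keep]], axis=1)
        samples = np.einsum("sk,tkj->tsj", bary, mesh.triangles).reshape(-1, 3)
        oracle = np.min(
            np.linalg.norm(pts[:, None, :] - samples[None, :, :], axis=-1), axis=1
        )
        assert np.all(dist <= oracle + 1e-9)
        assert np.max(dist - oracle) > -0.05  # sampling oracle overestimates
        assert np.allclose(dist, oracle, atol=0.05)

    def test_max_distance_prefilter_is_conservative(self):
        mesh = sphere_mesh(np.zeros(3), 5.0, 2)
        rng = np.random.default_rng(9)
        pts = rng.uniform(-8, 8, size=(500, 3))
        full, _ = geometry.nearest_face(pts, mesh)
        cut, face = geometry.nearest_face(pts, mesh, max_distance=1.0)
        close = full <= 1.0
        assert np.allclose(cut[close], full[close])
        assert np.all(np.isinf(cut[~close]) | (cut[~close] > 1.0))
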