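"""Lofting, swept tetrahedral meshing and stiffness interpolation."""

from collections import Counter

import numpy as np
import pytest

from lungmech import geometry as geo
from lungmech import synthetic as syn


def _circles(radii, inner_offset=0.005, n=48):
    ang = 2 * np.pi * np.arange(n) / n
    ring = lambda r: np.column_stack([r * np.cos(ang), r * np.sin(ang)])
    return syn.AxialOutlineStack(
        outlines=[ring(r) for r in radii],
        inner_outlines=[ring(r - inner_offset) for r in radii],
        z=np.arange(len(radii)) * 0.01)


class TestLoft:
    def test_cylinder_volume(self, circle_stack):
        outer, _ = geo.loft_outlines(circle_stack)
        v_true = np.pi * 0.05 ** 2 * 0.04
        assert abs(outer.volume() - v_true) / v_true < 0.02

    def test_frustum_volume(self):
        radii = np.linspace(0.05, 0.03, 5)
        outer, _ = geo.loft_outlines(_circles(radii))
        h, R, r = 0.04, 0.05, 0.03
        v_true = np.pi * h / 3 * (R * R + R * r + r * r)
        assert abs(outer.volume() - v_true) / v_true < 0.02

    def test_single_slice_rejected(self):
        ang = 2 * np.pi * np.arange(16) / 16
        ring = np.column_stack([np.cos(ang), np.sin(ang)])
        with pytest.raises(ValueError):
            syn.AxialOutlineStack(outlines=[ring], inner_outlines=[ring],
                                  z=np.array([0.0]))

    def test_cross_section_reproduces_input(self, lung_outlines):
        outer, _ = geo.loft_outlines(lung_outlines, n_theta=64)
        ring = outer.cross_section(lung_outlines.z[2])
        poly = lung_outlines.outlines[2]
        # directed distance to the polygon boundary, relative to diameter
        from shapely.geometry import LinearRing, Point
        boundary = LinearRing(poly)
        d = max(boundary.distance(Point(p)) for p in ring)
        diameter = poly[:, 0].max() - poly[:, 0].min()
        assert d / diameter < 0.01

    def test_volume_converges_under_slice_refinement(self):
        # ellipsoid-like analytic shape: r(z) = R sqrt(1 - (z/c)^2 * 0.5)
        def stack(n_slices):
            z = np.linspace(0, 0.04, n_slices)
            radii = 0.05 * np.sqrt(1 - 0.5 * ((z - 0.02) / 0.02) ** 2)
            ang = 2 * np.pi * np.arange(64) / 64
            ring = lambda r: np.column_stack([r * np.cos(ang),
                                              r * np.sin(ang)])
            return syn.AxialOutlineStack(
                outlines=[ring(r) for r in radii],
                inner_outlines=[ring(r - 0.004) for r in radii], z=z)

        z_f = np.linspace(0, 0.04, 400)
        r_f = 0.05 * np.sqrt(1 - 0.5 * ((z_f - 0.02) / 0.02) ** 2)
        v_true = np.trapezoid(np.pi * r_f ** 2, z_f)
        errs = []
        for n in (5, 9):
            outer, _ = geo.loft_outlines(stack(n))
            errs.append(abs(outer.volume() - v_true) / v_true)
        assert errs[1] <= errs[0] + 1e-4


class TestPrismSplit:
    def test_straight_extrusion_volume_exact(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(3, 2))
        verts = np.vstack([np.column_stack([base, np.zeros(3)]),
                           np.column_stack([base, np.ones(3)])])
        tets = geo.split_prisms(np.array([[0, 1, 2, 3, 4, 5]]))
        assert tets.shape == (3, 4)
        vol = 0.0
        for t in tets:
            d = verts[t[1:]] - verts[t[0]]
            vol += abs(np.dot(d[0], np.cross(d[1], d[2]))) / 6.0
        e1 = np.append(base[1] - base[0], 0.0)
        e2 = np.append(base[2] - base[0], 0.0)
        area = abs(np.cross(e1, e2)[2]) / 2.0
        assert abs(vol - area) < 1e-12 * max(area, 1.0)

    def test_adjacent_prisms_share_quad_diagonal(self):
        # two prisms sharing a vertical quad face must agree on its split
        verts2d = np.array([[0.0, 0], [1, 0], [0.4, 1], [1.3, 0.9]])
        verts = np.vstack([np.column_stack([verts2d, np.zeros(4)]),
                           np.column_stack([verts2d, np.ones(4)])])
        prisms = np.array([[0, 1, 2, 4, 5, 6], [1, 3, 2, 5, 7, 6]])
        tets = geo.split_prisms(prisms)
        faces = Counter()
        for t in tets:
            for f in geo.TET_FACES:
                faces[tuple(sorted(t[list(f)]))] += 1
        # shared quad (1,2,5,6): its two split triangles appear twice each
        shared = [k for k, v in faces.items() if v == 2
                  and set(k) <= {1, 2, 5, 6}]
        assert len(shared) == 2
        vols = []
        for t in tets:
            d = verts[t[1:]] - verts[t[0]]
            vols.append(abs(np.dot(d[0], np.cross(d[1], d[2]))) / 6.0)
        assert min(vols) > 0


class TestMeshing:
    def test_element_count_near_target(self, circle_stack):
        outer, inner = geo.loft_outlines(circle_stack)
        mesh = geo.mesh_solids(outer, inner, target_element_count=5000)
        assert abs(mesh.n_elements - 5000) / 5000 < 0.30

    def test_mesh_volume_matches_solid(self, circle_stack):
        outer, inner = geo.loft_outlines(circle_stack)
        mesh = geo.mesh_solids(outer, inner, target_element_count=5000)
        assert abs(mesh.volume() - outer.volume()) / outer.volume() < 0.01

    def test_positive_jacobians(self, lung_mesh_small):
        assert lung_mesh_small.element_volumes().min() > 0

    def test_conforming_faces(self, lung_mesh_small):
        c = Counter()
        for el in lung_mesh_small.elements:
            for f in geo.TET_FACES:
                c[tuple(sorted(el[list(f)]))] += 1
        assert set(c.values()) <= {1, 2}

    def test_refinement_decreases_edge_length(self, circle_stack):
        outer, inner = geo.loft_outlines(circle_stack)
        coarse = geo.mesh_solids(outer, inner, target_element_count=1000)
        fine = geo.mesh_solids(outer, inner, target_element_count=4000)
        assert fine.max_edge_length() < coarse.max_edge_length()

    def test_apical_faces_on_top_plane(self, lung_mesh_small):
        faces = lung_mesh_small.face_labels["apical"]
        z = lung_mesh_small.nodes[faces[:, :6], 2]
        assert np.allclose(z, z.max())

    def test_boundary_labels_partition(self, lung_mesh_small):
        c = Counter()
        for el in lung_mesh_small.elements:
            for f in geo.TET_FACES:
                c[tuple(sorted(el[list(f)]))] += 1
        n_boundary = sum(1 for v in c.values() if v == 1)
        n_labelled = sum(len(f) for f in lung_mesh_small.face_labels.values())
        assert n_boundary == n_labelled


class TestInterpolation:
    def test_constant_maps(self, lung_mesh_small):
        maps = np.full((5, 32, 32), 2500.0)
        model = geo.interpolate_stiffness(lung_mesh_small, maps,
                                          np.arange(5) * 0.01, 0.4 / 32)
        assert np.allclose(model.nodal_G, 2500.0)
        assert np.isclose(model.mean_G, 2500.0)

    def test_linear_in_z(self, lung_mesh_small):
        z = np.arange(5) * 0.01
        maps = np.ones((5, 32, 32)) * (1000 + 50000 * z)[:, None, None]
        model = geo.interpolate_stiffness(lung_mesh_small, maps, z, 0.4 / 32)
        inner_nodes = np.unique(
            lung_mesh_small.elements[lung_mesh_small.domain == 0])
        pts = lung_mesh_small.nodes[inner_nodes]
        expect = 1000 + 50000 * np.clip(pts[:, 2], z[0], z[-1])
        assert np.allclose(model.nodal_G[inner_nodes], expect, rtol=1e-6)

    def test_inclusion_contrast_preserved(self, lung_mesh_small):
        inc = syn.Inclusion(center=(0.0, 0.0, 0.02), radius=0.025,
                            modulus=9000.0)
        field = syn.generate_stiffness_field(syn.StiffnessFieldSpec(
            grid_shape=(5, 64, 64), pixel_spacing=3.125e-3,
            slice_spacing=0.01, base_modulus=3000.0, inclusion=inc))
        model = geo.interpolate_stiffness(lung_mesh_small, field.values,
                                          np.arange(5) * 0.01, 3.125e-3)
        cen = lung_mesh_small.element_centroids()
        r = np.linalg.norm(cen - np.array([0, 0, 0.02]), axis=1)
        g_el = model.nodal_G[lung_mesh_small.elements].mean(axis=1)
        inner = lung_mesh_small.domain == 0
        inside = np.median(g_el[inner & (r < 0.015)])
        outside = np.median(g_el[inner & (r > 0.035)])
        assert inside >= 2.0 * outside

    def test_convex_combination_bounds(self, lung_mesh_small):
        rng = np.random.default_rng(5)
        maps = rng.lognormal(8, 0.4, (5, 32, 32))
        valid = rng.random((5, 32, 32)) > 0.1
        maps_masked = np.where(valid, maps, np.nan)
        model = geo.interpolate_stiffness(lung_mesh_small, maps_masked,
                                          np.arange(5) * 0.01, 0.4 / 32,
                                          valid=valid)
        inner_nodes = np.unique(
            lung_mesh_small.elements[lung_mesh_small.domain == 0])
        assert model.nodal_G[inner_nodes].min() >= maps[valid].min() - 1e-9
        assert model.nodal_G[inner_nodes].max() <= maps[valid].max() + 1e-9


class TestBallMesh:
    def test_volume(self, ball_mesh):
        v_true = 4 / 3 * np.pi * 0.05 ** 3
        assert abs(ball_mesh.volume() - v_true) / v_true < 0.05

    def test_positive_volumes(self, ball_mesh):
        assert ball_mesh.element_volumes().min() > 0
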