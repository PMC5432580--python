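import numpy as np
import pytest
import scipy.ndimage as ndi

import headgeo as hg
from headgeo.electrode_detection import (DetectionError, closest_point_on_mesh,
                                         rasterize_view)


def _disc_image(shape, centers, radius):
    img = np.zeros(shape, dtype=np.uint8)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    for cx, cy in centers:
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2] = 1
    return img


class TestBinarize:
    def test_bright_disc_component_count(self, rng):
        tex = np.full((200, 400, 3), 30, dtype=np.uint8)
        centers = [(40 * i + 20, 100) for i in range(10)]
        for cx, cy in centers:
            yy, xx = np.mgrid[:200, :400]
            tex[(xx - cx) ** 2 + (yy - cy) ** 2 <= 8 ** 2] = 220
        binary = hg.binarize_texture(tex)
        _, n = ndi.label(binary)
        assert n == 10
        assert set(np.unique(binary)) <= {0, 1}

    def test_constant_texture_errors(self):
        with pytest.raises(DetectionError, match="contrast"):
            hg.binarize_texture(np.zeros((10, 10, 3), dtype=np.uint8))

    def test_polarity_swap_on_inversion(self):
        tex = np.full((50, 50, 3), 30, dtype=np.uint8)
        tex[10:20, 10:20] = 220
        fg = hg.binarize_texture(tex, polarity="bright")
        fg_inv = hg.binarize_texture(255 - tex, polarity="dark")
        assert np.array_equal(fg, fg_inv)


class TestRendering:
    def _view(self, direction, up, mesh):
        center = mesh.vertices.mean(axis=0)
        return hg.ViewProjection(direction, up, 0.5, (420, 420), center)

    def test_disc_visible_face_on(self, sphere_with_disc):
        mesh, gt = sphere_with_disc
        binary = hg.binarize_texture(mesh.texture)
        view = self._view([0, 0, -1], [0, 1, 0], mesh)
        render = hg.render_binary_views(mesh, binary, [view])[0]
        assert render.image.sum() > 100
        ys, xs = np.nonzero(render.image)
        # blob centered at the raster position of the disc center
        proj = view.project(gt.points)[0]
        assert abs(xs.mean() - proj[0]) < 2.0
        assert abs(ys.mean() - proj[1]) < 2.0

    def test_disc_occluded_from_below(self, sphere_with_disc):
        mesh, _ = sphere_with_disc
        binary = hg.binarize_texture(mesh.texture)
        view = self._view([0, 0, 1], [0, 1, 0], mesh)
        render = hg.render_binary_views(mesh, binary, [view])[0]
        assert render.image.sum() == 0

    def test_foreshortened_disc_elongated(self, sphere_with_disc):
        mesh, _ = sphere_with_disc
        binary = hg.binarize_texture(mesh.texture)
        # view 80 deg off the disc normal: projected ellipse with minor axis
        # compressed by cos(80 deg)
        ang = np.deg2rad(80.0)
        d = -np.array([0.0, np.sin(ang), np.cos(ang)])
        up = np.array([0.0, np.cos(ang), -np.sin(ang)])
        render = hg.render_binary_views(mesh, binary,
                                        [self._view(d, up, mesh)])[0]
        ys, xs = np.nonzero(render.image)
        assert len(xs) > 10
        ecc = (xs.max() - xs.min() + 1) / (ys.max() - ys.min() + 1)
        assert ecc > 1.5

    def test_degenerate_view_rejected(self):
        with pytest.raises(ValueError):
            hg.ViewProjection([0, 0, -1], [0, 1, 0], 0.0, (64, 64))
        with pytest.raises(ValueError, match="orthogonal"):
            hg.ViewProjection([0, 0, -1], [0, 0.5, -0.5], 0.5, (64, 64))


class TestDetectCircles:
    def test_blank_image_empty(self):
        assert hg.detect_circles(np.zeros((80, 80), np.uint8), 5, 15) == []

    def test_single_disc_center_and_radius(self):
        img = _disc_image((120, 120), [(50, 60)], 10)
        dets = hg.detect_circles(img, 5, 15)
        assert len(dets) == 1
        (cx, cy), r = dets[0].center_px, dets[0].radius_px
        assert abs(cx - 50) <= 1 and abs(cy - 60) <= 1
        assert abs(r - 10) <= 1

    def test_two_discs(self):
        img = _disc_image((120, 160), [(40, 60), (80, 60)], 9)
        dets = hg.detect_circles(img, 5, 15)
        assert len(dets) == 2
        got = sorted(d.center_px[0] for d in dets)
        assert abs(got[0] - 40) <= 1 and abs(got[1] - 80) <= 1

    def test_translation_equivariance(self):
        img = _disc_image((140, 140), [(45, 55)], 8)
        shifted = np.roll(np.roll(img, 20, axis=0), 13, axis=1)
        d0 = hg.detect_circles(img, 5, 12)[0]
        d1 = hg.detect_circles(shifted, 5, 12)[0]
        assert d1.center_px[0] - d0.center_px[0] == pytest.approx(13, abs=0.5)
        assert d1.center_px[1] - d0.center_px[1] == pytest.approx(20, abs=0.5)
        assert d1.radius_px == d0.radius_px


class TestBackprojection:
    def test_face_on_disc_roundtrip(self, painted):
        mesh, gt = painted
        binary = hg.binarize_texture(mesh.texture)
        view = hg.default_views(mesh)[7]  # elevation 55, azimuth 144
        render = hg.render_binary_views(mesh, binary, [view])[0]
        dets = hg.detect_circles(render.image, 6, 12)
        pts = hg.backproject(dets, render, mesh)
        assert len(pts) > 5
        from scipy.spatial import cKDTree
        d, _ = cKDTree(gt.points).query(pts)
        assert np.median(d) < 2 * view.pixel_pitch

    def test_background_detection_dropped(self, painted):
        mesh, _ = painted
        binary = hg.binarize_texture(mesh.texture)
        view = hg.default_views(mesh)[0]
        render = hg.render_binary_views(mesh, binary, [view])[0]
        from headgeo.electrode_detection import CircleDetection

        fake = CircleDetection((1.0, 1.0), 5.0, 1.0)  # corner = background
        with pytest.warns(UserWarning, match="background"):
            pts = hg.backproject([fake], render, mesh)
        assert len(pts) == 0

    def test_all_electrodes_covered_by_some_view(self, detection):
        detected, gt = detection
        from scipy.spatial import cKDTree
        d, _ = cKDTree(detected.points).query(gt.points)
        assert (d < 2.0).mean() >= 0.95


class TestMerge:
    def test_close_points_merge_to_midpoint(self):
        out = hg.merge_candidates(np.array([[0, 0, 0], [1, 0, 0]]), 5.0)
        assert len(out) == 1
        assert np.allclose(out.points[0], [0.5, 0, 0])

    def test_distant_points_stay_separate(self):
        out = hg.merge_candidates(np.array([[0, 0, 0], [20, 0, 0]]), 5.0)
        assert len(out) == 2

    def test_chain_single_linkage(self):
        chain = np.array([[4.0 * i, 0, 0] for i in range(6)])  # 20 mm span
        out = hg.merge_candidates(chain, 5.0)
        assert len(out) == 1

    def test_order_invariance(self, rng):
        pts = rng.normal(0, 40, (60, 3))
        a = hg.merge_candidates(pts, 8.0)
        b = hg.merge_candidates(pts[rng.permutation(60)], 8.0)
        assert np.allclose(a.points, b.points)


class TestProjectToScalp:
    def test_point_on_face_unchanged(self, small_head):
        mesh = small_head.mesh
        tri = mesh.vertices[mesh.faces[10]]
        p = tri.mean(axis=0)
        out = hg.project_to_scalp(hg.ElectrodeSet([p]), mesh)
        assert np.linalg.norm(out.points[0] - p) < 1e-9

    def test_outside_sphere_moves_radially(self, ball_scalp):
        p = np.array([0.0, 0.0, 53.0])  # 3 mm outside r=50 sphere
        out = hg.project_to_scalp(hg.ElectrodeSet([p]), ball_scalp)
        assert np.linalg.norm(out.points[0]) == pytest.approx(50.0, abs=0.5)
        assert np.linalg.norm(out.points[0] - p) == pytest.approx(3.0, abs=0.5)

    def test_matches_brute_force(self, small_head, rng):
        from trimesh.triangles import closest_point as tri_closest

        mesh = small_head.mesh
        q = rng.normal(0, 70, (15, 3))
        fast = closest_point_on_mesh(mesh, q)
        tris = mesh.face_corner_points()
        for i, p in enumerate(q):
            cp = tri_closest(tris, np.tile(p, (len(tris), 1)))
            best = cp[np.argmin(np.linalg.norm(cp - p, axis=1))]
            assert np.linalg.norm(
                np.linalg.norm(fast[i] - p) - np.linalg.norm(best - p)) < 1e-9


@pytest.fixture(scope="module")
def ball_scalp():
    zz, yy, xx = np.mgrid[:120, :120, :120]
    ball = (((xx - 60) ** 2 + (yy - 60) ** 2 + (zz - 60) ** 2) <= 50 ** 2)
    vol = hg.Volume(ball.astype(float) * 100, np.eye(4))
    mesh = hg.scalp_mesh_from_volume(vol, threshold_frac=0.5)
    mesh.vertices = mesh.vertices - 60.0  # center at origin
    return mesh


class TestDetectElectrodes:
    def test_full_cap_detection_accuracy(self, detection):
        detected, gt = detection
        assert len(detected) == len(gt)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(gt.points).query(detected.points)
        assert d.mean() <= 1.3

    def test_untextured_mesh_errors(self, head):
        with pytest.raises(DetectionError, match="texture"):
            hg.detect_electrodes(head.mesh)

    def test_single_electrode(self, small_head):
        eset = hg.ElectrodeSet(np.array([[0.0, 0.0, 100.0]]))
        mesh, _ = hg.paint_electrodes(small_head, eset)
        out = hg.detect_electrodes(mesh)
        assert len(out) == 1

    def test_correction_hook_applied(self, painted):
        mesh, _ = painted
        calls = []

        def hook(es):
            calls.append(len(es))
            return es.subset(range(10))

        out = hg.detect_electrodes(mesh, correction_hook=hook)
        assert calls and len(out) == 10
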