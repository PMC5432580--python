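import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import headgeo as hg
from headgeo.registration import (DegenerateGeometryError, FacialSegment,
                                  _rot_axis, coarse_align)


def _random_cloud(rng, n=40, scale=50.0):
    return rng.normal(0.0, scale, size=(n, 3))


class TestCentroid:
    def test_two_points(self):
        assert np.allclose(hg.centroid([(0, 0, 0), (2, 0, 0)]), (1, 0, 0))

    def test_single_point_identity(self):
        p = np.array([3.0, -1.0, 7.0])
        assert np.allclose(hg.centroid([p]), p)

    def test_matches_summation_oracle(self, rng):
        pts = _random_cloud(rng, 100)
        # independent oracle: explicit per-axis summation
        oracle = np.array([sum(p[k] for p in pts) / len(pts) for k in range(3)])
        assert np.abs(hg.centroid(pts) - oracle).max() < 1e-12

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            hg.centroid(np.zeros((0, 3)))


class TestScalingFactor:
    def test_identical_segments(self, rng):
        seg = FacialSegment(_random_cloud(rng))
        assert hg.scaling_factor(seg, seg) == pytest.approx(1.0)

    def test_scaled_segment_forced_value(self, rng):
        pts = _random_cloud(rng)
        assert hg.scaling_factor(FacialSegment(pts), FacialSegment(pts * 4)) \
            == pytest.approx(0.25)

    def test_formula_oracle(self, rng):
        a, b = rng.normal(0, 30, (5, 3)), rng.normal(0, 10, (5, 3))
        # independent evaluation of the mean-centroid-distance ratio
        num = np.mean([np.sqrt(((p - a.mean(0)) ** 2).sum()) for p in a])
        den = np.mean([np.sqrt(((p - b.mean(0)) ** 2).sum()) for p in b])
        got = hg.scaling_factor(FacialSegment(a), FacialSegment(b))
        assert got == pytest.approx(num / den, abs=1e-12)

    def test_reciprocity(self, rng):
        a = FacialSegment(_random_cloud(rng))
        b = FacialSegment(_random_cloud(rng, scale=17.0))
        assert hg.scaling_factor(a, b) * hg.scaling_factor(b, a) \
            == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_to_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        a = FacialSegment(_random_cloud(rng))
        b = FacialSegment(_random_cloud(rng, scale=20.0))
        T = hg.random_similarity(rng, with_scale=False)
        moved = FacialSegment(T.apply(b.points))
        assert hg.scaling_factor(a, moved) == pytest.approx(
            hg.scaling_factor(a, b), rel=1e-9)

    def test_degenerate_segment_errors(self):
        same = FacialSegment(np.zeros((5, 3)))
        other = FacialSegment(np.eye(3))
        with pytest.raises(DegenerateGeometryError):
            hg.scaling_factor(other, same)


class TestTransformAlgebra:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_compose_with_inverse_is_identity(self, seed):
        T = hg.random_similarity(np.random.default_rng(seed))
        M = T.compose(T.inverse()).matrix
        assert np.abs(M - np.eye(4)).max() < 1e-9

    def test_affine_inverse(self, rng):
        A = hg.AffineTransform(np.eye(3) + 0.1 * rng.normal(size=(3, 3)),
                               rng.normal(size=3))
        M = A.compose(A.inverse()).matrix
        assert np.abs(M - np.eye(4)).max() < 1e-9

    def test_compose_matches_matrix_product(self, rng):
        T1 = hg.random_similarity(rng)
        T2 = hg.random_similarity(rng)
        assert np.allclose(T1.compose(T2).matrix, T1.matrix @ T2.matrix)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="reflect|proper"):
            hg.SimilarityTransform(np.diag([1.0, 1.0, -1.0]))

    def test_save_load_round_trip(self, tmp_path, rng):
        T = hg.random_similarity(rng)
        hg.save_transform(T, tmp_path / "t.json")
        back = hg.load_transform(tmp_path / "t.json")
        assert np.abs(back.matrix - T.matrix).max() < 1e-9


class TestBestFitRigid:
    def test_identity(self, rng):
        pts = _random_cloud(rng)
        T = hg.best_fit_rigid(pts, pts)
        assert np.abs(T.matrix - np.eye(4)).max() < 1e-9

    def test_90_degree_z_rotation(self):
        src = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=float)
        R90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        T = hg.best_fit_rigid(src, src @ R90.T)
        assert np.abs(T.rotation - R90).max() < 1e-9

    def test_recovers_random_similarity(self, rng):
        src = _random_cloud(rng)
        T = hg.random_similarity(rng)
        got = hg.best_fit_rigid(src, T.apply(src), allow_scale=True)
        assert np.abs(got.matrix - T.matrix).max() < 1e-9

    def test_beats_random_search_oracle(self, rng):
        src = _random_cloud(rng, 12)
        tgt = T_true = hg.random_similarity(rng, with_scale=False).apply(src)
        tgt = tgt + rng.normal(0, 2.0, tgt.shape)
        best = hg.best_fit_rigid(src, tgt)
        res_best = ((best.apply(src) - tgt) ** 2).sum()
        # oracle: 1000 random rigid candidates must not do better
        for k in range(1000):
            cand = hg.random_similarity(np.random.default_rng(k), with_scale=False)
            cand = hg.SimilarityTransform(cand.rotation,
                                          tgt.mean(0) - cand.rotation @ src.mean(0))
            assert ((cand.apply(src) - tgt) ** 2).sum() >= res_best - 1e-9

    def test_collinear_errors(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            hg.best_fit_rigid(line, line)


class TestICP:
    def test_identity_on_identical_sets(self, rng):
        pts = _random_cloud(rng, 200)
        res = hg.icp(pts, pts)
        assert res.converged
        assert np.abs(res.transform.matrix - np.eye(4)).max() < 1e-9

    def test_recovers_known_transform(self, head):
        # 10 deg rotation + 5 mm shift of the facial patch; the coarse
        # principal-axis init puts ICP in the right basin
        seg = head.mesh.vertices[head.facial_idx]
        R = _rot_axis(np.deg2rad(10.0), 2)
        moved = seg @ R.T + np.array([5.0, 0.0, 0.0])
        res = hg.icp(moved, seg, init=coarse_align(moved, seg))
        d = res.transform.apply(moved) - seg
        assert np.sqrt((d ** 2).sum(axis=1)).mean() < 1e-3

    def test_trimming_rejects_outliers(self, rng):
        pts = _random_cloud(rng, 200, scale=30.0)
        outliers = rng.normal(0, 30, (50, 3)) + 200.0
        src = np.vstack([pts, outliers])
        res = hg.icp(src, pts, trim_frac=0.25)
        inlier_d = np.linalg.norm(res.transform.apply(pts) - pts, axis=1)
        assert inlier_d.mean() < 0.1

    def test_objective_monotone_nonincreasing(self, rng):
        # track the trajectory by re-running with increasing max_iter
        src = _random_cloud(rng, 150)
        T = hg.random_similarity(rng, with_scale=False)
        tgt = T.apply(src)
        prev = np.inf
        for it in range(1, 12):
            res = hg.icp(src, tgt, max_iter=it, tol=0.0)
            assert res.rms <= prev + 1e-9
            prev = res.rms

    def test_matches_best_fit_when_nn_correct(self, rng):
        pts = _random_cloud(rng, 100)
        tgt = pts + rng.normal(0, 0.01, pts.shape)  # NN correspondence = identity map
        one = hg.icp(pts, tgt, max_iter=1, tol=0.0).transform
        direct = hg.best_fit_rigid(pts, tgt)
        assert np.abs(one.matrix - direct.matrix).max() < 1e-9


class TestCoregistration:
    def test_shifted_copy_recovers_exactly(self, head, layout):
        seg = head.mesh.vertices[head.facial_idx]
        T = hg.SimilarityTransform(np.eye(3), [40.0, -25.0, 60.0], 1.0)
        back = hg.coregister_model_to_mri(head.mesh,
                                          FacialSegment(T.apply(seg)),
                                          FacialSegment(seg))
        rec = back.apply(T.apply(layout.points))
        assert np.linalg.norm(rec - layout.points, axis=1).max() < 1e-3

    def test_random_similarity_recovery(self, head, layout, rng):
        seg = head.mesh.vertices[head.facial_idx]
        errs = []
        for _ in range(5):
            T = hg.random_similarity(rng)
            back = hg.coregister_model_to_mri(head.mesh,
                                              FacialSegment(T.apply(seg)),
                                              FacialSegment(seg))
            rec = back.apply(T.apply(layout.points))
            errs.append(np.linalg.norm(rec - layout.points, axis=1).mean())
        assert np.mean(errs) < 0.01

    def test_disjoint_segments_large_residual(self, head):
        v = head.mesh.vertices
        az = np.rad2deg(np.arctan2(v[:, 0], v[:, 1]))
        nose = head.facial_idx
        back_idx = np.nonzero(np.abs(az) > 130)[0][:len(nose)]
        _, info = hg.coregister_model_to_mri(
            head.mesh, FacialSegment(v[back_idx]), FacialSegment(v[nose]),
            full_output=True)
        assert isinstance(info.converged, bool)  # flag reported either way
        assert info.rms > 1.0

    def test_coarse_align_recovers_axes(self, head):
        seg = head.mesh.vertices[head.facial_idx]
        T = hg.random_similarity(np.random.default_rng(7), with_scale=False)
        init = coarse_align(T.apply(seg), seg)
        d = np.linalg.norm(init.apply(T.apply(seg)) - seg, axis=1)
        assert d.mean() < 5.0  # good enough to seed ICP


class TestFiducialTransform:
    FIDS = {"nasion": np.array([0.0, 95.0, 10.0]),
            "LPA": np.array([-80.0, 0.0, -5.0]),
            "RPA": np.array([82.0, 1.0, -4.0])}

    def test_identity(self):
        T = hg.fiducial_transform(self.FIDS, self.FIDS)
        assert np.abs(T.matrix - np.eye(4)).max() < 1e-9

    def test_recovers_known_rigid_transform(self, rng):
        T_true = hg.random_similarity(rng, with_scale=False)
        moved = {k: T_true.apply(v.reshape(1, 3))[0] for k, v in self.FIDS.items()}
        got = hg.fiducial_transform(self.FIDS, moved)
        assert np.abs(got.matrix - T_true.matrix).max() < 1e-9

    def test_collinear_fiducials_error(self):
        bad = dict(self.FIDS)
        bad["nasion"] = (bad["LPA"] + bad["RPA"]) / 2.0
        with pytest.raises(DegenerateGeometryError):
            hg.fiducial_transform(bad, bad)


class TestRandomSimilarity:
    def test_deterministic_per_seed(self):
        a, b = hg.random_similarity(99), hg.random_similarity(99)
        assert np.allclose(a.matrix, b.matrix)

    def test_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            T = hg.random_similarity(rng)
            assert 1.0 <= T.scale <= 5.0
            assert np.all(T.translation >= 1.0) and np.all(T.translation <= 100.0)
            # rotation part orthonormal, det +1
            assert np.allclose(T.rotation @ T.rotation.T, np.eye(3), atol=1e-9)

    def test_mean_scale_law_of_large_numbers(self):
        rng = np.random.default_rng(1)
        scales = np.array([hg.random_similarity(rng).scale for _ in range(100_000)])
        assert scales.mean() == pytest.approx(3.0, abs=0.02)
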