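"""Coregistration of photogrammetric head models to MRI space.

The photogrammetric reconstruction lives in an arbitrary similarity frame
(unknown rotation, translation and global scale).  Coregistration proceeds in
two steps, using only rigid facial regions (forehead, eyebrows, cheekbones,
nose bone) selected on both the model and the MRI scalp surface:

1. an isotropic scaling factor, the ratio of the mean distances of each
   segment's points to its own centroid::

       s = [sum_i ||v_i_mri - C_mri|| / N_mri] / [sum_i ||v_i_model - C_model|| / N_model]

2. rigid ICP between the scaled model segment and the MRI segment, preceded
   by an automatic coarse initialization (principal-axis alignment over the
   four proper sign combinations).

A fiducial-based alternative (nasion / left and right preauricular points),
the standard approach of electromagnetic digitizers, is provided for the
comparative evaluation, together with the random similarity perturbations
used to measure coregistration error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree

from .geometry_io import ElectrodeSet, TexturedMesh


class DegenerateGeometryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Transform types
# ---------------------------------------------------------------------------

@dataclass
class SimilarityTransform:
    """x -> scale * R @ x + t with R proper orthonormal, scale > 0."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.scale = float(self.scale)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        R = self.rotation
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1); reflections rejected")

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.scale * self.rotation
        M[:3, 3] = self.translation
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "SimilarityTransform":
        M = np.asarray(M, dtype=np.float64)
        A = M[:3, :3]
        s = np.linalg.det(A) ** (1.0 / 3.0)
        return cls(A / s, M[:3, 3], s)

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return self.scale * pts @ self.rotation.T + self.translation

    def apply_to_mesh(self, mesh: TexturedMesh, frame_id: Optional[str] = None) -> TexturedMesh:
        out = mesh.copy()
        out.vertices = self.apply(mesh.vertices)
        if frame_id is not None:
            out.frame_id = frame_id
        return out

    def apply_to_electrodes(self, eset: ElectrodeSet,
                            frame_id: Optional[str] = None) -> ElectrodeSet:
        out = eset.copy()
        out.points = self.apply(eset.points)
        if frame_id is not None:
            out.frame_id = frame_id
        return out

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return T such that T(x) = self(other(x))."""
        R = self.rotation @ other.rotation
        s = self.scale * other.scale
        t = self.scale * self.rotation @ other.translation + self.translation
        return SimilarityTransform(R, t, s)

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(Rinv, -Rinv @ self.translation / self.scale,
                                   1.0 / self.scale)


@dataclass
class AffineTransform:
    """x -> A @ x + t with A invertible (positive determinant enforced)."""

    linear: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if np.linalg.det(self.linear) <= 1e-12:
            raise ValueError("affine linear part must have positive determinant")

    @property
    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.linear
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.linear.T + self.translation

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform(self.linear @ other.linear,
                               self.linear @ other.translation + self.translation)

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.linear)
        return AffineTransform(Ainv, -Ainv @ self.translation)


Transform = Union[SimilarityTransform, AffineTransform]


def save_transform(t: Transform, path) -> None:
    import json
    from pathlib import Path

    kind = "similarity" if isinstance(t, SimilarityTransform) else "affine"
    Path(path).write_text(json.dumps({"kind": kind, "matrix": t.matrix.tolist()},
                                     indent=1))


def load_transform(path) -> Transform:
    import json

    with open(path) as fh:
        d = json.load(fh)
    M = np.asarray(d["matrix"])
    if d.get("kind", "similarity") == "affine":
        return AffineTransform(M[:3, :3], M[:3, 3])
    return SimilarityTransform.from_matrix(M)


@dataclass
class FacialSegment:
    """Subset of mesh vertices over a rigid facial region."""

    points: np.ndarray
    source_frame: str = "model"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if len(self.points) == 0:
            raise ValueError("facial segment is empty")

    @classmethod
    def from_mesh(cls, mesh: TexturedMesh, vertex_idx: Sequence[int]) -> "FacialSegment":
        idx = np.asarray(vertex_idx, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= len(mesh.vertices)):
            raise ValueError("segment index out of range for mesh")
        return cls(mesh.vertices[idx], source_frame=mesh.frame_id)


# ---------------------------------------------------------------------------
# Scaling factor
# ---------------------------------------------------------------------------

def centroid(points: np.ndarray) -> np.ndarray:
    """Per-axis arithmetic mean of a non-empty point list."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.size == 0:
        raise ValueError("centroid of empty point list")
    return pts.mean(axis=0)


def _mean_spread(points: np.ndarray) -> float:
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    return float(np.linalg.norm(pts - centroid(pts), axis=1).mean())


def scaling_factor(mri_seg: FacialSegment, model_seg: FacialSegment) -> float:
    """Isotropic model-to-MRI scale from mean centroid distances.

    Multiplying the model coordinates by the returned factor brings it to
    MRI metric scale.
    """
    if len(mri_seg.points) < 2 or len(model_seg.points) < 2:
        raise ValueError("segments need at least 2 points")
    num = _mean_spread(mri_seg.points)
    den = _mean_spread(model_seg.points)
    if den < 1e-12:
        raise DegenerateGeometryError("model segment has zero spread")
    if num < 1e-12:
        raise DegenerateGeometryError("MRI segment has zero spread")
    return num / den


# ---------------------------------------------------------------------------
# Closed-form fits for known correspondences
# ---------------------------------------------------------------------------

def best_fit_rigid(source: np.ndarray, target: np.ndarray,
                   allow_scale: bool = False) -> SimilarityTransform:
    """Least-squares rigid (or similarity) fit for paired points.

    Minimizes sum ||T(s_i) - t_i||^2 over proper rotations (Kabsch/Umeyama,
    SVD solution); reflections are rejected by construction.
    """
    src = np.atleast_2d(np.asarray(source, dtype=np.float64))
    tgt = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if src.shape != tgt.shape or len(src) < 3:
        raise ValueError("need equal-length point lists with >= 3 points")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    ds, dt = src - mu_s, tgt - mu_t
    H = ds.T @ dt / len(src)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise DegenerateGeometryError("collinear points: rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scale:
        var_s = (ds ** 2).sum() / len(src)
        s = float(np.trace(np.diag(S) @ D) / var_s)
    else:
        s = 1.0
    t = mu_t - s * R @ mu_s
    return SimilarityTransform(R, t, s)


def best_fit_affine(source: np.ndarray, target: np.ndarray) -> AffineTransform:
    """Least-squares 12-parameter affine fit for paired points."""
    src = np.atleast_2d(np.asarray(source, dtype=np.float64))
    tgt = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if src.shape != tgt.shape or len(src) < 4:
        raise ValueError("need equal-length point lists with >= 4 points")
    X = np.hstack([src, np.ones((len(src), 1))])
    coef, *_ = np.linalg.lstsq(X, tgt, rcond=None)
    A, t = coef[:3].T, coef[3]
    if np.linalg.det(A) <= 1e-6:
        # mirror or collapsed solutions are anatomically invalid; fall back
        # to the similarity fit
        sim = best_fit_rigid(src, tgt, allow_scale=True)
        if sim.scale <= 1e-2:
            raise DegenerateGeometryError("affine fit collapsed")
        return AffineTransform(sim.scale * sim.rotation, sim.translation)
    return AffineTransform(A, t)


# ---------------------------------------------------------------------------
# ICP
# ---------------------------------------------------------------------------

@dataclass
class ICPResult:
    transform: Transform
    rms: float
    n_iter: int
    converged: bool


def icp(source: np.ndarray, target, mode: str = "rigid",
        init: Optional[Transform] = None, max_iter: int = 100,
        tol: float = 1e-6, trim_frac: float = 0.0) -> ICPResult:
    """Iterative closest point alignment of ``source`` onto ``target``.

    Alternates nearest-neighbor correspondence (KD-tree) with the
    closed-form least-squares fit; stops when the RMS distance changes by
    less than ``tol`` mm.  ``trim_frac`` drops the worst fraction of
    correspondences each iteration, a headless stand-in for the interactive
    removal of mismatching mesh parts.

    Returns an :class:`ICPResult`; ``converged`` is False when ``max_iter``
    was exhausted.
    """
    src = np.atleast_2d(np.asarray(source, dtype=np.float64))
    if isinstance(target, TexturedMesh):
        tgt = target.vertices
    else:
        tgt = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if len(src) < 3:
        raise ValueError("source needs >= 3 points")
    if mode not in ("rigid", "affine"):
        raise ValueError("mode must be 'rigid' or 'affine'")
    if not 0.0 <= trim_frac < 1.0:
        raise ValueError("trim_frac must be in [0, 1)")
    if init is None:
        init = SimilarityTransform.identity()
    tree = cKDTree(tgt)
    current: Transform = init
    moved = current.apply(src)
    dists, nn = tree.query(moved)
    prev_rms = float(np.sqrt((dists ** 2).mean()))
    rms = prev_rms
    converged = False
    n_done = 0
    for it in range(1, max_iter + 1):
        n_done = it
        if trim_frac > 0.0:
            keep = max(3, int(np.ceil((1.0 - trim_frac) * len(src))))
            order = np.argsort(dists)[:keep]
        else:
            order = slice(None)
        corr_src, corr_tgt = src[order], tgt[nn[order]]
        try:
            if mode == "rigid":
                current = best_fit_rigid(corr_src, corr_tgt)
            else:
                current = best_fit_affine(corr_src, corr_tgt)
        except DegenerateGeometryError:
            # correspondences collapsed onto a degenerate configuration:
            # keep the last valid transform
            break
        moved = current.apply(src)
        dists, nn = tree.query(moved)
        if trim_frac > 0.0:
            keep_d = np.sort(dists)[:max(3, int(np.ceil((1.0 - trim_frac) * len(src))))]
            rms = float(np.sqrt((keep_d ** 2).mean()))
        else:
            rms = float(np.sqrt((dists ** 2).mean()))
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms
    return ICPResult(current, rms, n_done, converged)


# ---------------------------------------------------------------------------
# Coarse initialization and full model-to-MRI coregistration
# ---------------------------------------------------------------------------

_SIGN_COMBOS = [np.diag(d) for d in
                ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1])]


def _principal_axes(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    cov = c.T @ c / len(points)
    w, V = np.linalg.eigh(cov)
    V = V[:, ::-1]  # descending variance
    if np.linalg.det(V) < 0:
        V[:, 2] *= -1
    return V


def coarse_align(source: np.ndarray, target: np.ndarray) -> SimilarityTransform:
    """Principal-axis alignment; the best of the 4 proper sign combinations.

    Replaces the interactive pre-orientation step: both segments are
    centered, their principal axes aligned, and of the four rotations that
    keep handedness, the one with the lowest nearest-neighbor RMS wins.
    """
    src = np.atleast_2d(np.asarray(source, dtype=np.float64))
    tgt = np.atleast_2d(np.asarray(target, dtype=np.float64))
    Vs, Vt = _principal_axes(src), _principal_axes(tgt)
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    tree = cKDTree(tgt)
    best = None
    for D in _SIGN_COMBOS:
        R = Vt @ D @ Vs.T
        t = mu_t - R @ mu_s
        cand = SimilarityTransform(R, t, 1.0)
        d, _ = tree.query(cand.apply(src))
        rms = float(np.sqrt((d ** 2).mean()))
        if best is None or rms < best[0]:
            best = (rms, cand)
    return best[1]


def coregister_model_to_mri(model: TexturedMesh, model_seg: FacialSegment,
                            mri_seg: FacialSegment,
                            icp_params: Optional[dict] = None,
                            full_output: bool = False):
    """Similarity transform taking the whole model into the MRI frame.

    Computes the centroid-spread scaling factor from the facial segments,
    coarse-aligns the scaled model segment to the MRI segment by principal
    axes, refines with rigid ICP, and composes scale -> rigid into a single
    :class:`SimilarityTransform` to be applied to the full model (mesh and
    electrode positions alike).
    """
    icp_params = dict(icp_params or {})
    s = scaling_factor(mri_seg, model_seg)
    scaled = model_seg.points * s
    init = coarse_align(scaled, mri_seg.points)
    res = icp(scaled, mri_seg.points, mode="rigid", init=init, **icp_params)
    rigid = res.transform
    total = rigid.compose(SimilarityTransform(scale=s))
    if full_output:
        return total, res
    return total


# ---------------------------------------------------------------------------
# Fiducial-based alignment (digitizer baseline)
# ---------------------------------------------------------------------------

_FID_LABELS = ("nasion", "LPA", "RPA")


def _canonical_frame(fids: dict) -> SimilarityTransform:
    """World -> canonical head frame from nasion/LPA/RPA.

    Origin at the preauricular midpoint, x toward RPA, y toward the nasion
    within the fiducial plane, z = x cross y.
    """
    nas = np.asarray(fids["nasion"], dtype=np.float64)
    lpa = np.asarray(fids["LPA"], dtype=np.float64)
    rpa = np.asarray(fids["RPA"], dtype=np.float64)
    origin = (lpa + rpa) / 2.0
    x = rpa - origin
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateGeometryError("LPA and RPA coincide")
    x = x / nx
    y = nas - origin
    y = y - (y @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise DegenerateGeometryError("nasion collinear with LPA-RPA axis")
    y = y / ny
    z = np.cross(x, y)
    R = np.stack([x, y, z])  # rows: world->canonical
    return SimilarityTransform(R, -R @ origin, 1.0)


def fiducial_transform(src_fids: dict, dst_fids: dict) -> SimilarityTransform:
    """Rigid transform mapping src-frame points into the dst frame via the
    canonical nasion/LPA/RPA head coordinate system.  Exact on noiseless
    fiducials."""
    for d in (src_fids, dst_fids):
        missing = [k for k in _FID_LABELS if k not in d]
        if missing:
            raise ValueError(f"missing fiducials: {missing}")
    to_canon_src = _canonical_frame(src_fids)
    to_canon_dst = _canonical_frame(dst_fids)
    return to_canon_dst.inverse().compose(to_canon_src)


# ---------------------------------------------------------------------------
# Random similarity perturbations (coregistration-error simulation)
# ---------------------------------------------------------------------------

def _rot_axis(angle_rad: float, axis: int) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s if axis != 1 else s
    R[j, i] = s if axis != 1 else -s
    return R


def random_similarity(rng, with_scale: bool = True) -> SimilarityTransform:
    """Random perturbation in the evaluation ranges: per-axis rotations
    uniform in [1, 360] degrees, per-axis translations uniform in [1, 100] mm,
    isotropic scale uniform in [1, 5] (identity scale when ``with_scale`` is
    False, for rigid-only digitizer perturbations).

    ``rng`` is an integer seed or a ``numpy.random.Generator``.  Rotation
    composition order is R = Rz @ Ry @ Rx.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ang = np.deg2rad(rng.uniform(1.0, 360.0, size=3))
    R = _rot_axis(ang[2], 2) @ _rot_axis(ang[1], 1) @ _rot_axis(ang[0], 0)
    t = rng.uniform(1.0, 100.0, size=3)
    s = float(rng.uniform(1.0, 5.0)) if with_scale else 1.0
    return SimilarityTransform(R, t, s)
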