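"""Texture-based electrode detection on textured head meshes.

Electrodes appear as high-contrast circular patches in the mesh texture.
Detection binarizes the texture, renders the binarized mesh orthographically
from several viewpoints (10 by default) with a z-buffer, finds circles in
each rendered view with a circular Hough transform, back-projects the circle
centers to the 3-D surface through the render's face/barycentric lookup, and
merges the multi-view candidates by single-linkage clustering.  Multiple
views compensate for electrodes that appear elliptical near the occluding
boundary of the head.  Raw positions can finally be projected orthogonally
onto the MRI scalp surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.filters import threshold_otsu
from skimage.transform import hough_circle, hough_circle_peaks

from .geometry_io import ElectrodeSet, TexturedMesh


class DetectionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Views
# ---------------------------------------------------------------------------

@dataclass
class ViewProjection:
    """Orthographic camera: ``direction`` is the viewing direction (into the
    scene), ``up`` the image-up vector (orthogonal to direction), ``origin``
    the 3-D point mapped to the raster center, ``pixel_pitch`` in mm/pixel
    and ``raster_size`` as (width, height)."""

    direction: np.ndarray
    up: np.ndarray
    pixel_pitch: float
    raster_size: tuple
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=np.float64)
        self.up = np.asarray(self.up, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        nd, nu = np.linalg.norm(self.direction), np.linalg.norm(self.up)
        if nd < 1e-12 or nu < 1e-12:
            raise ValueError("direction/up must be non-zero")
        self.direction = self.direction / nd
        self.up = self.up / nu
        if abs(self.direction @ self.up) > 1e-8:
            raise ValueError("up must be orthogonal to direction")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        self.raster_size = (int(self.raster_size[0]), int(self.raster_size[1]))

    @property
    def right(self) -> np.ndarray:
        return np.cross(self.direction, self.up)

    def project(self, points: np.ndarray) -> np.ndarray:
        """(N, 3) world points -> (N, 3) of (col, row, depth)."""
        p = np.atleast_2d(points) - self.origin
        w, h = self.raster_size
        col = p @ self.right / self.pixel_pitch + (w - 1) / 2.0
        row = -(p @ self.up) / self.pixel_pitch + (h - 1) / 2.0
        depth = p @ self.direction
        return np.stack([col, row, depth], axis=1)


def default_views(mesh: TexturedMesh,
                  azimuths_deg: Sequence[float] = (0, 72, 144, 216, 288),
                  elevations_deg: Sequence[float] = (20, 55),
                  pixel_pitch: float = 0.5) -> list:
    """The default 10 perspectives: 5 azimuths at 2 elevations above the
    horizontal plane of the head's vertical (+z) axis, chosen to cover the
    cap area with overlap."""
    center = mesh.vertices.mean(axis=0)
    rad = float(np.linalg.norm(mesh.vertices - center, axis=1).max())
    npx = int(np.ceil(2.2 * rad / pixel_pitch))
    views = []
    z = np.array([0.0, 0.0, 1.0])
    for el in elevations_deg:
        for az in azimuths_deg:
            a, e = np.deg2rad(az), np.deg2rad(el)
            outward = np.array([np.sin(a) * np.cos(e),
                                np.cos(a) * np.cos(e),
                                np.sin(e)])
            d = -outward
            up = z - (z @ d) * d
            up /= np.linalg.norm(up)
            views.append(ViewProjection(d, up, pixel_pitch, (npx, npx), center))
    return views


# ---------------------------------------------------------------------------
# Texture binarization
# ---------------------------------------------------------------------------

def binarize_texture(texture: np.ndarray, threshold: Optional[float] = None,
                     polarity: str = "bright") -> np.ndarray:
    """Binarize a color texture to separate electrodes from the cap.

    Converts to grayscale and applies a global threshold; when ``threshold``
    is None it is chosen to maximize the between-class variance (Otsu's
    criterion).  ``polarity`` selects which side is foreground: 'bright',
    'dark', or 'minority' (the smaller class).  Output values are {0, 1}.
    """
    tex = np.asarray(texture, dtype=np.float64)
    if tex.ndim == 3:
        gray = tex[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    else:
        gray = tex
    if gray.max() - gray.min() < 1e-9:
        raise DetectionError("texture has no contrast (constant intensity)")
    thr = float(threshold) if threshold is not None else float(threshold_otsu(gray))
    fg = gray > thr
    if polarity == "dark":
        fg = ~fg
    elif polarity == "minority":
        if fg.sum() > fg.size / 2:
            fg = ~fg
    elif polarity != "bright":
        raise ValueError("polarity must be 'bright', 'dark' or 'minority'")
    return fg.astype(np.uint8)


# ---------------------------------------------------------------------------
# Orthographic rasterization with reverse lookup
# ---------------------------------------------------------------------------

@dataclass
class RenderedView:
    """Binary render plus the per-pixel reverse lookup for back-projection."""

    image: np.ndarray        # (H, W) uint8 in {0, 1}
    face_index: np.ndarray   # (H, W) int32, -1 on background
    bary: np.ndarray         # (H, W, 3) float32 barycentric coords
    view: ViewProjection
    view_index: int = 0


def _sample_binary_texture(mesh: TexturedMesh, binary_tex: np.ndarray,
                           face_idx: np.ndarray, bary: np.ndarray) -> np.ndarray:
    """Texture value at surface points given by face + barycentric coords.

    UV wraps in both axes (seam faces carry U outside [0, 1]); V is measured
    from the bottom of the texture image, so image row 0 is V = 1.
    """
    uvc = mesh.uv[face_idx]                       # (K, 3, 2)
    uv = np.einsum("kc,kcd->kd", bary, uvc)       # (K, 2)
    th, tw = binary_tex.shape[:2]
    u = np.mod(uv[:, 0], 1.0)
    v = np.mod(uv[:, 1], 1.0)
    col = np.clip((u * tw).astype(np.int64), 0, tw - 1)
    row = np.clip(((1.0 - v) * th).astype(np.int64), 0, th - 1)
    return binary_tex[row, col]


def rasterize_view(mesh: TexturedMesh, view: ViewProjection,
                   values: Optional[np.ndarray] = None,
                   view_index: int = 0) -> RenderedView:
    """Depth-buffered orthographic rasterization of a triangular mesh.

    Every covered pixel records the front-most face and its barycentric
    coordinates; ``values`` (a binary texture) is sampled through the mesh UV
    map to produce the binary image.  Implemented as vectorized fragment
    generation over triangle bounding boxes with a lexsort z-buffer.
    """
    w, h = view.raster_size
    if w <= 0 or h <= 0:
        raise ValueError("degenerate raster size")
    proj = view.project(mesh.vertices)            # (N, 3) col,row,depth
    tri = proj[mesh.faces]                        # (M, 3, 3)
    xs, ys = tri[..., 0], tri[..., 1]
    x0 = np.clip(np.floor(xs.min(axis=1)), 0, w - 1).astype(np.int64)
    x1 = np.clip(np.ceil(xs.max(axis=1)), 0, w - 1).astype(np.int64)
    y0 = np.clip(np.floor(ys.min(axis=1)), 0, h - 1).astype(np.int64)
    y1 = np.clip(np.ceil(ys.max(axis=1)), 0, h - 1).astype(np.int64)
    visible = (xs.max(axis=1) >= 0) & (xs.min(axis=1) <= w - 1) & \
              (ys.max(axis=1) >= 0) & (ys.min(axis=1) <= h - 1)
    bw = x1 - x0 + 1
    bh = y1 - y0 + 1
    counts = np.where(visible, bw * bh, 0)
    total = int(counts.sum())
    face_map = np.full((h, w), -1, dtype=np.int32)
    bary_map = np.zeros((h, w, 3), dtype=np.float32)
    img = np.zeros((h, w), dtype=np.uint8)
    if total == 0:
        return RenderedView(img, face_map, bary_map, view, view_index)
    frag_face = np.repeat(np.arange(len(mesh.faces)), counts)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    local = np.arange(total) - np.repeat(starts, counts)
    fb = bw[frag_face]
    px = x0[frag_face] + local % fb
    py = y0[frag_face] + local // fb
    # barycentric coordinates at pixel centers
    A, B, C = tri[frag_face, 0, :2], tri[frag_face, 1, :2], tri[frag_face, 2, :2]
    q = np.stack([px, py], axis=1).astype(np.float64)
    v0, v1, v2 = B - A, C - A, q - A
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = d00 * d11 - d01 * d01
    ok = np.abs(denom) > 1e-12
    denom = np.where(ok, denom, 1.0)
    wb = (d11 * d20 - d01 * d21) / denom
    wc = (d00 * d21 - d01 * d20) / denom
    wa = 1.0 - wb - wc
    eps = -1e-9
    inside = ok & (wa >= eps) & (wb >= eps) & (wc >= eps)
    if not inside.any():
        return RenderedView(img, face_map, bary_map, view, view_index)
    frag_face = frag_face[inside]
    px, py = px[inside], py[inside]
    bary = np.stack([wa[inside], wb[inside], wc[inside]], axis=1)
    depth = np.einsum("ij,ij->i", bary, tri[frag_face, :, 2])
    pid = py * w + px
    order = np.lexsort((depth, pid))
    pid_s = pid[order]
    first = np.ones(len(pid_s), dtype=bool)
    first[1:] = pid_s[1:] != pid_s[:-1]
    win = order[first]
    face_map[py[win], px[win]] = frag_face[win]
    bary_map[py[win], px[win]] = bary[win].astype(np.float32)
    if values is not None:
        vals = _sample_binary_texture(mesh, values, frag_face[win], bary[win])
        img[py[win], px[win]] = vals.astype(np.uint8)
    return RenderedView(img, face_map, bary_map, view, view_index)


def render_binary_views(mesh: TexturedMesh, binary_tex: np.ndarray,
                        views: Sequence[ViewProjection]) -> list:
    """Render the binarized texture from each view with depth buffering."""
    if mesh.uv is None:
        raise DetectionError("mesh has no UV coordinates")
    return [rasterize_view(mesh, v, values=binary_tex, view_index=i)
            for i, v in enumerate(views)]


# ---------------------------------------------------------------------------
# Circular Hough transform
# ---------------------------------------------------------------------------

@dataclass
class CircleDetection:
    center_px: tuple      # (col, row), sub-pixel
    radius_px: float
    strength: float
    view_index: int = 0


def detect_circles(img: np.ndarray, r_min: int, r_max: int,
                   sensitivity: float = 0.45,
                   max_circles: int = 300) -> list:
    """Find circles in a binary image with a circular Hough transform.

    Accumulates over radii in [r_min, r_max] on the foreground boundary,
    keeps normalized-accumulator maxima above ``sensitivity`` (strongest
    first) and suppresses maxima closer than ``r_min`` to a stronger one.
    Centers are refined to sub-pixel precision by the intensity centroid of
    the foreground within the detected radius.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if not r_min < r_max:
        raise ValueError("need r_min < r_max")
    binary = img > 0
    if not binary.any():
        return []
    import scipy.ndimage as ndi

    edges = binary & ~ndi.binary_erosion(binary)
    radii = np.arange(int(r_min), int(r_max) + 1)
    accums = hough_circle(edges, radii, normalize=True)
    peaks = hough_circle_peaks(accums, radii,
                               min_xdistance=int(r_min),
                               min_ydistance=int(r_min),
                               threshold=sensitivity,
                               total_num_peaks=max_circles * 4)
    strengths, cxs, cys, rads = peaks
    # cross-radius non-maximum suppression: drop any peak within r_min of a
    # stronger one (hough_circle_peaks only suppresses within each radius)
    order = np.argsort(strengths)[::-1]
    kept = []
    for i in order:
        c = np.array([cxs[i], cys[i]], dtype=np.float64)
        if any(np.linalg.norm(c - k[0]) < r_min for k in kept):
            continue
        kept.append((c, float(rads[i]), float(strengths[i])))
        if len(kept) >= max_circles:
            break
    h, w = binary.shape
    dets = []
    for c, r, s in kept:
        cx, cy = _refine_center(binary, c[0], c[1], r)
        dets.append(CircleDetection((cx, cy), r, s))
    dets.sort(key=lambda d: -d.strength)
    return dets


def _refine_center(binary: np.ndarray, cx: float, cy: float, r: float):
    h, w = binary.shape
    rr = int(np.ceil(r)) + 1
    x0, x1 = max(0, int(cx) - rr), min(w, int(cx) + rr + 1)
    y0, y1 = max(0, int(cy) - rr), min(h, int(cy) + rr + 1)
    patch = binary[y0:y1, x0:x1]
    ys, xs = np.nonzero(patch)
    if len(xs) == 0:
        return float(cx), float(cy)
    xs = xs + x0
    ys = ys + y0
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    sel = d2 <= (r + 0.5) ** 2
    if not sel.any():
        return float(cx), float(cy)
    return float(xs[sel].mean()), float(ys[sel].mean())


# ---------------------------------------------------------------------------
# Back-projection and merging
# ---------------------------------------------------------------------------

def backproject(dets: Sequence[CircleDetection], render: RenderedView,
                mesh: TexturedMesh) -> np.ndarray:
    """Map 2-D circle centers to 3-D surface points via the render's
    face/barycentric reverse lookup.  Detections landing on background are
    dropped with a warning."""
    pts = []
    h, w = render.face_index.shape
    for det in dets:
        cx, cy = det.center_px
        found = None
        # search outward around the (sub-pixel) center for a covered pixel
        for radius in range(0, 4):
            y0, y1 = int(round(cy)) - radius, int(round(cy)) + radius + 1
            x0, x1 = int(round(cx)) - radius, int(round(cx)) + radius + 1
            cand = [(y, x) for y in range(max(0, y0), min(h, y1))
                    for x in range(max(0, x0), min(w, x1))
                    if render.face_index[y, x] >= 0]
            if cand:
                found = min(cand, key=lambda yx: (yx[0] - cy) ** 2 + (yx[1] - cx) ** 2)
                break
        if found is None:
            warnings.warn(f"detection at {det.center_px} lies on background; dropped")
            continue
        y, x = found
        f = render.face_index[y, x]
        bc = render.bary[y, x].astype(np.float64)
        corners = mesh.vertices[mesh.faces[f]]
        pts.append(bc @ corners)
    return np.asarray(pts).reshape(-1, 3)


def merge_candidates(points: np.ndarray, merge_radius: float = 10.0,
                     frame_id: str = "model") -> ElectrodeSet:
    """Consolidate multi-view candidates by single-linkage clustering at
    ``merge_radius``; each cluster is reduced to its centroid.  Output order:
    descending cluster size, then ascending z (deterministic, independent of
    input order)."""
    if merge_radius <= 0:
        raise ValueError("merge_radius must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if len(pts) == 0:
        return ElectrodeSet(np.zeros((0, 3)), frame_id=frame_id)
    if len(pts) == 1:
        return ElectrodeSet(pts.copy(), frame_id=frame_id)
    Z = linkage(pts, method="single")
    labels = fcluster(Z, t=merge_radius, criterion="distance")
    cents, sizes = [], []
    for lab in np.unique(labels):
        sel = labels == lab
        cents.append(pts[sel].mean(axis=0))
        sizes.append(int(sel.sum()))
    cents = np.asarray(cents)
    sizes = np.asarray(sizes)
    order = np.lexsort((cents[:, 0], cents[:, 1], cents[:, 2], -sizes))
    return ElectrodeSet(cents[order], frame_id=frame_id)


def closest_point_on_mesh(mesh: TexturedMesh, points: np.ndarray) -> np.ndarray:
    """Exact closest point on the triangulated surface for each query point.

    Candidate triangles are prefiltered with a KD-tree on face centroids
    (k nearest, exactness guaranteed by a circumradius bound, with a ball
    fallback for the rare violators); the per-pair point-to-triangle
    distance is the exact computation from trimesh.
    """
    from scipy.spatial import cKDTree
    from trimesh.triangles import closest_point as tri_closest

    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tris = mesh.face_corner_points()                   # (M, 3, 3)
    centroids = tris.mean(axis=1)
    max_circum = float(np.linalg.norm(
        tris - centroids[:, None, :], axis=2).max())
    tree = cKDTree(centroids)
    k = min(32, len(tris))
    dc, idx = tree.query(pts, k=k)
    dc, idx = np.atleast_2d(dc), np.atleast_2d(idx)
    flat_tris = tris[idx.ravel()]
    rep_pts = np.repeat(pts, k, axis=0)
    cand = tri_closest(flat_tris, rep_pts).reshape(len(pts), k, 3)
    d = np.linalg.norm(cand - pts[:, None, :], axis=2)
    best = np.argmin(d, axis=1)
    out = cand[np.arange(len(pts)), best]
    d_best = d[np.arange(len(pts)), best]
    # exact unless a non-candidate triangle could be closer than the best
    unsafe = np.nonzero(d_best > dc[:, -1] - max_circum)[0]
    for i in unsafe:
        ball = tree.query_ball_point(pts[i], d_best[i] + max_circum)
        if not ball:
            continue
        cp = tri_closest(tris[ball], np.tile(pts[i], (len(ball), 1)))
        dd = np.linalg.norm(cp - pts[i], axis=1)
        j = int(np.argmin(dd))
        if dd[j] < d_best[i]:
            out[i] = cp[j]
    return out


def project_to_scalp(eset: ElectrodeSet, scalp: TexturedMesh) -> ElectrodeSet:
    """Replace each electrode by its closest point on the scalp surface
    (exact point-to-triangle, not nearest-vertex)."""
    out = eset.copy()
    out.points = closest_point_on_mesh(scalp, eset.points)
    out.frame_id = scalp.frame_id
    return out


# ---------------------------------------------------------------------------
# Full detection pipeline
# ---------------------------------------------------------------------------

def detect_electrodes(mesh: TexturedMesh,
                      views: Optional[Sequence[ViewProjection]] = None,
                      r_min_mm: float = 2.0, r_max_mm: float = 8.0,
                      sensitivity: float = 0.45,
                      merge_radius: float = 10.0,
                      threshold: Optional[float] = None,
                      polarity: str = "bright",
                      correction_hook: Optional[Callable] = None,
                      return_debug: bool = False):
    """Detect electrode centers on a textured mesh.

    Pipeline: binarize texture -> render binary views (default 10) -> Hough
    circle detection per view (radius range given in mm, converted per view
    through the pixel pitch) -> back-project centers to the surface -> merge
    multi-view candidates.  ``correction_hook`` receives the merged
    :class:`ElectrodeSet` and may add/remove/move candidates before the
    result is returned (the manual-correction step of the interactive tool).
    """
    if not mesh.has_texture:
        raise DetectionError("mesh has no texture; electrode detection "
                             "requires a textured model")
    binary = binarize_texture(mesh.texture, threshold=threshold, polarity=polarity)
    if views is None:
        views = default_views(mesh)
    renders = render_binary_views(mesh, binary, views)
    all_pts = []
    all_dets = []
    for render in renders:
        r_min = max(2, int(round(r_min_mm / render.view.pixel_pitch)))
        r_max = max(r_min + 1, int(round(r_max_mm / render.view.pixel_pitch)))
        dets = detect_circles(render.image, r_min, r_max, sensitivity=sensitivity)
        for d in dets:
            d.view_index = render.view_index
        all_dets.append(dets)
        pts = backproject(dets, render, mesh)
        if len(pts):
            all_pts.append(pts)
    if not all_pts:
        raise DetectionError("no circular detections in any view; adjust the "
                             "binarization threshold or the radius range")
    merged = merge_candidates(np.vstack(all_pts), merge_radius=merge_radius,
                              frame_id=mesh.frame_id)
    if correction_hook is not None:
        merged = correction_hook(merged)
    if return_debug:
        return merged, {"renders": renders, "detections": all_dets}
    return merged
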