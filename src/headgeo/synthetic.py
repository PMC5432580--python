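"""Synthetic textured heads with known ground truth.

Stands in for the photogrammetric reconstructions, laser-scan ground truth
and structural MRIs of a real acquisition.  The head is a radially
parameterized deformed sphere (base radius 90 mm — an adult head) with the
rigid facial features surface coregistration relies on: nose ridge, brow,
cheekbones, chin, plus a small seeded random smooth deformation so no two
heads are identical.  The shape is parametric, not anatomical; it exercises
the geometry of the pipeline, not its robustness to real skin/hair.

Conventions: the head is centered at the origin of its own frame, +y is
anterior, +z superior, +x right.  The texture is a full spherical chart
(equirectangular: U = azimuth, V = elevation measured from the bottom of the
image, per the Wavefront convention), with the seam meridian placed at an
azimuth free of electrodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.ndimage as ndi

from .electrode_detection import ViewProjection, rasterize_view
from .geometry_io import ElectrodeSet, TexturedMesh, Volume
from .registration import SimilarityTransform, _rot_axis

# seam azimuth of the texture chart, degrees; chosen to stay >= 8 degrees
# from every electrode column of the canonical layout
SEAM_AZ_DEG = 189.0
BASE_RADIUS_MM = 90.0


def _dirs_from_azel(az_rad, el_rad):
    az = np.asarray(az_rad, dtype=np.float64)
    el = np.asarray(el_rad, dtype=np.float64)
    return np.stack([np.sin(az) * np.cos(el),
                     np.cos(az) * np.cos(el),
                     np.sin(el)], axis=-1)


def _dir_deg(az_deg, el_deg):
    return _dirs_from_azel(np.deg2rad(az_deg), np.deg2rad(el_deg))


# fixed facial features: (azimuth deg, elevation deg, amplitude mm, width deg)
_FEATURES = [
    (0.0, -15.0, 22.0, 9.0),    # nose tip
    (0.0, -2.0, 10.0, 7.0),     # nose bridge
    (-18.0, 18.0, 5.0, 10.0),   # brow (left)
    (0.0, 18.0, 5.0, 10.0),     # brow (center)
    (18.0, 18.0, 5.0, 10.0),    # brow (right)
    (-35.0, -12.0, 7.0, 11.0),  # cheekbone left
    (35.0, -12.0, 7.0, 11.0),   # cheekbone right
    (0.0, -50.0, 9.0, 13.0),    # chin
    (180.0, 5.0, 6.0, 25.0),    # occiput
]


def _make_radius_fn(seed: int) -> Callable[[np.ndarray], np.ndarray]:
    rng = np.random.default_rng(seed)
    n_rand = 8
    rand_dirs = rng.normal(size=(n_rand, 3))
    rand_dirs /= np.linalg.norm(rand_dirs, axis=1, keepdims=True)
    rand_amp = rng.normal(0.0, 1.2, size=n_rand)
    rand_sig = np.deg2rad(rng.uniform(15.0, 35.0, size=n_rand))
    centers = np.vstack([_dir_deg(az, el) for az, el, _, _ in _FEATURES] + [rand_dirs])
    amps = np.concatenate([[a for _, _, a, _ in _FEATURES], rand_amp])
    sigs = np.concatenate([np.deg2rad([w for _, _, _, w in _FEATURES]), rand_sig])

    def radius(dirs: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(np.asarray(dirs, dtype=np.float64))
        d = d / np.linalg.norm(d, axis=-1, keepdims=True)
        r = np.full(len(d), BASE_RADIUS_MM)
        for c, a, s in zip(centers, amps, sigs):
            ang = np.arccos(np.clip(d @ c, -1.0, 1.0))
            r += a * np.exp(-0.5 * (ang / s) ** 2)
        return r

    return radius


@dataclass
class SyntheticHead:
    """A generated head: mesh, analytic radial shape, and ground truth."""

    mesh: TexturedMesh
    radius_fn: Callable
    fiducials: dict           # nasion / LPA / RPA, mm, head frame
    facial_idx: np.ndarray    # vertex indices of the rigid facial segment
    seed: int

    def surface_point(self, az_deg: float, el_deg: float) -> np.ndarray:
        d = np.atleast_2d(_dir_deg(az_deg, el_deg))
        return d[0] * self.radius_fn(d)[0]

    def project_to_surface(self, points: np.ndarray) -> np.ndarray:
        """Radial projection of head-frame points onto the analytic surface."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64))
        d = p / np.linalg.norm(p, axis=1, keepdims=True)
        return d * self.radius_fn(d)[:, None]


def make_head(seed: int = 0, n_subdiv: int = 3) -> SyntheticHead:
    """Generate a closed head-like surface with facial features.

    The mesh is a latitude/longitude grid (``32 * n_subdiv`` rows) over the
    analytic radial function; per-face-corner UVs follow the equirectangular
    chart with the seam handled by U values outside [0, 1] on wrapping faces.
    Deterministic per seed.  Fiducials (nasion, LPA, RPA) and the facial
    segment (vertices within 50 deg azimuth and [-30, 40] deg elevation of
    the nose) are returned as ground truth.
    """
    radius_fn = _make_radius_fn(seed)
    n_lat = 32 * int(n_subdiv)
    n_lon = 2 * n_lat
    az0 = np.deg2rad(SEAM_AZ_DEG)

    el_rows = -np.pi / 2 + np.pi * np.arange(1, n_lat) / n_lat
    az_cols = az0 + 2 * np.pi * np.arange(n_lon) / n_lon
    azg, elg = np.meshgrid(az_cols, el_rows)
    dirs = _dirs_from_azel(azg.ravel(), elg.ravel())
    verts = dirs * radius_fn(dirs)[:, None]
    south = np.array([0.0, 0.0, -1.0]) * radius_fn([[0, 0, -1.0]])[0]
    north = np.array([0.0, 0.0, 1.0]) * radius_fn([[0, 0, 1.0]])[0]
    vertices = np.vstack([verts, south, north])
    i_south = len(verts)
    i_north = len(verts) + 1

    def vid(i, j):  # i: 1..n_lat-1 row, j wraps
        return (i - 1) * n_lon + (j % n_lon)

    faces, uvs = [], []
    u_of = lambda j: j / n_lon           # no wrap: j may equal n_lon -> u=1
    v_of = lambda i: i / n_lat
    for i in range(1, n_lat - 1):
        for j in range(n_lon):
            a, b = vid(i, j), vid(i, j + 1)
            c, d = vid(i + 1, j + 1), vid(i + 1, j)
            ua, ub = u_of(j), u_of(j + 1)
            va, vc = v_of(i), v_of(i + 1)
            faces.append([a, b, c])
            uvs.append([[ua, va], [ub, va], [ub, vc]])
            faces.append([a, c, d])
            uvs.append([[ua, va], [ub, vc], [ua, vc]])
    for j in range(n_lon):  # pole caps
        ua, ub = u_of(j), u_of(j + 1)
        um = 0.5 * (ua + ub)
        faces.append([i_south, vid(1, j + 1), vid(1, j)])
        uvs.append([[um, 0.0], [ub, v_of(1)], [ua, v_of(1)]])
        faces.append([i_north, vid(n_lat - 1, j), vid(n_lat - 1, j + 1)])
        uvs.append([[um, 1.0], [ua, v_of(n_lat - 1)], [ub, v_of(n_lat - 1)]])
    mesh = TexturedMesh(vertices, np.asarray(faces), np.asarray(uvs),
                        texture=None, frame_id=f"synthetic-head-{seed}")
    # fix winding so normals point outward
    tm = mesh.as_trimesh()
    if tm.volume < 0:
        mesh.faces = mesh.faces[:, ::-1].copy()
        mesh.uv = mesh.uv[:, ::-1].copy()

    fid = {
        "nasion": _surface(radius_fn, 0.0, 5.0),
        "LPA": _surface(radius_fn, -90.0, -8.0),
        "RPA": _surface(radius_fn, 90.0, -8.0),
    }
    az_v = np.rad2deg(np.arctan2(vertices[:, 0], vertices[:, 1]))
    el_v = np.rad2deg(np.arcsin(np.clip(
        vertices[:, 2] / np.linalg.norm(vertices, axis=1), -1, 1)))
    facial = np.nonzero((np.abs(az_v) <= 50.0) & (el_v >= -30.0) & (el_v <= 40.0))[0]
    return SyntheticHead(mesh, radius_fn, fid, facial, seed)


def _surface(radius_fn, az_deg, el_deg):
    d = np.atleast_2d(_dir_deg(az_deg, el_deg))
    return d[0] * radius_fn(d)[0]


# ---------------------------------------------------------------------------
# Canonical 68-channel layout (10-20-like naming)
# ---------------------------------------------------------------------------

_RINGS = [
    (90.0, ["Cz"], 0.0),
    (68.0, ["FCz", "FC2", "C2", "CP2", "CPz", "CP1", "C1", "FC1"], 0.0),
    (46.0, ["Fz", "F2", "FC4", "C4", "CP4", "P4", "P2", "Pz",
            "P1", "P3", "CP3", "C3", "FC3", "F1"], 0.0),
    (24.0, ["AFz", "AF4", "F4", "F6", "FC6", "C6", "CP6", "P6", "PO4", "PO2",
            "POz", "PO1", "PO3", "P5", "CP5", "C5", "FC5", "F5", "F3", "AF3"], 0.0),
    (2.0, ["Fpz", "Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2",
           "Oz", "O1", "PO7", "P7", "TP7", "T7", "FT7", "F7", "AF7", "Fp1"], 0.0),
]
# sub-equatorial posterior band: real caps extend below the inion at the
# back but not over the face, which makes the lower band back-heavy — the
# asymmetry the landmark detector keys on
_LOW_BAND = (-15.0, ["P10", "PO10", "Iz", "PO9", "P9"], [140.0, 160.0, 180.0, 200.0, 220.0])


def canonical_68_layout(head: Optional[SyntheticHead] = None) -> ElectrodeSet:
    """The default labeled 68-electrode cap layout (10-20-like names,
    including the Fpz and Oz landmark electrodes).  Points lie on the head
    surface when ``head`` is given, else on the base sphere."""
    pts, labels = [], []
    for el, names, offset in _RINGS:
        n = len(names)
        for k, name in enumerate(names):
            az = offset + 360.0 * k / n
            pts.append((az, el))
            labels.append(name)
    el, names, azs = _LOW_BAND
    for name, az in zip(names, azs):
        pts.append((az, el))
        labels.append(name)
    az = np.array([p[0] for p in pts])
    el = np.array([p[1] for p in pts])
    dirs = _dir_deg(az, el)
    if head is not None:
        xyz = dirs * head.radius_fn(dirs)[:, None]
        frame = head.mesh.frame_id
    else:
        xyz = dirs * BASE_RADIUS_MM
        frame = "canonical-layout"
    return ElectrodeSet(xyz, labels, frame_id=frame)


# ---------------------------------------------------------------------------
# Electrode painting
# ---------------------------------------------------------------------------

def paint_electrodes(head: SyntheticHead, layout: ElectrodeSet,
                     radius_mm: float = 4.0,
                     fg_color=(235, 235, 235), bg_color=(45, 45, 45),
                     tex_shape=(1024, 2048)):
    """Paint filled electrode discs into the head texture.

    Each layout point is radially projected onto the analytic surface; every
    texel whose 3-D surface position lies within ``radius_mm`` of a center is
    painted foreground, so discs stay circular on the surface (geodesic
    painting) regardless of chart distortion.  Returns the textured mesh and
    the ground-truth 3-D centers.
    """
    H, W = tex_shape
    centers = head.project_to_surface(layout.points)
    if len(centers) > 1:
        from scipy.spatial.distance import pdist
        if pdist(centers).min() < 2 * radius_mm:
            warnings.warn("electrode discs overlap")
    tex = np.empty((H, W, 3), dtype=np.uint8)
    tex[:] = np.asarray(bg_color, dtype=np.uint8)
    az0 = np.deg2rad(SEAM_AZ_DEG)
    for c in centers:
        r_c = np.linalg.norm(c)
        psi = radius_mm / r_c                    # angular radius, rad
        el_c = np.arcsin(np.clip(c[2] / r_c, -1, 1))
        az_c = np.arctan2(c[0], c[1])
        v_c = (el_c + np.pi / 2) / np.pi
        row_c = (1.0 - v_c) * H
        dr = int(np.ceil(1.6 * psi / np.pi * H)) + 1
        r0, r1 = max(0, int(row_c) - dr), min(H, int(row_c) + dr + 1)
        # azimuthal half-width must cover the disc at its extreme latitudes;
        # a disc touching a pole needs every column
        el_lo, el_hi = el_c - 1.3 * psi, el_c + 1.3 * psi
        if el_hi >= np.pi / 2 - 1e-9 or el_lo <= -np.pi / 2 + 1e-9:
            dcol = W // 2
        else:
            cos_min = min(np.cos(el_lo), np.cos(el_hi))
            dcol = min(W // 2,
                       int(np.ceil(1.3 * psi / cos_min / (2 * np.pi) * W)) + 1)
        u_c = ((az_c - az0) / (2 * np.pi)) % 1.0
        col_c = int(u_c * W)
        cols = np.arange(col_c - dcol, col_c + dcol + 1) % W
        rows = np.arange(r0, r1)
        cg, rg = np.meshgrid(cols, rows)
        u = (cg + 0.5) / W
        v = 1.0 - (rg + 0.5) / H
        d = _dirs_from_azel(az0 + 2 * np.pi * u, np.pi * v - np.pi / 2)
        p = d * head.radius_fn(d.reshape(-1, 3)).reshape(d.shape[:2])[..., None]
        hit = np.linalg.norm(p - c, axis=-1) <= radius_mm
        tex[rg[hit], cg[hit]] = np.asarray(fg_color, dtype=np.uint8)
    mesh = head.mesh.copy()
    mesh.texture = tex
    gt = ElectrodeSet(centers, None if layout.labels is None else list(layout.labels),
                      frame_id=head.mesh.frame_id)
    return mesh, gt


# ---------------------------------------------------------------------------
# MRI-like volume
# ---------------------------------------------------------------------------

def make_mri_like(head: SyntheticHead, smooth_mm: float = 1.0,
                  voxel_mm: float = 1.5, noise_sd: float = 1.0,
                  seed: int = 0):
    """Voxelize the head interior into an MRI-like volume.

    The volume lives in a world frame rigidly offset from the head frame by
    a known transform (returned).  Interior voxels get intensity 100,
    Gaussian-smoothed by ``smooth_mm``; mild noise emulates background
    signal.  Returns ``(Volume, head_to_world: SimilarityTransform)``.
    """
    rng = np.random.default_rng(seed)
    ang = np.deg2rad(8.0)
    T = SimilarityTransform(_rot_axis(ang, 2), np.array([15.0, -10.0, 25.0]), 1.0)
    corners = head.mesh.vertices
    world = T.apply(corners)
    lo = world.min(axis=0) - 8.0
    hi = world.max(axis=0) + 8.0
    shape = np.ceil((hi - lo) / voxel_mm).astype(int) + 1
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = lo
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    pts_world = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * voxel_mm + lo
    pts_head = T.inverse().apply(pts_world)
    rr = np.linalg.norm(pts_head, axis=1)
    d = pts_head / np.maximum(rr, 1e-9)[:, None]
    inside = rr <= head.radius_fn(d)
    vox = np.zeros(np.prod(shape))
    vox[inside] = 100.0
    vox = vox.reshape(shape)
    if smooth_mm > 0:
        vox = ndi.gaussian_filter(vox, sigma=smooth_mm / voxel_mm)
    if noise_sd > 0:
        vox = vox + rng.normal(0.0, noise_sd, size=vox.shape)
    return Volume(vox, affine, frame_id="mri"), T


# ---------------------------------------------------------------------------
# Chroma-key photo fixtures
# ---------------------------------------------------------------------------

def make_chroma_photo(head: SyntheticHead, view: ViewProjection,
                      key_color=(0, 190, 70)):
    """Orthographic shaded render of the head over a uniform key-color
    background with a vertical brightness gradient (emulating uneven screen
    lighting).  Returns ``(photo_uint8, silhouette_bool)``."""
    render = rasterize_view(head.mesh, view)
    cover = render.face_index >= 0
    h, w = cover.shape
    grad = np.linspace(1.0, 0.72, h)[:, None]
    photo = np.empty((h, w, 3), dtype=np.float64)
    photo[:] = np.asarray(key_color, dtype=np.float64)
    photo *= grad[..., None]
    if cover.any():
        tm = head.mesh
        fn = np.cross(
            tm.vertices[tm.faces[:, 1]] - tm.vertices[tm.faces[:, 0]],
            tm.vertices[tm.faces[:, 2]] - tm.vertices[tm.faces[:, 0]])
        fn /= np.maximum(np.linalg.norm(fn, axis=1, keepdims=True), 1e-12)
        lam = np.abs(fn @ view.direction)
        shade = 0.3 + 0.7 * lam[render.face_index[cover]]
        skin = np.array([205.0, 172.0, 150.0])
        photo[cover] = skin * shade[:, None]
    return np.clip(photo, 0, 255).astype(np.uint8), cover


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

def jitter_electrodes(eset: ElectrodeSet, sigma_mm: float, rng) -> ElectrodeSet:
    """Isotropic Gaussian displacement of each electrode; ``rng`` is a seed
    or Generator.  Reproducible per seed."""
    if sigma_mm < 0:
        raise ValueError("sigma must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = eset.copy()
    if sigma_mm > 0:
        out.points = out.points + rng.normal(0.0, sigma_mm, size=out.points.shape)
    return out
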