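"""Mesh, volume and electrode I/O plus scalp-surface extraction.

All world coordinates are millimetres.  Meshes are triangular with optional
UV-mapped textures; UV follows the Wavefront convention (V measured from the
*bottom* of the texture image, values outside [0,1] wrap).  MRI volumes carry
a voxel-to-world affine (NIfTI convention, RAS expected but not enforced).
Each spatial object carries a free-text ``frame_id`` so that accidental mixing
of coordinate frames can be detected downstream.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import scipy.ndimage as ndi
import trimesh
from skimage import measure


class MeshFormatError(ValueError):
    """Raised for malformed OBJ/electrode files (message names the line)."""


@dataclass
class TexturedMesh:
    """Closed triangular surface, optionally with a UV-mapped texture.

    Parameters
    ----------
    vertices : (N, 3) float array, mm
    faces : (M, 3) int array of vertex indices
    uv : (M, 3, 2) float array or None
        Per-face-corner texture coordinates.  U may exceed [0, 1] on faces
        crossing the texture seam; samplers wrap.
    texture : (H, W, 3) uint8 array or None
    frame_id : str
        Coordinate-frame tag, carried through transforms.
    """

    vertices: np.ndarray
    faces: np.ndarray
    uv: Optional[np.ndarray] = None
    texture: Optional[np.ndarray] = None
    frame_id: str = "model"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (N, 3)")
        if len(self.vertices) < 4:
            raise ValueError("mesh needs at least 4 vertices")
        if not np.isfinite(self.vertices).all():
            raise ValueError("vertex coordinates contain NaN/inf")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (M, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")
        if self.uv is not None:
            self.uv = np.asarray(self.uv, dtype=np.float64)
            if self.uv.shape != (len(self.faces), 3, 2):
                raise ValueError("uv must be (n_faces, 3, 2)")
        if self.texture is not None:
            self.texture = np.asarray(self.texture)
            if self.uv is None:
                raise ValueError("textured mesh requires per-corner uv")

    @property
    def has_texture(self) -> bool:
        return self.texture is not None and self.uv is not None

    def copy(self) -> "TexturedMesh":
        return TexturedMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.uv is None else self.uv.copy(),
            None if self.texture is None else self.texture.copy(),
            self.frame_id,
        )

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def face_corner_points(self) -> np.ndarray:
        """(M, 3, 3) corner coordinates, convenience for rasterization."""
        return self.vertices[self.faces]


@dataclass
class Volume:
    """Scalar 3-D image with a voxel-to-world affine (world in mm)."""

    voxels: np.ndarray
    affine: np.ndarray
    frame_id: str = "mri"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be rank 3")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class ElectrodeSet:
    """Ordered list of (optionally labeled) 3-D points on/near a scalp, mm."""

    points: np.ndarray
    labels: Optional[list] = None
    frame_id: str = "model"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if self.labels is not None:
            self.labels = [str(l) for l in self.labels]
            if len(self.labels) != len(self.points):
                raise ValueError("labels length must match points")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("duplicate electrode labels")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def labeled(self) -> bool:
        return self.labels is not None

    def copy(self) -> "ElectrodeSet":
        return ElectrodeSet(self.points.copy(),
                            None if self.labels is None else list(self.labels),
                            self.frame_id)

    def subset(self, idx) -> "ElectrodeSet":
        idx = np.asarray(idx)
        return ElectrodeSet(self.points[idx],
                            None if self.labels is None else [self.labels[i] for i in idx],
                            self.frame_id)

    def point_for(self, label: str) -> np.ndarray:
        if self.labels is None:
            raise ValueError("electrode set is unlabeled")
        return self.points[self.labels.index(label)]


# ---------------------------------------------------------------------------
# Wavefront OBJ
# ---------------------------------------------------------------------------

def _parse_face_token(tok: str, n_v: int, n_vt: int, lineno: int):
    parts = tok.split("/")
    try:
        vi = int(parts[0])
    except ValueError:
        raise MeshFormatError(f"line {lineno}: bad face vertex index {tok!r}")
    ti = None
    if len(parts) > 1 and parts[1] != "":
        try:
            ti = int(parts[1])
        except ValueError:
            raise MeshFormatError(f"line {lineno}: bad face texture index {tok!r}")
    vi = vi - 1 if vi > 0 else n_v + vi
    if not 0 <= vi < n_v:
        raise MeshFormatError(f"line {lineno}: vertex index out of range in {tok!r}")
    if ti is not None:
        ti = ti - 1 if ti > 0 else n_vt + ti
        if not 0 <= ti < n_vt:
            raise MeshFormatError(f"line {lineno}: texture index out of range in {tok!r}")
    return vi, ti


def _find_texture_file(obj_path: Path, mtl_name: Optional[str]) -> Optional[Path]:
    # MTL first, then any sibling image with the OBJ's stem
    if mtl_name:
        mtl = obj_path.parent / mtl_name
        if mtl.is_file():
            for line in mtl.read_text().splitlines():
                line = line.strip()
                if line.lower().startswith("map_kd"):
                    cand = obj_path.parent / line.split(None, 1)[1].strip()
                    if cand.is_file():
                        return cand
    for ext in (".png", ".jpg", ".jpeg"):
        cand = obj_path.with_suffix(ext)
        if cand.is_file():
            return cand
    return None


def read_textured_mesh(path, frame_id: str = "model") -> TexturedMesh:
    """Read an OBJ file (v/vt/f records) with its texture image.

    1-based OBJ indices are converted to 0-based; quad (or larger) faces are
    fan-triangulated from the first corner.  A missing texture image when
    faces carry ``vt`` degrades to an untextured mesh with a warning.
    """
    path = Path(path)
    verts, uvs, mtl_name = [], [], None
    face_v, face_t = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"line {lineno}: vertex needs 3 coordinates")
                verts.append([float(x) for x in parts[1:4]])
            elif tag == "vt":
                if len(parts) < 3:
                    raise MeshFormatError(f"line {lineno}: vt needs 2 coordinates")
                uvs.append([float(parts[1]), float(parts[2])])
            elif tag == "f":
                if len(parts) < 4:
                    raise MeshFormatError(f"line {lineno}: face needs >= 3 corners")
                corners = [_parse_face_token(t, len(verts), len(uvs), lineno)
                           for t in parts[1:]]
                for k in range(1, len(corners) - 1):  # fan triangulation
                    tri = [corners[0], corners[k], corners[k + 1]]
                    face_v.append([c[0] for c in tri])
                    face_t.append([c[1] for c in tri])
            elif tag == "mtllib":
                mtl_name = parts[1] if len(parts) > 1 else None
    if not verts:
        raise MeshFormatError(f"{path}: no vertices")
    faces = np.asarray(face_v, dtype=np.int64)
    has_vt = any(t is not None for tri in face_t for t in tri)
    uv = None
    texture = None
    if has_vt:
        uv_arr = np.asarray(uvs, dtype=np.float64)
        uv = np.zeros((len(faces), 3, 2))
        for fi, tri in enumerate(face_t):
            for ci, ti in enumerate(tri):
                if ti is None:
                    raise MeshFormatError("face mixes textured and untextured corners")
                uv[fi, ci] = uv_arr[ti]
        tex_file = _find_texture_file(path, mtl_name)
        if tex_file is None:
            warnings.warn(f"{path}: faces carry vt but no texture image found; "
                          "returning untextured mesh")
            uv = None
        else:
            texture = np.asarray(iio.imread(tex_file))
            if texture.ndim == 2:
                texture = np.stack([texture] * 3, axis=-1)
            texture = texture[..., :3]
    return TexturedMesh(np.asarray(verts), faces, uv, texture, frame_id=frame_id)


def write_mesh(mesh: TexturedMesh, path) -> Path:
    """Write OBJ (+ MTL + PNG texture when present).  Deterministic output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if mesh.has_texture:
        lines.append(f"mtllib {path.stem}.mtl")
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.8f} {v[1]:.8f} {v[2]:.8f}")
    if mesh.has_texture:
        # emit per-face-corner vt records; deduplicate exact repeats
        uv_flat = mesh.uv.reshape(-1, 2)
        uniq, inverse = np.unique(uv_flat.round(8), axis=0, return_inverse=True)
        for t in uniq:
            lines.append(f"vt {t[0]:.8f} {t[1]:.8f}")
        inv = inverse.reshape(-1, 3)
        lines.append("usemtl material0")
        for fi, f in enumerate(mesh.faces):
            a = [f"{f[c] + 1}/{inv[fi, c] + 1}" for c in range(3)]
            lines.append("f " + " ".join(a))
    else:
        for f in mesh.faces:
            lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    path.write_text("\n".join(lines) + "\n")
    if mesh.has_texture:
        tex_path = path.with_suffix(".png")
        iio.imwrite(tex_path, mesh.texture.astype(np.uint8))
        mtl = (f"newmtl material0\nKd 1.0 1.0 1.0\nmap_Kd {tex_path.name}\n")
        (path.parent / f"{path.stem}.mtl").write_text(mtl)
    return path


# ---------------------------------------------------------------------------
# Electrode text format:  "label x y z"  or  "x y z", '#' comments
# ---------------------------------------------------------------------------

def read_electrodes(path, frame_id: str = "model") -> ElectrodeSet:
    path = Path(path)
    points, labels = [], []
    any_label = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip().replace(",", " ")
            if not line:
                continue
            parts = line.split()
            if len(parts) == 4:
                lab, coords = parts[0], parts[1:]
                any_label = True
            elif len(parts) == 3:
                lab, coords = None, parts
            else:
                raise MeshFormatError(
                    f"{path}:{lineno}: expected 'label x y z' or 'x y z'")
            try:
                xyz = [float(c) for c in coords]
            except ValueError:
                raise MeshFormatError(f"{path}:{lineno}: non-numeric coordinate")
            points.append(xyz)
            labels.append(lab)
    if not points:
        raise MeshFormatError(f"{path}: no electrode records")
    if any_label:
        if any(l is None for l in labels):
            raise MeshFormatError(f"{path}: mixes labeled and unlabeled lines")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise MeshFormatError(f"{path}: duplicate labels {dup}")
        return ElectrodeSet(np.asarray(points), labels, frame_id=frame_id)
    return ElectrodeSet(np.asarray(points), None, frame_id=frame_id)


def write_electrodes(eset: ElectrodeSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# frame: {eset.frame_id}"]
    for i, p in enumerate(eset.points):
        pre = f"{eset.labels[i]} " if eset.labeled else ""
        lines.append(f"{pre}{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# NIfTI volumes and scalp-surface extraction
# ---------------------------------------------------------------------------

def read_volume(path, frame_id: str = "mri") -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    return Volume(np.asanyarray(img.dataobj).astype(np.float64),
                  img.affine, frame_id=frame_id)


def write_volume(vol: Volume, path) -> Path:
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), vol.affine), str(path))
    return path


def scalp_mesh_from_volume(vol: Volume, threshold_frac: float = 0.10,
                           closing_radius: int = 2) -> TexturedMesh:
    """Extract the outer head (scalp) surface from an MRI-like volume.

    The volume is binarized at ``threshold_frac`` times its robust maximum
    (99th percentile), morphologically closed, reduced to its largest
    connected component with internal holes filled, and the 0.5 isosurface
    of the binary mask is extracted and mapped to world coordinates through
    the affine.
    """
    vox = vol.voxels.astype(np.float64)
    robust_max = np.percentile(vox, 99)
    thr = threshold_frac * robust_max
    mask = (vox >= thr) & (vox > 0)
    if robust_max <= 0 or not mask.any():
        raise ValueError(
            f"no foreground above threshold {thr:.3g}; lower threshold_frac")
    if closing_radius > 0:
        ball = _ball_struct(closing_radius)
        mask = ndi.binary_closing(mask, structure=ball)
    lab, n = ndi.label(mask)
    if n > 1:
        sizes = ndi.sum(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    mask = ndi.binary_fill_holes(mask)
    # pad so the isosurface is closed even when the head touches the array edge
    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts -= 1.0
    world = vol.voxel_to_world(verts)
    mesh = trimesh.Trimesh(world, faces, process=False)
    comps = mesh.split(only_watertight=False)
    if len(comps) > 1:
        mesh = max(comps, key=lambda c: len(c.vertices))
    return TexturedMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces),
                        frame_id=vol.frame_id)


def _ball_struct(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (xx ** 2 + yy ** 2 + zz ** 2) <= r ** 2
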