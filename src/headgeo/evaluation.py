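"""Accuracy evaluation workflows.

Four comparisons, mirroring how the method is validated against ground
truth: mesh-to-mesh deviation (per-vertex nearest-neighbor offsets, per-axis
L1 and Euclidean L2), electrode-to-electrode deviation (L2 per matched
electrode), pure position accuracy (residuals after optimal rigid
alignment, separating the method's own error from coregistration error),
and a coregistration-error simulation that perturbs the model with random
similarity transforms and measures how far electrodes land from their
originals after coregistering back — by facial surface matching or by the
fiducial-based baseline of electromagnetic digitizers.  Paired deviations
are compared with Wilcoxon's signed-rank test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from .geometry_io import ElectrodeSet, TexturedMesh
from .registration import (FacialSegment, SimilarityTransform, best_fit_rigid,
                           coarse_align, coregister_model_to_mri,
                           fiducial_transform, icp, random_similarity,
                           scaling_factor)


@dataclass
class DeviationReport:
    """Per-item deviations plus summary statistics (all mm).

    ``per_axis`` holds absolute per-axis offsets (L1 components); ``euclidean``
    is the L2 norm of the signed offsets.  Summary: mean, median, sd (sample),
    and the 95th percentile of the Euclidean deviations.
    """

    euclidean: np.ndarray
    per_axis: np.ndarray
    labels: Optional[list] = None

    def __post_init__(self):
        self.euclidean = np.asarray(self.euclidean, dtype=np.float64).ravel()
        self.per_axis = np.atleast_2d(np.asarray(self.per_axis, dtype=np.float64))
        if self.per_axis.shape != (len(self.euclidean), 3):
            raise ValueError("per_axis must be (n, 3)")

    @classmethod
    def from_diffs(cls, diffs: np.ndarray, labels=None) -> "DeviationReport":
        diffs = np.atleast_2d(np.asarray(diffs, dtype=np.float64))
        return cls(np.linalg.norm(diffs, axis=1), np.abs(diffs), labels)

    @property
    def summary(self) -> dict:
        e = self.euclidean
        return {
            "n": int(len(e)),
            "mean": float(e.mean()),
            "median": float(np.median(e)),
            "sd": float(e.std(ddof=1)) if len(e) > 1 else 0.0,
            "percentile95": float(np.percentile(e, 95)),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "summary": self.summary,
            "per_item": [
                {"label": None if self.labels is None else self.labels[i],
                 "euclidean": float(self.euclidean[i]),
                 "per_axis": self.per_axis[i].tolist()}
                for i in range(len(self.euclidean))],
        }, indent=1))

    def to_csv(self, path) -> None:
        lines = ["label,dx,dy,dz,euclidean"]
        for i in range(len(self.euclidean)):
            lab = "" if self.labels is None else self.labels[i]
            d = self.per_axis[i]
            lines.append(f"{lab},{d[0]:.6f},{d[1]:.6f},{d[2]:.6f},"
                         f"{self.euclidean[i]:.6f}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Mesh and electrode deviation
# ---------------------------------------------------------------------------

def mesh_deviation(test: TexturedMesh, truth: TexturedMesh,
                   align: bool = False, mode: str = "vertex") -> DeviationReport:
    """Deviation of each test vertex from the ground-truth surface.

    ``mode='vertex'`` matches each test vertex to the closest *vertex* of
    the truth mesh (the convention of the original evaluation);
    ``mode='triangle'`` measures true point-to-surface distance instead.
    ``align=True`` first rescales the test mesh by the centroid-spread
    scaling factor and rigidly ICP-aligns it to the truth.
    """
    if len(test.vertices) == 0 or len(truth.vertices) == 0:
        raise ValueError("empty mesh")
    pts = test.vertices
    if align:
        s = scaling_factor(FacialSegment(truth.vertices),
                           FacialSegment(test.vertices))
        scaled = pts * s
        init = coarse_align(scaled, truth.vertices)
        res = icp(scaled, truth.vertices, mode="rigid", init=init)
        pts = res.transform.apply(scaled)
    if mode == "vertex":
        tree = cKDTree(truth.vertices)
        _, nn = tree.query(pts)
        diffs = pts - truth.vertices[nn]
    elif mode == "triangle":
        from .electrode_detection import closest_point_on_mesh

        diffs = pts - closest_point_on_mesh(truth, pts)
    else:
        raise ValueError("mode must be 'vertex' or 'triangle'")
    return DeviationReport.from_diffs(diffs)


def _match_sets(test: ElectrodeSet, truth: ElectrodeSet, match_by: str,
                exclude: Sequence[str] = ()):
    if match_by == "labels":
        if not (test.labeled and truth.labeled):
            raise ValueError("label matching requires labeled sets")
        common = [l for l in test.labels if l in set(truth.labels)
                  and l not in set(exclude)]
        if not common:
            raise ValueError("no common labels between sets")
        a = np.stack([test.point_for(l) for l in common])
        b = np.stack([truth.point_for(l) for l in common])
        return a, b, common
    elif match_by == "order":
        if len(test) != len(truth):
            raise ValueError("order matching requires equal cardinality")
        labels = test.labels if test.labeled else None
        keep = [i for i in range(len(test))
                if labels is None or labels[i] not in set(exclude)]
        labs = None if labels is None else [labels[i] for i in keep]
        return test.points[keep], truth.points[keep], labs
    raise ValueError("match_by must be 'labels' or 'order'")


def electrode_deviation(test: ElectrodeSet, truth: ElectrodeSet,
                        match_by: str = "labels",
                        exclude: Sequence[str] = ()) -> DeviationReport:
    """Euclidean (L2) deviation per matched electrode.

    ``exclude`` drops labels from the comparison (e.g., an electrode that is
    unreliable on the physical reference).
    """
    a, b, labels = _match_sets(test, truth, match_by, exclude)
    return DeviationReport.from_diffs(a - b, labels)


def pure_position_deviation(test: ElectrodeSet, truth: ElectrodeSet,
                            match_by: str = "order",
                            exclude: Sequence[str] = ()) -> DeviationReport:
    """Residual deviations after the optimal rigid alignment of the test set
    onto the truth set (removes any global coregistration error, leaving the
    method-specific localization error).  With matched correspondences, the
    closed-form least-squares rigid fit is the converged alignment and is
    globally optimal."""
    a, b, labels = _match_sets(test, truth, match_by, exclude)
    T = best_fit_rigid(a, b)
    return DeviationReport.from_diffs(T.apply(a) - b, labels)


# ---------------------------------------------------------------------------
# Coregistration-error simulation
# ---------------------------------------------------------------------------

def coreg_error_simulation(model: TexturedMesh, electrodes: ElectrodeSet,
                           fiducials: dict, segment_idx: Sequence[int],
                           method: str = "surface", n_reps: int = 100,
                           seed: int = 0, fiducial_sigma_mm: float = 2.0,
                           transforms: Optional[Sequence] = None,
                           icp_params: Optional[dict] = None) -> DeviationReport:
    """Coregistration accuracy under random spatial perturbations.

    Each repetition applies a random similarity transform (rotations 1-360
    degrees and translations 1-100 mm per axis; a random 1-5 scale for the
    surface method only, emulating the arbitrary scale of a photogrammetric
    reconstruction) to the model and its electrodes, coregisters the
    perturbed copy back — ``method='surface'``: centroid-spread scaling +
    facial-segment rigid ICP against the unperturbed model;
    ``method='fiducial'``: nasion/LPA/RPA landmark alignment with
    ``fiducial_sigma_mm`` of isotropic Gaussian placement noise (digitizer
    uncertainty; noiseless fiducials would recover exactly) — and pools the
    per-electrode distances to the original positions.  Reproducible per
    ``seed``; ``transforms`` overrides the random perturbations.
    """
    if method not in ("surface", "fiducial"):
        raise ValueError("method must be 'surface' or 'fiducial'")
    rng = np.random.default_rng(seed)
    seg_pts = model.vertices[np.asarray(segment_idx, dtype=np.int64)]
    mri_seg = FacialSegment(seg_pts, source_frame=model.frame_id)
    diffs = []
    for rep in range(n_reps):
        if transforms is not None:
            T = transforms[rep % len(transforms)]
        else:
            T = random_similarity(rng, with_scale=(method == "surface"))
        moved_elec = T.apply(electrodes.points)
        if method == "surface":
            moved_seg = FacialSegment(T.apply(seg_pts))
            back = coregister_model_to_mri(model, moved_seg, mri_seg,
                                           icp_params=icp_params)
        else:
            moved_fids = {
                k: T.apply(np.reshape(v, (1, 3)))[0]
                + rng.normal(0, fiducial_sigma_mm, 3)
                for k, v in fiducials.items()}
            back = fiducial_transform(moved_fids, fiducials)
        recovered = back.apply(moved_elec)
        diffs.append(recovered - electrodes.points)
    return DeviationReport.from_diffs(
        np.vstack(diffs),
        None if electrodes.labels is None else list(electrodes.labels) * n_reps)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(a, b, exact_max_n: int = 12) -> dict:
    """Two-sided Wilcoxon signed-rank test for paired deviations.

    Zero differences are dropped; tied absolute differences get midranks.
    For n <= ``exact_max_n`` remaining pairs the null distribution of the
    positive-rank sum is enumerated exactly over all sign assignments
    (conditional on the observed ranks); above that a normal approximation
    with tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    mu = total / 2.0
    if n <= exact_max_n:
        # exact: distribution of the positive-rank sum over all 2^n signings
        sums = np.zeros(1)
        for r in ranks:
            sums = np.concatenate([sums, sums + r])
        p = float(np.mean(np.abs(sums - mu) >= abs(w_pos - mu) - 1e-12))
    else:
        t_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((t_counts ** 3 - t_counts).sum()) / 48.0
        z = (abs(w_pos - mu) - 0.5) / np.sqrt(var)
        p = float(2.0 * _norm.sf(z))
    return {"statistic": w_pos, "p_value": min(1.0, p), "n": n}
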