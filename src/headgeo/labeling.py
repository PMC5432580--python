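"""Automatic electrode labeling by template majority vote.

Detected electrodes are unlabeled 3-D points.  Labeling anchors each of
(by default) seven fully labeled template layouts to the input set via two
automatically detected landmark electrodes (Fpz anterior, Oz posterior on
the midline), refines with an affine ICP registration, and lets each
template propose for every input electrode the label of its nearest
template electrode.  The final label is the mode of the proposals; ties go
to the lowest template index and duplicate winners are resolved by a
globally optimal one-to-one assignment.  The procedure assumes the input
set and the templates agree in electrode count and relative arrangement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .geometry_io import ElectrodeSet
from .registration import SimilarityTransform, best_fit_rigid, icp


class LabelingError(ValueError):
    pass


@dataclass
class TemplateSet:
    """A bank of fully labeled electrode layouts sharing one label inventory."""

    templates: List[ElectrodeSet] = field(default_factory=list)

    def __post_init__(self):
        for t in self.templates:
            self._check(t)

    def _check(self, entry: ElectrodeSet):
        if not entry.labeled:
            raise LabelingError("template entries must be fully labeled")
        if self.templates:
            ref = set(self.templates[0].labels)
            if set(entry.labels) != ref:
                raise LabelingError("template label inventory mismatch")

    def add(self, entry: ElectrodeSet):
        self._check(entry)
        self.templates.append(entry)

    def __len__(self):
        return len(self.templates)

    @property
    def label_inventory(self) -> list:
        return sorted(self.templates[0].labels)


def build_template(labeled_set: ElectrodeSet) -> ElectrodeSet:
    """Normalize a labeled layout for storage: centered, unit RMS radius.

    The normalization makes templates acquired at different scales
    comparable; the landmark-anchored similarity init restores metric scale
    at use time.
    """
    if not labeled_set.labeled:
        raise LabelingError("cannot build a template from unlabeled points")
    pts = labeled_set.points - labeled_set.points.mean(axis=0)
    rms = np.sqrt((pts ** 2).sum(axis=1).mean())
    if rms < 1e-12:
        raise LabelingError("degenerate layout (zero spread)")
    return ElectrodeSet(pts / rms, list(labeled_set.labels),
                        frame_id="template-normalized")


# ---------------------------------------------------------------------------
# Landmark detection
# ---------------------------------------------------------------------------

def _fit_sphere_center(pts: np.ndarray) -> np.ndarray:
    # algebraic (Kasa) least-squares sphere fit
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def _head_axes(pts: np.ndarray):
    """(center, up, ap_axis, lr_axis, ambiguous_axes) from the point cloud.

    Up points from the best-fit sphere center toward the cloud centroid (the
    cap covers the upper head).  Of the two horizontal principal axes, the
    left-right axis is the one whose mirror plane maps the cloud onto itself
    best (EEG layouts are left-right symmetric); the other is
    anterior-posterior.
    """
    center = _fit_sphere_center(pts)
    rel = pts - center
    up = rel.mean(axis=0)
    nu = np.linalg.norm(up)
    if nu < 1e-9:
        raise LabelingError("cannot orient electrode cloud (isotropic)")
    up = up / nu
    # refine: the top of the cap is azimuthally symmetric, so the normal of
    # its best-fit plane is a tilt-free vertical (the centroid direction is
    # biased when the lower band is back-heavy)
    h = rel @ up
    top = rel[h >= h.min() + 0.65 * (h.max() - h.min())]
    if len(top) >= 4:
        tc = top - top.mean(axis=0)
        w_t, V_t = np.linalg.eigh(tc.T @ tc)
        normal = V_t[:, 0]
        if normal @ up < 0:
            normal = -normal
        if normal @ up > 0.8:  # refinement is a small correction, not a flip
            up = normal
    # the left-right axis is the normal of the best mirror plane through the
    # vertical (EEG layouts are left-right symmetric).  The in-plane
    # principal axes are useless here — the horizontal spread is nearly
    # isotropic, so PCA directions are noise — hence a direct scan over the
    # mirror-plane angle, coarse then refined.
    e1 = np.array([1.0, 0.0, 0.0])
    if abs(e1 @ up) > 0.9:
        e1 = np.array([0.0, 1.0, 0.0])
    e1 = e1 - (e1 @ up) * up
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(up, e1)
    tree = cKDTree(pts)

    def mirror_score(theta):
        normal = np.cos(theta) * e1 + np.sin(theta) * e2
        refl = pts - 2.0 * np.outer((pts - center) @ normal, normal)
        d, _ = tree.query(refl)
        return float(d.mean())

    coarse = np.linspace(0.0, np.pi, 91)[:-1]
    scores = np.array([mirror_score(t) for t in coarse])
    t_best = coarse[int(np.argmin(scores))]
    fine = t_best + np.linspace(-2.5, 2.5, 21) * np.pi / 180
    fs = np.array([mirror_score(t) for t in fine])
    t_best = fine[int(np.argmin(fs))]
    s_best = fs.min()
    lr = np.cos(t_best) * e1 + np.sin(t_best) * e2
    ap = np.cross(up, lr)
    s_ortho = mirror_score(t_best + np.pi / 2)
    ambiguous = s_ortho < 2.0 * s_best + 1e-9
    return center, up, ap, lr, ambiguous


def _lower_band(rel: np.ndarray, up: np.ndarray) -> np.ndarray:
    # lowest 35% of the height *range* (robust to how many electrodes sit in
    # each ring, unlike a count quantile)
    h = rel @ up
    return h <= h.min() + 0.35 * (h.max() - h.min())


def _landmark_pair(pts: np.ndarray, center, up, ap, lr):
    """Indices of the two extreme midline electrodes in the lower cap band
    along the anterior-posterior axis, as (plus_side, minus_side)."""
    rel = pts - center
    band = _lower_band(rel, up)
    spread = np.abs(rel @ lr).max()
    for tol in (0.15, 0.25, 0.4, 1.0):
        mid = band & (np.abs(rel @ lr) <= tol * spread)
        if mid.sum() >= 2:
            break
    idx = np.nonzero(mid)[0]
    a = rel[idx] @ ap
    return int(idx[np.argmax(a)]), int(idx[np.argmin(a)])


def detect_landmark_candidates(eset: ElectrodeSet):
    """Candidate (fpz_index, oz_index) pairs plus a confidence flag.

    The first entry follows the density heuristic (the lower cap band is
    back-heavy in real layouts, so the sparser side is anterior); the
    swapped pair — and both pairs of the other horizontal axis when the
    mirror-symmetry test is inconclusive — follow for trial alignment.
    ``confident`` is True when the axis is unambiguous and the lower-band
    count margin is at least 2 electrodes; only then should callers skip the
    trial of the alternative orientations.
    """
    pts = eset.points
    if len(pts) < 10:
        raise LabelingError("need at least 10 electrodes covering the scalp")
    center, up, ap, lr, ambiguous = _head_axes(pts)
    rel = pts - center
    band = _lower_band(rel, up)

    def side_counts(axis):
        a = rel[band] @ axis
        eps = 1e-9 * max(1.0, float(np.abs(a).max()))  # on-plane points count neither side
        return int((a > eps).sum()), int((a < -eps).sum())

    # the lower-band count asymmetry identifies the AP axis (and its
    # anterior side) far more robustly under jitter than residual scores do
    m_ap = abs(np.subtract(*side_counts(ap)))
    m_lr = abs(np.subtract(*side_counts(lr)))
    if m_lr > m_ap:
        ap, lr = lr, ap
        m_ap, m_lr = m_lr, m_ap
    confident = (not ambiguous or m_ap - m_lr >= 2) and m_ap >= 2
    cands = []
    axis_pairs = [(ap, lr)] + ([(lr, ap)] if ambiguous else [])
    for a_ap, a_lr in axis_pairs:
        plus, minus = _landmark_pair(pts, center, up, a_ap, a_lr)
        n_plus, n_minus = side_counts(a_ap)
        if n_plus <= n_minus:          # sparser side is anterior
            first, second = (plus, minus), (minus, plus)
        else:
            first, second = (minus, plus), (plus, minus)
        cands += [first, second]
    return cands, confident


def detect_landmark_electrodes(eset: ElectrodeSet):
    """Return the (Fpz, Oz) landmark positions of an electrode set.

    Raises :class:`LabelingError` when the lower-band density heuristic
    cannot disambiguate anterior from posterior; use the template-anchored
    trial alignment inside :func:`label_majority_vote` in that case.
    """
    pts = eset.points
    cands, confident = detect_landmark_candidates(eset)
    if not confident:
        (fi, oi), (fj, oj) = cands[0], cands[1]
        raise LabelingError(
            "anterior/posterior ambiguous; candidate (Fpz, Oz) pairs: "
            f"{pts[fi]}/{pts[oi]} and {pts[fj]}/{pts[oj]}")
    fi, oi = cands[0]
    return pts[fi].copy(), pts[oi].copy()


# ---------------------------------------------------------------------------
# Majority-vote labeling
# ---------------------------------------------------------------------------

def _anchor_init(template: ElectrodeSet, set_pts: np.ndarray,
                 fpz: np.ndarray, oz: np.ndarray):
    """Similarity init mapping the template's Fpz/Oz/centroid onto the
    detected landmarks and centroid of the set."""
    t_pts = template.points
    anchors_t = np.vstack([template.point_for("Fpz"), template.point_for("Oz"),
                           t_pts.mean(axis=0)])
    anchors_s = np.vstack([fpz, oz, set_pts.mean(axis=0)])
    return best_fit_rigid(anchors_t, anchors_s, allow_scale=True)


def _axis_rotation(axis, angle):
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _up_of(pts: np.ndarray):
    center = _fit_sphere_center(pts)
    up = (pts - center).mean(axis=0)
    return center, up / np.linalg.norm(up)


def _azimuth_sweep_inits(template: ElectrodeSet, set_pts: np.ndarray,
                         n_keep: int = 2, step_deg: float = 10.0) -> list:
    """Init candidates from an exhaustive sweep of the azimuthal rotation.

    With the cap's vertical axes of template and set matched, the only
    weakly determined degree of freedom is the rotation about the vertical;
    ring-structured layouts have strong local minima there (alignments
    rotated by one electrode slot), so it is scanned exhaustively and the
    ``n_keep`` best-scoring rotations are returned as similarity inits.
    """
    c_t, up_t = _up_of(template.points)
    c_s, up_s = _up_of(set_pts)
    v = np.cross(up_t, up_s)
    sv, cv = np.linalg.norm(v), float(up_t @ up_s)
    if sv < 1e-12:
        R0 = np.eye(3) if cv > 0 else _axis_rotation(
            np.array([1.0, 0.0, 0.0]) if abs(up_t[0]) < 0.9 else
            np.array([0.0, 1.0, 0.0]), np.pi)
    else:
        R0 = _axis_rotation(v / sv, np.arctan2(sv, cv))
    rel_t = template.points - c_t
    rel_s = set_pts - c_s
    scale = np.sqrt((rel_s ** 2).sum(axis=1).mean() /
                    (rel_t ** 2).sum(axis=1).mean())
    tree = cKDTree(set_pts)
    scored = []
    for phi in np.deg2rad(np.arange(0.0, 360.0, step_deg)):
        R = _axis_rotation(up_s, phi) @ R0
        moved = scale * rel_t @ R.T + c_s
        d, _ = tree.query(moved)
        scored.append((float(d.mean()), R))
    scored.sort(key=lambda t: t[0])
    inits = []
    for _, R in scored[:n_keep]:
        t = c_s - scale * R @ c_t
        inits.append(SimilarityTransform(R, t, scale))
    return inits


def _align_template(template: ElectrodeSet, set_pts: np.ndarray,
                    inits: list, icp_params: dict):
    """Affine ICP of the template onto the set from each init; the
    alignment with the lowest mean nearest-neighbor residual wins.
    Returns (aligned_points, score)."""
    t_pts = template.points
    tree = cKDTree(set_pts)
    best = None
    for init in inits:
        res = icp(t_pts, set_pts, mode="affine", init=init, **icp_params)
        aligned = res.transform.apply(t_pts)
        d, _ = tree.query(aligned)
        score = float(d.mean())
        if best is None or score < best[1]:
            best = (aligned, score)
    return best


def label_majority_vote(eset: ElectrodeSet, templates: TemplateSet,
                        icp_params: Optional[dict] = None) -> ElectrodeSet:
    """Assign montage labels to an unlabeled electrode set.

    Per template: trial the landmark candidate orientations, keep the
    alignment with the lowest residual, and propose for each input electrode
    the label of its nearest template electrode.  Electrode count must match
    the templates; relative arrangement is assumed comparable.
    """
    if len(templates) == 0:
        raise LabelingError("empty template set")
    n_t = len(templates.templates[0])
    if len(eset) != n_t:
        raise LabelingError(
            f"electrode count {len(eset)} does not match template count {n_t}")
    icp_params = dict(icp_params or {"max_iter": 50, "tol": 1e-6})
    set_pts = eset.points
    if "Fpz" not in templates.templates[0].labels or \
       "Oz" not in templates.templates[0].labels:
        raise LabelingError("templates must contain the Fpz and Oz landmarks")
    candidates, confident = detect_landmark_candidates(eset)
    if confident:
        candidates = candidates[:2]

    proposals = []          # per template: list of labels per electrode
    aligned_templates = []  # per template: aligned points + labels
    for tpl in templates.templates:
        inits = [_anchor_init(tpl, set_pts, set_pts[fi], set_pts[oi])
                 for fi, oi in candidates]
        inits += _azimuth_sweep_inits(tpl, set_pts)
        aligned, _ = _align_template(tpl, set_pts, inits, icp_params)
        _, nn = cKDTree(aligned).query(set_pts)
        proposals.append([tpl.labels[j] for j in nn])
        aligned_templates.append((aligned, tpl.labels))

    n = len(eset)
    winners = []
    for i in range(n):
        props = [p[i] for p in proposals]
        counts = Counter(props)
        top = max(counts.values())
        tied = {lab for lab, c in counts.items() if c == top}
        if len(tied) == 1:
            winners.append(tied.pop())
        else:
            # tie broken by the proposal of the lowest template index
            winners.append(next(lab for lab in props if lab in tied))

    dup = {lab for lab, c in Counter(winners).items() if c > 1}
    if dup:
        winners = _resolve_duplicates(winners, dup, set_pts, aligned_templates,
                                      templates.label_inventory)
    out = eset.copy()
    out.labels = winners
    return out


def _resolve_duplicates(winners, dup, set_pts, aligned_templates, inventory):
    """Optimal one-to-one reassignment of the conflicting electrodes.

    The electrodes whose winning label is duplicated compete for the
    duplicated labels plus the labels nobody won, with cost the mean
    distance to each label's position across the aligned templates."""
    unique_winners = {lab for lab in winners if winners.count(lab) == 1}
    conflict_idx = [i for i, lab in enumerate(winners) if lab in dup]
    avail = [lab for lab in inventory if lab not in unique_winners]
    if len(avail) != len(conflict_idx):
        raise LabelingError(f"cannot resolve duplicate labels: {sorted(dup)}")
    label_pos = {}
    for lab in avail:
        ps = [aligned[labels.index(lab)] for aligned, labels in aligned_templates]
        label_pos[lab] = np.mean(ps, axis=0)
    cost = np.array([[np.linalg.norm(set_pts[i] - label_pos[lab])
                      for lab in avail] for i in conflict_idx])
    ri, ci = linear_sum_assignment(cost)
    resolved = list(winners)
    for r, c in zip(ri, ci):
        resolved[conflict_idx[r]] = avail[c]
    return resolved


def default_templates(n_templates: int = 7, sigma_mm: float = 3.0,
                      seed: int = 1234) -> TemplateSet:
    """The shipped template bank: seven fixed-seed jittered copies of the
    canonical 68-channel layout.  Real-world template curation (the template
    builder) is user-supplied."""
    from .synthetic import canonical_68_layout, jitter_electrodes

    base = canonical_68_layout()
    rng = np.random.default_rng(seed)
    return TemplateSet([jitter_electrodes(base, sigma_mm, rng)
                        for _ in range(n_templates)])
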