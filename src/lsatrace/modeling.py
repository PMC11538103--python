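"""Smooth centerline models, morphometry, and inter-model agreement statistics.

Screened branch tracks become piecewise third-order (cubic) Bezier
centerlines with C1 joints that interpolate the tracked points exactly;
diameters are measured from the mask cross-section perpendicular to the
local tangent (equivalent-circle diameter 2*sqrt(A/pi)).  Morphometry
reports per-branch length, diameter and curvature plus branch counts per
order; comparisons between two models report key-point offsets, signed
length/diameter differences, Pearson correlations and Bland-Altman limits
of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .tracking import BranchTrack

__all__ = [
    "BezierCenterline", "ModelBranch", "VesselModel", "MorphometryTable",
    "ModelComparison", "fit_centerline", "arc_length", "estimate_diameters",
    "morphometry", "compare_models", "bland_altman", "export_tube_mesh",
]


class BezierCenterline:
    """Piecewise cubic Bezier curve with C1 joints.

    ``segments`` has shape (m, 4, 3): four control points per segment in
    mm, with segment i ending where segment i+1 starts.
    """

    def __init__(self, segments: np.ndarray):
        segments = np.asarray(segments, dtype=float)
        if segments.ndim != 3 or segments.shape[1:] != (4, 3):
            raise ValueError("segments must have shape (m, 4, 3)")
        if len(segments) > 1 and not np.allclose(segments[:-1, 3], segments[1:, 0]):
            raise ValueError("segment joints must coincide")
        self.segments = segments

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def evaluate(self, seg: int, t) -> np.ndarray:
        """Point(s) on segment `seg` at parameter(s) t in [0, 1]."""
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        p0, p1, p2, p3 = self.segments[seg]
        return ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
                + 3 * (1 - t) * t**2 * p2 + t**3 * p3)

    def derivative(self, seg: int, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        p0, p1, p2, p3 = self.segments[seg]
        return (3 * (1 - t) ** 2 * (p1 - p0) + 6 * (1 - t) * t * (p2 - p1)
                + 3 * t**2 * (p3 - p2))

    def second_derivative(self, seg: int, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))[:, None]
        p0, p1, p2, p3 = self.segments[seg]
        return 6 * (1 - t) * (p2 - 2 * p1 + p0) + 6 * t * (p3 - 2 * p2 + p1)

    def sample(self, n_per_segment: int = 16) -> np.ndarray:
        """Polyline samples over the full curve (shared joint points deduplicated)."""
        pts = [self.evaluate(0, np.linspace(0, 1, n_per_segment + 1))]
        for s in range(1, self.n_segments):
            pts.append(self.evaluate(s, np.linspace(0, 1, n_per_segment + 1))[1:])
        return np.concatenate(pts)

    def sample_at_fractions(self, fractions) -> np.ndarray:
        """Points at the given fractions of total arc length (0..1)."""
        dense = self.sample(64)
        seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        total = cum[-1]
        targets = np.asarray(fractions, dtype=float) * total
        out = np.empty((len(targets), 3))
        for a in range(3):
            out[:, a] = np.interp(targets, cum, dense[:, a])
        return out

    def tangents_at_fractions(self, fractions) -> np.ndarray:
        dense = self.sample(64)
        g = np.gradient(dense, axis=0)
        g /= np.linalg.norm(g, axis=1, keepdims=True) + 1e-30
        seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        targets = np.asarray(fractions, dtype=float) * cum[-1]
        out = np.empty((len(targets), 3))
        for a in range(3):
            out[:, a] = np.interp(targets, cum, g[:, a])
        return out / (np.linalg.norm(out, axis=1, keepdims=True) + 1e-30)

    def curvature(self, samples_per_segment: int = 16) -> np.ndarray:
        """Analytic curvature |B' x B''| / |B'|^3 at uniform parameters (1/mm)."""
        ks = []
        ts = np.linspace(0, 1, samples_per_segment)
        for s in range(self.n_segments):
            d1 = self.derivative(s, ts)
            d2 = self.second_derivative(s, ts)
            cross = np.cross(d1, d2)
            denom = np.linalg.norm(d1, axis=1) ** 3 + 1e-30
            ks.append(np.linalg.norm(cross, axis=1) / denom)
        return np.concatenate(ks)


def fit_centerline(points) -> BezierCenterline:
    """Interpolating piecewise cubic Bezier with C1 joints.

    Control points come from Catmull-Rom-style local tangent estimates, so
    the curve passes exactly through every input point.  Duplicate
    consecutive points are collapsed first.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("need at least 2 distinct points")
    n = len(pts)
    tangents = np.empty_like(pts)
    tangents[0] = pts[1] - pts[0]
    tangents[-1] = pts[-1] - pts[-2]
    if n > 2:
        tangents[1:-1] = (pts[2:] - pts[:-2]) / 2.0
    segments = np.empty((n - 1, 4, 3))
    for i in range(n - 1):
        segments[i, 0] = pts[i]
        segments[i, 1] = pts[i] + tangents[i] / 3.0
        segments[i, 2] = pts[i + 1] - tangents[i + 1] / 3.0
        segments[i, 3] = pts[i + 1]
    return BezierCenterline(segments)


def arc_length(c: BezierCenterline, rtol: float = 1e-4, max_refine: int = 10) -> float:
    """Arc length by adaptive polyline refinement until relative change < rtol."""
    n = 8
    prev = np.linalg.norm(np.diff(c.sample(n), axis=0), axis=1).sum()
    for _ in range(max_refine):
        n *= 2
        cur = np.linalg.norm(np.diff(c.sample(n), axis=0), axis=1).sum()
        if abs(cur - prev) <= rtol * max(cur, 1e-30):
            return float(cur)
        prev = cur
    return float(prev)


# ---------------------------------------------------------------------------
# diameters

def estimate_diameters(c: BezierCenterline, mask, spacing, step_mm: float | None = None,
                       median_window: int = 3):
    """Equivalent-circle diameters from perpendicular mask cross-sections.

    At each arc-length-uniform sample, the mask is resampled (nearest
    neighbor) on a plane grid perpendicular to the local tangent; the
    connected in-plane region containing the centerline gives an area A and
    diameter 2*sqrt(A/pi).  The profile is median filtered (window 3).
    Samples falling outside the mask inherit the nearest in-mask sample's
    diameter and are flagged.

    Returns ``(diameters, sample_points, flags)``.
    """
    mask = np.asarray(mask) != 0
    sp = np.asarray(spacing, dtype=float)
    sp_min = float(sp.min())
    if step_mm is None:
        step_mm = sp_min
    total = arc_length(c)
    n = max(int(np.ceil(total / step_mm)) + 1, 5)
    fracs = np.linspace(0.0, 1.0, n)
    pts = c.sample_at_fractions(fracs)
    tans = c.tangents_at_fractions(fracs)

    dt = ndimage.distance_transform_edt(mask, sampling=sp)
    cell = 0.5 * sp_min
    diams = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    shape = np.asarray(mask.shape)
    for i in range(n):
        p, t = pts[i], tans[i]
        a = np.array([1.0, 0.0, 0.0])
        if abs(t @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        u = np.cross(t, a)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        ci = np.rint(p / sp).astype(int)
        in_grid = np.all((ci >= 0) & (ci < shape))
        r0 = dt[tuple(ci)] if in_grid else 0.0
        if r0 <= 0:
            flags[i] = True
            continue
        half = max(3.0 * r0, 3.0 * sp_min)
        m = int(np.ceil(half / cell))
        # half-cell offset keeps sample points off voxel-boundary planes
        g = (np.arange(-m, m) + 0.5) * cell
        gu, gv = np.meshgrid(g, g, indexing="ij")
        plane = p + gu[..., None] * u + gv[..., None] * v
        idx = np.rint(plane / sp).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=-1)
        inmask = np.zeros(gu.shape, dtype=bool)
        sel = idx[ok]
        inmask[ok] = mask[sel[:, 0], sel[:, 1], sel[:, 2]]
        labels, _ = ndimage.label(inmask)
        center_lab = 0
        for ci, cj in ((m - 1, m - 1), (m - 1, m), (m, m - 1), (m, m)):
            if labels[ci, cj]:
                center_lab = labels[ci, cj]
                break
        if center_lab == 0:
            flags[i] = True
            continue
        area = float(np.sum(labels == center_lab)) * cell * cell
        diams[i] = 2.0 * np.sqrt(area / np.pi)

    valid = ~np.isnan(diams)
    if not valid.any():
        raise ValueError("centerline has no in-mask samples")
    if (~valid).any():
        vi = np.flatnonzero(valid)
        for i in np.flatnonzero(~valid):
            diams[i] = diams[vi[np.argmin(np.abs(vi - i))]]
    if median_window > 1 and n >= median_window:
        diams = ndimage.median_filter(diams, size=median_window, mode="nearest")
    return diams, pts, flags


# ---------------------------------------------------------------------------
# vessel model

@dataclass
class ModelBranch:
    centerline: BezierCenterline
    diameters: np.ndarray
    sample_points: np.ndarray
    order: int
    parent: tuple[int, int] | None
    track: BranchTrack | None = None

    @property
    def length(self) -> float:
        return arc_length(self.centerline)

    @property
    def mean_diameter(self) -> float:
        return float(np.mean(self.diameters))


@dataclass
class VesselModel:
    """All modeled branches plus the bifurcation topology."""

    branches: list[ModelBranch] = field(default_factory=list)
    bifurcation_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    @classmethod
    def from_tracks(cls, tracks: list[BranchTrack], mask=None, spacing=None) -> "VesselModel":
        """Fit Bezier centerlines (and mask-based diameters if a mask is given)."""
        branches = []
        bifs = []
        for tr in tracks:
            cl = fit_centerline(tr.points)
            if mask is not None and spacing is not None:
                diams, pts, _flags = estimate_diameters(cl, mask, spacing)
            else:
                pts = cl.sample_at_fractions(np.linspace(0, 1, max(len(tr.points), 5)))
                tree = cKDTree(tr.points)
                _, nn = tree.query(pts)
                diams = 2.0 * tr.radii[nn]
            branches.append(ModelBranch(centerline=cl, diameters=diams, sample_points=pts,
                                        order=tr.order, parent=tr.parent, track=tr))
            if tr.parent is not None:
                bifs.append(tr.points[0])
        return cls(branches=branches,
                   bifurcation_points=np.asarray(bifs).reshape(-1, 3))

    @property
    def tracks(self) -> list[BranchTrack]:
        return [b.track for b in self.branches if b.track is not None]


def morphometry(m: VesselModel) -> "MorphometryTable":
    """Per-branch geometry table plus branch counts per order (3+ capped)."""
    rows = []
    for i, b in enumerate(m.branches):
        curv = b.centerline.curvature()
        rows.append({
            "branch": i,
            "order": min(b.order, 3),
            "length_mm": b.length,
            "mean_diameter_mm": float(np.mean(b.diameters)),
            "min_diameter_mm": float(np.min(b.diameters)),
            "max_diameter_mm": float(np.max(b.diameters)),
            "mean_curvature_per_mm": float(np.mean(curv)),
        })
    table = pd.DataFrame(rows, columns=["branch", "order", "length_mm", "mean_diameter_mm",
                                        "min_diameter_mm", "max_diameter_mm",
                                        "mean_curvature_per_mm"])
    counts = table["order"].value_counts().to_dict() if len(table) else {}
    return MorphometryTable(per_branch=table, branch_counts={int(k): int(v) for k, v in counts.items()})


@dataclass
class MorphometryTable:
    per_branch: pd.DataFrame
    branch_counts: dict[int, int]

    def to_csv(self, path) -> None:
        self.per_branch.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# comparison statistics

def bland_altman(a, b) -> tuple[float, float, float]:
    """Mean difference and +/- 1.96 SD limits of agreement for paired values."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


@dataclass
class ModelComparison:
    matched_pairs: list[tuple[int, int]]
    keypoint_offsets: np.ndarray      # mm, all matched key points pooled
    length_diffs: np.ndarray          # mm, signed a - b per matched branch
    diameter_diffs: np.ndarray        # mm, signed a - b per matched branch
    pearson_r: dict[str, float]
    bland_altman_limits: dict[str, tuple[float, float, float]]
    flags: list[str] = field(default_factory=list)


def _safe_pearson(x, y) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def compare_models(a: VesselModel, b: VesselModel, match_threshold: float = 1.0,
                   keypoint_step: float = 0.5) -> ModelComparison:
    """Branch-matched agreement statistics between two vessel models.

    Branches are matched greedily by symmetric mean closest-point distance
    (threshold `match_threshold` mm); key points are arc-length-matched
    samples every `keypoint_step` mm (plus endpoints) on matched branches.
    """
    if not a.branches or not b.branches:
        raise ValueError("both models must be non-empty")
    sa = [br.centerline.sample(16) for br in a.branches]
    sb = [br.centerline.sample(16) for br in b.branches]
    trees_b = [cKDTree(s) for s in sb]
    trees_a = [cKDTree(s) for s in sa]
    cost = np.empty((len(sa), len(sb)))
    for i in range(len(sa)):
        for j in range(len(sb)):
            dij = trees_b[j].query(sa[i])[0].mean()
            dji = trees_a[i].query(sb[j])[0].mean()
            cost[i, j] = 0.5 * (dij + dji)
    pairs: list[tuple[int, int]] = []
    used_a, used_b = set(), set()
    for flat in np.argsort(cost, axis=None):
        i, j = np.unravel_index(flat, cost.shape)
        if i in used_a or j in used_b or cost[i, j] > match_threshold:
            continue
        pairs.append((int(i), int(j)))
        used_a.add(i)
        used_b.add(j)

    flags = []
    if not pairs:
        flags.append("no branch matches within threshold")
        return ModelComparison(pairs, np.zeros(0), np.zeros(0), np.zeros(0),
                               {"length": float("nan"), "diameter": float("nan")},
                               {"length": (0.0, 0.0, 0.0), "diameter": (0.0, 0.0, 0.0)}, flags)

    offsets = []
    len_a, len_b, dia_a, dia_b = [], [], [], []
    for i, j in pairs:
        ba, bb = a.branches[i], b.branches[j]
        La, Lb = ba.length, bb.length
        n_kp = max(int(np.floor(min(La, Lb) / keypoint_step)) + 1, 2)
        fr = np.linspace(0.0, 1.0, n_kp)
        pa = ba.centerline.sample_at_fractions(fr)
        pb = bb.centerline.sample_at_fractions(fr)
        offsets.append(np.linalg.norm(pa - pb, axis=1))
        len_a.append(La)
        len_b.append(Lb)
        dia_a.append(ba.mean_diameter)
        dia_b.append(bb.mean_diameter)

    len_a, len_b = np.asarray(len_a), np.asarray(len_b)
    dia_a, dia_b = np.asarray(dia_a), np.asarray(dia_b)
    return ModelComparison(
        matched_pairs=pairs,
        keypoint_offsets=np.concatenate(offsets),
        length_diffs=len_a - len_b,
        diameter_diffs=dia_a - dia_b,
        pearson_r={"length": _safe_pearson(len_a, len_b),
                   "diameter": _safe_pearson(dia_a, dia_b)},
        bland_altman_limits={"length": bland_altman(len_a, len_b),
                             "diameter": bland_altman(dia_a, dia_b)},
        flags=flags,
    )


# ---------------------------------------------------------------------------
# tube meshes

def export_tube_mesh(m: VesselModel, n_theta: int = 16, samples_per_mm: float = 4.0,
                     path=None):
    """Watertight tube surface per branch with per-vertex diameter scalar.

    Rings of `n_theta` vertices are swept along each centerline with
    parallel-transported frames and closed with end-cap fans.  Returns a
    ``trimesh.Trimesh`` (vertex attribute ``diameter``); pass `path` to
    also write a PLY file.
    """
    import trimesh

    all_v, all_f, all_d = [], [], []
    offset = 0
    for br in m.branches:
        L = br.length
        n = max(int(np.ceil(L * samples_per_mm)) + 1, 4)
        fr = np.linspace(0, 1, n)
        pts = br.centerline.sample_at_fractions(fr)
        tans = br.centerline.tangents_at_fractions(fr)
        diams = np.interp(fr, np.linspace(0, 1, len(br.diameters)), br.diameters)

        # parallel transport of the ring frame
        t0 = tans[0]
        ref = np.array([1.0, 0.0, 0.0])
        if abs(t0 @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(t0, ref)
        u /= np.linalg.norm(u)
        frames = [u]
        for i in range(1, n):
            u = frames[-1] - (frames[-1] @ tans[i]) * tans[i]
            nrm = np.linalg.norm(u)
            u = u / nrm if nrm > 1e-12 else frames[-1]
            frames.append(u)

        theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        verts, diam_attr = [], []
        for i in range(n):
            v = np.cross(tans[i], frames[i])
            ring = (pts[i] + 0.5 * diams[i]
                    * (np.cos(theta)[:, None] * frames[i] + np.sin(theta)[:, None] * v))
            verts.append(ring)
            diam_attr.extend([diams[i]] * n_theta)
        verts = np.concatenate(verts)
        faces = []
        for i in range(n - 1):
            for k in range(n_theta):
                a0 = i * n_theta + k
                a1 = i * n_theta + (k + 1) % n_theta
                b0 = a0 + n_theta
                b1 = a1 + n_theta
                faces += [[a0, b0, a1], [a1, b0, b1]]
        # end caps
        c0 = len(verts)
        verts = np.vstack([verts, pts[0], pts[-1]])
        diam_attr += [diams[0], diams[-1]]
        for k in range(n_theta):
            faces.append([c0, (k + 1) % n_theta, k])
            base = (n - 1) * n_theta
            faces.append([c0 + 1, base + k, base + (k + 1) % n_theta])
        all_v.append(verts)
        all_f.append(np.asarray(faces) + offset)
        all_d.append(np.asarray(diam_attr))
        offset += len(verts)

    vertices = np.concatenate(all_v) if all_v else np.zeros((0, 3))
    faces = np.concatenate(all_f) if all_f else np.zeros((0, 3), dtype=int)
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    mesh.vertex_attributes["diameter"] = np.concatenate(all_d) if all_d else np.zeros(0)
    if path is not None:
        mesh.export(str(path))
    return mesh
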