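"""Centerline tracking through the vessel mask with a random-forest step scorer.

Vessels are traced as chains of short cylinders.  Each candidate step is
described by five features -- (1) the vessel-voxel fraction of the cylinder
volume, (2) the variance of the distances from the cylinder end-face
center to the vessel-region edge, (3) the turning angle against the
previous step, (4) the vessel voxel count in the 5x5x5 neighborhood of the
cylinder end, and (5) the Hessian eigenvalues (Gaussian scale sigma = 1.5
voxels) in the 11x11x11 neighborhoods of the cylinder endpoints of the
original image -- and scored by a random forest combined with a
minimal-path-style energy term.  Bifurcations are found by intersecting a
spherical shell with the mask and counting connected components on it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .volume import Volume

__all__ = [
    "Cylinder", "StepFeatures", "StepForestConfig", "TrackingConfig", "Seed",
    "BranchTrack", "StepForest", "compute_step_features", "detect_seeds",
    "train_step_forest", "step", "detect_bifurcation", "trace_tree",
    "make_step_training_data",
]


@dataclass
class Cylinder:
    """Tracking primitive: base point (mm), unit axis, radius and height (mm)."""

    base: np.ndarray
    axis: np.ndarray
    radius: float
    height: float

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ValueError("cylinder axis must be non-zero")
            self.axis = self.axis / n
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("radius and height must be > 0")

    @property
    def end(self) -> np.ndarray:
        return self.base + self.axis * self.height


@dataclass
class StepFeatures:
    f1: float                 # vessel fraction of cylinder volume, [0, 1]
    f2: float                 # variance of end-face center-to-edge distances, mm^2
    f3: float                 # turning angle vs previous axis, radians [0, pi]
    f4: int                   # vessel voxels in the 5x5x5 end neighborhood
    f5: np.ndarray            # Hessian eigenvalues at sigma = 1.5, ascending

    def vector(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, float(self.f4), *self.f5])


@dataclass
class StepForestConfig:
    n_trees: int = 2000
    n_iterations: int = 100          # provenance: ensemble grown in bootstrap rounds
    randomize_samples: bool = True   # bootstrap resampling per tree
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class TrackingConfig:
    max_turn_deg: float = 60.0
    step_height_voxels: float = 3.0
    radius_factors: tuple = (0.5, 0.75, 1.0, 1.25, 1.5)
    n_candidate_directions: int = 40
    stop_score: float = 0.3
    min_f1: float = 0.2
    lambda_curvature: float = 0.5      # curvature penalty weight inside the energy
    lambda_energy: float = 0.2         # energy weight against the forest probability
    shell_factor: float = 2.0          # bifurcation shell radius = factor x local radius
    shell_scan: tuple = (1.0, 1.33, 1.67, 2.0)  # multipliers of the shell radius tried in turn
    shell_thickness_voxels: float = 1.5
    max_steps: int = 300
    max_branches: int = 100
    junction_merge_voxels: float = 3.0


@dataclass
class Seed:
    point: np.ndarray      # mm
    direction: np.ndarray  # unit
    radius: float          # mm

    def __iter__(self):
        yield self.point
        yield self.direction


@dataclass
class BranchTrack:
    """Ordered centerline samples (mm) with radii and tree linkage."""

    points: np.ndarray
    radii: np.ndarray
    parent: tuple[int, int] | None = None   # (branch id, attachment point index)
    order: int = 1
    provenance: str = "seed"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if len(self.points) < 2:
            raise ValueError("BranchTrack needs >= 2 points")
        if len(self.radii) != len(self.points):
            raise ValueError("radii must match points")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be > 0")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# shared tracing context (caches the distance transform etc.)

class _TraceContext:
    def __init__(self, mask: np.ndarray, original: Volume):
        self.mask = np.asarray(mask) != 0
        self.spacing = np.asarray(original.spacing, dtype=float)
        self.data = np.asarray(original.data, dtype=np.float64)
        self.dt = ndimage.distance_transform_edt(self.mask, sampling=self.spacing)
        self.visited = np.zeros(self.mask.shape, dtype=bool)

    def mask_at(self, pts_mm: np.ndarray) -> np.ndarray:
        idx = np.rint(np.atleast_2d(pts_mm) / self.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(self.mask.shape)), axis=1)
        out = np.zeros(len(idx), dtype=bool)
        sel = idx[ok]
        out[ok] = self.mask[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def dt_at(self, pts_mm: np.ndarray) -> np.ndarray:
        idx = np.rint(np.atleast_2d(pts_mm) / self.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < np.asarray(self.mask.shape)), axis=1)
        out = np.zeros(len(idx))
        sel = idx[ok]
        out[ok] = self.dt[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out


def _cylinder_voxels(ctx: _TraceContext, cyl: Cylinder):
    """Indices of voxels whose centers lie inside the cylinder."""
    sp = ctx.spacing
    pts = np.stack([cyl.base, cyl.end])
    pad = cyl.radius + sp.max()
    lo = np.clip(np.floor((pts.min(axis=0) - pad) / sp).astype(int), 0, np.asarray(ctx.mask.shape))
    hi = np.clip(np.ceil((pts.max(axis=0) + pad) / sp).astype(int) + 1, 0, np.asarray(ctx.mask.shape))
    if np.any(lo >= hi):
        return np.zeros((0, 3), dtype=int)
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    idx = np.stack(grids, axis=-1).reshape(-1, 3)
    rel = idx * sp - cyl.base
    ax = rel @ cyl.axis
    radial = np.linalg.norm(rel - ax[:, None] * cyl.axis, axis=1)
    inside = (ax >= 0) & (ax <= cyl.height) & (radial <= cyl.radius)
    return idx[inside]


def _orthonormal_frame(axis: np.ndarray):
    a = np.array([1.0, 0.0, 0.0])
    if abs(axis @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, a)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _hessian_eigvals(ctx: _TraceContext, point_mm: np.ndarray, sigma: float = 1.5,
                     window: int = 11) -> np.ndarray:
    """Hessian matrix of the sigma-smoothed image at `point_mm` (voxel units)."""
    h = window // 2
    c = np.rint(point_mm / ctx.spacing).astype(int)
    idx = [np.clip(np.arange(c[a] - h, c[a] + h + 1), 0, ctx.data.shape[a] - 1) for a in range(3)]
    sub = ctx.data[np.ix_(*idx)]
    H = np.empty((3, 3))
    orders = {(0, 0): (2, 0, 0), (1, 1): (0, 2, 0), (2, 2): (0, 0, 2),
              (0, 1): (1, 1, 0), (0, 2): (1, 0, 1), (1, 2): (0, 1, 1)}
    for (a, b), order in orders.items():
        d = ndimage.gaussian_filter(sub, sigma=sigma, order=order, mode="nearest")[h, h, h]
        H[a, b] = H[b, a] = d
    return H


# ---------------------------------------------------------------------------
# operations

def compute_step_features(cyl: Cylinder, prev_axis, mask, original: Volume,
                          context: _TraceContext | None = None,
                          n_rays: int = 16) -> StepFeatures:
    """The five step features for one candidate cylinder."""
    ctx = context or _TraceContext(mask, original)
    vox = _cylinder_voxels(ctx, cyl)
    if len(vox) == 0:
        raise ValueError("cylinder does not intersect the grid")
    f1 = float(ctx.mask[vox[:, 0], vox[:, 1], vox[:, 2]].mean())

    # f2: ray-march in the end-face plane to the mask boundary
    end = cyl.end
    u, v = _orthonormal_frame(cyl.axis)
    sp = ctx.spacing.min()
    max_march = 4.0 * cyl.radius + 2.0 * sp
    steps = np.arange(0.0, max_march, 0.5 * sp)
    dists = np.empty(n_rays)
    for r_i, theta in enumerate(np.linspace(0, 2 * np.pi, n_rays, endpoint=False)):
        ray = np.cos(theta) * u + np.sin(theta) * v
        pts = end + steps[:, None] * ray
        inside = ctx.mask_at(pts)
        out = np.flatnonzero(~inside)
        dists[r_i] = steps[out[0]] if len(out) else max_march
    f2 = float(np.var(dists))

    prev_axis = np.asarray(prev_axis, dtype=float)
    prev_axis = prev_axis / (np.linalg.norm(prev_axis) + 1e-30)
    f3 = float(np.arccos(np.clip(cyl.axis @ prev_axis, -1.0, 1.0)))

    c = np.rint(end / ctx.spacing).astype(int)
    lo = np.clip(c - 2, 0, np.asarray(ctx.mask.shape))
    hi = np.clip(c + 3, 0, np.asarray(ctx.mask.shape))
    f4 = int(ctx.mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].sum())

    H = 0.5 * (_hessian_eigvals(ctx, cyl.base) + _hessian_eigvals(ctx, end))
    f5 = np.sort(np.linalg.eigvalsh(H))
    return StepFeatures(f1=f1, f2=f2, f3=f3, f4=f4, f5=f5)


def _geodesic_distance(mask: np.ndarray, start: tuple[int, int, int]) -> np.ndarray:
    """26-connected BFS distance (in steps) within the mask; -1 outside reach."""
    dist = np.full(mask.shape, -1, dtype=np.int32)
    cur = np.zeros(mask.shape, dtype=bool)
    cur[start] = True
    dist[start] = 0
    reached = cur.copy()
    st = np.ones((3, 3, 3), dtype=bool)
    d = 0
    while True:
        nxt = ndimage.binary_dilation(cur, st) & mask & ~reached
        if not nxt.any():
            return dist
        d += 1
        dist[nxt] = d
        reached |= nxt
        cur = nxt


def detect_seeds(mask, large_vessel_mask=None, spacing=(1.0, 1.0, 1.0),
                 config: TrackingConfig | None = None) -> list[Seed]:
    """Find tracking start points.

    Where a large-vessel mask is available, seeds sit where small-vessel
    components abut it, pointing away from the large vessel (emulating
    tracking outward from the parent artery).  Without one -- the phantom
    mode -- each mask component is seeded at a geodesically extremal tip
    (an endpoint of its medial structure), preferring the tip with the
    largest inscribed radius (the stem is widest); the initial direction
    points inward along the component.
    """
    mask = np.asarray(mask) != 0
    sp = np.asarray(spacing, dtype=float)
    if not mask.any():
        return []
    lv = np.asarray(large_vessel_mask) != 0 if large_vessel_mask is not None else None
    small = mask & ~lv if lv is not None else mask
    dt = ndimage.distance_transform_edt(small, sampling=sp)
    labels, n = ndimage.label(small, structure=np.ones((3, 3, 3)))
    seeds: list[Seed] = []
    lv_dil = ndimage.binary_dilation(lv, np.ones((3, 3, 3))) if lv is not None and lv.any() else None
    for comp in range(1, n + 1):
        cmask = labels == comp
        cidx = np.argwhere(cmask)
        if len(cidx) < 3:
            continue
        if lv_dil is not None:
            contact = cmask & lv_dil
            if contact.any():
                cpt = np.argwhere(contact).mean(axis=0) * sp
                direction = cidx.mean(axis=0) * sp - cpt
                nrm = np.linalg.norm(direction)
                if nrm == 0:
                    continue
                r = max(float(dt[tuple(np.rint(cpt / sp).astype(int))]), float(sp.min()))
                seeds.append(Seed(point=cpt, direction=direction / nrm, radius=r))
                continue
        # geodesic tips: farthest point from a central voxel, then farthest from it
        c0 = tuple(cidx[np.argmax(dt[cidx[:, 0], cidx[:, 1], cidx[:, 2]])])
        d0 = _geodesic_distance(cmask, c0)
        tip_a = tuple(cidx[np.argmax(d0[cidx[:, 0], cidx[:, 1], cidx[:, 2]])])
        dA = _geodesic_distance(cmask, tip_a)
        tip_b = tuple(cidx[np.argmax(dA[cidx[:, 0], cidx[:, 1], cidx[:, 2]])])
        dB = _geodesic_distance(cmask, tip_b)
        cands = []
        for tip, gdist in ((tip_a, dA), (tip_b, dB)):
            # shift the seed onto the local medial axis: max-dt voxel near the tip
            near = cidx[gdist[cidx[:, 0], cidx[:, 1], cidx[:, 2]] <= 3]
            pos = near[np.argmax(dt[near[:, 0], near[:, 1], near[:, 2]])]
            ring = cidx[(gdist[cidx[:, 0], cidx[:, 1], cidx[:, 2]] >= 4)
                        & (gdist[cidx[:, 0], cidx[:, 1], cidx[:, 2]] <= 10)]
            if len(ring) == 0:
                ring = cidx
            direction = (ring.mean(axis=0) - pos) * sp
            nrm = np.linalg.norm(direction)
            if nrm == 0:
                continue
            r = max(float(dt[tuple(pos)]), float(sp.min()))
            cands.append(Seed(point=pos * sp, direction=direction / nrm, radius=r))
        if cands:
            best = int(np.argmax([c.radius for c in cands]))
            seeds.append(cands[best])
    return seeds


class StepForest:
    """Random-forest step validity scorer with bootstrap sample randomization."""

    def __init__(self, config: StepForestConfig):
        self.config = config
        self.model = RandomForestClassifier(
            n_estimators=config.n_trees, bootstrap=config.randomize_samples,
            oob_score=config.randomize_samples, random_state=config.seed, n_jobs=1)
        self.oob_accuracy: float | None = None

    @property
    def n_trees(self) -> int:
        return len(self.model.estimators_)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        proba = self.model.predict_proba(features)
        col = list(self.model.classes_).index(1)
        return proba[:, col]


def train_step_forest(examples, config: StepForestConfig | None = None) -> StepForest:
    """Train the step-validity forest on (StepFeatures, label) pairs.

    Also accepts a pre-built (X, y) array pair.  The returned forest
    carries its out-of-bag accuracy estimate.
    """
    config = config or StepForestConfig()
    if isinstance(examples, tuple) and len(examples) == 2:
        X, y = examples
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
    else:
        X = np.stack([f.vector() for f, _lab in examples])
        y = np.array([int(lab) for _f, lab in examples])
    if len(np.unique(y)) < 2:
        raise ValueError("step-forest training needs both valid and invalid examples")
    forest = StepForest(config)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # oob may be noisy on tiny inputs
        forest.model.fit(X, y)
    if config.randomize_samples and hasattr(forest.model, "oob_score_"):
        forest.oob_accuracy = float(forest.model.oob_score_)
    return forest


def _candidate_directions(prev_axis: np.ndarray, n: int, max_turn_rad: float) -> np.ndarray:
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    dirs = np.vstack([prev_axis, dirs])
    cos = dirs @ prev_axis
    return dirs[cos >= np.cos(max_turn_rad) - 1e-12]


def step(current: Cylinder, prev_axis, mask, original: Volume, forest: StepForest,
         config: TrackingConfig | None = None,
         context: _TraceContext | None = None) -> Cylinder | None:
    """One tracking step: the best forest+energy-scored candidate, or None (STOP).

    Candidates are enumerated over a cone of directions within the turning
    cap and a radius grid around the current radius; each is scored by
    score = p_forest - lambda_E * E with the minimal-path energy
    E = -(mean centerline depth / radius) + lambda_c * f3^2.  The voxels of
    an accepted cylinder are claimed as visited.
    """
    config = config or TrackingConfig()
    ctx = context or _TraceContext(mask, original)
    prev_axis = np.asarray(prev_axis, dtype=float)
    prev_axis = prev_axis / (np.linalg.norm(prev_axis) + 1e-30)
    start = current.end
    sp_min = float(ctx.spacing.min())
    height = config.step_height_voxels * sp_min
    max_turn = np.deg2rad(config.max_turn_deg)

    cands: list[Cylinder] = []
    feats: list[StepFeatures] = []
    energies: list[float] = []
    for d in _candidate_directions(prev_axis, config.n_candidate_directions, max_turn):
        for f in config.radius_factors:
            r = float(np.clip(current.radius * f, 0.5 * sp_min, 10 * sp_min))
            cyl = Cylinder(start.copy(), d.copy(), r, height)
            vox = _cylinder_voxels(ctx, cyl)
            if len(vox) == 0:
                continue
            inmask = ctx.mask[vox[:, 0], vox[:, 1], vox[:, 2]]
            f1 = float(inmask.mean())
            if f1 < config.min_f1:
                continue
            # must claim at least one new vessel voxel (no re-tracing)
            vis = ctx.visited[vox[:, 0], vox[:, 1], vox[:, 2]]
            if not np.any(inmask & ~vis):
                continue
            sf = compute_step_features(cyl, prev_axis, None, None, context=ctx)
            axis_pts = start + np.linspace(0.2, 1.0, 5)[:, None] * (d * height)
            depth = float(ctx.dt_at(axis_pts).mean())
            E = -(depth / max(current.radius, sp_min)) + config.lambda_curvature * sf.f3**2
            cands.append(cyl)
            feats.append(sf)
            energies.append(E)

    if not cands:
        return None
    X = np.stack([f.vector() for f in feats])
    probs = forest.predict_proba(X)
    scores = probs - config.lambda_energy * np.asarray(energies)
    best = int(np.argmax(scores))
    if scores[best] < config.stop_score:
        return None
    chosen = cands[best]

    # recenter the endpoint on the local mask cross-section
    end = chosen.end
    vox = _cylinder_voxels(ctx, Cylinder(start, chosen.axis, max(1.5 * chosen.radius, 2 * sp_min),
                                         chosen.height + sp_min))
    if len(vox):
        inmask = ctx.mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        pts = vox[inmask] * ctx.spacing
        if len(pts):
            ax_off = (pts - end) @ chosen.axis
            slab = pts[np.abs(ax_off) <= sp_min]
            if len(slab):
                new_end = slab.mean(axis=0)
                d = new_end - start
                nrm = np.linalg.norm(d)
                if nrm > 0.3 * height:
                    d = d / nrm
                    if np.arccos(np.clip(d @ prev_axis, -1, 1)) <= max_turn:
                        chosen = Cylinder(start, d, chosen.radius, float(nrm))

    r_local = float(ctx.dt_at(chosen.end[None])[0])
    radius = float(np.clip(r_local if r_local > 0 else chosen.radius,
                           0.5 * sp_min, 2.0 * current.radius + sp_min))
    chosen = Cylinder(chosen.base, chosen.axis, radius, chosen.height)

    claim = _cylinder_voxels(ctx, chosen)
    if len(claim):
        ctx.visited[claim[:, 0], claim[:, 1], claim[:, 2]] = True
    return chosen


def _shell_components(mask, sp, point, R, th):
    """Directions and centroids (mm) of mask components on one spherical shell."""
    lo = np.clip(np.floor((point - R - th) / sp).astype(int), 0, np.asarray(mask.shape))
    hi = np.clip(np.ceil((point + R + th) / sp).astype(int) + 1, 0, np.asarray(mask.shape))
    if np.any(lo >= hi):
        return []
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    idx = np.stack(grids, axis=-1)
    dist = np.linalg.norm(idx * sp - point, axis=-1)
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    shell = sub & (np.abs(dist - R) <= th / 2 + 1e-12)
    labels, n = ndimage.label(shell, structure=np.ones((3, 3, 3)))
    out = []
    for comp in range(1, n + 1):
        cidx = np.argwhere(labels == comp) + lo
        if len(cidx) < 3:        # tangential shell-surface fragments
            continue
        centroid = cidx.mean(axis=0) * sp
        d = centroid - point
        nrm = np.linalg.norm(d)
        if nrm > 0:
            out.append((d / nrm, centroid, len(cidx)))
    return out


def detect_bifurcation(point, radius, mask, spacing=(1.0, 1.0, 1.0),
                       incoming_axis=None, config: TrackingConfig | None = None):
    """Child directions at `point` from the spherical-shell component test.

    A shell of radius ``shell_factor x radius`` is intersected with the
    mask; 26-connected components on the shell give one direction each
    (component centroid minus point).  Because children leaving a junction
    at a narrow angle can merge on a tight shell, the shell radius is
    scanned over ``shell_scan`` multipliers and the scale resolving the
    most components wins.  When ``incoming_axis`` is given, the component
    best aligned with the backward direction is removed, so a mid-vessel
    point yields a single continuation, an endpoint none, and a junction
    two or more.
    """
    dirs, _R = _detect_bifurcation_full(point, radius, mask, spacing, incoming_axis, config)
    return dirs


def _detect_bifurcation_full(point, radius, mask, spacing, incoming_axis,
                             config: TrackingConfig | None):
    config = config or TrackingConfig()
    mask = np.asarray(mask) != 0
    sp = np.asarray(spacing, dtype=float)
    point = np.asarray(point, dtype=float)
    th = max(config.shell_thickness_voxels * sp.min(), 1.2 * sp.min())
    best: list = []
    best_R = max(config.shell_scan[0] * config.shell_factor * radius, 2.0 * sp.min())
    for mult in config.shell_scan:
        R = max(mult * config.shell_factor * radius, 2.0 * sp.min())
        comps = _shell_components(mask, sp, point, R, th)
        if incoming_axis is not None and comps:
            back = -np.asarray(incoming_axis, dtype=float)
            back = back / (np.linalg.norm(back) + 1e-30)
            drop = int(np.argmax([d @ back for d, _c, _s in comps]))
            if comps[drop][0] @ back > np.cos(np.deg2rad(100.0)):
                comps = [c for i, c in enumerate(comps) if i != drop]
        # merge near-parallel directions (a grazing shell can split one
        # vessel into fragments); keep the largest component per cluster
        comps = sorted(comps, key=lambda c: -c[2])
        dirs: list[np.ndarray] = []
        for d, _c, _s in comps:
            if all(float(d @ e) < np.cos(np.deg2rad(30.0)) for e in dirs):
                dirs.append(d)
        if len(dirs) > len(best):
            best = dirs
            best_R = R
    return best, best_R


def _refine_junction(point, incoming_axis, radius, mask, spacing,
                     config: TrackingConfig, R_resolved: float | None = None) -> np.ndarray:
    """Least-squares junction estimate from stem and child centerline lines.

    Shell-component centroids at two radii give a point and direction per
    outgoing child; the junction is the point minimizing the summed squared
    distance to the stem line and all child lines.  ``R_resolved`` should
    be the shell radius at which the children were actually separated.
    """
    mask = np.asarray(mask) != 0
    sp = np.asarray(spacing, dtype=float)
    point = np.asarray(point, dtype=float)
    th = max(config.shell_thickness_voxels * sp.min(), 1.2 * sp.min())
    R1 = R_resolved if R_resolved is not None else max(config.shell_factor * radius, 2.0 * sp.min())
    R2 = 1.4 * R1
    c1 = _shell_components(mask, sp, point, R1, th)
    c2 = _shell_components(mask, sp, point, R2, th)
    lines = [(point, np.asarray(incoming_axis, dtype=float))]
    for d1, p1, _s1 in c1:
        if len(c2):
            dots = [d1 @ d2 for d2, _p, _s in c2]
            k = int(np.argmax(dots))
            if dots[k] > 0.7:
                u = c2[k][1] - p1
                nrm = np.linalg.norm(u)
                if nrm > 1e-9:
                    lines.append((p1, u / nrm))
                    continue
        lines.append((p1, d1))
    A = np.zeros((3, 3))
    rhs = np.zeros(3)
    for p, u in lines:
        u = u / (np.linalg.norm(u) + 1e-30)
        P = np.eye(3) - np.outer(u, u)
        A += P
        rhs += P @ p
    try:
        x = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        return point
    if np.linalg.norm(x - point) > 2.0 * R2:
        return point
    return x


def trace_tree(seeds, mask, original: Volume, forest: StepForest,
               config: TrackingConfig | None = None) -> list[BranchTrack]:
    """Breadth-first tracing from seeds, spawning children at bifurcations.

    A branch terminates on STOP or when the spherical-shell test reports
    two or more outgoing components, in which case each child direction is
    traced as a new branch of order parent + 1.  Visited-voxel claiming
    limits re-tracing and guarantees termination.
    """
    config = config or TrackingConfig()
    ctx = _TraceContext(mask, original)
    sp_min = float(ctx.spacing.min())
    branches: list[BranchTrack] = []
    junctions: list[np.ndarray] = []
    queue: list[tuple] = [(np.asarray(s.point, float), np.asarray(s.direction, float),
                           float(s.radius), None, 1, "seed") for s in seeds]
    qi = 0
    while qi < len(queue) and len(branches) < config.max_branches:
        point, direction, radius, parent, order, prov = queue[qi]
        qi += 1
        radius = float(np.clip(radius, 0.5 * sp_min, 10 * sp_min))
        cur = Cylinder(point - direction * 1e-6, direction, radius, 1e-6)
        points = [point.copy()]
        radii = [radius]
        prev_axis = direction
        spawned: list[tuple] = []
        stopped_at_tip = False
        for _ in range(config.max_steps):
            nxt = step(cur, prev_axis, None, None, forest, config, context=ctx)
            if nxt is None:
                stopped_at_tip = True
                break
            points.append(nxt.end.copy())
            radii.append(nxt.radius)
            kids, R_used = _detect_bifurcation_full(nxt.end, nxt.radius, ctx.mask,
                                                    tuple(ctx.spacing), nxt.axis, config)
            if len(kids) >= 2:
                stem_dir = nxt.axis
                if len(points) >= 3:
                    d = points[-1] - points[-3]
                    nrm = np.linalg.norm(d)
                    if nrm > 0:
                        stem_dir = d / nrm
                jpt = _refine_junction(nxt.end, stem_dir, nxt.radius, ctx.mask,
                                       tuple(ctx.spacing), config, R_resolved=R_used)
                # child directions are sharper when measured from the junction
                kids2, _R2 = _detect_bifurcation_full(jpt, nxt.radius, ctx.mask,
                                                      tuple(ctx.spacing), stem_dir, config)
                if len(kids2) >= 2:
                    kids = kids2
                # a junction seen once must not re-trigger from its children:
                # the dedupe radius scales with the largest scanning shell
                merge_r = max(config.junction_merge_voxels * sp_min,
                              max(config.shell_scan) * config.shell_factor * nxt.radius)
                jnear = any(np.linalg.norm(jpt - j) < merge_r for j in junctions)
                if not jnear:
                    junctions.append(jpt.copy())
                    points[-1] = jpt
                    for d in kids:
                        spawned.append((jpt.copy(), d, nxt.radius,
                                        len(points) - 1, order + 1))
                    break
            cur = nxt
            prev_axis = nxt.axis
        if stopped_at_tip and len(points) >= 3:
            # steps can overrun into the rounded end cap, where the inscribed
            # radius collapses; trim trailing points that sank below it
            r_med = float(np.median(radii))
            while len(points) > 2 and ctx.dt_at(points[-1][None])[0] < 0.6 * r_med:
                points.pop()
                radii.pop()
        if len(points) >= 3:
            # damp sub-voxel zigzag from the discrete direction grid
            pts = np.asarray(points)
            pts[1:-1] = 0.25 * pts[:-2] + 0.5 * pts[1:-1] + 0.25 * pts[2:]
            points = [p for p in pts]
        if len(points) >= 2:
            bid = len(branches)
            branches.append(BranchTrack(points=np.asarray(points), radii=np.asarray(radii),
                                        parent=parent, order=order, provenance=prov))
            for (pt, d, r, pidx, o) in spawned:
                queue.append((pt, d, r, (bid, pidx), o, "bifurcation"))
    return branches


# ---------------------------------------------------------------------------
# training-data synthesis for the step forest

def make_step_training_data(volume: Volume, gt, n_valid: int = 500, n_invalid: int = 500,
                            seed: int = 0, config: TrackingConfig | None = None):
    """Labeled step examples from a phantom: on-axis steps vs off-vessel/misaligned.

    Valid examples are cylinders riding the ground-truth centerline with
    the local tangent; invalid ones are random off-vessel cylinders and
    on-vessel cylinders with strongly misaligned axes.  Returns (X, y).
    """
    config = config or TrackingConfig()
    rng = np.random.default_rng(seed)
    ctx = _TraceContext(gt.mask, volume)
    sp_min = float(ctx.spacing.min())
    height = config.step_height_voxels * sp_min
    ext = (np.asarray(volume.shape) - 1) * ctx.spacing

    cl = gt.all_centerline_points()
    tangents = []
    for pts in gt.centerlines:
        g = np.gradient(pts, axis=0)
        g /= np.linalg.norm(g, axis=1, keepdims=True) + 1e-30
        tangents.append(g)
    tangents = np.concatenate(tangents, axis=0)
    rads = np.concatenate(gt.radii)

    X, y = [], []
    n_cl = len(cl)
    while sum(y) < n_valid:
        i = int(rng.integers(n_cl))
        t = tangents[i]
        jitter = rng.normal(0, 0.15, 3)
        ax = t + jitter
        ax /= np.linalg.norm(ax)
        base = cl[i] - ax * height * rng.uniform(0.3, 0.7)
        r = rads[i] * rng.uniform(0.8, 1.2)
        try:
            f = compute_step_features(Cylinder(base, ax, r, height), t, None, None, context=ctx)
        except ValueError:
            continue
        X.append(f.vector())
        y.append(1)

    n_bad = 0
    while n_bad < n_invalid:
        mode = rng.integers(3)
        if mode == 0:       # random off-vessel cylinder
            base = rng.uniform(0, 1, 3) * ext
            ax = rng.normal(0, 1, 3)
            ax /= np.linalg.norm(ax)
            prev = ax
            r = rng.uniform(1, 4) * sp_min
        elif mode == 1:     # on vessel but sharply misaligned
            i = int(rng.integers(n_cl))
            t = tangents[i]
            ax = rng.normal(0, 1, 3)
            ax -= (ax @ t) * t          # near-perpendicular axis
            ax /= np.linalg.norm(ax) + 1e-30
            base = cl[i]
            prev = t
            r = rads[i]
        else:               # stepping off the vessel end into background
            i = int(rng.integers(n_cl))
            t = tangents[i]
            base = cl[i] + t * rng.uniform(2, 6) * height
            base = np.clip(base, 0, ext)
            ax = t
            prev = t
            r = rads[i]
        try:
            f = compute_step_features(Cylinder(base, ax, r, height), prev, None, None, context=ctx)
        except ValueError:
            continue
        if f.f1 > 0.8 and f.f3 < 0.3:   # accidentally a genuinely valid step
            continue
        X.append(f.vector())
        y.append(0)
        n_bad += 1
    return np.asarray(X), np.asarray(y)
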