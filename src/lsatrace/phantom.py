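"""Synthetic vascular phantoms with exact ground truth.

Generates 3D volumes that emulate the statistical structure of high-field
TOF-MRA around small perforating arteries: bright tubes of 0.2-1.5 mm
diameter on a darker noisy background, optionally with a smooth
multiplicative bias field and a very bright "large vessel".  Every phantom
carries exact ground truth (binary mask, per-tube centerlines, per-point
radii, bifurcation points, branch orders), so downstream segmentation,
tracking, screening and morphometry can all be trained and scored without
patient data.

Intensities are rendered directly on the standardized 0-255 scale
(background 60, small tubes 100, large vessel 200 by default) so that the
pre-screen interval (80, 120) is meaningful on synthetic volumes.  Voxels
are labeled vessel by the hard center-in rule (voxel center within the
interpolated tube radius); rendered intensity is antialiased by
supersampling (default 2x per axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.spatial import cKDTree

from .volume import Volume

__all__ = [
    "TubeSpec", "PhantomSpec", "GroundTruth", "PatchDataset",
    "render_phantom", "make_training_patches", "hemisphere_directions",
    "direction_bin", "make_straight_tube_phantom", "make_y_phantom",
    "make_tree_phantom", "make_training_phantoms", "make_large_vessel_phantom",
]

BACKGROUND_LEVEL = 60.0
SMALL_TUBE_LEVEL = 100.0
LARGE_VESSEL_LEVEL = 200.0


@dataclass
class TubeSpec:
    """One tube: a centerline polyline (mm) with a radius profile (mm)."""

    control_points: np.ndarray          # (k, 3) mm
    radius_profile: np.ndarray          # (k,) mm, may taper
    intensity: float = SMALL_TUBE_LEVEL  # on the standardized 0-255 scale

    def __post_init__(self) -> None:
        self.control_points = np.atleast_2d(np.asarray(self.control_points, dtype=float))
        self.radius_profile = np.atleast_1d(np.asarray(self.radius_profile, dtype=float))
        if self.radius_profile.size == 1:
            self.radius_profile = np.full(len(self.control_points), self.radius_profile[0])
        if len(self.control_points) < 2:
            raise ValueError("TubeSpec needs at least 2 control points")
        if len(self.radius_profile) != len(self.control_points):
            raise ValueError("radius_profile length must match control_points")
        if np.any(self.radius_profile <= 0):
            raise ValueError("all radii must be > 0")
        if not 0.0 <= self.intensity <= 255.0:
            raise ValueError("intensity must lie in [0, 255]")


@dataclass
class PhantomSpec:
    """Full description of a synthetic volume; rendering is seeded and pure."""

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    tubes: list[TubeSpec] = field(default_factory=list)
    tree_topology: list[int | None] = field(default_factory=list)  # parent tube index per tube
    background_level: float = BACKGROUND_LEVEL
    noise_sd: float = 0.0
    bias_field: dict[tuple[int, int, int], float] | None = None  # polynomial coeffs on [-1,1]^3
    large_vessel: TubeSpec | None = None
    seed: int = 0
    supersample: int = 2

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.tree_topology:
            self.tree_topology = [None] * len(self.tubes)
        if len(self.tree_topology) != len(self.tubes):
            raise ValueError("tree_topology must have one entry per tube")
        for t in self.tubes:
            if self.background_level >= t.intensity:
                raise ValueError("background_level must be below tube intensities")


@dataclass
class GroundTruth:
    """Exact labels exported with each phantom."""

    mask: np.ndarray                       # uint8, small-vessel voxels
    large_vessel_mask: np.ndarray          # uint8
    centerlines: list[np.ndarray]          # per tube, (n, 3) mm
    radii: list[np.ndarray]                # per tube, (n,) mm
    bifurcation_points: np.ndarray         # (m, 3) mm
    branch_orders: list[int]               # per tube, 1-based generation

    def all_centerline_points(self) -> np.ndarray:
        if not self.centerlines:
            return np.zeros((0, 3))
        return np.concatenate(self.centerlines, axis=0)


# ---------------------------------------------------------------------------
# rendering

def _densify(tube: TubeSpec, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample the control polyline at roughly `step` mm spacing."""
    pts, rads = [], []
    cp, rp = tube.control_points, tube.radius_profile
    for i in range(len(cp) - 1):
        seg = cp[i + 1] - cp[i]
        n = max(int(np.ceil(np.linalg.norm(seg) / step)), 1)
        ts = np.arange(n) / n
        pts.append(cp[i] + ts[:, None] * seg)
        rads.append(rp[i] + ts * (rp[i + 1] - rp[i]))
    pts.append(cp[-1:])
    rads.append(rp[-1:])
    return np.concatenate(pts), np.concatenate(rads)


def _segment_bbox(shape, spacing, p0, p1, pad_mm):
    lo = np.floor((np.minimum(p0, p1) - pad_mm) / spacing).astype(int)
    hi = np.ceil((np.maximum(p0, p1) + pad_mm) / spacing).astype(int) + 1
    lo = np.clip(lo, 0, np.asarray(shape))
    hi = np.clip(hi, 0, np.asarray(shape))
    return lo, hi


def _capsule_occupancy(shape, spacing, tube: TubeSpec, offsets_mm: np.ndarray) -> np.ndarray:
    """Fraction of supersample points inside the tube, per voxel (float32).

    `offsets_mm` is (s, 3): sub-voxel sample offsets; with a single zero
    offset this is the exact hard center-in test.
    """
    spacing = np.asarray(spacing, dtype=float)
    occ = np.zeros(shape, dtype=np.float32)
    cp, rp = tube.control_points, tube.radius_profile
    nss = len(offsets_mm)
    for i in range(len(cp) - 1):
        p0, p1 = cp[i], cp[i + 1]
        r0, r1 = rp[i], rp[i + 1]
        pad = max(r0, r1) + spacing.max()
        lo, hi = _segment_bbox(shape, spacing, p0, p1, pad)
        if np.any(lo >= hi):
            continue
        ix, iy, iz = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
        centers = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3) * spacing
        d = p1 - p0
        dd = float(d @ d)
        count = np.zeros(len(centers), dtype=np.int32)
        for off in offsets_mm:
            x = centers + off
            t = np.clip((x - p0) @ d / dd, 0.0, 1.0) if dd > 0 else np.zeros(len(x))
            closest = p0 + t[:, None] * d
            dist = np.linalg.norm(x - closest, axis=1)
            rad = r0 + t * (r1 - r0)
            count += (dist <= rad + 1e-12)
        frac = (count / nss).astype(np.float32).reshape(ix.shape)
        sl = tuple(slice(lo[a], hi[a]) for a in range(3))
        occ[sl] = np.maximum(occ[sl], frac)
    return occ


def _bias_field_grid(shape, coeffs) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    u, v, w = np.meshgrid(*axes, indexing="ij")
    fieldv = np.zeros(shape, dtype=float)
    for (i, j, k), c in coeffs.items():
        fieldv += c * u**i * v**j * w**k
    return fieldv


def render_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Render a phantom volume and its exact ground truth.

    The binary ground-truth mask uses the hard center-in rule; intensity is
    antialiased by supersampling, multiplied by the bias field (if any) and
    perturbed with additive Gaussian noise.  Identical spec + seed give
    bit-identical output.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent_lo = -0.5 * spacing
    extent_hi = (np.asarray(shape) - 0.5) * spacing

    all_tubes = list(spec.tubes) + ([spec.large_vessel] if spec.large_vessel else [])
    for t in all_tubes:
        dense, _ = _densify(t, spacing.min() / 2)
        inside = np.all((dense >= extent_lo) & (dense <= extent_hi), axis=1)
        if not inside.any():
            raise ValueError("tube extends fully outside the grid; rejecting spec")

    ss = max(int(spec.supersample), 1)
    offs_1d = ((np.arange(ss) + 0.5) / ss - 0.5)
    offsets = np.array(list(product(offs_1d, offs_1d, offs_1d))) * spacing
    center_only = np.zeros((1, 3))

    intensity = np.full(shape, float(spec.background_level))
    mask = np.zeros(shape, dtype=np.uint8)
    lv_mask = np.zeros(shape, dtype=np.uint8)

    for t in spec.tubes:
        hard = _capsule_occupancy(shape, spacing, t, center_only) >= 1.0
        mask |= hard.astype(np.uint8)
        occ = _capsule_occupancy(shape, spacing, t, offsets) if ss > 1 else hard.astype(np.float32)
        intensity = np.maximum(intensity, spec.background_level + occ * (t.intensity - spec.background_level))
    if spec.large_vessel is not None:
        t = spec.large_vessel
        hard = _capsule_occupancy(shape, spacing, t, center_only) >= 1.0
        lv_mask |= hard.astype(np.uint8)
        occ = _capsule_occupancy(shape, spacing, t, offsets) if ss > 1 else hard.astype(np.float32)
        intensity = np.maximum(intensity, spec.background_level + occ * (t.intensity - spec.background_level))

    scale = "standardized"
    if spec.bias_field:
        fieldv = _bias_field_grid(shape, spec.bias_field)
        if fieldv.min() <= 0:
            raise ValueError("bias field must be strictly positive over the grid")
        intensity = intensity * fieldv
        scale = "raw"
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=shape)

    step = spacing.min() / 2
    centerlines, radii = [], []
    for t in spec.tubes:
        pts, rads = _densify(t, step)
        centerlines.append(pts)
        radii.append(rads)

    orders = _branch_orders(spec.tree_topology)
    bifs = [spec.tubes[i].control_points[0]
            for i, parent in enumerate(spec.tree_topology) if parent is not None]
    gt = GroundTruth(
        mask=mask, large_vessel_mask=lv_mask, centerlines=centerlines, radii=radii,
        bifurcation_points=np.asarray(bifs).reshape(-1, 3), branch_orders=orders,
    )
    vol = Volume(data=intensity, spacing=tuple(spacing), intensity_scale=scale)
    return vol, gt


def _branch_orders(topology) -> list[int]:
    orders: list[int] = [0] * len(topology)

    def order_of(i: int) -> int:
        if orders[i]:
            return orders[i]
        p = topology[i]
        orders[i] = 1 if p is None else order_of(p) + 1
        return orders[i]

    for i in range(len(topology)):
        order_of(i)
    return orders


# ---------------------------------------------------------------------------
# direction binning (positive-patch orientation coverage)

def hemisphere_directions(n: int) -> np.ndarray:
    """`n` roughly uniform unit directions on the upper hemisphere (Fibonacci)."""
    k = np.arange(n)
    z = (k + 0.5) / n                      # upper hemisphere only
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _canonical(v: np.ndarray) -> np.ndarray:
    v = v / (np.linalg.norm(v, axis=-1, keepdims=True) + 1e-30)
    sign = np.where(v[..., 2] != 0, np.sign(v[..., 2]),
                    np.where(v[..., 1] != 0, np.sign(v[..., 1]), np.sign(v[..., 0] + 1e-30)))
    return v * sign[..., None]


def direction_bin(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign direction(s) to one of `n_bins` hemisphere reference bins."""
    refs = hemisphere_directions(n_bins)
    v = _canonical(np.atleast_2d(np.asarray(v, dtype=float)))
    return np.argmax(np.abs(v @ refs.T), axis=1)


# ---------------------------------------------------------------------------
# training patches

@dataclass
class PatchDataset:
    """Cubic patches with center-voxel vessel labels and a train/test split."""

    patches: np.ndarray       # (N, s, s, s) float32 in [0, 1]
    labels: np.ndarray        # (N,) uint8, 1 = center voxel is vessel
    train: np.ndarray         # (N,) bool
    norm_min: float
    norm_max: float
    directions: np.ndarray    # (N, 3) local tube direction for positives, nan otherwise
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.labels) != len(self.patches):
            raise ValueError("labels must match patches")
        if not self.norm_min < self.norm_max:
            raise ValueError("norm_min must be < norm_max")

    @property
    def n_train(self) -> int:
        return int(self.train.sum())

    @property
    def n_test(self) -> int:
        return int((~self.train).sum())

    def direction_bin_count(self, n_bins: int) -> int:
        pos = self.labels == 1
        if not pos.any():
            return 0
        return len(np.unique(direction_bin(self.directions[pos], n_bins)))


def _extract_raw_patch(data: np.ndarray, center: np.ndarray, size: int) -> np.ndarray:
    """Cube around `center` with edge replication outside the grid."""
    h = size // 2
    idx = []
    for a in range(3):
        r = np.clip(np.arange(center[a] - h, center[a] + h + 1), 0, data.shape[a] - 1)
        idx.append(r)
    return data[np.ix_(*idx)]


def make_training_patches(volumes, n_pos: int, n_neg: int, patch_size: int = 25,
                          n_orientations: int = 18, split_ratio: float = 0.8,
                          seed: int = 0, stride: int = 1,
                          interval: tuple[float, float] = (80.0, 120.0),
                          neg_mode: str = "interval",
                          pos_mode: str = "all") -> PatchDataset:
    """Sample labeled center-voxel patches from phantoms.

    Positives are centered on ground-truth vessel voxels (with the local
    tube direction recorded).  Negatives depend on ``neg_mode``:
    ``"interval"`` (default) takes non-vessel voxels whose intensity falls
    strictly inside the pre-screen interval -- exactly the voxels the
    classifier will be asked about at inference time; ``"background"``
    takes flat-noise voxels at least 2 voxels away from any vessel.
    ``pos_mode="core"`` restricts positives to voxels at least one voxel
    inside the vessel surface; combined with ``neg_mode="background"``
    this yields a cleanly separable bright-tube-vs-flat-noise dataset.
    The dataset is split train:test by ``split_ratio`` per class, and
    patch normalization bounds are the min/max over the training split.
    """
    if patch_size % 2 == 0:
        raise ValueError("patch_size must be odd")
    if neg_mode not in ("interval", "background"):
        raise ValueError(f"unknown neg_mode {neg_mode!r}")
    if pos_mode not in ("all", "core"):
        raise ValueError(f"unknown pos_mode {pos_mode!r}")
    rng = np.random.default_rng(seed)
    t_bg, t_v = interval

    pos_centers, pos_dirs, pos_vol = [], [], []
    neg_centers, neg_vol = [], []
    trees = []
    for vi, (vol, gt) in enumerate(volumes):
        cl = gt.all_centerline_points()
        tree = cKDTree(cl) if len(cl) else None
        tangents = _centerline_tangents(gt)
        trees.append((tree, tangents))
        pos_region = gt.mask > 0
        if pos_mode == "core":
            from scipy import ndimage as _ndi
            core = _ndi.binary_erosion(pos_region, np.ones((3, 3, 3), bool))
            if core.any():
                pos_region = core
        pidx = np.argwhere(pos_region)
        if stride > 1:
            pidx = pidx[::stride]
        for c in pidx:
            pos_centers.append(c)
            pos_vol.append(vi)
        if tree is not None and len(pidx):
            pts_mm = pidx * np.asarray(vol.spacing)
            _, nn = tree.query(pts_mm)
            pos_dirs.extend(tangents[nn])
        vessel_free = (gt.mask == 0) & (gt.large_vessel_mask == 0)
        if neg_mode == "interval":
            inside = (vol.data > t_bg) & (vol.data < t_v) & vessel_free
        else:
            from scipy import ndimage as _ndi
            far = ~_ndi.binary_dilation(gt.mask | gt.large_vessel_mask,
                                        np.ones((5, 5, 5), bool))
            inside = vessel_free & far
        nidx = np.argwhere(inside)
        if stride > 1:
            nidx = nidx[::stride]
        for c in nidx:
            neg_centers.append(c)
            neg_vol.append(vi)

    if n_pos > len(pos_centers):
        raise ValueError(f"requested {n_pos} positives but only {len(pos_centers)} available")
    if n_neg > len(neg_centers):
        raise ValueError(f"requested {n_neg} negatives but only {len(neg_centers)} available")

    flags = []
    if n_pos == 0:
        flags.append("negatives-only dataset")

    sel_pos = rng.choice(len(pos_centers), size=n_pos, replace=False) if n_pos else np.array([], int)
    sel_neg = rng.choice(len(neg_centers), size=n_neg, replace=False) if n_neg else np.array([], int)

    centers = [np.asarray(pos_centers[i]) for i in sel_pos] + [np.asarray(neg_centers[i]) for i in sel_neg]
    vols_of = [pos_vol[i] for i in sel_pos] + [neg_vol[i] for i in sel_neg]
    labels = np.array([1] * len(sel_pos) + [0] * len(sel_neg), dtype=np.uint8)
    dirs = np.full((len(labels), 3), np.nan)
    for row, i in enumerate(sel_pos):
        dirs[row] = pos_dirs[i]

    raw = np.stack([
        _extract_raw_patch(volumes[vols_of[i]][0].data, centers[i], patch_size)
        for i in range(len(centers))
    ]).astype(np.float32) if len(centers) else np.zeros((0, patch_size, patch_size, patch_size), np.float32)

    # stratified train/test split
    train = np.zeros(len(labels), dtype=bool)
    for lab in (0, 1):
        idx = np.flatnonzero(labels == lab)
        perm = rng.permutation(idx)
        n_tr = int(round(len(idx) * split_ratio))
        train[perm[:n_tr]] = True

    if train.any():
        norm_min = float(raw[train].min())
        norm_max = float(raw[train].max())
    elif len(raw):
        norm_min, norm_max = float(raw.min()), float(raw.max())
    else:
        norm_min, norm_max = 0.0, 1.0
    if norm_max <= norm_min:
        norm_max = norm_min + 1.0
        flags.append("degenerate normalization range")
    patches = np.clip((raw - norm_min) / (norm_max - norm_min), 0.0, 1.0)

    return PatchDataset(patches=patches, labels=labels, train=train,
                        norm_min=norm_min, norm_max=norm_max, directions=dirs, flags=flags)


def merge_patch_datasets(a: PatchDataset, b: PatchDataset) -> PatchDataset:
    """Concatenate two datasets on `a`'s normalization bounds."""
    raw_b = b.patches * (b.norm_max - b.norm_min) + b.norm_min
    bn = np.clip((raw_b - a.norm_min) / (a.norm_max - a.norm_min), 0.0, 1.0)
    return PatchDataset(
        patches=np.concatenate([a.patches, bn.astype(a.patches.dtype)]),
        labels=np.concatenate([a.labels, b.labels]),
        train=np.concatenate([a.train, b.train]),
        norm_min=a.norm_min, norm_max=a.norm_max,
        directions=np.concatenate([a.directions, b.directions]),
        flags=sorted(set(a.flags) | set(b.flags)))


def _centerline_tangents(gt: GroundTruth) -> np.ndarray:
    tans = []
    for pts in gt.centerlines:
        if len(pts) < 2:
            tans.append(np.zeros((len(pts), 3)))
            continue
        g = np.gradient(pts, axis=0)
        g /= np.linalg.norm(g, axis=1, keepdims=True) + 1e-30
        tans.append(g)
    if not tans:
        return np.zeros((0, 3))
    return np.concatenate(tans, axis=0)


# ---------------------------------------------------------------------------
# ready-made phantom builders (the package's study conditions)

def make_straight_tube_phantom(radius: float = 0.3, spacing: float = 0.1,
                               shape=(40, 40, 40), axis: int = 2,
                               intensity: float = SMALL_TUBE_LEVEL,
                               noise_sd: float = 0.0, seed: int = 0,
                               margin: int = 4) -> PhantomSpec:
    """A single axis-aligned straight tube through the grid center."""
    shape = tuple(shape)
    center = (np.asarray(shape) - 1) / 2 * spacing
    p0, p1 = center.copy(), center.copy()
    p0[axis] = margin * spacing
    p1[axis] = (shape[axis] - 1 - margin) * spacing
    tube = TubeSpec(np.stack([p0, p1]), np.array([radius, radius]), intensity)
    return PhantomSpec(grid_shape=shape, spacing=(spacing,) * 3, tubes=[tube],
                       noise_sd=noise_sd, seed=seed)


def make_y_phantom(spacing: float = 0.1, shape=(60, 60, 60), radius: float = 0.3,
                   child_radius: float = 0.22, branch_angle_deg: float = 40.0,
                   noise_sd: float = 0.0, seed: int = 0) -> PhantomSpec:
    """One bifurcation: a stem splitting into two children (Y junction)."""
    shape = tuple(shape)
    ext = (np.asarray(shape) - 1) * spacing
    start = np.array([ext[0] / 2, ext[1] / 2, 3 * spacing])
    junction = np.array([ext[0] / 2, ext[1] / 2, ext[2] * 0.45])
    stem = TubeSpec(np.stack([start, junction]), np.array([radius, radius]))
    ang = np.deg2rad(branch_angle_deg)
    length = ext[2] * 0.45
    kids = []
    for s in (+1, -1):
        d = np.array([s * np.sin(ang), 0.0, np.cos(ang)])
        end = junction + d * length
        end = np.clip(end, 2 * spacing, ext - 2 * spacing)
        kids.append(TubeSpec(np.stack([junction, end]), np.array([child_radius, child_radius])))
    return PhantomSpec(grid_shape=shape, spacing=(spacing,) * 3,
                       tubes=[stem] + kids, tree_topology=[None, 0, 0],
                       noise_sd=noise_sd, seed=seed)


def make_tree_phantom(seed: int = 0, spacing: float = 0.1, shape=(72, 72, 72),
                      n_levels: int = 2, root_radius: float = 0.45,
                      taper: float = 0.75, noise_sd: float = 0.0) -> PhantomSpec:
    """A branching tree with `n_levels` bifurcation levels.

    Branching angles are drawn uniformly from 30-70 degrees per seed; child
    radii taper by `taper` per generation, staying within the 0.1-0.75 mm
    radius range typical of the target vessels.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    ext = (np.asarray(shape) - 1) * spacing
    lo, hi = 3 * spacing, ext - 3 * spacing

    tubes: list[TubeSpec] = []
    topology: list[int | None] = []

    def grow(start, direction, radius, level, parent):
        length = (0.40 - 0.06 * level) * ext.mean()
        end = np.clip(start + direction * length, lo, hi)
        tubes.append(TubeSpec(np.stack([start, end]),
                              np.array([radius, max(radius * 0.9, 0.1)])))
        topology.append(parent)
        me = len(tubes) - 1
        if level < n_levels:
            # orthonormal frame around the parent direction
            a = np.array([1.0, 0.0, 0.0])
            if abs(direction @ a) > 0.9:
                a = np.array([0.0, 1.0, 0.0])
            u = np.cross(direction, a)
            u /= np.linalg.norm(u)
            v = np.cross(direction, u)
            phi0 = rng.uniform(0, 2 * np.pi)
            for s in range(2):
                ang = np.deg2rad(rng.uniform(30.0, 70.0))
                phi = phi0 + s * np.pi + rng.uniform(-0.4, 0.4)
                d = (np.cos(ang) * direction
                     + np.sin(ang) * (np.cos(phi) * u + np.sin(phi) * v))
                d /= np.linalg.norm(d)
                grow(end, d, max(radius * taper, 0.12), level + 1, me)

    root_dir = np.array([0.15, 0.1, 1.0])
    root_dir /= np.linalg.norm(root_dir)
    start = np.array([ext[0] * 0.5, ext[1] * 0.5, 3 * spacing])
    grow(start, root_dir, root_radius, 0, None)
    return PhantomSpec(grid_shape=shape, spacing=(spacing,) * 3, tubes=tubes,
                       tree_topology=topology, noise_sd=noise_sd, seed=seed)


def make_training_phantoms(seed: int = 0, n_orientations: int = 18,
                           spacing: float = 0.1, shape=(48, 48, 48),
                           radius_range=(0.2, 0.45), noise_sd: float = 10.0,
                           tubes_per_volume: int = 3):
    """Phantoms whose tubes span >= `n_orientations` hemisphere directions.

    Returns a list of (Volume, GroundTruth) suitable for
    :func:`make_training_patches`; background noise populates the
    pre-screen interval so negative patches exist.
    """
    rng = np.random.default_rng(seed)
    dirs = hemisphere_directions(n_orientations)
    out = []
    shape = np.asarray(shape)
    ext = (shape - 1) * spacing
    center = ext / 2
    half_len = 0.38 * ext.min()
    for start in range(0, n_orientations, tubes_per_volume):
        batch = dirs[start:start + tubes_per_volume]
        tubes = []
        for d in batch:
            r = rng.uniform(*radius_range)
            jitter = rng.uniform(-0.05, 0.05, 3) * ext
            c = center + jitter
            tubes.append(TubeSpec(np.stack([c - d * half_len, c + d * half_len]),
                                  np.array([r, r])))
        spec = PhantomSpec(grid_shape=tuple(int(n) for n in shape),
                           spacing=(spacing,) * 3, tubes=tubes,
                           noise_sd=noise_sd, seed=int(rng.integers(2**31 - 1)))
        out.append(render_phantom(spec))
    return out


def make_large_vessel_phantom(seed: int = 0, spacing: float = 0.1, shape=(64, 64, 64),
                              small_radius: float = 0.3, large_radius: float = 0.8,
                              noise_sd: float = 0.0) -> PhantomSpec:
    """A bright large vessel with one small tube branching off its wall."""
    shape = tuple(shape)
    ext = (np.asarray(shape) - 1) * spacing
    lv_x = ext[0] * 0.2
    lv = TubeSpec(np.array([[lv_x, ext[1] / 2, 2 * spacing],
                            [lv_x, ext[1] / 2, ext[2] - 2 * spacing]]),
                  np.array([large_radius, large_radius]), LARGE_VESSEL_LEVEL)
    start = np.array([lv_x + large_radius * 0.5, ext[1] / 2, ext[2] * 0.5])
    end = np.array([ext[0] - 3 * spacing, ext[1] / 2, ext[2] * 0.62])
    small = TubeSpec(np.stack([start, end]), np.array([small_radius, small_radius]))
    return PhantomSpec(grid_shape=shape, spacing=(spacing,) * 3, tubes=[small],
                       large_vessel=lv, noise_sd=noise_sd, seed=seed)
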