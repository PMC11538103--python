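"""Branch screening: removal of duplicated, artifactual, and noise branches.

Iterative tracking produces false-positive branches from three failure
modes: repeated tracking of the same vessel, pulsation-artifact structures
hugging the large vessels, and scattered noise producing short or poorly
supported connections.  Screening applies one rule-based filter per mode,
in that order, then recomputes branch orders on the surviving tree.
Screening never adds points and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .modeling import VesselModel
from .tracking import BranchTrack

__all__ = ["ScreeningConfig", "remove_duplicates", "remove_artifact_branches",
           "remove_noise_branches", "screen"]


@dataclass
class ScreeningConfig:
    overlap_threshold: float = 0.7      # fraction of points within 1 voxel to call duplicate
    min_length: float = 2.0             # mm
    min_mask_support: float = 0.8       # fraction of points inside the vessel mask
    artifact_zone: float = 1.0          # mm dilation around the large-vessel mask
    artifact_max_tortuosity: float = 2.0  # path/chord cutoff inside the zone
    voxel_size_mm: float = 0.1          # "1 voxel" for the duplicate tolerance

    def __post_init__(self) -> None:
        for name in ("min_length", "artifact_zone", "artifact_max_tortuosity", "voxel_size_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("overlap_threshold", "min_mask_support"):
            val = getattr(self, name)
            if not 0 < val <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


def _dense_points(tr: BranchTrack, step: float) -> np.ndarray:
    out = []
    for i in range(len(tr.points) - 1):
        seg = tr.points[i + 1] - tr.points[i]
        n = max(int(np.ceil(np.linalg.norm(seg) / step)), 1)
        ts = np.arange(n) / n
        out.append(tr.points[i] + ts[:, None] * seg)
    out.append(tr.points[-1:])
    return np.concatenate(out)


def _mask_support(tr: BranchTrack, mask, spacing) -> float:
    if mask is None:
        return 1.0
    mask = np.asarray(mask) != 0
    sp = np.asarray(spacing, dtype=float)
    pts = _dense_points(tr, sp.min())
    idx = np.rint(pts / sp).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
    inside = np.zeros(len(idx), dtype=bool)
    sel = idx[ok]
    inside[ok] = mask[sel[:, 0], sel[:, 1], sel[:, 2]]
    return float(inside.mean())


def _tortuosity(tr: BranchTrack) -> float:
    chord = float(np.linalg.norm(tr.points[-1] - tr.points[0]))
    return tr.length / max(chord, 1e-9)


def _resolve_parents(branches: list[BranchTrack], keep: list[bool],
                     parent_of_removed: dict[int, tuple | None]) -> list[BranchTrack]:
    """Drop unkept branches, re-parenting children to the nearest kept ancestor."""
    new_index = {}
    survivors = []
    for i, (b, k) in enumerate(zip(branches, keep)):
        if k:
            new_index[i] = len(survivors)
            survivors.append(b)

    def resolve(parent):
        seen = set()
        while parent is not None and parent[0] not in new_index:
            if parent[0] in seen:
                return None
            seen.add(parent[0])
            parent = parent_of_removed.get(parent[0])
        return parent

    out = []
    for i, b in enumerate(branches):
        if not keep[i]:
            continue
        parent = resolve(b.parent)
        if parent is not None:
            pb = branches[parent[0]]
            # attachment index may be stale after re-parenting; snap to nearest
            att = int(np.argmin(np.linalg.norm(pb.points - b.points[0], axis=1)))
            parent = (new_index[parent[0]], att)
        out.append(BranchTrack(points=b.points.copy(), radii=b.radii.copy(),
                               parent=parent, order=b.order, provenance=b.provenance))
    return out


def remove_duplicates(branches: list[BranchTrack],
                      config: ScreeningConfig | None = None) -> list[BranchTrack]:
    """Collapse branches that retrace an already-kept branch.

    A branch whose points lie mostly (>= overlap_threshold) within one
    voxel of a longer kept branch is dropped; if it diverges, its novel
    tail is re-attached as a child of the branch it duplicated.  Branches
    are considered longest-first with the earlier seed index breaking ties.
    """
    config = config or ScreeningConfig()
    tol = config.voxel_size_mm
    order = sorted(range(len(branches)), key=lambda i: (-branches[i].length, i))
    kept: list[BranchTrack] = []
    kept_src: list[int] = []
    kept_trees: list[cKDTree] = []
    orig_to_kept: dict[int, int] = {}     # surviving original index -> kept position
    dropped_to_kept: dict[int, int] = {}  # duplicate original index -> kept target
    tail_parent: dict[int, int] = {}      # kept position of a tail -> kept parent position
    for i in order:
        b = branches[i]
        pts = _dense_points(b, tol / 2)
        dup_of = None
        near_frac_best = 0.0
        near_best = None
        for kidx, tree in enumerate(kept_trees):
            d = tree.query(pts)[0]
            frac = float((d <= tol).mean())
            if frac >= config.overlap_threshold and frac > near_frac_best:
                near_frac_best = frac
                dup_of = kidx
                near_best = d <= tol
        if dup_of is None:
            kept.append(b)
            kept_src.append(i)
            kept_trees.append(cKDTree(pts))
            orig_to_kept[i] = len(kept) - 1
            continue
        dropped_to_kept[i] = dup_of
        # novel trailing tail -> re-attach as child of the duplicated branch
        novel = ~near_best
        if novel.any():
            first_novel = int(np.argmax(novel))
            tail = pts[max(first_novel - 1, 0):]
            tail_len = float(np.linalg.norm(np.diff(tail, axis=0), axis=1).sum()) if len(tail) > 1 else 0.0
            if tail_len > 2 * tol and novel[-1]:
                # subsample the dense tail back to roughly the original sampling
                stride = max(len(tail) // max(len(b.points), 2), 1)
                tpts = np.vstack([tail[::stride], tail[-1]])
                keep_pts = np.ones(len(tpts), bool)
                keep_pts[1:] = np.linalg.norm(np.diff(tpts, axis=0), axis=1) > 1e-9
                tpts = tpts[keep_pts]
                if len(tpts) >= 2:
                    r = float(np.median(b.radii))
                    kept.append(BranchTrack(points=tpts, radii=np.full(len(tpts), r),
                                            parent=None, order=kept[dup_of].order + 1,
                                            provenance="dedup-tail"))
                    kept_src.append(i)
                    kept_trees.append(cKDTree(tpts))
                    tail_parent[len(kept) - 1] = dup_of
    # deterministic ordering by source index; remap parent links
    reorder = sorted(range(len(kept)), key=lambda k: kept_src[k])
    perm = {old: new for new, old in enumerate(reorder)}
    out: list[BranchTrack] = [None] * len(kept)  # type: ignore[list-item]
    for k in reorder:
        b = kept[k]
        if k in tail_parent:
            target = tail_parent[k]
        else:
            target = None
            p = b.parent
            if p is not None:
                p0 = p[0]
                target = orig_to_kept.get(p0, dropped_to_kept.get(p0))
        parent = None
        if target is not None and target != k:
            pb = kept[target]
            att = int(np.argmin(np.linalg.norm(pb.points - b.points[0], axis=1)))
            parent = (perm[target], att)
        out[perm[k]] = BranchTrack(points=b.points, radii=b.radii, parent=parent,
                                   order=b.order, provenance=b.provenance)
    return out


def remove_artifact_branches(branches: list[BranchTrack], large_vessel_mask,
                             config: ScreeningConfig | None = None,
                             spacing=(0.1, 0.1, 0.1), mask=None) -> list[BranchTrack]:
    """Drop pulsation-artifact-like branches hugging the large vessels.

    A branch is removed when >= 50% of its points lie inside the
    artifact zone (large-vessel mask dilated by `artifact_zone` mm) AND it
    is either highly tortuous or poorly supported by the vessel mask.
    With an empty large-vessel mask this is the identity.
    """
    config = config or ScreeningConfig()
    if large_vessel_mask is None or not np.any(large_vessel_mask):
        return list(branches)
    lv = np.asarray(large_vessel_mask) != 0
    sp = np.asarray(spacing, dtype=float)
    dist_out = ndimage.distance_transform_edt(~lv, sampling=sp)
    zone = dist_out <= config.artifact_zone

    keep = []
    parent_of_removed: dict[int, tuple | None] = {}
    for i, b in enumerate(branches):
        pts = _dense_points(b, sp.min())
        idx = np.clip(np.rint(pts / sp).astype(int), 0, np.asarray(zone.shape) - 1)
        in_zone = float(zone[idx[:, 0], idx[:, 1], idx[:, 2]].mean())
        bad = in_zone >= 0.5 and (
            _tortuosity(b) > config.artifact_max_tortuosity
            or _mask_support(b, mask, sp) < config.min_mask_support)
        keep.append(not bad)
        if bad:
            parent_of_removed[i] = b.parent
    return _resolve_parents(branches, keep, parent_of_removed)


def remove_noise_branches(branches: list[BranchTrack], mask,
                          config: ScreeningConfig | None = None,
                          spacing=(0.1, 0.1, 0.1)) -> list[BranchTrack]:
    """Drop short or poorly mask-supported branches (scattered-noise artifacts).

    Children of a removed branch are re-parented to its parent, or dropped
    when orphaned and themselves below the length cutoff.
    """
    config = config or ScreeningConfig()
    keep = []
    parent_of_removed: dict[int, tuple | None] = {}
    for i, b in enumerate(branches):
        bad = (b.length < config.min_length
               or _mask_support(b, mask, spacing) < config.min_mask_support)
        keep.append(not bad)
        if bad:
            parent_of_removed[i] = b.parent
    return _resolve_parents(branches, keep, parent_of_removed)


def _recompute_orders(branches: list[BranchTrack]) -> list[BranchTrack]:
    orders: dict[int, int] = {}

    def order_of(i: int) -> int:
        if i in orders:
            return orders[i]
        p = branches[i].parent
        orders[i] = 1 if p is None else order_of(p[0]) + 1
        return orders[i]

    out = []
    for i, b in enumerate(branches):
        out.append(BranchTrack(points=b.points, radii=b.radii, parent=b.parent,
                               order=order_of(i), provenance=b.provenance))
    return out


def screen(branches: list[BranchTrack], mask=None, large_vessel_mask=None,
           spacing=(0.1, 0.1, 0.1), config: ScreeningConfig | None = None) -> VesselModel:
    """Duplicates -> artifacts -> noise, then rebuild the surviving tree.

    Returns a :class:`~lsatrace.modeling.VesselModel` whose ``tracks``
    property exposes the surviving branch tracks (screening twice equals
    screening once).
    """
    config = config or ScreeningConfig()
    out = remove_duplicates(list(branches), config)
    out = remove_artifact_branches(out, large_vessel_mask, config, spacing, mask)
    out = remove_noise_branches(out, mask, config, spacing)
    out = _recompute_orders(out)
    return VesselModel.from_tracks(out, mask=mask, spacing=spacing if mask is not None else None)
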