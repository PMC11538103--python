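"""Candidate pre-screening, patch classification, and segmentation metrics.

Segmentation is framed as center-voxel detection: only voxels whose
standardized intensity lies strictly between the background threshold
T_bg = 80 and the large-vessel threshold T_v = 120 are handed to the
patch classifier; voxels at or above T_v are large vessel by fiat, voxels
at or below T_bg are background.  The three sets partition the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .nn import SPCNN
from .volume import Volume

__all__ = [
    "IntensityInterval", "SegMetrics", "prescreen_candidates", "extract_patch",
    "segment_volume", "dice", "hausdorff", "fp_fn_rates",
    "fp_fn_rates_conventional", "evaluate_segmentation",
]


@dataclass
class IntensityInterval:
    """Pre-screen interval (T_bg, T_v) on the standardized 0-255 scale."""

    t_bg: float = 80.0
    t_v: float = 120.0

    def __post_init__(self) -> None:
        if not self.t_bg < self.t_v:
            raise ValueError("t_bg must be < t_v")


def prescreen_candidates(v: Volume, interval: IntensityInterval | None = None):
    """Partition voxels into CNN candidates, large vessel, and background.

    Returns ``(candidate_indices, large_vessel_mask, background_mask)``
    where candidates are the (n, 3) voxel indices with intensity strictly
    inside (t_bg, t_v).
    """
    interval = interval or IntensityInterval()
    if v.intensity_scale != "standardized":
        raise ValueError("prescreen_candidates requires a standardized volume")
    data = v.data
    large = data >= interval.t_v
    background = data <= interval.t_bg
    candidates = np.argwhere(~large & ~background)
    return candidates, large.astype(np.uint8), background.astype(np.uint8)


def extract_patch(v: Volume, center, size: int, norm_min: float, norm_max: float) -> np.ndarray:
    """Cube of `size`^3 voxels centered on a voxel index, normalized to [0, 1].

    Intensities are mapped by (x - norm_min) / (norm_max - norm_min) and
    clipped; voxels outside the grid are filled by edge replication.
    """
    if size % 2 == 0:
        raise ValueError("patch size must be odd")
    center = np.asarray(center, dtype=int)
    shape = np.asarray(v.shape)
    if np.any(center < 0) or np.any(center >= shape):
        raise ValueError(f"patch center {tuple(center)} outside grid {tuple(shape)}")
    h = size // 2
    idx = [np.clip(np.arange(center[a] - h, center[a] + h + 1), 0, shape[a] - 1)
           for a in range(3)]
    cube = v.data[np.ix_(*idx)].astype(np.float64)
    return np.clip((cube - norm_min) / (norm_max - norm_min), 0.0, 1.0)


def segment_volume(v: Volume, classifier: SPCNN, interval: IntensityInterval | None = None,
                   threshold: float = 0.5, norm_min: float | None = None,
                   norm_max: float | None = None, small_vessels_only: bool = False,
                   batch_size: int = 512) -> np.ndarray:
    """Classify every pre-screened candidate voxel; return a binary mask.

    The mask is the union of the large-vessel set and the candidates the
    classifier accepts at `threshold`; with ``small_vessels_only`` the
    large-vessel set is excluded.  ``norm_min``/``norm_max`` default to the
    interval the training patches were normalized with (0, 255 if unknown).
    """
    interval = interval or IntensityInterval()
    if norm_min is None or norm_max is None:
        norm_min, norm_max = 0.0, 255.0
    candidates, large, _bg = prescreen_candidates(v, interval)
    mask = np.zeros(v.shape, dtype=np.uint8)
    if not small_vessels_only:
        mask |= large
    size = classifier.config.patch_size
    for i in range(0, len(candidates), batch_size):
        batch = candidates[i:i + batch_size]
        patches = np.stack([extract_patch(v, c, size, norm_min, norm_max) for c in batch])
        probs = classifier.predict_proba(patches, batch_size=batch_size)
        accept = batch[probs >= threshold]
        mask[accept[:, 0], accept[:, 1], accept[:, 2]] = 1
    return mask


# ---------------------------------------------------------------------------
# metrics

@dataclass
class SegMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    dsc: float
    hd: float
    fp_rate: float
    fn_rate: float


def _check_same_grid(pred, gt):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {gt.shape}")
    return pred != 0, gt != 0


def dice(pred, gt) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN).

    Defined as 1 when both masks are empty, 0 when they are disjoint.
    """
    p, g = _check_same_grid(pred, gt)
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    if tp == 0 and fp + fn == 0:
        return 1.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def hausdorff(pred, gt, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between two voxel sets, in mm.

    HD(P, G) = max(h(P, G), h(G, P)) with the directed distance
    h(P, G) = max over p in P of min over g in G of ||p - g||.
    """
    p, g = _check_same_grid(pred, gt)
    P = np.argwhere(p) * np.asarray(spacing, dtype=float)
    G = np.argwhere(g) * np.asarray(spacing, dtype=float)
    if len(P) == 0 or len(G) == 0:
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    tp = cKDTree(P)
    tg = cKDTree(G)
    h_pg = tg.query(P)[0].max()
    h_gp = tp.query(G)[0].max()
    return float(max(h_pg, h_gp))


def fp_fn_rates(pred, gt) -> tuple[float, float]:
    """FP/FN rates with the printed denominators.

    fp_rate = FP / (ground-truth vessel voxels);
    fn_rate = FN / (ground-truth background voxels).
    See :func:`fp_fn_rates_conventional` for the per-class convention.
    """
    p, g = _check_same_grid(pred, gt)
    n_vessel = int(g.sum())
    n_bg = int((~g).sum())
    if n_vessel == 0 or n_bg == 0:
        raise ValueError("fp_fn_rates needs >= 1 vessel and >= 1 background voxel in gt")
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    return fp / n_vessel, fn / n_bg


def fp_fn_rates_conventional(pred, gt) -> tuple[float, float]:
    """Conventional rates: FP over background voxels, FN over vessel voxels."""
    p, g = _check_same_grid(pred, gt)
    n_vessel = int(g.sum())
    n_bg = int((~g).sum())
    if n_vessel == 0 or n_bg == 0:
        raise ValueError("needs >= 1 vessel and >= 1 background voxel in gt")
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    return fp / n_bg, fn / n_vessel


def evaluate_segmentation(pred, gt, spacing=(1.0, 1.0, 1.0)) -> SegMetrics:
    """All segmentation metrics in one table row."""
    p, g = _check_same_grid(pred, gt)
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    fpr, fnr = fp_fn_rates(pred, gt)
    return SegMetrics(tp=tp, fp=fp, fn=fn, tn=tn, dsc=dice(pred, gt),
                      hd=hausdorff(pred, gt, spacing), fp_rate=fpr, fn_rate=fnr)
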