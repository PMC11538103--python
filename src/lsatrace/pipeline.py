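"""End-to-end pipeline: preprocess -> segment -> track -> screen -> model.

The pipeline can run on a real NIfTI volume with pre-trained checkpoints,
or in phantom mode where it synthesizes its own training data, trains the
(scaled-down) patch classifier and the step forest, and evaluates against
exact ground truth.  Every run writes a manifest with the config hash,
seed and per-artifact content hashes; deterministic stages reproduce
identical hashes for identical config + seed.

All randomness flows from the single pipeline seed through named
substreams (phantom, patches, cnn, forest), each derived with
``numpy.random.SeedSequence`` so stages stay independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as vio
from .modeling import VesselModel, morphometry
from .nn import SPCNN, SPCNNConfig, build_spcnn, train_spcnn
from .phantom import (make_training_patches, make_training_phantoms, make_tree_phantom,
                      merge_patch_datasets, render_phantom)
from .preprocess import PreprocessConfig, denoise, preprocess
from .screening import ScreeningConfig, screen
from .segmentation import IntensityInterval, prescreen_candidates, segment_volume
from .tracking import (StepForestConfig, TrackingConfig, detect_seeds,
                       make_step_training_data, trace_tree, train_step_forest)
from .volume import Volume, read_volume, write_mask, write_volume

log = logging.getLogger("lsatrace")

__all__ = ["PipelineConfig", "run_pipeline", "render_mip", "train_phantom_classifier"]


def train_phantom_classifier(seed: int, cnn_config: SPCNNConfig,
                             n_pos: int = 500, n_neg: int = 500,
                             noise_sd: float = 15.0,
                             preprocess_config: PreprocessConfig | None = None):
    """Train the patch classifier on synthetic phantoms (the phantom-mode protocol).

    Phantoms are denoised as in the pipeline; negatives mix pre-screen
    interval voxels (the hard, inference-relevant class) with flat
    background voxels so the classifier sees both regimes.  Returns
    ``(classifier, dataset, history)``; the dataset carries the
    normalization bounds segmentation must reuse.
    """
    pc = preprocess_config or PreprocessConfig()
    phantoms = [(denoise(v, pc), g)
                for v, g in make_training_phantoms(seed=seed, noise_sd=noise_sd)]
    hard = make_training_patches(phantoms, n_pos, n_neg // 2,
                                 patch_size=cnn_config.patch_size, seed=seed)
    flat = make_training_patches(phantoms, 0, n_neg - n_neg // 2,
                                 patch_size=cnn_config.patch_size, seed=seed + 500,
                                 neg_mode="background")
    data = merge_patch_datasets(hard, flat)
    model = build_spcnn(cnn_config)
    model, history = train_spcnn(model, data, cnn_config)
    return model, data, history


@dataclass
class PipelineConfig:
    """Nested configuration for the full pipeline."""

    seed: int = 0
    working_resolution: float = 0.10          # mm, isotropic (sensible range 0.10-0.20)
    input_path: str | None = None             # NIfTI input; None -> phantom mode
    cnn_checkpoint: str | None = None
    train: bool = True                        # train on phantoms when no checkpoint
    prob_threshold: float = 0.5
    small_vessels_only: bool = True
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    interval: IntensityInterval = field(default_factory=IntensityInterval)
    cnn: SPCNNConfig = field(default_factory=lambda: SPCNNConfig(
        patch_size=9, initial_feature_maps=16, dense_width=32,
        max_epochs=30, early_stop_epoch=30, initial_lr=3e-4))
    forest: StepForestConfig = field(default_factory=lambda: StepForestConfig(n_trees=200))
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    # phantom-mode study conditions
    phantom_noise_sd: float = 15.0
    phantom_shape: tuple = (72, 72, 72)
    n_pos_patches: int = 600
    n_neg_patches: int = 600
    n_step_examples: int = 400

    def __post_init__(self) -> None:
        if not 0 < self.working_resolution < 1:
            raise ValueError("working_resolution must be in (0, 1) mm")

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return asdict(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _substream(seed: int, name: str) -> int:
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline and write artifacts + manifest to `outdir`.

    Returns the manifest dict.  In phantom mode the ground truth is also
    saved, and the returned manifest carries the in-memory results under
    the ``results`` key (volume, masks, model, morphometry).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
    results: dict = {}

    def stage(name):
        t0 = time.time()
        log.info("stage %s ...", name)
        return t0

    def done(name, t0, voxels=None, outputs=()):
        entry = {"wall_time_s": round(time.time() - t0, 3)}
        if voxels is not None:
            entry["voxels"] = int(voxels)
        entry["outputs"] = {Path(p).name: _sha256(Path(p)) for p in outputs}
        manifest["stages"][name] = entry
        log.info("stage %s done in %.2fs", name, entry["wall_time_s"])

    try:
        # ---- input ---------------------------------------------------------
        t0 = stage("input")
        gt = None
        if config.input_path is not None:
            vol = read_volume(config.input_path)
        else:
            spec = make_tree_phantom(seed=_substream(config.seed, "phantom"),
                                     shape=config.phantom_shape, n_levels=1,
                                     noise_sd=config.phantom_noise_sd)
            vol, gt = render_phantom(spec)
        done("input", t0, voxels=np.prod(vol.shape))

        # ---- preprocess ----------------------------------------------------
        t0 = stage("preprocess")
        if vol.intensity_scale == "standardized":
            work = denoise(vol, config.preprocess)   # phantom is already standardized
        else:
            work = preprocess(vol, config.preprocess)
        vol_path = outdir / "preprocessed.nii.gz"
        write_volume(work, vol_path)
        done("preprocess", t0, voxels=np.prod(work.shape), outputs=[vol_path])

        # ---- classifier ----------------------------------------------------
        t0 = stage("train-cnn")
        norm = (0.0, 255.0)
        if config.cnn_checkpoint is not None:
            cnn = SPCNN.load(config.cnn_checkpoint)
        elif config.train:
            cfg = SPCNNConfig(**{**asdict(config.cnn), "seed": _substream(config.seed, "cnn")})
            cnn, data, history = train_phantom_classifier(
                _substream(config.seed, "patches"), cfg,
                n_pos=config.n_pos_patches, n_neg=config.n_neg_patches,
                noise_sd=config.phantom_noise_sd, preprocess_config=config.preprocess)
            norm = (data.norm_min, data.norm_max)
            results["cnn_history"] = history
            cnn.save(outdir / "spcnn.npz")
        else:
            raise RuntimeError("stage train-cnn: no checkpoint given and --train not set")
        done("train-cnn", t0, outputs=[p for p in [outdir / "spcnn.npz"] if p.exists()])

        # ---- segmentation --------------------------------------------------
        t0 = stage("segment")
        mask = segment_volume(work, cnn, config.interval, threshold=config.prob_threshold,
                              norm_min=norm[0], norm_max=norm[1],
                              small_vessels_only=config.small_vessels_only)
        _cands, lv_mask, _bg = prescreen_candidates(work, config.interval)
        mask_path = outdir / "vessel_mask.nii.gz"
        write_mask(mask, work, mask_path)
        done("segment", t0, voxels=mask.sum(), outputs=[mask_path])

        # ---- tracking ------------------------------------------------------
        t0 = stage("track")
        if config.train:
            if gt is not None:
                X, y = make_step_training_data(work, gt, config.n_step_examples,
                                               config.n_step_examples,
                                               seed=_substream(config.seed, "forest-data"),
                                               config=config.tracking)
            else:
                raise RuntimeError("stage track: forest training requires phantom mode")
            fcfg = StepForestConfig(**{**asdict(config.forest),
                                       "seed": _substream(config.seed, "forest")})
            forest = train_step_forest((X, y), fcfg)
        else:
            raise RuntimeError("stage track: no forest checkpoint support without --train")
        seeds = detect_seeds(mask, lv_mask if lv_mask.any() else None,
                             spacing=work.spacing, config=config.tracking)
        tracks = trace_tree(seeds, mask, work, forest, config.tracking)
        branches_path = outdir / "branches.json"
        vio.save_branches(tracks, branches_path)
        done("track", t0, outputs=[branches_path])

        # ---- screening + modeling -----------------------------------------
        t0 = stage("screen-model")
        model = screen(tracks, mask=mask, large_vessel_mask=lv_mask if lv_mask.any() else None,
                       spacing=work.spacing, config=config.screening)
        table = morphometry(model)
        csv_path = outdir / "morphometry.csv"
        table.to_csv(csv_path)
        screened_path = outdir / "screened_branches.json"
        vio.save_branches(model.tracks, screened_path)
        vtk_path = outdir / "centerlines.vtk"
        vio.write_vtk_polylines(model.tracks, vtk_path)
        done("screen-model", t0, outputs=[csv_path, screened_path, vtk_path])

        results.update({"volume": work, "mask": mask, "large_vessel_mask": lv_mask,
                        "ground_truth": gt, "model": model, "morphometry": table,
                        "tracks_raw": tracks})
    except Exception as exc:
        manifest["failed_stage"] = getattr(exc, "stage", str(exc))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    manifest["results"] = results
    return manifest


def render_mip(v: Volume, axis="z", overlay=None, path=None) -> np.ndarray:
    """Maximum-intensity projection along an axis, optional mask/model overlay.

    With an overlay (binary mask array or :class:`VesselModel`) the result
    is an RGB image with the overlay in the red channel; otherwise a 2D
    grayscale array.  Pass `path` to also write a PNG.
    """
    ax = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    if ax not in (0, 1, 2):
        raise ValueError("axis must be one of x, y, z")
    mip = v.data.max(axis=ax)
    if overlay is None:
        out = mip
    else:
        if isinstance(overlay, VesselModel):
            omask = np.zeros(v.shape, dtype=bool)
            sp = np.asarray(v.spacing)
            for br in overlay.branches:
                idx = np.rint(br.centerline.sample(32) / sp).astype(int)
                ok = np.all((idx >= 0) & (idx < np.asarray(v.shape)), axis=1)
                sel = idx[ok]
                omask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        else:
            omask = np.asarray(overlay) != 0
        oproj = omask.max(axis=ax)
        lo, hi = float(mip.min()), float(mip.max())
        gray = (mip - lo) / (hi - lo) if hi > lo else np.zeros_like(mip)
        out = np.stack([gray, gray, gray], axis=-1)
        out[oproj, 0] = 1.0
        out[oproj, 1] *= 0.3
        out[oproj, 2] *= 0.3
    if path is not None:
        import imageio.v3 as iio
        img = out if out.ndim == 3 else (np.stack([out] * 3, axis=-1) - out.min()) / max(np.ptp(out), 1e-30)
        iio.imwrite(str(path), (np.clip(img, 0, 1) * 255).astype(np.uint8))
    return out
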