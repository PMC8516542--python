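"""End-to-end pipeline: preprocessing -> enhancement -> segmentation ->
ridge detection -> tracking, chained under one configuration."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import chanvese, preprocess, ridges as ridges_mod, tracker, vesselness
from .config import PipelineConfig
from .image_io import validate_image

__all__ = ["PipelineResult", "preprocess_image", "enhance", "run_pipeline"]

log = logging.getLogger("coroseg")


@dataclass
class PipelineResult:
    preprocessed: np.ndarray
    enhanced: np.ndarray
    multiscale: vesselness.MultiscaleResult
    mask: np.ndarray
    contours: list
    ridges: ridges_mod.RidgeMap
    ridges_filtered: ridges_mod.RidgeMap
    seed_index: int
    skeleton: tracker.Skeleton


def preprocess_image(img: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Denoise -> unsharp mask -> CLAHE, honoring the enable switches."""
    out = validate_image(img)
    if cfg.enable_denoise and cfg.denoise.noise_sigma > 0:
        out = preprocess.denoise(out, cfg.denoise)
        log.info("denoise: sigma=%.1f range=[%.1f, %.1f]",
                 cfg.denoise.noise_sigma, out.min(), out.max())
    if cfg.enable_unsharp:
        out = preprocess.unsharp_mask(out, cfg.unsharp)
        log.info("unsharp: k=%.2f range=[%.1f, %.1f]",
                 cfg.unsharp.k, out.min(), out.max())
    if cfg.enable_clahe:
        out = preprocess.clahe(out, cfg.clahe)
        log.info("clahe: clip=%.2f tiles=%dx%d range=[%.1f, %.1f]",
                 cfg.clahe.clip_limit, cfg.clahe.tile_rows,
                 cfg.clahe.tile_cols, out.min(), out.max())
    return out


def enhance(preprocessed: np.ndarray, cfg: PipelineConfig):
    """Polarity inversion (dark vessels) + multiscale vesselness."""
    work = 255.0 - preprocessed if cfg.vessel_polarity == "dark" \
        else preprocessed
    ms = vesselness.vesselness_multiscale(work, cfg.vesselness)
    log.info("vesselness: scales [%.1f..%.1f]x%d, response max %.1f",
             cfg.vesselness.sigma_min, cfg.vesselness.sigma_max,
             cfg.vesselness.n_scales, ms.response.max())
    return ms


def run_pipeline(img: np.ndarray, cfg: PipelineConfig,
                 seed_index: int | None = None) -> PipelineResult:
    """Run the whole chain on a raw image and return every stage output.

    ``seed_index`` overrides the random seed-point choice (an index into
    the filtered ridge map); otherwise the choice is driven by
    ``cfg.rng_seed``.
    """
    cfg.validate()
    pre = preprocess_image(img, cfg)
    ms = enhance(pre, cfg)

    mask, contours, _, history = chanvese.segment(
        ms.response, cfg.cv, init_kind=cfg.cv_init)
    log.info("chanvese: %d iters, %d contours, mask area %d",
             len(history), len(contours), int(mask.sum()))

    rmap = ridges_mod.detect_ridge_points(ms.response, ms, cfg.ridge)
    rfil = ridges_mod.filter_scattered_ridges(rmap, cfg.ridge)
    log.info("ridges: %d detected, %d after scatter filter",
             len(rmap), len(rfil))

    if seed_index is None:
        seed_index = tracker.select_seed(rfil, cfg.rng_seed)
    elif not 0 <= seed_index < len(rfil):
        raise IndexError("seed_index outside the filtered ridge map")
    seed_xy = rfil.xy[seed_index].astype(np.float64)
    skel = tracker.track(ms.response, mask, rfil, seed_xy, cfg.track)

    return PipelineResult(
        preprocessed=pre, enhanced=ms.response, multiscale=ms,
        mask=mask, contours=contours, ridges=rmap, ridges_filtered=rfil,
        seed_index=seed_index, skeleton=skel,
    )
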