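"""Shared phantom fixtures.

The heavy products (vesselness fields, Chan-Vese masks, tracked
skeletons) are session-scoped: they are deterministic for fixed
parameters, and several test modules assert different properties of the
same run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pytest

from coroseg import chanvese, ridges, tracker, vesselness
from coroseg.config import PipelineConfig
from coroseg.phantom import (
    PhantomTruth,
    gaussian_bar_image,
    render_phantom,
    straight_tube_spec,
    y_tree_spec,
)

logging.disable(logging.INFO)


@dataclass
class PhantomRun:
    """All pipeline products for one phantom."""

    image: np.ndarray
    truth: PhantomTruth
    ms: vesselness.MultiscaleResult
    mask: np.ndarray
    contours: list
    history: list
    ridges_raw: ridges.RidgeMap
    ridges: ridges.RidgeMap
    cfg: PipelineConfig


def _run(spec) -> PhantomRun:
    cfg = PipelineConfig()
    img, truth = render_phantom(spec)
    ms = vesselness.vesselness_multiscale(img, cfg.vesselness)
    mask, contours, _, history = chanvese.segment(ms.response, cfg.cv)
    raw = ridges.detect_ridge_points(ms.response, ms, cfg.ridge)
    fil = ridges.filter_scattered_ridges(raw, cfg.ridge)
    return PhantomRun(image=img, truth=truth, ms=ms, mask=mask,
                      contours=contours, history=history,
                      ridges_raw=raw, ridges=fil, cfg=cfg)


@pytest.fixture(scope="session")
def tube_run() -> PhantomRun:
    """Noiseless straight tube, bright polarity, fully processed."""
    return _run(straight_tube_spec())


@pytest.fixture(scope="session")
def ytree_run() -> PhantomRun:
    """Noiseless Y-tree, bright polarity, fully processed."""
    return _run(y_tree_spec())


@pytest.fixture(scope="session")
def ytree_skeletons(ytree_run):
    """Skeletons tracked from one seed per branch of the Y-tree."""
    run = ytree_run
    out = {}
    for label, (tx, ty) in [("trunk", (60, 128)), ("upper", (160, 100)),
                            ("lower", (160, 156))]:
        i = int(np.argmin(np.abs(run.ridges.xy[:, 0] - tx)
                          + np.abs(run.ridges.xy[:, 1] - ty)))
        out[label] = tracker.track(run.ms.response, run.mask, run.ridges,
                                   run.ridges.xy[i].astype(float),
                                   run.cfg.track)
    return out


@pytest.fixture(scope="session")
def tube_skeleton(tube_run):
    run = tube_run
    i = int(np.argmin(np.abs(run.ridges.xy[:, 0] - 128)))
    return tracker.track(run.ms.response, run.mask, run.ridges,
                         run.ridges.xy[i].astype(float), run.cfg.track)


@pytest.fixture(scope="session")
def bar_ms():
    """Multiscale vesselness of a Gaussian bar with profile std 3 px."""
    cfg = PipelineConfig()
    bar = gaussian_bar_image(shape=(128, 256), profile_std=3.0, peak=200.0)
    return bar, vesselness.vesselness_multiscale(bar, cfg.vesselness)


@pytest.fixture(scope="session")
def disk_image():
    """200/20 two-level disk image with its analytic mask."""
    h = w = 128
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    inside = np.hypot(xx - 64, yy - 64) <= 30
    return np.where(inside, 200.0, 20.0), inside
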