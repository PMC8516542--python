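"""Denoising and contrast enhancement.

The stage order is fixed: collaborative block-matching denoising, then
unsharp masking, then contrast-limited adaptive histogram equalization
(CLAHE). Each operator is shape-preserving and maps [0, 255] into
[0, 255].
"""

from __future__ import annotations

import numpy as np
import scipy.fft
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter

from .config import ClaheParams, DenoiseParams, UnsharpParams
from .image_io import validate_image

__all__ = ["denoise", "unsharp_mask", "clip_histogram", "clahe"]


def _block_sums(arr: np.ndarray, b: int) -> np.ndarray:
    """Sum of every b-by-b block, indexed by top-left corner."""
    c = np.cumsum(np.cumsum(arr, axis=0), axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    return c[b:, b:] - c[:-b, b:] - c[b:, :-b] + c[:-b, :-b]


def denoise(img: np.ndarray, p: DenoiseParams) -> np.ndarray:
    """Collaborative block-matching filter.

    Overlapping blocks are grouped by L2 similarity within a local search
    window, jointly transformed (2D DCT per block plus a 1D DCT along the
    group), hard-thresholded at ``threshold_factor * noise_sigma``, and the
    filtered blocks are aggregated back with weights proportional to the
    inverse retained-coefficient count. The group-mean (DC) coefficient is
    never thresholded, so constant images pass through unchanged.
    """
    p.validate()
    img = validate_image(img)
    if p.noise_sigma == 0:
        return img.copy()

    h, w = img.shape
    b = min(p.block_size, h, w)
    radius = max((p.search_window - 1) // 2, 1)
    pad = radius
    padded = np.pad(img, pad, mode="reflect")
    hp, wp = padded.shape

    offsets = [(dy, dx) for dy in range(-radius, radius + 1)
               for dx in range(-radius, radius + 1)]
    offsets.sort(key=lambda o: (o != (0, 0), o))  # self-match first
    offsets = np.array(offsets)

    # reference top-left corners (padded coords), stride grid incl. last
    ys = sorted(set(list(range(0, h - b + 1, p.ref_stride)) + [h - b]))
    xs = sorted(set(list(range(0, w - b + 1, p.ref_stride)) + [w - b]))
    ref_y, ref_x = np.meshgrid(np.array(ys) + pad, np.array(xs) + pad,
                               indexing="ij")
    ref_y, ref_x = ref_y.ravel(), ref_x.ravel()
    nref = ref_y.size

    # block L2 distances per offset via integral images
    dists = np.empty((len(offsets), nref))
    for i, (dy, dx) in enumerate(offsets):
        lo_y, hi_y = max(0, -dy), min(hp, hp - dy)
        lo_x, hi_x = max(0, -dx), min(wp, wp - dx)
        diff2 = np.full((hp, wp), np.inf)
        diff2[lo_y:hi_y, lo_x:hi_x] = (
            padded[lo_y:hi_y, lo_x:hi_x]
            - padded[lo_y + dy:hi_y + dy, lo_x + dx:hi_x + dx]
        ) ** 2
        bs = _block_sums(np.where(np.isfinite(diff2), diff2, 0.0), b)
        valid = _block_sums(np.isfinite(diff2).astype(float), b) > b * b - 0.5
        bs[~valid] = np.inf
        dists[i] = bs[ref_y, ref_x]

    k = min(p.max_group, len(offsets))
    top = np.argpartition(dists, k - 1, axis=0)[:k]  # (k, nref)
    sel = offsets[top]  # (k, nref, 2)
    mem_y = ref_y[None, :] + sel[:, :, 0]
    mem_x = ref_x[None, :] + sel[:, :, 1]

    blocks = sliding_window_view(padded, (b, b))
    groups = blocks[mem_y, mem_x]  # (k, nref, b, b)

    coeffs = scipy.fft.dctn(groups, axes=(2, 3), norm="ortho")
    coeffs = scipy.fft.dct(coeffs, axis=0, norm="ortho")
    thr = p.threshold_factor * p.noise_sigma
    keep = np.abs(coeffs) >= thr
    keep[0, :, 0, 0] = True  # group DC always survives
    coeffs *= keep
    kept = keep.sum(axis=(0, 2, 3))  # per reference group
    weights = 1.0 / np.maximum(kept, 1)

    est = scipy.fft.idct(coeffs, axis=0, norm="ortho")
    est = scipy.fft.idctn(est, axes=(2, 3), norm="ortho")

    byy, bxx = np.meshgrid(np.arange(b), np.arange(b), indexing="ij")
    lin = ((mem_y[:, :, None, None] + byy) * wp
           + (mem_x[:, :, None, None] + bxx))
    wfull = np.broadcast_to(weights[None, :, None, None], est.shape)
    acc = np.bincount(lin.ravel(), weights=(est * wfull).ravel(),
                      minlength=hp * wp).reshape(hp, wp)
    wacc = np.bincount(lin.ravel(), weights=wfull.ravel(),
                       minlength=hp * wp).reshape(hp, wp)

    out = np.where(wacc > 0, acc / np.maximum(wacc, 1e-300), padded)
    return np.clip(out[pad:pad + h, pad:pad + w], 0.0, 255.0)


def unsharp_mask(img: np.ndarray, p: UnsharpParams,
                 clip: bool = True) -> np.ndarray:
    """Edge enhancement g = I + k * (I - lowpass(I)).

    The low-pass filter is a mean filter of ``lowpass_kernel_size`` with
    replicate borders; the high-frequency residual (I - lowpass) is scaled
    by the enlarge coefficient k and added back. Output clipped to
    [0, 255] unless ``clip`` is False (useful for inspecting over/undershoot).
    """
    p.validate()
    img = np.asarray(img, dtype=np.float64)
    if min(img.shape) < 1 or p.lowpass_kernel_size > max(img.shape):
        raise ValueError("lowpass kernel does not fit the image")
    low = uniform_filter(img, size=p.lowpass_kernel_size, mode="nearest")
    g = img + p.k * (img - low)
    return np.clip(g, 0.0, 255.0) if clip else g


def clip_histogram(hist: np.ndarray, clip_limit_count: float,
                   max_rounds: int = 16) -> np.ndarray:
    """Clip histogram bins at a count limit, redistributing the excess.

    The excess above the limit is spread equally over all bins; because the
    redistribution can push bins back over the limit, the clip/redistribute
    round is repeated until the residual excess drops below one count or a
    fixed number of rounds is reached. Total mass is conserved.
    """
    if clip_limit_count <= 0:
        raise ValueError("clip_limit_count must be > 0")
    h = np.asarray(hist, dtype=np.float64).copy()
    if (h < 0).any():
        raise ValueError("histogram counts must be >= 0")
    n = h.size
    for _ in range(max_rounds):
        excess = np.clip(h - clip_limit_count, 0, None).sum()
        if excess < 1.0:
            break
        h = np.minimum(h, clip_limit_count)
        h += excess / n
    return h


def _tile_slices(n: int, tiles: int) -> list[slice]:
    bounds = np.linspace(0, n, tiles + 1).round().astype(int)
    return [slice(bounds[i], bounds[i + 1]) for i in range(tiles)]


def clahe(img: np.ndarray, p: ClaheParams) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is divided into a tile grid; each tile's histogram is clipped
    (see :func:`clip_histogram`, limit = ``clip_limit`` times the uniform
    bin height) and turned into a CDF mapping to [0, 255]; pixel values are
    remapped by bilinear interpolation between the four surrounding tile
    mappings.
    """
    p.validate()
    img = validate_image(img)
    h, w = img.shape
    if h < p.tile_rows or w < p.tile_cols:
        raise ValueError("tile grid larger than image")

    nb = p.n_bins
    bins = np.minimum((np.clip(img, 0, 255) * nb / 256.0).astype(int), nb - 1)

    row_sl = _tile_slices(h, p.tile_rows)
    col_sl = _tile_slices(w, p.tile_cols)
    luts = np.empty((p.tile_rows, p.tile_cols, nb))
    cy = np.empty(p.tile_rows)
    cx = np.empty(p.tile_cols)
    for r, rs in enumerate(row_sl):
        cy[r] = 0.5 * (rs.start + rs.stop - 1)
        for c, cs in enumerate(col_sl):
            cx[c] = 0.5 * (cs.start + cs.stop - 1)
            tile_bins = bins[rs, cs].ravel()
            npix = tile_bins.size
            hist = np.bincount(tile_bins, minlength=nb).astype(np.float64)
            limit = p.clip_limit * npix / nb
            hist = clip_histogram(hist, limit)
            cdf = np.cumsum(hist)
            luts[r, c] = 255.0 * cdf / cdf[-1]

    def _axis_interp(coords: np.ndarray, centers: np.ndarray):
        if centers.size == 1:
            z = np.zeros_like(coords, dtype=int)
            return z, z, np.zeros_like(coords, dtype=np.float64)
        hi = np.clip(np.searchsorted(centers, coords), 1, centers.size - 1)
        lo = hi - 1
        frac = np.clip((coords - centers[lo]) / (centers[hi] - centers[lo]),
                       0.0, 1.0)
        return lo, hi, frac

    r0, r1, fy = _axis_interp(np.arange(h, dtype=np.float64), cy)
    c0, c1, fx = _axis_interp(np.arange(w, dtype=np.float64), cx)
    fy = fy[:, None]
    fx = fx[None, :]
    v00 = luts[r0[:, None], c0[None, :], bins]
    v01 = luts[r0[:, None], c1[None, :], bins]
    v10 = luts[r1[:, None], c0[None, :], bins]
    v11 = luts[r1[:, None], c1[None, :], bins]
    out = ((1 - fy) * ((1 - fx) * v00 + fx * v01)
           + fy * ((1 - fx) * v10 + fx * v11))
    return np.clip(out, 0.0, 255.0)
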