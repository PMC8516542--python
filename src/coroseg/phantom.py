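"""Synthetic tubular-tree phantoms with exact ground truth, plus metrics.

A phantom is a set of quadratic Bezier branches with Gaussian
cross-sections (sigma = half-width / 2) laid over a background with an
optional linear illumination gradient and additive Gaussian noise.
Ground truth — dense centerline polylines, local half-widths, the binary
tube mask and bifurcation points — is computed analytically from the
curves, never from the rendered image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "BranchSpec",
    "PhantomSpec",
    "PhantomTruth",
    "render_phantom",
    "centerline_error",
    "bifurcation_score",
    "straight_tube_spec",
    "s_tube_spec",
    "y_tree_spec",
    "gaussian_bar_image",
]


@dataclass
class BranchSpec:
    """One vessel branch: quadratic Bezier centerline with linear width
    and contrast taper.

    Real vessels narrow and lose contrast toward their distal end (the
    contrast agent dilutes); ``peak_intensity_end`` defaults to
    ``peak_intensity`` for an untapered tube. A perfectly constant-width,
    constant-contrast tube is a degenerate input for curvature-based
    ridge tests (the along-vessel Hessian eigenvalue is identically
    zero), so the canonical tree phantoms taper.
    """

    control: np.ndarray            # (3, 2) control points, (x, y)
    halfwidth_start: float = 3.0
    halfwidth_end: float = 3.0
    peak_intensity: float = 120.0
    peak_intensity_end: float | None = None

    def __post_init__(self):
        self.control = np.asarray(self.control, dtype=np.float64)
        if self.control.shape != (3, 2):
            raise ValueError("a quadratic Bezier needs 3 control points")
        if min(self.halfwidth_start, self.halfwidth_end) < 1.0:
            raise ValueError("half-widths must be >= 1 px")
        if self.peak_intensity_end is None:
            self.peak_intensity_end = self.peak_intensity

    def sample(self, spacing: float = 0.5):
        """Arc-length-uniform centerline samples with local half-widths
        and peak intensities."""
        t = np.linspace(0.0, 1.0, 512)
        b = ((1 - t)[:, None] ** 2 * self.control[0]
             + 2 * ((1 - t) * t)[:, None] * self.control[1]
             + (t**2)[:, None] * self.control[2])
        seg = np.linalg.norm(np.diff(b, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        total = arclen[-1]
        n = max(int(np.ceil(total / spacing)) + 1, 2)
        s = np.linspace(0.0, total, n)
        pts = np.stack([np.interp(s, arclen, b[:, 0]),
                        np.interp(s, arclen, b[:, 1])], axis=1)
        frac = s / total
        hw = self.halfwidth_start + frac * (self.halfwidth_end
                                            - self.halfwidth_start)
        peak = self.peak_intensity + frac * (self.peak_intensity_end
                                             - self.peak_intensity)
        return pts, hw, peak


@dataclass
class PhantomSpec:
    shape: tuple[int, int] = (256, 256)          # (height, width)
    branches: list[BranchSpec] = field(default_factory=list)
    background_level: float = 30.0
    illumination_gradient: tuple[float, float] = (0.0, 0.0)  # per-px (gx, gy)
    noise_sigma: float = 0.0
    vessel_polarity: str = "bright"
    rng_seed: int = 0

    def validate(self) -> None:
        h, w = self.shape
        if h < 16 or w < 16:
            raise ValueError("phantom must be at least 16x16")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.vessel_polarity not in ("bright", "dark"):
            raise ValueError("vessel_polarity must be 'bright' or 'dark'")
        for br in self.branches:
            if ((br.control < -0.5).any()
                    or (br.control[:, 0] > w - 0.5).any()
                    or (br.control[:, 1] > h - 0.5).any()):
                raise ValueError("branch control points must lie in the image")


@dataclass
class PhantomTruth:
    centerlines: list[np.ndarray]        # per-branch (n, 2) polylines (x, y)
    halfwidths: list[np.ndarray]         # per-branch local half-widths
    bifurcations: np.ndarray             # (k, 2) points (x, y)
    mask: np.ndarray                     # binary tube mask {0, 1}

    @property
    def all_points(self) -> np.ndarray:
        return np.concatenate(self.centerlines) if self.centerlines \
            else np.empty((0, 2))


def _truth_bifurcations(branches: list[BranchSpec]) -> np.ndarray:
    """Points where >= 3 branch endpoints coincide (shared junctions)."""
    ends = []
    for br in branches:
        ends.append(br.control[0])
        ends.append(br.control[2])
    if not ends:
        return np.empty((0, 2))
    ends = np.asarray(ends)
    used = np.zeros(len(ends), bool)
    out = []
    for i in range(len(ends)):
        if used[i]:
            continue
        close = np.linalg.norm(ends - ends[i], axis=1) < 1e-6
        if close.sum() >= 3:
            out.append(ends[i])
        used |= close
    return np.asarray(out) if out else np.empty((0, 2))


def render_phantom(spec: PhantomSpec):
    """Render a phantom image and its analytic ground truth.

    Branch intensity profiles are Gaussian in the distance to the
    centerline (sigma = local half-width / 2) and combine across branches
    by per-pixel maximum; polarity decides whether tubes add to or
    subtract from the background. Noise is seeded additive Gaussian.
    Returns ``(image, truth)``.
    """
    spec.validate()
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    pix = np.stack([xx.ravel(), yy.ravel()], axis=1)

    tube = np.zeros(h * w)
    mask = np.zeros(h * w, bool)
    centerlines, halfwidths = [], []
    for br in spec.branches:
        pts, hw, peak = br.sample(spacing=0.5)
        centerlines.append(pts)
        halfwidths.append(hw)
        tree = cKDTree(pts)
        dist, idx = tree.query(pix)
        local_hw = hw[idx]
        sigma = local_hw / 2.0
        tube = np.maximum(tube, peak[idx] * np.exp(-dist**2 / (2 * sigma**2)))
        mask |= dist <= local_hw

    gx, gy = spec.illumination_gradient
    img = (spec.background_level
           + gx * (xx - w / 2.0) + gy * (yy - h / 2.0))
    signed = tube if spec.vessel_polarity == "bright" else -tube
    img = img + signed.reshape(h, w)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 255.0)

    truth = PhantomTruth(
        centerlines=centerlines,
        halfwidths=halfwidths,
        bifurcations=_truth_bifurcations(spec.branches),
        mask=mask.reshape(h, w).astype(np.uint8),
    )
    return img, truth


def _densify(polyline: np.ndarray, spacing: float = 0.5) -> np.ndarray:
    """Resample an ordered polyline at <= spacing intervals."""
    if len(polyline) < 2:
        return polyline
    out = [polyline[:1]]
    for a, b in zip(polyline[:-1], polyline[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / spacing)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a + t * (b - a))
    return np.concatenate(out)


def _skeleton_points(skel, densify: bool = False) -> np.ndarray:
    if hasattr(skel, "branches"):
        pts = []
        for br in skel.branches:
            if not len(br):
                continue
            arr = np.array([[pt.x, pt.y] for pt in br])
            pts.append(_densify(arr) if densify else arr)
        return np.concatenate(pts) if pts else np.empty((0, 2))
    return np.asarray(skel, dtype=np.float64).reshape(-1, 2)


def centerline_error(skel, truth: PhantomTruth | np.ndarray,
                     coverage_tol: float = 2.0) -> dict:
    """Distance metrics between a tracked skeleton and the true centerline.

    mean_dist: mean distance from tracked skeleton points to the nearest
    truth point; coverage: fraction of truth points within
    ``coverage_tol`` px of the skeleton *curve* (branch polylines are
    resampled at 0.5 px so tracked points d apart trace a curve, not a
    dotted line); hausdorff: max of the two directed sup-distances.
    """
    sk = _skeleton_points(skel)
    sk_curve = _skeleton_points(skel, densify=True)
    tp = truth.all_points if isinstance(truth, PhantomTruth) \
        else np.asarray(truth, dtype=np.float64)
    if len(sk) == 0 or len(tp) == 0:
        raise ValueError("empty skeleton or truth")
    t_tree = cKDTree(tp)
    s_tree = cKDTree(sk_curve)
    d_sk, _ = t_tree.query(sk)     # skeleton points -> truth
    d_tr, _ = s_tree.query(tp)     # truth -> skeleton curve
    return {
        "mean_dist": float(d_sk.mean()),
        "hausdorff": float(max(d_sk.max(), d_tr.max())),
        "coverage": float((d_tr <= coverage_tol).mean()),
    }


def coverage_vector(skel, truth: PhantomTruth, tol: float = 2.0) -> np.ndarray:
    """Boolean per-truth-point coverage indicator (used for agreement)."""
    sk = _skeleton_points(skel, densify=True)
    tp = truth.all_points
    d, _ = cKDTree(sk).query(tp)
    return d <= tol


def _merge_clusters(points: np.ndarray, tol: float) -> np.ndarray:
    """Merge mutually close detections (single-linkage) to centroids."""
    if len(points) == 0:
        return points
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(points)
    for i, j in tree.query_pairs(tol):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return np.array([points[idx].mean(axis=0) for idx in groups.values()])


def bifurcation_score(detected, truth, tol: float = 5.0) -> dict:
    """Greedy one-to-one bifurcation matching within ``tol`` pixels.

    Detections within ``tol`` of each other are merged to their centroid
    first. recall = matched / n_truth; precision = matched / n_detected
    (defined as 1 when there are no detections: no false alarms).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    det = np.asarray(detected, dtype=np.float64).reshape(-1, 2)
    tru = np.asarray(truth, dtype=np.float64).reshape(-1, 2)
    det = _merge_clusters(det, tol)
    if len(det) == 0:
        return {"recall": 0.0 if len(tru) else 1.0, "precision": 1.0}
    if len(tru) == 0:
        return {"recall": 1.0, "precision": 0.0}
    pairs = [(np.linalg.norm(d - t), i, j)
             for i, d in enumerate(det) for j, t in enumerate(tru)]
    pairs.sort(key=lambda x: x[0])
    used_d, used_t = set(), set()
    matched = 0
    for dist, i, j in pairs:
        if dist > tol:
            break
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        matched += 1
    return {
        "recall": matched / len(tru),
        "precision": matched / len(det),
    }


# ---------------------------------------------------------------------------
# canonical test phantoms

def straight_tube_spec(shape=(256, 256), halfwidth: float = 3.0,
                       peak: float = 120.0, background: float = 30.0,
                       polarity: str = "bright") -> PhantomSpec:
    """Horizontal straight tube through the image center."""
    h, w = shape
    # keep the axis off the pixel grid: exact alignment is a degenerate
    # geometry (the transverse gradient vanishes identically on the crest)
    y = h / 2.0 + 0.3
    br = BranchSpec(
        control=np.array([[20.0, y], [w / 2.0, y], [w - 20.0, y]]),
        halfwidth_start=halfwidth, halfwidth_end=halfwidth,
        peak_intensity=peak,
    )
    return PhantomSpec(shape=shape, branches=[br],
                       background_level=background,
                       vessel_polarity=polarity)


def s_tube_spec(shape=(256, 256), halfwidth: float = 3.0,
                peak: float = 120.0, background: float = 30.0,
                polarity: str = "bright") -> PhantomSpec:
    """Gently curved S-shaped tube (two stacked quadratic arcs)."""
    h, w = shape
    top = BranchSpec(
        control=np.array([[30.0, h * 0.25], [w * 0.5, h * 0.55],
                          [w - 30.0, h * 0.45]]),
        halfwidth_start=halfwidth, halfwidth_end=halfwidth,
        peak_intensity=peak,
    )
    return PhantomSpec(shape=shape, branches=[top],
                       background_level=background,
                       vessel_polarity=polarity)


def y_tree_spec(shape=(256, 256), halfwidth: float = 3.0,
                peak: float = 120.0, background: float = 30.0,
                branch_angle_deg: float = 40.0,
                noise_sigma: float = 0.0,
                illumination_gradient=(0.0, 0.0),
                polarity: str = "bright", rng_seed: int = 0) -> PhantomSpec:
    """Y-shaped tree: a horizontal trunk forking into two daughters.

    Each daughter leaves the junction at ``branch_angle_deg`` on either
    side of the trunk axis. Following real coronary anatomy, the
    daughters are narrower than the trunk and lose contrast toward their
    distal ends (``halfwidth`` and ``peak`` set the values at the
    junction).
    """
    h, w = shape
    jx, jy = w * 0.5, h * 0.5 + 0.3  # trunk axis off the pixel grid
    trunk = BranchSpec(
        control=np.array([[25.0, jy], [(25.0 + jx) / 2, jy], [jx, jy]]),
        halfwidth_start=halfwidth + 0.5, halfwidth_end=halfwidth,
        peak_intensity=peak + 10.0, peak_intensity_end=peak,
    )
    ang = np.deg2rad(branch_angle_deg)
    length = min(h, w) * 0.33
    kids = []
    for sgn in (+1.0, -1.0):
        direction = np.array([np.cos(ang), sgn * np.sin(ang)])
        end = np.array([jx, jy]) + length * direction
        mid = np.array([jx, jy]) + 0.5 * length * direction
        kids.append(BranchSpec(
            control=np.array([[jx, jy], mid, end]),
            halfwidth_start=halfwidth, halfwidth_end=0.75 * halfwidth,
            peak_intensity=peak, peak_intensity_end=peak / 1.5,
        ))
    return PhantomSpec(shape=shape, branches=[trunk] + kids,
                       background_level=background,
                       illumination_gradient=tuple(illumination_gradient),
                       noise_sigma=noise_sigma,
                       vessel_polarity=polarity, rng_seed=rng_seed)


def gaussian_bar_image(shape=(128, 128), profile_std: float = 3.0,
                       peak: float = 200.0, background: float = 0.0,
                       horizontal: bool = True) -> np.ndarray:
    """Straight bright bar with an exact Gaussian cross-section profile."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    across = yy - h / 2.0 if horizontal else xx - w / 2.0
    return background + peak * np.exp(-across**2 / (2.0 * profile_std**2))
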