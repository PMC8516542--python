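"""Adaptive vessel-centerline tracking.

From a randomly chosen ridge seed, the tracker searches the circle of
radius d around the seed for the intensity maximum to fix the forward
direction, mirrors it for the backward direction, and then repeatedly
steps to the intensity maximum on the forward arc (half-angle
delta_theta, radius d). A step is accepted only while the enhanced
intensity stays above the floor I0 (vessel-end guard) and fewer than
tau_P previously accepted points lie within np_radius of the candidate
(loop guard). Every accepted point is re-centered using the segmentation
contour (midpoint of the cross-sectional chord along the trajectory
normal) and then probed for bifurcations: ridge points inside the fan
ring (radii r1..r2, half-angle delta_theta_prime around the current
direction) that open an angle gap larger than tau1/tau2 with the current
and previous directions, lie farther than d, and have fewer than tau_B
accepted bifurcations within nb_radius, spawn a new branch (FIFO).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import TrackParams
from .ridges import RidgeMap

__all__ = [
    "TrackPoint",
    "TrackState",
    "Skeleton",
    "select_seed",
    "initial_directions",
    "step",
    "center_adjust",
    "detect_bifurcation",
    "track",
    "SeedError",
]

log = logging.getLogger("coroseg")


class SeedError(RuntimeError):
    """Raised when tracking cannot start from the given seed."""


@dataclass
class TrackPoint:
    x: float
    y: float
    adjusted: bool = False
    raw_x: float = None
    raw_y: float = None

    def __post_init__(self):
        if self.raw_x is None:
            self.raw_x = self.x
        if self.raw_y is None:
            self.raw_y = self.y

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class TrackState:
    p_prev: np.ndarray
    p_cur: np.ndarray
    u_cur: np.ndarray
    theta_cur: float        # degrees, angle of u_cur
    theta_prev: float       # direction angle at the previous accepted point


@dataclass
class Skeleton:
    branches: list = field(default_factory=list)     # lists of TrackPoint
    bifurcations: list = field(default_factory=list)  # (x, y) tuples
    seed: tuple = (0.0, 0.0)
    truncated: bool = False
    terminations: list = field(default_factory=list)

    @property
    def points_all(self) -> np.ndarray:
        pts = [[p.x, p.y] for br in self.branches for p in br]
        return np.asarray(pts) if pts else np.empty((0, 2))

    @property
    def n_points(self) -> int:
        return sum(len(br) for br in self.branches)


def _wrap180(angle_deg):
    """Absolute angular difference wrapped to [0, 180] degrees."""
    return np.abs((np.asarray(angle_deg) + 180.0) % 360.0 - 180.0)


def _bilinear(img: np.ndarray, xs, ys):
    """Bilinear image interpolation; NaN outside the image domain."""
    xs = np.atleast_1d(np.asarray(xs, dtype=np.float64))
    ys = np.atleast_1d(np.asarray(ys, dtype=np.float64))
    h, w = img.shape
    out = np.full(xs.shape, np.nan)
    ok = (xs >= 0) & (ys >= 0) & (xs <= w - 1) & (ys <= h - 1)
    x = xs[ok]
    y = ys[ok]
    x0 = np.clip(np.floor(x).astype(int), 0, w - 2)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 2)
    fx = x - x0
    fy = y - y0
    v = ((1 - fy) * ((1 - fx) * img[y0, x0] + fx * img[y0, x0 + 1])
         + fy * ((1 - fx) * img[y0 + 1, x0] + fx * img[y0 + 1, x0 + 1]))
    out[ok] = v
    return out


def _arc_offsets(half_deg: float, step_deg: float) -> np.ndarray:
    """Angular offsets covering [-half, +half], ordered by (|off|, off)."""
    n = int(np.floor(half_deg / step_deg + 1e-9))
    offs = [0.0]
    for i in range(1, n + 1):
        offs.append(-i * step_deg)
        offs.append(+i * step_deg)
    return np.array(offs)


def _unit(vec: np.ndarray) -> np.ndarray:
    nrm = float(np.linalg.norm(vec))
    if nrm < 1e-12:
        raise ValueError("zero-length direction")
    return vec / nrm


def select_seed(ridges: RidgeMap, rng_seed: int) -> int:
    """Uniform random ridge index; deterministic for a fixed rng_seed."""
    if len(ridges) == 0:
        raise SeedError("no ridge points to seed from")
    rng = np.random.default_rng(rng_seed)
    return int(rng.integers(len(ridges)))


def initial_directions(img: np.ndarray, seed: np.ndarray, p: TrackParams):
    """Bidirectional initial directions from the circle search.

    P+ is the interpolated-intensity maximum on the full circle of radius
    d around the seed (ties: smallest angle); P- the maximum on the arc
    of half-angle delta_theta centered opposite P+. Returns
    ``(p_plus, u_plus, theta_plus, p_minus, u_minus, theta_minus)``.
    """
    p.validate()
    seed = np.asarray(seed, dtype=np.float64)
    angles = np.arange(0.0, 360.0, p.arc_step_deg)
    rad = np.deg2rad(angles)
    xs = seed[0] + p.d * np.cos(rad)
    ys = seed[1] + p.d * np.sin(rad)
    vals = _bilinear(img, xs, ys)
    if np.all(np.isnan(vals)):
        raise SeedError("search circle leaves the image")
    if np.nanmax(vals) <= p.I0:
        raise SeedError("seed not on vessel: circle maximum below I0")
    if np.nanmax(vals) - np.nanmin(vals) < 1e-9:
        log.warning("degenerate circle search: all samples tie; taking 0 deg")
    i = int(np.nanargmax(vals))  # first max -> smallest angle on ties
    theta_plus = float(angles[i])
    p_plus = np.array([xs[i], ys[i]])
    u_plus = _unit(p_plus - seed)

    center = theta_plus + 180.0
    offs = _arc_offsets(p.delta_theta, p.arc_step_deg)
    back_angles = center + offs
    rad = np.deg2rad(back_angles)
    bx = seed[0] + p.d * np.cos(rad)
    by = seed[1] + p.d * np.sin(rad)
    bvals = _bilinear(img, bx, by)
    if np.all(np.isnan(bvals)):
        raise SeedError("backward arc leaves the image")
    j = int(np.nanargmax(bvals))  # offsets pre-ordered by (|off|, off)
    p_minus = np.array([bx[j], by[j]])
    u_minus = _unit(p_minus - seed)
    theta_minus = float(np.degrees(np.arctan2(u_minus[1], u_minus[0])))
    return p_plus, u_plus, theta_plus, p_minus, u_minus, theta_minus


@dataclass
class StepResult:
    status: str            # "ok" | "intensity" | "loop" | "border"
    point: np.ndarray = None
    value: float = 0.0


def step(img: np.ndarray, state: TrackState, accepted: np.ndarray,
         p: TrackParams) -> StepResult:
    """One arc-search step from the current state.

    ``accepted`` is the (n, 2) array of already-accepted tracking points
    used by the loop guard.
    """
    offs = _arc_offsets(p.delta_theta, p.arc_step_deg)
    angles = state.theta_cur + offs
    rad = np.deg2rad(angles)
    xs = state.p_cur[0] + p.d * np.cos(rad)
    ys = state.p_cur[1] + p.d * np.sin(rad)
    vals = _bilinear(img, xs, ys)
    if np.all(np.isnan(vals)):
        return StepResult("border")
    j = int(np.nanargmax(vals))
    if not np.isfinite(vals[j]) or vals[j] <= p.I0:
        return StepResult("intensity")
    cand = np.array([xs[j], ys[j]])
    if len(accepted):
        n_p = int((np.linalg.norm(accepted - cand, axis=1)
                   <= p.np_radius).sum())
        if n_p >= p.tau_P:
            return StepResult("loop")
    return StepResult("ok", point=cand, value=float(vals[j]))


def center_adjust(mask: np.ndarray, state: TrackState, p: TrackParams):
    """Re-center the current point on the vessel cross-section.

    Rays are cast from the current point along both trajectory normals in
    0.25 px sub-steps; the two contour crossings (0.5-level of the
    bilinearly sampled mask) give the chord whose midpoint is the
    adjusted point. If the point is outside the mask or either ray finds
    no crossing within max_ray, the state is returned unchanged with
    ``adjusted=False``.
    """
    maskf = np.asarray(mask, dtype=np.float64)
    pcur = state.p_cur
    v0 = float(_bilinear(maskf, pcur[0], pcur[1])[0])
    if not np.isfinite(v0) or v0 < 0.5:
        return state, False
    normal = np.array([-state.u_cur[1], state.u_cur[0]])
    ts = np.arange(0.25, p.max_ray + 1e-9, 0.25)

    crossings = []
    for sgn in (+1.0, -1.0):
        xs = pcur[0] + sgn * ts * normal[0]
        ys = pcur[1] + sgn * ts * normal[1]
        vals = _bilinear(maskf, xs, ys)
        prev_t, prev_v = 0.0, v0
        t_star = None
        for t, v in zip(ts, vals):
            if not np.isfinite(v):
                break
            if v < 0.5:
                frac = (prev_v - 0.5) / max(prev_v - v, 1e-12)
                t_star = prev_t + (t - prev_t) * frac
                break
            prev_t, prev_v = t, v
        if t_star is None:
            return state, False
        crossings.append(pcur + sgn * t_star * normal)

    p_adj = 0.5 * (crossings[0] + crossings[1])
    delta = p_adj - state.p_prev
    # the direction update needs a real displacement from the previous
    # point; at a branch anchor (p_prev == p_cur) the delta is just the
    # adjustment itself and its direction is meaningless
    if np.linalg.norm(delta) < 0.5 * p.d:
        u_adj, theta_adj = state.u_cur, state.theta_cur
    else:
        u_adj = _unit(delta)
        theta_adj = float(np.degrees(np.arctan2(u_adj[1], u_adj[0])))
    new_state = TrackState(
        p_prev=state.p_prev, p_cur=p_adj, u_cur=u_adj,
        theta_cur=theta_adj, theta_prev=state.theta_prev,
    )
    return new_state, True


def detect_bifurcation(ridges: RidgeMap, state: TrackState,
                       bifurcations: list, p: TrackParams):
    """Fan-ring bifurcation search from the current state.

    Returns ``(p_b, u0, theta0)`` for the qualifying ridge point of
    maximal enhanced intensity, or None.
    """
    if len(ridges) == 0:
        return None
    pts = ridges.xy.astype(np.float64)
    rel = pts - state.p_cur
    dist = np.linalg.norm(rel, axis=1)
    theta_b = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))

    in_ring = (dist >= p.r1) & (dist <= p.r2)
    in_fan = _wrap180(theta_b - state.theta_cur) <= p.delta_theta_prime
    c1 = _wrap180(theta_b - state.theta_cur) > p.tau1
    c2 = _wrap180(theta_b - state.theta_prev) > p.tau2
    c3 = dist > p.d
    ok = in_ring & in_fan & c1 & c2 & c3
    if ok.any() and bifurcations:
        bif = np.asarray(bifurcations, dtype=np.float64)
        idxs = np.where(ok)[0]
        for i in idxs:
            n_b = int((np.linalg.norm(bif - pts[i], axis=1)
                       <= p.nb_radius).sum())
            if n_b >= p.tau_B:
                ok[i] = False
    if not ok.any():
        return None
    inten = ridges.intensity if ridges.intensity is not None \
        else np.zeros(len(ridges))
    cands = np.where(ok)[0]
    best = cands[int(np.argmax(inten[cands]))]
    p_b = pts[best]
    u0 = _unit(p_b - state.p_cur)
    theta0 = float(np.degrees(np.arctan2(u0[1], u0[0])))
    return p_b, u0, theta0


def track(img: np.ndarray, mask: np.ndarray, ridges: RidgeMap,
          seed_xy: np.ndarray, p: TrackParams) -> Skeleton:
    """Full skeleton extraction from one seed.

    Tracks forward and backward from the seed (merged into one branch
    through it), re-centers and probes for bifurcations at every accepted
    point, and tracks detected branches in FIFO order. Stops when the
    branch queue empties or ``max_points`` is reached.
    """
    p.validate()
    img = np.asarray(img, dtype=np.float64)
    seed = np.asarray(seed_xy, dtype=np.float64)
    skel = Skeleton(seed=(float(seed[0]), float(seed[1])))
    accepted: list[np.ndarray] = []   # raw acceptance positions (loop guard)

    p_plus, u_plus, th_plus, p_minus, u_minus, th_minus = \
        initial_directions(img, seed, p)

    def accept(branch, state, raw_pos):
        """Record a point, re-center it, probe for bifurcations."""
        accepted.append(np.asarray(raw_pos, dtype=np.float64))
        new_state, adjusted = center_adjust(mask, state, p)
        branch.append(TrackPoint(
            x=float(new_state.p_cur[0]), y=float(new_state.p_cur[1]),
            adjusted=adjusted,
            raw_x=float(raw_pos[0]), raw_y=float(raw_pos[1]),
        ))
        found = detect_bifurcation(ridges, new_state, skel.bifurcations, p)
        if found is not None:
            p_b, u0, theta0 = found
            skel.bifurcations.append((float(p_b[0]), float(p_b[1])))
            queue.append((p_b, u0, theta0, new_state.p_cur.copy()))
        return new_state

    def track_half(branch, state):
        """Step until a terminal condition; returns the terminal status."""
        while True:
            if len(accepted) >= p.max_points:
                skel.truncated = True
                return "truncated"
            res = step(img, state, np.asarray(accepted), p)
            if res.status != "ok":
                return res.status
            u_new = _unit(res.point - state.p_cur)
            theta_new = float(np.degrees(np.arctan2(u_new[1], u_new[0])))
            state = TrackState(
                p_prev=state.p_cur, p_cur=res.point, u_cur=u_new,
                theta_cur=theta_new, theta_prev=state.theta_cur,
            )
            state = accept(branch, state, res.point)

    queue: list[tuple] = []

    # seed itself is the anchor point of the main branch
    seed_state = TrackState(p_prev=seed, p_cur=seed, u_cur=u_plus,
                            theta_cur=th_plus, theta_prev=th_plus)
    main: list[TrackPoint] = []
    accept(main, seed_state, seed)

    forward: list[TrackPoint] = []
    fwd_state = TrackState(p_prev=seed, p_cur=p_plus, u_cur=u_plus,
                           theta_cur=th_plus, theta_prev=th_plus)
    fwd_state = accept(forward, fwd_state, p_plus)
    skel.terminations.append(track_half(forward, fwd_state))

    backward: list[TrackPoint] = []
    bwd_state = TrackState(p_prev=seed, p_cur=p_minus, u_cur=u_minus,
                           theta_cur=th_minus, theta_prev=th_minus)
    bwd_state = accept(backward, bwd_state, p_minus)
    skel.terminations.append(track_half(backward, bwd_state))

    skel.branches.append(backward[::-1] + main + forward)

    while queue and not skel.truncated:
        p_b, u0, theta0, parent = queue.pop(0)
        if len(accepted) >= p.max_points:
            skel.truncated = True
            break
        arr = np.asarray(accepted)
        n_p = int((np.linalg.norm(arr - p_b, axis=1) <= p.np_radius).sum())
        if n_p >= p.tau_P:
            continue  # branch start already swamped by existing tracking
        branch: list[TrackPoint] = []
        st = TrackState(p_prev=parent, p_cur=p_b, u_cur=u0,
                        theta_cur=theta0, theta_prev=theta0)
        st = accept(branch, st, p_b)
        skel.terminations.append(track_half(branch, st))
        skel.branches.append(branch)

    log.info("track: %d branches, %d points, %d bifurcations%s",
             len(skel.branches), skel.n_points, len(skel.bifurcations),
             " (truncated)" if skel.truncated else "")
    return skel
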