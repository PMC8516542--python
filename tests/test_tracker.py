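"""Seed selection, arc stepping, center adjustment, bifurcation search
and full skeleton assembly."""

import numpy as np
import pytest

from coroseg.config import TrackParams
from coroseg.phantom import centerline_error, gaussian_bar_image
from coroseg.ridges import RidgeMap
from coroseg.tracker import (
    SeedError,
    Skeleton,
    TrackState,
    center_adjust,
    detect_bifurcation,
    initial_directions,
    select_seed,
    step,
    track,
)


def _ridge_map(xy, intensity=None):
    xy = np.asarray(xy, dtype=int).reshape(-1, 2)
    inten = np.ones(len(xy)) if intensity is None else np.asarray(intensity)
    return RidgeMap(xy=xy, directions=np.tile([1.0, 0.0], (len(xy), 1)),
                    intensity=inten)


def _state(p_prev, p_cur, theta, theta_prev=None):
    th = np.deg2rad(theta)
    return TrackState(p_prev=np.asarray(p_prev, float),
                      p_cur=np.asarray(p_cur, float),
                      u_cur=np.array([np.cos(th), np.sin(th)]),
                      theta_cur=float(theta),
                      theta_prev=float(theta if theta_prev is None
                                       else theta_prev))


class TestSelectSeed:
    def test_singleton(self):
        rm = _ridge_map([[3, 4]])
        assert select_seed(rm, 0) == 0
        assert select_seed(rm, 99) == 0

    def test_deterministic(self):
        rm = _ridge_map([[x, 0] for x in range(50)])
        assert select_seed(rm, 7) == select_seed(rm, 7)

    def test_uniformity(self):
        rm = _ridge_map([[x, 0] for x in range(10)])
        draws = np.array([select_seed(rm, s) for s in range(10000)])
        freqs = np.bincount(draws, minlength=10) / 10000
        assert np.abs(freqs - 0.1).max() <= 0.02

    def test_empty_rejected(self):
        with pytest.raises(SeedError):
            select_seed(_ridge_map(np.empty((0, 2))), 0)


class TestInitialDirections:
    def test_bar_gives_opposite_directions(self):
        img = gaussian_bar_image(shape=(64, 128), profile_std=3.0, peak=200.0)
        p = TrackParams()
        pp, up, tp, pm, um, tm = initial_directions(img, (64.0, 32.0), p)
        assert min(abs(tp - 0), abs(tp - 180), abs(tp - 360)) <= p.arc_step_deg
        assert float(np.dot(up, um)) <= -0.99

    def test_constant_image_tie_break(self):
        img = np.full((64, 64), 100.0)
        p = TrackParams()
        pp, up, tp, *_ = initial_directions(img, (32.0, 32.0), p)
        assert tp == 0.0

    def test_off_center_seed_recovers_axis(self):
        img = gaussian_bar_image(shape=(64, 128), profile_std=3.0, peak=200.0)
        p = TrackParams()
        _, up, tp, *_ = initial_directions(img, (64.0, 34.0), p)
        # the circle maximum sits where the circle reaches the bar axis:
        # at offset 2 and radius d = 5 that is asin(2/5) ~ 23.6 deg off
        axis_angle = min(abs(((tp + 180) % 360) - 180),
                         180 - abs(((tp + 180) % 360) - 180))
        assert axis_angle <= 24.0

    def test_background_seed_rejected(self):
        img = np.full((64, 64), 1.0)
        with pytest.raises(SeedError):
            initial_directions(img, (32.0, 32.0), TrackParams())


class TestStep:
    img = gaussian_bar_image(shape=(64, 128), profile_std=3.0, peak=200.0)

    def test_step_follows_bar(self):
        p = TrackParams()
        st = _state((40.0, 32.0), (45.0, 32.0), 0.0)
        res = step(self.img, st, np.empty((0, 2)), p)
        assert res.status == "ok"
        assert abs(res.point[1] - 32.0) <= 1.0
        assert np.linalg.norm(res.point - st.p_cur) == pytest.approx(p.d)

    def test_background_arc_terminates(self):
        p = TrackParams()
        st = _state((5.0, 5.0), (10.0, 5.0), 0.0)  # far from the bar
        res = step(self.img, st, np.empty((0, 2)), p)
        assert res.status == "intensity"

    def test_loop_guard(self):
        p = TrackParams()
        st = _state((40.0, 32.0), (45.0, 32.0), 0.0)
        crowd = np.tile([50.0, 32.0], (p.tau_P, 1))
        res = step(self.img, st, crowd, p)
        assert res.status == "loop"

    def test_border_terminates(self):
        p = TrackParams()
        st = _state((130.0, 32.0), (200.0, 32.0), 0.0)
        res = step(self.img, st, np.empty((0, 2)), p)
        assert res.status == "border"


class TestCenterAdjust:
    def _tube_mask(self):
        mask = np.zeros((64, 128))
        mask[29:35, :] = 1.0  # width-6 horizontal tube, rows 29..34
        return mask

    def test_offset_point_recentred(self):
        p = TrackParams()
        st = _state((40.0, 33.5), (45.0, 33.5), 0.0)
        new, adjusted = center_adjust(self._tube_mask(), st, p)
        assert adjusted
        assert abs(new.p_cur[1] - 31.5) <= 0.5
        assert new.p_cur[0] == pytest.approx(45.0)

    def test_on_axis_unmoved(self):
        p = TrackParams()
        st = _state((40.0, 31.5), (45.0, 31.5), 0.0)
        new, adjusted = center_adjust(self._tube_mask(), st, p)
        assert adjusted
        assert abs(new.p_cur[1] - 31.5) <= 0.25

    def test_point_outside_mask_flagged(self):
        p = TrackParams()
        st = _state((40.0, 10.0), (45.0, 10.0), 0.0)
        new, adjusted = center_adjust(self._tube_mask(), st, p)
        assert not adjusted
        assert (new.p_cur == st.p_cur).all()

    def test_mask_hole_flagged(self):
        mask = self._tube_mask()
        mask[:, 44:47] = 0.0
        p = TrackParams()
        st = _state((40.0, 31.5), (45.0, 31.5), 0.0)
        new, adjusted = center_adjust(mask, st, p)
        assert not adjusted


class TestDetectBifurcation:
    def test_straight_chain_never_fires(self):
        # all ridge points lie along the current direction: tau1 blocks
        p = TrackParams()
        rm = _ridge_map([[x, 30] for x in range(10, 60)])
        st = _state((25.0, 30.0), (30.0, 30.0), 0.0)
        assert detect_bifurcation(rm, st, [], p) is None

    def test_close_candidate_rejected_by_distance(self):
        p = TrackParams()
        # candidate at distance 4 < d = 5, even with a wide angle
        rm = _ridge_map([[30, 34]])
        st = _state((25.0, 30.0), (30.0, 30.0), 0.0)
        assert detect_bifurcation(rm, st, [], p) is None

    def test_side_branch_detected(self):
        p = TrackParams()
        pts = [[30 + int(round(8 * np.cos(np.deg2rad(70)))),
                30 + int(round(8 * np.sin(np.deg2rad(70))))]]
        rm = _ridge_map(pts)
        st = _state((25.0, 30.0), (30.0, 30.0), 0.0)
        hit = detect_bifurcation(rm, st, [], p)
        assert hit is not None
        p_b, u0, th0 = hit
        assert np.linalg.norm(p_b - np.array(pts[0], float)) < 1e-9

    def test_duplication_cap(self):
        p = TrackParams()
        pts = [[33, 38]]
        rm = _ridge_map(pts)
        st = _state((25.0, 30.0), (30.0, 30.0), 0.0)
        bifs = [(33.0, 37.0), (34.0, 38.0)]  # tau_B = 2 already nearby
        assert detect_bifurcation(rm, st, bifs, p) is None

    def test_max_intensity_candidate_wins(self):
        p = TrackParams()
        a = [30 + int(round(8 * np.cos(np.deg2rad(70)))),
             30 + int(round(8 * np.sin(np.deg2rad(70))))]
        b = [30 + int(round(10 * np.cos(np.deg2rad(80)))),
             30 + int(round(10 * np.sin(np.deg2rad(80))))]
        rm = _ridge_map([a, b], intensity=[5.0, 9.0])
        st = _state((25.0, 30.0), (30.0, 30.0), 0.0)
        p_b, _, _ = detect_bifurcation(rm, st, [], p)
        assert (p_b == np.array(b, float)).all()


class TestTrack:
    def test_straight_tube_single_branch(self, tube_run, tube_skeleton):
        skel = tube_skeleton
        assert len(skel.branches) == 1
        assert len(skel.bifurcations) == 0
        m = centerline_error(skel, tube_run.truth)
        assert m["coverage"] >= 0.90
        assert m["mean_dist"] <= 1.5

    def test_step_spacing_invariant(self, tube_skeleton):
        # the arc search has radius d from the current (adjusted) point,
        # so each raw candidate is exactly d from its predecessor; in the
        # merged main branch the backward half is stored reversed and the
        # two halves join through the raw seed position
        p = TrackParams()
        for br in tube_skeleton.branches:
            for a, b in zip(br[:-1], br[1:]):
                dists = [np.hypot(b.raw_x - a.x, b.raw_y - a.y),
                         np.hypot(a.raw_x - b.x, a.raw_y - b.y),
                         np.hypot(a.raw_x - b.raw_x, a.raw_y - b.raw_y)]
                assert min(abs(dd - p.d) for dd in dists) <= 1e-6

    def test_loop_guard_bookkeeping(self, ytree_skeletons):
        # at acceptance, no raw candidate had tau_P prior points within
        # np_radius; verify post-hoc on the recorded raw positions
        p = TrackParams()
        for skel in ytree_skeletons.values():
            raw = []
            for br in skel.branches:
                for pt in br:
                    raw.append((pt.raw_x, pt.raw_y))
            # reconstruct in acceptance order is not possible from the
            # branch layout alone; assert the weaker global property that
            # no point has an excessive crowd of *other* points
            arr = np.array(raw)
            for i, q in enumerate(arr):
                n = (np.linalg.norm(arr - q, axis=1) <= p.np_radius).sum() - 1
                assert n <= 2 * p.tau_P

    def test_ytree_coverage_and_bifurcation(self, ytree_run, ytree_skeletons):
        skel = ytree_skeletons["trunk"]
        assert len(skel.bifurcations) >= 1
        m = centerline_error(skel, ytree_run.truth)
        assert m["coverage"] >= 0.90
        assert m["mean_dist"] <= 1.5
        # every detected branch point lies on the vessel tree
        from scipy.spatial import cKDTree
        t = cKDTree(ytree_run.truth.all_points)
        d, _ = t.query(np.array(skel.bifurcations))
        assert d.max() <= 2.0

    def test_deterministic(self, ytree_run):
        run = ytree_run
        i = 10
        seed = run.ridges.xy[i].astype(float)
        s1 = track(run.ms.response, run.mask, run.ridges, seed, run.cfg.track)
        s2 = track(run.ms.response, run.mask, run.ridges, seed, run.cfg.track)
        assert s1.bifurcations == s2.bifurcations
        assert [[(p.x, p.y) for p in br] for br in s1.branches] \
            == [[(p.x, p.y) for p in br] for br in s2.branches]

    def test_seed_robustness(self, ytree_run, ytree_skeletons):
        from coroseg.phantom import coverage_vector
        covs = [coverage_vector(sk, ytree_run.truth)
                for sk in ytree_skeletons.values()]
        for i in range(len(covs)):
            for j in range(i + 1, len(covs)):
                assert (covs[i] == covs[j]).mean() >= 0.85
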