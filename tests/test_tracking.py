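"""Spot detection, sub-pixel fitting, linking, filtering, registration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from autosmi.simulate import SimulationConfig, render_frame, render_movie
from autosmi.tracking import (Spot, Trajectory, correlation_map, detect_spots,
                              fit_channel_transform, fit_spot,
                              gaussian_template, link_frames, track_movie)


def brute_force_correlation(image, template, i, j):
    r = template.shape[0] // 2
    win = image[i - r:i + r + 1, j - r:j + r + 1]
    a = template - template.mean()
    b = win - win.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    return np.sum(a * b) / denom if denom > 0 else 0.0


class TestCorrelationMap:
    def test_template_pasted_gives_one(self):
        tmpl = gaussian_template()
        img = np.zeros((32, 32))
        img[10:21, 14:25] = tmpl
        corr, _ = correlation_map(img, tmpl)
        assert corr[15, 19] == pytest.approx(1.0, abs=1e-12)

    def test_negated_template_gives_minus_one(self):
        tmpl = gaussian_template()
        img = np.zeros((32, 32))
        img[10:21, 14:25] = -tmpl
        corr, _ = correlation_map(img, tmpl)
        assert corr[15, 19] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_brute_force_everywhere(self, rng):
        img = rng.random((32, 32))
        tmpl = gaussian_template()
        corr, valid = correlation_map(img, tmpl)
        r = tmpl.shape[0] // 2
        for i in range(r, 32 - r):
            for j in range(r, 32 - r):
                assert abs(corr[i, j] - brute_force_correlation(img, tmpl, i, j)) < 1e-10

    @given(seed=st.integers(0, 100))
    def test_values_bounded(self, seed):
        img = np.random.default_rng(seed).normal(size=(24, 24)) * 100
        corr, valid = correlation_map(img)
        vals = corr[valid]
        assert np.all(vals >= -1.0) and np.all(vals <= 1.0)

    def test_constant_window_defined_as_zero(self):
        img = np.full((24, 24), 7.0)
        corr, valid = correlation_map(img)
        assert np.all(corr[valid] == 0.0)

    def test_border_marked_invalid(self, rng):
        corr, valid = correlation_map(rng.random((20, 20)))
        assert not valid[0, 0] and np.isnan(corr[0, 0])
        assert valid[10, 10]

    def test_image_smaller_than_template_rejected(self):
        with pytest.raises(ValueError):
            correlation_map(np.zeros((8, 8)))


class TestDetectSpots:
    def test_all_below_threshold_gives_empty(self):
        corr = np.full((20, 20), 0.1)
        centroids, _ = detect_spots(corr)
        assert len(centroids) == 0

    def test_two_separated_spots_give_two_components(self):
        cfg = SimulationConfig(field_size=(48, 48), noise_model="none")
        frame = render_frame(np.array([[12.0, 12.0], [36.0, 34.0]]),
                             np.array([1000.0, 800.0]), cfg)
        corr, _ = correlation_map(frame)
        centroids, _ = detect_spots(corr)
        assert len(centroids) == 2

    def test_threshold_tradeoff(self, rng):
        """Raising the threshold toward 1 loses dim spots; lowering toward 0
        admits noise pixels."""
        cfg = SimulationConfig(field_size=(48, 48), noise_model="gaussian",
                               read_noise_sd=20.0, rng_seed=4)
        frame = render_frame(np.array([[24.0, 24.0]]), np.array([120.0]),
                             cfg, rng=cfg.rng())
        corr, valid = correlation_map(frame)
        assert len(detect_spots(corr, threshold=0.95)[0]) == 0  # dim spot missed
        centroids, _ = detect_spots(corr, threshold=0.25)
        assert any(np.hypot(c[0] - 24, c[1] - 24) < 2 for c in centroids)
        # thresholded area grows monotonically as the threshold drops
        areas = [(np.nan_to_num(corr, nan=-1) >= t).sum()
                 for t in (0.95, 0.25, 0.02)]
        assert areas[0] < areas[1] < areas[2]


class TestFitSpot:
    def test_noiseless_parameters_recovered(self):
        cfg = SimulationConfig(field_size=(32, 32), noise_model="none",
                               background_offset=100.0)
        frame = render_frame(np.array([[15.4, 16.2]]), np.array([1000.0]), cfg)
        s = fit_spot(frame, (15, 16))
        assert s.x == pytest.approx(15.4, abs=1e-3)
        assert s.y == pytest.approx(16.2, abs=1e-3)
        assert s.i0 == pytest.approx(1000.0, rel=1e-3)
        assert s.sigma_a == pytest.approx(2.0, rel=1e-3)
        assert s.i_back == pytest.approx(100.0, rel=1e-3)

    def test_tilted_background_slopes_noiseless_exact(self):
        cfg = SimulationConfig(field_size=(32, 32), noise_model="none",
                               background_offset=500.0,
                               background_slope=(2.0, -1.0))
        frame = render_frame(np.array([[16.0, 16.0]]), np.array([1000.0]), cfg)
        s = fit_spot(frame, (16, 16))
        assert s.a == pytest.approx(2.0, rel=1e-3)
        assert s.b == pytest.approx(-1.0, rel=1e-3)

    def test_tilted_background_slopes_unbiased_at_snr_10(self):
        """Averaged over many spots at SNR 10 (peak 1000, noise SD 100) the
        fitted slopes agree with the generator truth within 3 SE."""
        cfg = SimulationConfig(field_size=(32, 32), noise_model="gaussian",
                               read_noise_sd=100.0, background_offset=500.0,
                               background_slope=(2.0, -1.0), rng_seed=1)
        r = cfg.rng()
        a_hat, b_hat = [], []
        for _ in range(400):
            frame = render_frame(np.array([[16.0, 16.0]]), np.array([1000.0]),
                                 cfg, rng=r)
            s = fit_spot(frame, (16, 16))
            if s is not None:
                a_hat.append(s.a)
                b_hat.append(s.b)
        se_a = np.std(a_hat, ddof=1) / np.sqrt(len(a_hat))
        se_b = np.std(b_hat, ddof=1) / np.sqrt(len(b_hat))
        assert abs(np.mean(a_hat) - 2.0) < 3 * se_a
        assert abs(np.mean(b_hat) + 1.0) < 3 * se_b

    def test_border_spot_not_fitted(self):
        assert fit_spot(np.zeros((32, 32)), (2, 2)) is None


class TestLinking:
    def test_pair_within_distance_linked(self):
        pairs, up, uc = link_frames([(0.0, 0.0)], [(3.0, 0.0)])
        assert pairs == [(0, 0)] and not up and not uc

    def test_pair_beyond_distance_not_linked(self):
        pairs, up, uc = link_frames([(0.0, 0.0)], [(7.0, 0.0)])
        assert pairs == [] and up == [0] and uc == [0]

    @given(seed=st.integers(0, 500))
    def test_greedy_matches_exhaustive_on_small_sets(self, seed):
        """On <= 5 spots per frame with moderate separation, greedy
        ascending-distance assignment equals the exhaustive minimum-total-
        distance matching."""
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 5))
        prev = r.uniform(0, 20, size=(n, 2))
        curr = prev + r.normal(0, 0.8, size=(n, 2))  # steps << separation
        pairs, _, _ = link_frames(prev, curr)
        best_cost, best_pairs = np.inf, None
        for perm in itertools.permutations(range(n)):
            d = [np.hypot(*(prev[i] - curr[perm[i]])) for i in range(n)]
            if max(d) >= 6.0:
                continue
            if sum(d) < best_cost:
                best_cost, best_pairs = sum(d), {(i, perm[i]) for i in range(n)}
        if best_pairs is not None and len(pairs) == n:
            assert set(pairs) == best_pairs

    def test_crossing_geometry_greedy_equals_optimal(self):
        prev = np.array([[0.0, 0.0], [4.0, 0.0]])
        curr = np.array([[1.0, 0.0], [3.0, 0.0]])
        greedy, _, _ = link_frames(prev, curr, method="greedy")
        optimal, _, _ = link_frames(prev, curr, method="optimal")
        assert set(greedy) == set(optimal) == {(0, 0), (1, 1)}


def _make_traj(points, sigma=2.0, start_frame=0):
    return Trajectory(spots=[Spot(frame=start_frame + k, x=float(x), y=float(y),
                                  i0=1000.0, sigma_a=sigma, a=0.0, b=0.0,
                                  i_back=100.0)
                             for k, (x, y) in enumerate(points)])


class TestFilter:
    def test_inside_mask_good_sigma_kept(self):
        from autosmi.tracking import filter_trajectories
        mask = np.ones((32, 32))
        kept, log = filter_trajectories([_make_traj([(5, 5), (6, 6)])], mask)
        assert len(kept) == 1 and log["kept"] == 1

    def test_oversized_sigma_removed(self):
        from autosmi.tracking import filter_trajectories
        kept, log = filter_trajectories(
            [_make_traj([(5, 5), (6, 6)], sigma=2.6)], np.ones((32, 32)))
        assert not kept and log["sigma_bounds"] == 1

    def test_hand_labeled_fixture_counts(self):
        """10 trajectories, 4 violating (2 off-mask, 1 small, 1 large sigma)
        -> exactly 6 kept."""
        from autosmi.tracking import filter_trajectories
        mask = np.zeros((32, 32))
        mask[:, :16] = 1
        trajs = [_make_traj([(5, 5), (6, 5)]) for _ in range(6)]
        trajs.append(_make_traj([(25, 5), (26, 5)]))          # off mask
        trajs.append(_make_traj([(5, 5), (25, 5)]))           # wanders off
        trajs.append(_make_traj([(5, 5), (6, 5)], sigma=1.0))  # too small
        trajs.append(_make_traj([(5, 5), (6, 5)], sigma=3.0))  # too large
        kept, log = filter_trajectories(trajs, mask)
        assert len(kept) == 6
        assert log["outside_mask"] == 2 and log["sigma_bounds"] == 2


class TestChannelTransform:
    def test_identity_on_identical_sets(self, rng):
        pts = rng.uniform(0, 100, size=(6, 2))
        t = fit_channel_transform(pts, pts)
        np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-9)
        assert t.residual_rms == pytest.approx(0.0, abs=1e-9)

    def test_rotation_and_shift_recovered_exactly(self, rng):
        pts = rng.uniform(0, 100, size=(8, 2))
        theta = np.deg2rad(2.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([3.2, -1.1])
        t = fit_channel_transform(moved, pts)
        assert t.rotation_deg == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(t.translation, [3.2, -1.1], atol=1e-9)
        np.testing.assert_allclose(t.apply(pts), moved, atol=1e-9)

    def test_noisy_fiducials_residual_near_noise_level(self, rng):
        pts = rng.uniform(0, 100, size=(50, 2))
        noise = 0.1
        moved = pts + rng.normal(0, noise, size=pts.shape)
        t = fit_channel_transform(moved, pts)
        assert 0.05 < t.residual_rms < 0.25

    def test_collinear_fiducials_rejected(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError):
            fit_channel_transform(pts, pts)


class TestEndToEnd:
    def test_noiseless_movie_exact_recovery(self):
        """Noiseless well-separated emitters: trajectory count, lengths and
        linking equal ground truth; positional RMSE < 0.05 px."""
        cfg = SimulationConfig(field_size=(96, 96), noise_model="none",
                               n_frames=12, rng_seed=8)
        rng = cfg.rng()
        n_tracks = 5
        starts = np.column_stack([np.linspace(1.5, 7.5, n_tracks),
                                  np.linspace(1.5, 7.5, n_tracks)])
        steps = rng.normal(0, 0.04, size=(n_tracks, cfg.n_frames - 1, 2))
        pos = np.concatenate([starts[:, None, :],
                              starts[:, None, :] + np.cumsum(steps, axis=1)],
                             axis=1)
        stack, truth = render_movie(pos, 1, cfg, rng=rng)
        trajs, log = track_movie(stack.frames)
        assert len(trajs) == n_tracks
        assert all(len(t) == cfg.n_frames for t in trajs)
        rec = sorted(trajs, key=lambda t: t.spots[0].x)
        order = np.argsort(pos[:, 0, 0])
        err = []
        for tr, i in zip(rec, order):
            err.append(tr.positions - pos[i] / cfg.pixel_size)
        rmse = np.sqrt(np.mean(np.concatenate(err) ** 2))
        assert rmse < 0.05
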