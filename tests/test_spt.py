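"""Motion analysis: linking, MSD, power-law fits, classification, coverage."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucuslab import spt


def _walk(rng, n, d=0.05, dt=0.2):
    xy = np.vstack([np.zeros((1, 2)),
                    np.cumsum(rng.normal(0, np.sqrt(2 * d * dt), (n - 1, 2)), axis=0)])
    return spt.Trajectory(0, np.arange(n), xy, dt)


# ---------------------------------------------------------------------------
# linking


class TestLinking:
    def test_single_drifting_particle_yields_one_full_track(self):
        frames = np.arange(30)
        df = pd.DataFrame({"frame": frames, "x_um": 0.1 * frames, "y_um": 0.0})
        trajs = spt.link_detections(df, max_disp=0.5)
        assert len(trajs) == 1 and len(trajs[0]) == 30

    def test_two_distant_parallel_tracks_stay_separate(self):
        frames = np.arange(20)
        df = pd.concat([
            pd.DataFrame({"frame": frames, "x_um": 0.05 * frames, "y_um": 0.0}),
            pd.DataFrame({"frame": frames, "x_um": 0.05 * frames, "y_um": 5.0}),
        ])
        trajs = spt.link_detections(df, max_disp=0.5)
        assert len(trajs) == 2
        assert all(len(t) == 20 for t in trajs)
        for t in trajs:  # no crossover: y stays constant per track
            assert np.ptp(t.xy[:, 1]) == 0

    def test_ambiguous_pairing_matches_min_total_displacement(self):
        # two particles, 3 frames; one frame transition is ambiguous but the
        # greedy choice coincides with the global optimum, found here by
        # enumerating every frame-to-frame assignment.
        pts = {
            0: np.array([[0.0, 0.0], [1.0, 0.0]]),
            1: np.array([[0.1, 0.1], [0.9, 0.05]]),
            2: np.array([[0.15, 0.2], [0.85, 0.1]]),
        }
        df = pd.concat([
            pd.DataFrame({"frame": f, "x_um": p[:, 0], "y_um": p[:, 1]})
            for f, p in pts.items()
        ])

        best_cost, best_paths = np.inf, None
        for p1 in itertools.permutations(range(2)):
            for p2 in itertools.permutations(range(2)):
                cost = sum(np.linalg.norm(pts[1][p1[i]] - pts[0][i]) for i in range(2))
                cost += sum(np.linalg.norm(pts[2][p2[p1[i]]] - pts[1][p1[i]]) for i in range(2))
                if cost < best_cost:
                    best_cost = cost
                    best_paths = {
                        i: np.array([pts[0][i], pts[1][p1[i]], pts[2][p2[p1[i]]]])
                        for i in range(2)
                    }

        trajs = spt.link_detections(df, max_disp=0.5)
        assert len(trajs) == 2
        got = sorted([t.xy.tolist() for t in trajs])
        want = sorted([p.tolist() for p in best_paths.values()])
        assert got == want

    def test_gap_beyond_max_gap_starts_new_track(self):
        df = pd.DataFrame({"frame": [0, 1, 5, 6], "x_um": 0.0, "y_um": 0.0})
        assert len(spt.link_detections(df, max_disp=1.0, max_gap=0)) == 2
        assert len(spt.link_detections(df, max_disp=1.0, max_gap=4)) == 1

    def test_empty_input_gives_empty_list(self):
        assert spt.link_detections(pd.DataFrame(columns=["frame", "x_um", "y_um"]), 1.0) == []


# ---------------------------------------------------------------------------
# MSD


class TestMSD:
    def test_stationary_particle_has_zero_msd(self):
        t = spt.Trajectory(0, np.arange(10), np.ones((10, 2)), 1.0)
        msd = spt.compute_msd(t)
        assert np.all(msd.msd == 0)

    def test_ballistic_hand_values(self):
        # positions (0,0),(1,0),(2,0) at dt=1 s: MSD(1)=1, MSD(2)=4 µm²
        t = spt.Trajectory(0, np.arange(3), np.array([[0, 0], [1, 0], [2, 0]], float), 1.0)
        msd = spt.compute_msd(t, max_lag_frac=1.0, method="direct")
        assert msd.msd == pytest.approx([1.0, 4.0])
        assert msd.n_pairs.tolist() == [2, 1]

    @given(st.integers(0, 2**31 - 1), st.integers(10, 200))
    @settings(max_examples=25, deadline=None)
    def test_fft_equals_direct_sum(self, seed, n):
        traj = _walk(np.random.default_rng(seed), n)
        fft = spt.compute_msd(traj, method="fft")
        direct = spt.compute_msd(traj, method="direct")
        np.testing.assert_allclose(fft.msd, direct.msd, rtol=1e-9, atol=1e-15)
        assert np.array_equal(fft.n_pairs, direct.n_pairs)

    def test_gapped_track_averages_existing_pairs(self):
        # frames 0,1,3: lag 1 has pairs (0,1); lag 2 has (1,3); lag 3 has (0,3)
        xy = np.array([[0, 0], [1, 0], [3, 0]], float)
        t = spt.Trajectory(0, np.array([0, 1, 3]), xy, 1.0)
        msd = spt.compute_msd(t, max_lag_frac=1.0)
        assert dict(zip(msd.lags, msd.msd)) == {1.0: 1.0, 2.0: 4.0, 3.0: 9.0}
        assert msd.n_pairs.tolist() == [1, 1, 1]

    def test_too_short_trajectory_rejected(self):
        t = spt.Trajectory(0, np.array([0]), np.zeros((1, 2)), 1.0)
        with pytest.raises(ValueError):
            spt.compute_msd(t)


# ---------------------------------------------------------------------------
# fits and classification


class TestFit:
    def _curve(self, msd_fn, n=20, dt=1.0):
        lags = np.arange(1, n + 1) * dt
        return spt.MSDCurve(lags, msd_fn(lags), np.full(n, 100), dt)

    def test_exact_brownian_curve_recovers_D_1_alpha_1(self):
        mp = spt.fit_motion_params(self._curve(lambda t: 4.0 * t))
        assert mp.alpha == pytest.approx(1.0, abs=1e-12)
        assert mp.D == pytest.approx(1.0, rel=1e-12)
        assert mp.mobility_class == "free"

    def test_exact_subdiffusive_curve_recovered_to_machine_precision(self):
        mp = spt.fit_motion_params(self._curve(lambda t: 4 * 0.05 * t**0.5))
        assert mp.alpha == pytest.approx(0.5, abs=1e-12)
        assert mp.D == pytest.approx(0.05, rel=1e-12)

    def test_flat_curve_is_immobile(self):
        mp = spt.fit_motion_params(self._curve(lambda t: np.full_like(t, 0.01)))
        assert mp.alpha == pytest.approx(0.0, abs=1e-12)
        assert mp.mobility_class == "immobile"

    def test_all_zero_msd_is_immobile_with_zero_D(self):
        mp = spt.fit_motion_params(self._curve(lambda t: np.zeros_like(t)))
        assert (mp.alpha, mp.D, mp.mobility_class) == (0.0, 0.0, "immobile")

    def test_too_few_usable_lags_flagged_unreliable(self):
        lags = np.array([1.0, 2.0])
        curve = spt.MSDCurve(lags, np.array([0.1, 0.2]), np.array([5, 4]), 1.0)
        mp = spt.fit_motion_params(curve)
        assert not mp.reliable

    @pytest.mark.parametrize(
        "alpha,expected",
        [
            (0.8, "free"),
            (0.01, "confined"),
            (0.0005, "immobile"),
            (0.001, "confined"),  # boundary values fall in the middle bin
            (0.5, "confined"),
            (1.2, "free"),
        ],
    )
    def test_mobility_thresholds(self, alpha, expected):
        assert spt.classify_mobility(alpha) == expected


# ---------------------------------------------------------------------------
# coverage


def _coverage_reference(trajs, quantile, bin_size):
    """Independent straight-loop re-implementation of the coverage rule."""
    pts = []
    for t in trajs:
        origin = t.xy[0]
        for p in t.xy:
            pts.append((p[0] - origin[0], p[1] - origin[1]))
    pts = np.array(pts)
    radial = np.sqrt(pts[:, 0] ** 2 + pts[:, 1] ** 2)
    cut = np.quantile(radial, quantile)
    bins = set()
    for p, r in zip(pts, radial):
        if r <= cut:
            bins.add((int(np.floor(p[0] / bin_size)), int(np.floor(p[1] / bin_size))))
    return len(bins) * bin_size**2


class TestCoverage:
    def test_immobile_particles_occupy_one_bin(self):
        trajs = [
            spt.Trajectory(i, np.arange(5), np.full((5, 2), c), 1.0)
            for i, c in enumerate([0.0, 3.0, -1.0])  # re-origin collapses all
        ]
        cov = spt.coverage(trajs, quantile=0.98)
        assert cov.coverage_area == pytest.approx(0.183**2)
        assert cov.coverage_area == pytest.approx(0.0335, abs=2e-4)

    def test_area_monotone_in_quantile(self, brownian_movie):
        trajs, _ = brownian_movie
        a98 = spt.coverage(trajs[:100], quantile=0.98).coverage_area
        a100 = spt.coverage(trajs[:100], quantile=1.0).coverage_area
        assert a100 >= a98

    def test_matches_independent_reimplementation(self, brownian_movie):
        trajs, _ = brownian_movie
        sub = trajs[:50]
        cov = spt.coverage(sub, quantile=0.98, bin_size=0.183)
        ref = _coverage_reference(sub, 0.98, 0.183)
        assert cov.coverage_area == pytest.approx(ref, rel=0.15)


# ---------------------------------------------------------------------------
# group summaries


class TestSummaries:
    def _params(self, movie, classes, group="g1"):
        return pd.DataFrame({
            "group": group, "movie": movie,
            "particle_id": range(len(classes)),
            "D": 0.05, "mobility_class": classes, "reliable": True,
        })

    def test_fraction_counting(self):
        classes = ["free"] * 49 + ["confined"] * 50 + ["immobile"] * 1
        out = spt.summarize_groups(self._params("m1", classes))
        row = out.iloc[0]
        assert row["mean_frac_free"] == pytest.approx(49.0)
        assert row["mean_frac_confined"] == pytest.approx(50.0)
        assert row["mean_frac_immobile"] == pytest.approx(1.0)

    def test_duplicated_movies_have_zero_sd(self):
        classes = ["free"] * 5 + ["confined"] * 5
        params = pd.concat([self._params("m1", classes), self._params("m2", classes)])
        out = spt.summarize_groups(params)
        assert out.iloc[0]["sd_frac_free"] == pytest.approx(0.0)
        assert out.iloc[0]["sd_D"] == pytest.approx(0.0)

    @given(st.lists(st.sampled_from(["free", "confined", "immobile"]), min_size=1, max_size=60))
    @settings(max_examples=30, deadline=None)
    def test_fractions_sum_to_100_exactly(self, classes):
        out = spt.summarize_groups(self._params("m1", classes))
        row = out.iloc[0]
        total = row["mean_frac_free"] + row["mean_frac_confined"] + row["mean_frac_immobile"]
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_mixture_recovery_within_5_points(self):
        from mucuslab import synth

        spec = synth.TrajectorySimSpec(
            n_particles=500, class_mix=(0.50, 0.45, 0.05), seed=21
        )
        trajs, _ = synth.simulate_trajectories(spec)
        params = spt.analyze_trajectories(trajs)
        params["group"], params["movie"] = "g", "m"
        out = spt.summarize_groups(params)
        row = out.iloc[0]
        assert row["mean_frac_free"] == pytest.approx(50.0, abs=5.0)
        assert row["mean_frac_confined"] == pytest.approx(45.0, abs=5.0)
        assert row["mean_frac_immobile"] == pytest.approx(5.0, abs=5.0)

    def test_empty_movie_reported_nd(self):
        params = self._params("m1", ["free"] * 3)
        params["reliable"] = False
        with pytest.warns(UserWarning, match="no usable particles"):
            out = spt.summarize_groups(params)
        assert np.isnan(out.iloc[0]["mean_D"])
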