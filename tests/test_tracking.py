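import numpy as np
import pandas as pd
import pytest

from nucleopol.simulate import TrackSimSpec, simulate_tracks
from nucleopol.tracking import (
    AnomalousDiffusionMSD,
    MSDCurve,
    MSDFit,
    classify_mobility,
    compute_msd,
    fit_anomalous,
    link_tracks,
    summarize_mobility,
)

from _oracles import msd_bruteforce


def track_df(xyz, frames=None, dt=0.032):
    xyz = np.asarray(xyz, float)
    frames = np.arange(len(xyz)) if frames is None else np.asarray(frames)
    cols = {"track_id": 0, "frame": frames, "t_s": frames * dt,
            "x_um": xyz[:, 0], "y_um": xyz[:, 1]}
    if xyz.shape[1] == 3:
        cols["z_um"] = xyz[:, 2]
    return pd.DataFrame(cols)


class TestComputeMSD:
    def test_immobile_track_is_zero(self):
        curve = compute_msd(track_df(np.zeros((20, 3))))
        assert np.all(curve.msd == 0.0)

    def test_three_frame_hand_example(self):
        curve = compute_msd(track_df([(0, 0, 0), (1, 0, 0), (2, 0, 0)], dt=1.0))
        np.testing.assert_allclose(curve.msd, [1.0, 4.0])
        np.testing.assert_array_equal(curve.n_pairs, [2, 1])

    def test_gap_excludes_spanning_pairs(self):
        # frames 0,1,3: lag-1 pairs (0,1) only; lag-2 pairs (1,3); lag-3 (0,3)
        curve = compute_msd(
            track_df([(0, 0), (1, 0), (3, 0)], frames=[0, 1, 3], dt=1.0)
        )
        np.testing.assert_array_equal(curve.n_pairs, [1, 1, 1])
        np.testing.assert_allclose(curve.msd, [1.0, 4.0, 9.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        xyz = rng.normal(0, 1, (n, 3))
        frames = np.sort(rng.choice(np.arange(2 * n), size=n, replace=False))
        curve = compute_msd(track_df(xyz, frames=frames, dt=0.032))
        lags, msds, counts = msd_bruteforce(xyz, frames, 0.032)
        np.testing.assert_allclose(curve.lags, lags, rtol=1e-12)
        np.testing.assert_allclose(curve.msd, msds, rtol=1e-9)
        np.testing.assert_array_equal(curve.n_pairs, counts)

    def test_ensemble_brownian_msd_matches_closed_form(self):
        # mean MSD over many 3D Brownian tracks approaches 6 D tau
        D, dt = 0.4, 0.032
        spec = TrackSimSpec(n_tracks=300, frames=40, dt=dt, D=D, alpha=1.0,
                            dims=3, loc_error_sigma=0.0, seed=1)
        traj, _ = simulate_tracks(spec)
        lag1 = []
        for _, tr in traj.groupby("track_id"):
            lag1.append(compute_msd(tr).msd[0])
        assert np.mean(lag1) == pytest.approx(6 * D * dt, rel=0.05)


class TestFitAnomalous:
    def test_noiseless_brownian_curve_exact(self):
        lags = np.arange(1, 11) * 0.032
        curve = MSDCurve(lags=lags, msd=6 * 0.4 * lags, n_pairs=np.full(10, 50), dims=3)
        fit = fit_anomalous(curve)
        assert fit.D == pytest.approx(0.4, rel=1e-12)
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)

    def test_noiseless_subdiffusive_curve_exact(self):
        lags = np.arange(1, 21) * 0.032
        curve = MSDCurve(lags=lags, msd=4 * 1.5 * lags**0.6, n_pairs=np.full(20, 50), dims=2)
        fit = fit_anomalous(curve)
        assert fit.D == pytest.approx(1.5, rel=1e-12)
        assert fit.alpha == pytest.approx(0.6, abs=1e-12)

    def test_all_zero_curve_is_static(self):
        curve = MSDCurve(lags=np.arange(1, 5) * 0.032, msd=np.zeros(4),
                         n_pairs=np.full(4, 3), dims=3)
        fit = fit_anomalous(curve)
        assert fit.D == 0.0 and fit.mobility_class == "static"
        assert np.isnan(fit.alpha)

    def test_too_few_lags_flags_failure(self):
        curve = MSDCurve(lags=np.array([0.032, 0.064]), msd=np.array([0.1, 0.2]),
                         n_pairs=np.array([5, 4]), dims=3)
        assert not fit_anomalous(curve).ok

    def test_offset_variant_recovers_error_floor(self):
        # msd = 6 D tau^alpha + 2*3*sigma^2 with a visible static-error floor
        lags = np.arange(1, 11) * 0.032
        sigma2 = 0.02**2
        curve = MSDCurve(lags=lags, msd=6 * 0.02 * lags + 6 * sigma2,
                         n_pairs=np.full(10, 50), dims=3)
        plain = fit_anomalous(curve)
        offset = fit_anomalous(curve, loc_error_offset=True)
        assert offset.D == pytest.approx(0.02, rel=1e-3)
        assert offset.alpha == pytest.approx(1.0, abs=1e-3)
        # the default log-log fit absorbs the floor into a biased alpha
        assert abs(plain.alpha - 1.0) > abs(offset.alpha - 1.0)

    def test_subdiffusive_recovery_from_fbm(self):
        spec = TrackSimSpec(n_tracks=200, frames=100, D=0.5, alpha=0.5, dims=3,
                            loc_error_sigma=0.0, seed=2)
        traj, _ = simulate_tracks(spec)
        est = AnomalousDiffusionMSD().fit(traj)
        assert abs(est.fits_["alpha"].median() - 0.5) < 0.1


class TestClassification:
    @pytest.mark.parametrize(
        "D,expected",
        [
            (0.05, "static"),
            (0.1, "diffusive"),  # boundary closed on the right
            (2.0, "diffusive"),
            (5.0, "diffusive"),
            (7.0, "hypermobile"),
        ],
    )
    def test_thresholds(self, D, expected):
        assert classify_mobility(D) == expected

    def test_pure_function_of_D(self):
        rng = np.random.default_rng(3)
        Ds = rng.uniform(0, 10, 50)
        classes = [classify_mobility(D) for D in Ds]
        perm = rng.permutation(50)
        assert [classify_mobility(D) for D in Ds[perm]] == [classes[i] for i in perm]


class TestSummarize:
    @staticmethod
    def fit(D, cls=None):
        return MSDFit(D=D, alpha=1.0, dims=3, fit_lags=5, rss=0.0,
                      mobility_class=cls or classify_mobility(D), ok=True)

    def test_all_static(self):
        s = summarize_mobility([self.fit(0.01)] * 5)
        assert s.static_fraction == 1.0 and s.mobile_fraction == 0.0

    def test_52_48_split(self):
        fits = [self.fit(0.05)] * 52 + [self.fit(1.0)] * 48
        s = summarize_mobility(fits)
        assert s.static_fraction == pytest.approx(0.52)

    def test_hypermobile_excluded_from_mean_D(self):
        fits = [self.fit(0.05), self.fit(1.0), self.fit(100.0)]
        s = summarize_mobility(fits)
        assert s.mean_D == pytest.approx((0.05 + 1.0) / 2)
        assert s.n_tracks == 3

    def test_include_hypermobile_flag_changes_mean_only(self):
        fits = [self.fit(0.05), self.fit(1.0), self.fit(100.0)]
        s_in = summarize_mobility(fits, include_hypermobile=True)
        s_out = summarize_mobility(fits)
        assert s_in.mean_D == pytest.approx((0.05 + 1.0 + 100.0) / 3)
        assert s_in.static_fraction == s_out.static_fraction

    def test_no_successful_fits_raises(self):
        bad = MSDFit(D=np.nan, alpha=np.nan, dims=3, fit_lags=0, rss=np.nan,
                     mobility_class="unclassified", ok=False)
        with pytest.raises(ValueError):
            summarize_mobility([bad])


class TestLinkTracks:
    @staticmethod
    def detections(points_by_frame):
        rows = []
        for f, pts in enumerate(points_by_frame):
            for p in pts:
                rows.append({"frame": f, "x_um": p[0], "y_um": p[1], "z_um": 0.0})
        return pd.DataFrame(rows)

    def test_drifting_particle_single_track(self):
        det = self.detections([[(0.1 * f, 0.0)] for f in range(15)])
        out = link_tracks(det, max_disp=0.4, min_frames=10)
        assert out["track_id"].nunique() == 1
        assert len(out) == 15

    def test_oversized_jump_splits_track(self):
        pts = [[(0.0, 0.0)]] * 12 + [[(0.5, 0.0)]] * 12
        det = self.detections(pts)
        out = link_tracks(det, max_disp=0.4, min_frames=10)
        assert out["track_id"].nunique() == 2

    def test_two_distant_particles_no_identity_swap(self):
        pts = [[(0.05 * f, 0.0), (0.05 * f, 5.0)] for f in range(12)]
        out = link_tracks(self.detections(pts), max_disp=0.4, min_frames=10)
        assert out["track_id"].nunique() == 2
        for _, tr in out.groupby("track_id"):
            assert tr["y_um"].nunique() == 1  # each track stays on its own line

    def test_short_tracks_discarded(self):
        det = self.detections([[(0.0, 0.0)]] * 5)
        out = link_tracks(det, max_disp=0.4, min_frames=10)
        assert len(out) == 0
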