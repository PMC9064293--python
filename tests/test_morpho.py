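"""Convergence/thickening morphometrics, changepoints, group statistics."""

import numpy as np
import pandas as pd
import pytest

from tensiomorph.morpho import (
    BlastoporeMetrics,
    RegionSeries,
    SphereGeometry,
    TrackTable,
    blastopore_closure,
    cell_shape_metrics,
    detect_rate_change,
    estimate_rate,
    region_widths,
    spherical_area_correction,
    summarize_groups,
)
from tensiomorph.synthetic import SyntheticTrackSpec, gen_track_table


def make_tracks(rows):
    return TrackTable(data=pd.DataFrame(rows, columns=["point_id", "region", "t_hr", "x", "y"]))


class TestRegionWidths:
    def test_static_points_give_unit_ratio(self):
        rows = []
        for t in [0.0, 1.0, 2.0]:
            rows += [("a", "IMZ", t, 0.0, 0.0), ("b", "IMZ", t, 100.0, 0.0)]
        s = region_widths(make_tracks(rows), {"IMZ": ("a", "b")})["IMZ"]
        assert np.allclose(s.ratio, 1.0)

    def test_translation_invariance(self):
        rows, rows_shifted = [], []
        rng = np.random.default_rng(0)
        for t in np.linspace(0, 2, 5):
            w = 100 - 10 * t
            for pid, x in [("a", 0.0), ("b", None)]:
                xv = w if x is None else x
                rows.append((pid, "IMZ", t, xv, 0.0))
                rows_shifted.append((pid, "IMZ", t, xv + 55.0, -30.0))
        s0 = region_widths(make_tracks(rows), {"IMZ": ("a", "b")})["IMZ"]
        s1 = region_widths(make_tracks(rows_shifted), {"IMZ": ("a", "b")})["IMZ"]
        assert np.allclose(s0.ratio, s1.ratio)

    def test_missing_timepoints_dropped_and_logged(self):
        rows = [
            ("a", "IMZ", 0.0, 0.0, 0.0),
            ("b", "IMZ", 0.0, 50.0, 0.0),
            ("a", "IMZ", 1.0, 0.0, 0.0),  # b missing at t=1
            ("a", "IMZ", 2.0, 0.0, 0.0),
            ("b", "IMZ", 2.0, 40.0, 0.0),
        ]
        s = region_widths(make_tracks(rows), {"IMZ": ("a", "b")})["IMZ"]
        assert len(s.t_hr) == 2
        assert s.meta["dropped_timepoints"] == 1

    def test_duplicate_track_rows_rejected(self):
        rows = [("a", "IMZ", 0.0, 0.0, 0.0), ("a", "IMZ", 0.0, 1.0, 0.0)]
        with pytest.raises(ValueError):
            make_tracks(rows)


class TestEstimateRate:
    def test_exact_linear_ratio(self):
        t = np.linspace(0, 2, 9)
        s = RegionSeries(label="IMZ", t_hr=t, W_t=100 * (1 - 0.1 * t))
        assert estimate_rate(s)["rate_pct_per_hr"] == pytest.approx(10.0, abs=1e-10)

    def test_constant_ratio_zero_rate(self):
        s = RegionSeries(label="NIMZ", t_hr=np.linspace(0, 2, 9), W_t=np.full(9, 80.0))
        assert estimate_rate(s)["rate_pct_per_hr"] == pytest.approx(0.0, abs=1e-12)

    def test_noisy_recovery_mean_within_half_percent_per_hr(self):
        estimates = []
        for seed in range(20):
            spec = SyntheticTrackSpec(
                regions=(("NIMZ", 7.0, 7.0, 99.0),), seed=seed
            )
            s = region_widths(gen_track_table(spec))["NIMZ"]
            estimates.append(estimate_rate(s)["rate_pct_per_hr"])
        assert np.mean(estimates) == pytest.approx(7.0, abs=0.5)

    def test_too_few_points_rejected(self):
        s = RegionSeries(label="x", t_hr=np.array([0.0, 1.0]), W_t=np.array([1.0, 0.9]))
        with pytest.raises(ValueError):
            estimate_rate(s)


class TestChangepoint:
    def test_exact_recovery_on_noise_free_break(self):
        spec = SyntheticTrackSpec(
            regions=(("NIMZ", 7.0, 0.0, -0.7),), positional_noise_sd=0.0
        )
        s = region_widths(gen_track_table(spec))["NIMZ"]
        res = detect_rate_change(s)
        assert res["changepoint_hr"] == pytest.approx(-0.7, abs=1e-9)
        assert res["rate_before_pct_per_hr"] == pytest.approx(7.0, abs=1e-6)
        assert res["rate_after_pct_per_hr"] == pytest.approx(0.0, abs=1e-6)

    def test_single_slope_series_reports_no_changepoint(self):
        t = np.linspace(-2, 1, 40)
        s = RegionSeries(label="IMZ", t_hr=t, W_t=1000 * (1 - 0.1 * (t - t[0])))
        assert detect_rate_change(s)["changepoint_hr"] is None

    def test_noisy_breakpoint_within_ten_minutes(self):
        hits = 0
        for seed in range(20):
            spec = SyntheticTrackSpec(regions=(("NIMZ", 7.0, 0.0, -0.7),), seed=seed)
            s = region_widths(gen_track_table(spec))["NIMZ"]
            res = detect_rate_change(s)
            if res["changepoint_hr"] is not None and abs(res["changepoint_hr"] + 0.7) <= 10 / 60:
                hits += 1
        assert hits >= 16


class TestSphericalCorrection:
    def test_hemisphere_ratio_exactly_two(self):
        geom = SphereGeometry(R=1.0)
        assert spherical_area_correction(geom, 1.0)["ratio"] == pytest.approx(2.0, abs=1e-12)

    def test_small_cap_limit_ratio_one(self):
        geom = SphereGeometry(R=1.0)
        r = np.sin(0.009)  # theta < 0.01 rad
        assert spherical_area_correction(geom, r)["ratio"] == pytest.approx(1.0, abs=1e-3)

    def test_half_radius_cap(self):
        geom = SphereGeometry(R=1.0)
        expected = 2 * (1 - np.cos(np.deg2rad(30))) / 0.25
        assert spherical_area_correction(geom, 0.5)["ratio"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.072, abs=2e-3)

    def test_monotonic_in_projected_radius(self):
        geom = SphereGeometry(R=1.0)
        ratios = [
            spherical_area_correction(geom, r)["ratio"] for r in np.linspace(0.05, 1.0, 12)
        ]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_annulus_as_cap_difference(self):
        geom = SphereGeometry(R=1.0)
        full = spherical_area_correction(geom, 0.8)["area_true"]
        inner = spherical_area_correction(geom, 0.3)["area_true"]
        ann = spherical_area_correction(geom, 0.8, r_proj_inner=0.3)["area_true"]
        assert ann == pytest.approx(full - inner, rel=1e-12)

    def test_out_of_range_radius_rejected(self):
        with pytest.raises(ValueError):
            spherical_area_correction(SphereGeometry(R=1.0), 1.2)


class TestBlastoporeClosure:
    def test_zero_area_is_closed(self):
        df = blastopore_closure([BlastoporeMetrics(0.0, 0.0, 10.0)])
        assert df["ratio"].iloc[0] == 0.0
        assert bool(df["closed"].iloc[0])

    def test_ratio_scale_invariant(self):
        a = BlastoporeMetrics(0.0, 2.0, 10.0)
        b = BlastoporeMetrics(0.0, 2.0 * 4.0, 10.0 * 4.0)  # uniform rescale
        assert a.ratio == pytest.approx(b.ratio, rel=1e-12)

    def test_radius_halving_quarters_ratio(self):
        series = [
            BlastoporeMetrics(0.0, np.pi * 1.0**2, 100.0),
            BlastoporeMetrics(1.0, np.pi * 0.5**2, 100.0),
        ]
        df = blastopore_closure(series)
        assert df["ratio"].iloc[1] == pytest.approx(df["ratio"].iloc[0] / 4.0, rel=1e-12)

    def test_blastopore_larger_than_embryo_rejected(self):
        with pytest.raises(ValueError):
            BlastoporeMetrics(0.0, 11.0, 10.0)


class TestCellShape:
    @staticmethod
    def ellipse(a, b, n=300):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return np.column_stack([a * np.cos(t), b * np.sin(t)])

    def test_circle_metrics(self):
        m = cell_shape_metrics([self.ellipse(1.0, 1.0)])
        assert m.circularity[0] == pytest.approx(1.0, abs=1e-3)
        assert m.length_width_ratio[0] == pytest.approx(1.0, abs=1e-3)

    def test_two_to_one_ellipse(self):
        m = cell_shape_metrics([self.ellipse(2.0, 1.0)])
        assert m.length_width_ratio[0] == pytest.approx(2.0, abs=0.02)
        assert m.circularity[0] == pytest.approx(0.84, abs=0.01)

    def test_stationary_cell_zero_speed(self):
        poly = self.ellipse(1.0, 1.0)
        m = cell_shape_metrics([poly, poly.copy()], times=[0.0, 2.5])
        assert m.centroid_speed[1] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(m.centroid_speed[0])

    def test_self_intersecting_outline_rejected(self):
        t = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        eight = np.column_stack([np.sin(2 * t), np.sin(t)])
        with pytest.raises(ValueError, match="self-intersecting"):
            cell_shape_metrics([eight])


class TestGroupSummaries:
    def test_identical_values_zero_sem(self):
        res = summarize_groups([3.0, 3.0, 3.0])
        assert res["groups"][0]["sem"] == 0.0

    def test_identical_groups_t_zero_p_one(self):
        res = summarize_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t_stat"] == pytest.approx(0.0, abs=1e-12)
        assert res["p_value"] == pytest.approx(1.0, abs=1e-12)

    def test_p_value_matches_independent_reference(self):
        # cross-check the pooled two-sample test against statsmodels
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        a = [4.2, 5.1, 3.8, 4.9, 5.5]
        b = [6.1, 5.9, 7.2, 6.5]
        res = summarize_groups(a, b)
        _, p_ref, _ = sm_ttest(np.asarray(a), np.asarray(b), usevar="pooled")
        assert res["p_value"] == pytest.approx(float(p_ref), abs=1e-10)

    def test_sem_matches_definition(self):
        vals = [1.0, 2.0, 4.0, 7.0]
        res = summarize_groups(vals)
        assert res["groups"][0]["sem"] == pytest.approx(
            np.std(vals, ddof=1) / np.sqrt(len(vals)), rel=1e-12
        )

    def test_single_sample_flagged(self):
        res = summarize_groups([1.0])
        assert np.isnan(res["groups"][0]["sem"])
        assert res["groups"][0]["flag"] == "sem_undefined_n_lt_2"


class TestRegimeReproduction:
    def test_imz_nimz_rate_difference_exceeds_4_pct_after_break(self):
        # the convergence signature: IMZ holds ~10 %/hr while NIMZ slows
        # to ~0 %/hr after the changepoint at -0.7 h
        spec = SyntheticTrackSpec(seed=11)
        series = region_widths(gen_track_table(spec))
        cp = detect_rate_change(series["NIMZ"])
        assert cp["changepoint_hr"] is not None
        imz_post = estimate_rate(series["IMZ"], window=(cp["changepoint_hr"], 10.0))
        diff = imz_post["rate_pct_per_hr"] - cp["rate_after_pct_per_hr"]
        assert diff > 4.0
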