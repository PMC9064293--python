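"""Generators: ground-truth plumbing, determinism, noise calibration."""

import numpy as np
import pytest

from tensiomorph.geometry import point_polyline_distances, polygon_area
from tensiomorph.laplace import FluidContext, integrate_profile
from tensiomorph.synthetic import (
    OverConvergenceError,
    SyntheticDropSpec,
    SyntheticTraceSpec,
    SyntheticTrackSpec,
    gen_drop_image,
    gen_drop_profile,
    gen_pushback_trace,
    gen_track_table,
)


class TestDropProfiles:
    def test_noise_free_points_lie_on_oracle_profile(self):
        spec = SyntheticDropSpec.for_bond(1.0, radial_noise_sd=0.0)
        contour = gen_drop_profile(spec)
        ctx = FluidContext(gamma=spec.gamma, delta_rho=spec.delta_rho, g=spec.g)
        oracle = integrate_profile(ctx, spec.R0, n_samples=8000)
        d = point_polyline_distances(contour.points, oracle.outline())
        assert d.max() < 1e-6 * spec.R0

    def test_zero_bond_contour_is_a_circle(self):
        spec = SyntheticDropSpec(delta_rho=0.0, R0=5e-4)
        pts = gen_drop_profile(spec).points
        center = np.array([0.0, spec.R0])
        radii = np.hypot(*(pts - center).T)
        assert np.abs(radii - spec.R0).max() < 1e-6 * spec.R0

    def test_same_seed_bitwise_identical(self):
        spec = SyntheticDropSpec.for_bond(1.0, radial_noise_sd=0.02, seed=42)
        a = gen_drop_profile(spec).points
        b = gen_drop_profile(spec).points
        assert a.tobytes() == b.tobytes()

    def test_truth_recorded_in_metadata(self):
        spec = SyntheticDropSpec.for_bond(2.0, seed=3)
        c = gen_drop_profile(spec)
        assert c.source["truth"]["gamma"] == spec.gamma
        assert c.source["bond_number"] == pytest.approx(2.0)

    def test_noise_scaling_doubles_point_distance_sd(self):
        # doubling the radial noise SD doubles the spread of
        # point-to-oracle distances (pooled over 50 seeds, within 10%)
        spec0 = SyntheticDropSpec.for_bond(1.0)
        ctx = FluidContext(gamma=spec0.gamma, delta_rho=spec0.delta_rho, g=spec0.g)
        outline = integrate_profile(ctx, spec0.R0, n_samples=8000).outline()

        def pooled_sd(noise):
            pools = []
            for seed in range(50):
                spec = SyntheticDropSpec.for_bond(
                    1.0, radial_noise_sd=noise, seed=seed
                )
                d = point_polyline_distances(gen_drop_profile(spec).points, outline)
                pools.append(d)
            return np.concatenate(pools).std()

        ratio = pooled_sd(0.02) / pooled_sd(0.01)
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticDropSpec(gamma=-1.0)
        with pytest.raises(ValueError):
            SyntheticDropSpec(R0=0.0)
        with pytest.raises(ValueError):
            SyntheticDropSpec(n_points=10)
        with pytest.raises(ValueError):
            SyntheticDropSpec(radial_noise_sd=-0.1)


class TestDropImages:
    def test_sharp_mask_area_matches_analytic_silhouette(self):
        spec = SyntheticDropSpec.for_bond(1.0, seed=0)
        px = spec.R0 / 80
        img = gen_drop_image(spec, pixel_scale=px, blur_sd=0.0, image_noise_sd=0.0)
        mask_area = (img.intensities > 0.5).sum() * px**2
        analytic = polygon_area(img.meta["truth_contour"])
        # within one pixel-row of boundary area
        perimeter_px = 2 * np.pi * spec.R0 / px
        assert abs(mask_area - analytic) < perimeter_px * px**2

    def test_circle_image_area_recovered_through_extraction(self):
        from tensiomorph.extraction import extract_contour

        R0 = 5e-4
        spec = SyntheticDropSpec(delta_rho=0.0, R0=R0, seed=1)
        img = gen_drop_image(spec, pixel_scale=R0 / 50, blur_sd=2.0)
        c = extract_contour(img)
        area = polygon_area(c.points)
        assert area == pytest.approx(np.pi * R0**2, rel=0.03)

    def test_drop_too_large_for_frame_errors(self):
        spec = SyntheticDropSpec.for_bond(1.0)
        with pytest.raises(ValueError, match="does not fit"):
            gen_drop_image(spec, pixel_scale=spec.R0 / 100, frame_shape=(64, 64))

    def test_degenerate_radius_rejected(self):
        with pytest.raises(ValueError):
            SyntheticDropSpec(R0=0.0)


class TestPushbackTraces:
    def test_ramp_free_trace_never_increases_noiselessly(self):
        trace = gen_pushback_trace(SyntheticTraceSpec(ramp_rate=0.0, noise_sd=0.0))
        assert np.all(np.diff(trace.F) <= 0)

    def test_noise_free_onset_at_construction_time(self):
        spec = SyntheticTraceSpec(noise_sd=0.0, onset_time=3600.0)
        trace = gen_pushback_trace(spec)
        rising = np.flatnonzero(np.diff(trace.F) > 0)
        assert trace.t[rising[0]] == pytest.approx(3600.0, abs=spec.dt)

    def test_determinism_and_truth(self):
        spec = SyntheticTraceSpec(seed=9)
        a, b = gen_pushback_trace(spec), gen_pushback_trace(spec)
        assert a.F.tobytes() == b.F.tobytes()
        assert a.source["truth"]["onset_time"] == 3600.0

    def test_invalid_trace_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTraceSpec(dt=0.0)
        with pytest.raises(ValueError):
            SyntheticTraceSpec(noise_sd=-1e-9)


class TestTrackTables:
    def test_linear_construction_hits_exact_final_ratio(self):
        spec = SyntheticTrackSpec(
            regions=(("IMZ", 10.0, 10.0, 99.0),),
            positional_noise_sd=0.0,
            t_start=0.0,
            time_span=2.0,
        )
        table = gen_track_table(spec)
        from tensiomorph.morpho import region_widths

        s = region_widths(table)["IMZ"]
        assert s.ratio[-1] == pytest.approx(0.80, abs=1e-12)

    def test_zero_rate_gives_constant_separation(self):
        spec = SyntheticTrackSpec(
            regions=(("NIMZ", 0.0, 0.0, 0.0),), positional_noise_sd=0.0
        )
        from tensiomorph.morpho import region_widths

        s = region_widths(gen_track_table(spec))["NIMZ"]
        assert np.allclose(s.ratio, 1.0)

    def test_over_convergence_raises(self):
        spec = SyntheticTrackSpec(
            regions=(("IMZ", 60.0, 60.0, 99.0),),
            t_start=0.0,
            time_span=2.0,
            positional_noise_sd=0.0,
        )
        with pytest.raises(OverConvergenceError):
            gen_track_table(spec)

    def test_duplicate_region_labels_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTrackSpec(regions=(("IMZ", 1, 1, 0), ("IMZ", 2, 2, 0)))

    def test_determinism(self):
        spec = SyntheticTrackSpec(seed=5)
        a = gen_track_table(spec).data
        b = gen_track_table(spec).data
        assert a.equals(b)
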