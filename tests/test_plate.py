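"""Plate-compression tension formula, strain protocol, push-back analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tensiomorph.plate import (
    CompressionGeometry,
    ForceTrace,
    GeometryError,
    analyze_pushback,
    compute_plate_sigma,
    compute_strain,
)
from tensiomorph.synthetic import SyntheticTraceSpec, gen_pushback_trace


class TestPlateSigma:
    def test_worked_geometry_evaluates_to_1p43_mN_per_m(self):
        geom = CompressionGeometry(
            F=0.5e-6, R1=250e-6, R2=80e-6, R3=150e-6, A=np.deg2rad(60)
        )
        assert compute_plate_sigma(geom) * 1e3 == pytest.approx(1.43, abs=0.01)

    def test_linearity_in_force(self):
        g1 = CompressionGeometry(F=0.5e-6, R1=250e-6, R2=80e-6, R3=150e-6, A=1.0)
        g2 = CompressionGeometry(F=1.0e-6, R1=250e-6, R2=80e-6, R3=150e-6, A=1.0)
        assert compute_plate_sigma(g2) == pytest.approx(2 * compute_plate_sigma(g1), rel=1e-12)

    def test_degenerate_denominator_raises(self):
        r = 100e-6
        with pytest.raises(GeometryError):
            compute_plate_sigma(
                CompressionGeometry(F=1e-6, R1=r, R2=r, R3=r, A=np.pi / 2)
            )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        sigma=st.floats(1e-4, 1e-2),
        r1=st.floats(100e-6, 500e-6),
        r2=st.floats(50e-6, 200e-6),
        a=st.floats(0.3, 1.4),
    )
    def test_round_trip_recovers_sigma_exactly(self, sigma, r1, r2, a):
        # synthesize the force a drop of tension sigma would exert
        r3 = 0.5 * min(r1, r2)
        denom = np.pi * r3**2 * (1 / r1 + 1 / r2) - 2 * np.pi * r3 * np.sin(a)
        if denom <= 0:
            return
        geom = CompressionGeometry(F=sigma * denom, R1=r1, R2=r2, R3=r3, A=a)
        assert compute_plate_sigma(geom) == pytest.approx(sigma, rel=1e-14)

    def test_dimensional_round_trip_mm_scaling(self):
        # all lengths x1000 with F fixed scales sigma by 1/1000
        geom_m = CompressionGeometry(F=0.5e-6, R1=250e-6, R2=80e-6, R3=150e-6, A=1.0)
        geom_mm = CompressionGeometry(F=0.5e-6, R1=250e-3, R2=80e-3, R3=150e-3, A=1.0)
        assert compute_plate_sigma(geom_mm) == pytest.approx(
            compute_plate_sigma(geom_m) / 1e3, rel=1e-12
        )

    def test_formula_symmetric_in_r1_r2(self):
        a = CompressionGeometry(F=1e-6, R1=250e-6, R2=80e-6, R3=60e-6, A=0.3)
        b = CompressionGeometry(F=1e-6, R1=80e-6, R2=250e-6, R3=60e-6, A=0.3)
        assert compute_plate_sigma(a) == compute_plate_sigma(b)


class TestStrain:
    def test_in_protocol_band(self):
        eps, flag = compute_strain(100e-6, 80e-6)
        assert eps == pytest.approx(0.20)
        assert flag == "in_protocol"

    def test_zero_strain(self):
        eps, flag = compute_strain(100e-6, 100e-6)
        assert eps == 0.0
        assert flag == "below_protocol"

    def test_solid_like_regime_above_22_percent(self):
        eps, flag = compute_strain(100e-6, 75e-6)
        assert eps == pytest.approx(0.25)
        assert flag == "solid_like_regime"

    def test_expansion_rejected(self):
        with pytest.raises(ValueError):
            compute_strain(100e-6, 110e-6)


class TestPushbackAnalysis:
    def test_ramp_free_trace_has_no_onset(self):
        trace = gen_pushback_trace(SyntheticTraceSpec(ramp_rate=0.0, noise_sd=0.0))
        res = analyze_pushback(trace)
        assert res.onset_time is None
        assert res.delta_F_30min is None

    def test_noise_free_onset_and_force_increment(self):
        spec = SyntheticTraceSpec(noise_sd=0.0, onset_time=3600.0, ramp_rate=5e-11)
        res = analyze_pushback(gen_pushback_trace(spec))
        assert res.onset_time == pytest.approx(3600.0, abs=spec.dt)
        # force increase over 30 min from onset is ramp_rate * 1800 s
        assert res.delta_F_30min == pytest.approx(5e-11 * 1800.0, rel=1e-3)

    def test_onset_recovery_rate_with_noise(self):
        hits = 0
        for seed in range(20):
            trace = gen_pushback_trace(SyntheticTraceSpec(seed=seed))
            res = analyze_pushback(trace)
            if res.onset_time is not None and abs(res.onset_time - 3600.0) <= 300.0:
                hits += 1
        assert hits >= 18

    def test_constant_offset_does_not_move_onset(self):
        spec = SyntheticTraceSpec(seed=4)
        trace = gen_pushback_trace(spec)
        res0 = analyze_pushback(trace)
        shifted = ForceTrace(t=trace.t, F=trace.F + 1e-7)
        res1 = analyze_pushback(shifted)
        assert res1.onset_time == pytest.approx(res0.onset_time, abs=trace.dt)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            analyze_pushback(ForceTrace(t=np.arange(5.0), F=np.zeros(5)))

    def test_trace_validation(self):
        with pytest.raises(ValueError):
            ForceTrace(t=np.array([0.0, 1.0, 1.0]), F=np.zeros(3))

    def test_relaxation_parameters_recovered(self):
        spec = SyntheticTraceSpec(noise_sd=0.0, ramp_rate=0.0)
        res = analyze_pushback(gen_pushback_trace(spec))
        assert res.relax_tau == pytest.approx(spec.relax_tau, rel=0.1)
        assert res.plateau_force == pytest.approx(
            spec.preload - spec.relax_amplitude + spec.plateau_level, rel=0.01
        )
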