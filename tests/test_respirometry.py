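"""Slope extraction, blank correction and cycle segmentation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from winterq import CyclePlan, RespirometerGeometry, simulate_oxygen_trace
from winterq.respirometry import (Mo2Interval, blank_correct_and_scale,
                                  fit_slope, match_blank, process_trace,
                                  segment_cycles)


def _trace(t_end=3600.0, dt=5.0):
    t = np.arange(0.0, t_end + dt, dt)
    return pd.DataFrame({"time_s": t, "o2_mg_per_l": 8.0, "temp_c": 10.0,
                         "chamber_id": "ch1"})


class TestSegmentCycles:
    def test_three_full_cycles_fit(self):
        plan = CyclePlan(900, 300)
        wins = segment_cycles(_trace(3600), plan)
        assert len(wins) == 3
        assert wins[0] == (0.0, 900.0)
        assert wins[1][0] == 1200.0

    def test_trace_shorter_than_closed_period(self):
        plan = CyclePlan(900, 300)
        assert segment_cycles(_trace(300), plan) == []

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            segment_cycles(_trace(3600).iloc[0:0], CyclePlan(900, 300))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(closed=st.floats(500, 2000), flush=st.floats(0, 800),
           t_end=st.floats(1000, 20000))
    def test_windows_disjoint_and_bounded(self, closed, flush, t_end):
        plan = CyclePlan(closed, flush)
        wins = segment_cycles(_trace(t_end), plan)
        for (s1, e1), (s2, _) in zip(wins, wins[1:]):
            assert e1 <= s2
        for s, e in wins:
            assert e - s <= closed + 1e-9


class TestFitSlope:
    def test_exact_linear_decline(self):
        t = np.linspace(0, 1800, 100)                  # 0.5 h
        o2 = 8.0 - 1.0 * t / 3600.0                    # -1.0 mg/L/h
        slope, r2, n = fit_slope(t, o2, exclusion_s=0.0)
        assert slope == pytest.approx(-1.0, abs=1e-10)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert n == 100

    def test_constant_oxygen(self):
        t = np.linspace(0, 1800, 50)
        slope, _, _ = fit_slope(t, np.full(50, 8.0), exclusion_s=0.0)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        t = np.sort(rng.uniform(0, 1200, 200))
        o2 = 9.0 - 2.3 * t / 3600.0 + rng.normal(0, 0.01, t.size)
        slope, r2, _ = fit_slope(t, o2, exclusion_s=0.0)
        # closed-form least squares via the normal equations, independently
        x = t / 3600.0
        xc, yc = x - x.mean(), o2 - o2.mean()
        beta = float(np.sum(xc * yc) / np.sum(xc**2))
        assert slope == pytest.approx(beta, abs=1e-10)
        assert 0 < r2 <= 1

    def test_too_few_samples_flags_not_raises(self):
        t = np.linspace(0, 400, 20)                    # all inside exclusion
        slope, r2, n = fit_slope(t, 8.0 - t / 3600.0, exclusion_s=390.0)
        assert np.isnan(slope) and n < 10


class TestBlankCorrection:
    def test_hand_arithmetic(self):
        geom = RespirometerGeometry(chamber_volume_l=0.945, body_mass_kg=0.045)
        mo2, ok = blank_correct_and_scale(-1.0, -0.1, geom)
        assert geom.effective_volume_l == pytest.approx(0.9)
        assert mo2 == pytest.approx(18.0) and ok

    def test_raw_equals_blank_gives_zero(self):
        geom = RespirometerGeometry(1.01, 0.01)
        mo2, ok = blank_correct_and_scale(-0.5, -0.5, geom)
        assert mo2 == pytest.approx(0.0) and ok

    def test_no_background(self):
        geom = RespirometerGeometry(1.01, 0.01)
        mo2, ok = blank_correct_and_scale(-1.0, 0.0, geom)
        assert mo2 == pytest.approx(100.0) and ok

    def test_negative_mo2_flagged_not_clamped(self):
        geom = RespirometerGeometry(1.01, 0.01)
        mo2, ok = blank_correct_and_scale(-0.1, -0.5, geom)
        assert mo2 < 0 and not ok

    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            RespirometerGeometry(0.5, 0.6)   # fish bigger than chamber
        with pytest.raises(ValueError):
            RespirometerGeometry(1.0, 0.0)


def _iv(mid, slope=-0.1):
    return Mo2Interval("b", 0, mid - 50, mid + 50, 10.0, slope, 1.0, 50)


class TestMatchBlank:
    def test_single_blank_used_everywhere(self):
        fish = [_iv(m, -1.0) for m in (100, 900, 2500)]
        match_blank(fish, [_iv(1200, -0.07)])
        assert all(iv.blank_slope == -0.07 for iv in fish)

    def test_equidistant_tie_goes_to_earlier(self):
        fish = [_iv(1000, -1.0)]
        early, late = _iv(500, -0.05), _iv(1500, -0.09)
        match_blank(fish, [late, early])
        assert fish[0].blank_slope == -0.05

    def test_matches_brute_force_nearest(self):
        rng = np.random.default_rng(3)
        blanks = [_iv(m, -0.01 * k) for k, m in
                  enumerate(sorted(rng.uniform(0, 10000, 8)))]
        fish = [_iv(m, -1.0) for m in rng.uniform(0, 10000, 30)]
        match_blank(fish, blanks)
        for iv in fish:
            best = min(blanks, key=lambda b: (abs(b.mid_s - iv.mid_s), b.mid_s))
            assert iv.blank_slope == best.raw_slope

    def test_no_blanks_leaves_zero(self):
        fish = [_iv(100, -1.0)]
        match_blank(fish, [])
        assert fish[0].blank_slope == 0.0


class TestRoundTrip:
    def test_recovers_true_mo2_without_sensor_noise(self):
        plan = CyclePlan(900, 300)
        geom = RespirometerGeometry(1.01, 0.01)
        tr = simulate_oxygen_trace(100.0, geom.body_mass_kg,
                                   geom.effective_volume_l, 900, 300,
                                   n_cycles=3, background_slope=0.05,
                                   sensor_sd=0.0)
        blank = simulate_oxygen_trace(0.0, geom.body_mass_kg,
                                      geom.effective_volume_l, 900, 300,
                                      n_cycles=3, background_slope=0.05,
                                      sensor_sd=0.0)
        ivs = process_trace(tr, plan, geom, blank_trace=blank)
        assert ivs and all(iv.qc_pass for iv in ivs)
        for iv in ivs:
            assert iv.mo2 == pytest.approx(100.0, rel=0.02)

    def test_mo2_scales_with_volume_and_inverse_mass(self):
        tr = simulate_oxygen_trace(100.0, 0.01, 1.0, 900, 300, n_cycles=1,
                                   sensor_sd=0.0)
        plan = CyclePlan(900, 300)
        base = process_trace(tr, plan, RespirometerGeometry(1.01, 0.01))[0].mo2
        double_v = process_trace(tr, plan,
                                 RespirometerGeometry(2.01, 0.01))[0].mo2
        double_m = process_trace(tr, plan,
                                 RespirometerGeometry(1.02, 0.02))[0].mo2
        assert double_v == pytest.approx(2.0 * base, rel=1e-9)   # V_eff 1 -> 2 L
        assert double_m == pytest.approx(0.5 * base, rel=1e-9)   # mass 10 -> 20 g

    def test_exclusion_never_worsens_bias_with_transient(self):
        # exponential post-flush equilibration transient on top of the line
        t = np.arange(0.0, 900.0, 5.0)
        true_slope = -1.0
        for tau in (30.0, 60.0, 120.0):
            o2 = 8.0 + true_slope * t / 3600.0 + 0.3 * np.exp(-t / tau)
            s_all, _, _ = fit_slope(t, o2, exclusion_s=0.0)
            s_exc, _, _ = fit_slope(t, o2, exclusion_s=300.0)
            assert abs(s_exc - true_slope) <= abs(s_all - true_slope) + 1e-12

    def test_low_r2_interval_fails_qc(self):
        rng = np.random.default_rng(0)
        tr = simulate_oxygen_trace(5.0, 0.01, 1.0, 900, 300, n_cycles=1,
                                   sensor_sd=0.5, seed=0)
        ivs = process_trace(tr, CyclePlan(900, 300),
                            RespirometerGeometry(1.01, 0.01), min_r2=0.9)
        assert not ivs[0].qc_pass and "r2" in ivs[0].qc_note
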