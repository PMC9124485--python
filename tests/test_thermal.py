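"""Q10 arithmetic, MRD classification and Arrhenius breakpoints."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from winterq import (MRD_Q10_THRESHOLD, SyntheticConfig, TemperatureInterval,
                     arrhenius_breakpoints, classify_mrd, default_intervals,
                     generate_pairs, q10, q10_of_routine_vs_smr, q10_per_fish,
                     smr_individual, true_smr)
from winterq.smr import estimate_all
from winterq.synthetic import FishTruth
from winterq.thermal import Q10Result


class TestQ10:
    def test_rate_halving_over_ten_degrees(self):
        assert q10(50.0, 4.0, 100.0, 14.0) == pytest.approx(2.0, rel=1e-12)

    def test_equal_rates(self):
        assert q10(80.0, 4.0, 80.0, 14.0) == pytest.approx(1.0)

    def test_hand_logarithm_arithmetic(self):
        # 0.3 ** (10 / -11.5) = exp(-ln 0.3 * 10/11.5)
        assert q10(30.0, 2.5, 100.0, 14.0) == pytest.approx(2.849, abs=1e-3)

    @pytest.mark.parametrize("args", [
        (50.0, 14.0, 100.0, 14.0),   # equal temperatures
        (50.0, 15.0, 100.0, 14.0),   # inverted interval
        (0.0, 4.0, 100.0, 14.0),     # non-positive rate
        (50.0, 4.0, -1.0, 14.0),
    ])
    def test_input_errors(self, args):
        with pytest.raises(ValueError):
            q10(*args)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(r=st.floats(1.0, 500.0), big_r=st.floats(1.0, 500.0),
           k=st.floats(0.01, 100.0))
    def test_scale_invariance(self, r, big_r, k):
        assert q10(r * k, 2.5, big_r * k, 14.0) == pytest.approx(
            q10(r, 2.5, big_r, 14.0), rel=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(ra=st.floats(10.0, 300.0), rb=st.floats(10.0, 300.0),
           rc=st.floats(10.0, 300.0))
    def test_composition_over_subintervals(self, ra, rb, rc):
        ta, tb, tc = 14.0, 8.0, 2.5
        q_ab, q_bc = q10(rb, tb, ra, ta), q10(rc, tc, rb, tb)
        q_ac = q10(rc, tc, ra, ta)
        combined = np.exp(((ta - tb) * np.log(q_ab) + (tb - tc) * np.log(q_bc))
                          / (ta - tc))
        assert q_ac == pytest.approx(combined, rel=1e-9)


class TestQ10PerFish:
    def _estimates(self, values_by_fish):
        rows = []
        for fish, (warm, cold) in values_by_fish.items():
            rows.append((fish, "acute_14", 14.0, "extrapolated_individual", warm))
            rows.append((fish, "acute_2.5", 2.5, "extrapolated_individual", cold))
        return pd.DataFrame(rows, columns=["scope", "condition", "temp_c",
                                           "method", "value"])

    def test_homogeneous_population(self):
        # every fish's SMR falls by exactly Q10 = 2.5 over 14 -> 2.5 degC
        cold_over_warm = 2.5 ** ((2.5 - 14.0) / 10.0)
        est = self._estimates({f"f{i}": (100.0, 100.0 * cold_over_warm)
                               for i in range(6)})
        iv = TemperatureInterval("full_cooling", "acute_14", "acute_2.5", 14.0, 2.5)
        res = q10_per_fish(est, [iv])[0]
        assert res.n == 6 and res.n_dropped == 0
        assert np.allclose(res.per_fish_q10, 2.5, rtol=1e-12)
        assert res.mean_q10 == pytest.approx(2.5)
        assert res.sem_q10 == pytest.approx(0.0, abs=1e-12)

    def test_fish_missing_an_endpoint_are_dropped(self):
        est = self._estimates({"f0": (100.0, 40.0), "f1": (90.0, 35.0)})
        est = est.drop(est[(est.scope == "f1") &
                           (est.condition == "acute_2.5")].index)
        iv = TemperatureInterval("full_cooling", "acute_14", "acute_2.5", 14.0, 2.5)
        res = q10_per_fish(est, [iv])[0]
        # brute-force set difference oracle
        have_both = {"f0"}
        assert set(res.per_fish_q10.index) == have_both
        assert res.n_dropped == 1

    def test_mean_and_sem_match_textbook_formulas(self):
        est = self._estimates({"f0": (100.0, 40.0), "f1": (90.0, 30.0),
                               "f2": (110.0, 50.0)})
        iv = TemperatureInterval("full_cooling", "acute_14", "acute_2.5", 14.0, 2.5)
        res = q10_per_fish(est, [iv])[0]
        v = res.per_fish_q10.to_numpy()
        assert res.mean_q10 == pytest.approx(v.mean())
        assert res.sem_q10 == pytest.approx(v.std(ddof=1) / np.sqrt(v.size))


class TestClassifyMrd:
    def _result(self, values):
        iv = TemperatureInterval("full_cooling", "acute_14", "acute_2.5", 14.0, 2.5)
        s = pd.Series(values, dtype=float)
        return Q10Result(iv, "extrapolated_individual", s,
                         mean_q10=float(s.mean()),
                         sem_q10=float(s.sem()), n=len(s))

    def test_passive_mean(self):
        flag, text = classify_mrd(self._result([2.8, 3.0, 2.9]))
        assert not flag and "passive" in text

    def test_mrd_flagged_mean(self):
        # marginal means like 3.73 / 3.61 sit above the threshold
        flag, text = classify_mrd(self._result([3.9, 3.6, 3.7]))
        assert flag and "MRD" in text

    def test_boundary_is_passive(self):
        flag, _ = classify_mrd(self._result([3.5, 3.5, 3.5]))
        assert not flag

    def test_verdict_reports_straddling_fraction(self):
        _, text = classify_mrd(self._result([3.0, 4.0]))
        assert "50%" in text


def _mean_smr_frame(temps, q10_by_temp):
    """ln-linear SMR with a prescribed, possibly piecewise, Q10."""
    temps = np.asarray(temps, float)
    smr = [100.0]
    for t0, t1 in zip(temps, temps[1:]):
        q = q10_by_temp(0.5 * (t0 + t1))
        smr.append(smr[-1] * q ** ((t1 - t0) / 10.0))
    return pd.DataFrame({"temp_c": temps, "smr": smr})


class TestArrhenius:
    def test_single_regime_prefers_no_break(self):
        # exactly collinear on the Arrhenius axes: constant activation
        # energy, ln SMR linear in 1/T_K (a constant Q10 is only linear
        # in degC and would show genuine curvature here)
        temps = np.arange(14.0, 1.9, -1.0)
        inv_t = 1.0 / (temps + 273.15)
        df = pd.DataFrame({"temp_c": temps,
                           "smr": np.exp(30.0 - 7000.0 * inv_t)})
        fit = arrhenius_breakpoints(df)
        assert not fit.has_breakpoint
        assert fit.slopes[0] == pytest.approx(-7000.0, rel=1e-6)

    def test_two_regime_break_recovered_within_one_degree(self):
        df = _mean_smr_frame(np.arange(14.0, 1.9, -1.0),
                             lambda t: 2.0 if t > 8.0 else 4.0)
        fit = arrhenius_breakpoints(df)
        assert fit.has_breakpoint
        assert abs(fit.breakpoint_c - 8.0) <= 1.0
        # the cold segment is steeper on the 1/T axis
        assert abs(fit.slopes[1]) > abs(fit.slopes[0])

    def test_grid_search_matches_exhaustive_sse_minimisation(self):
        rng = np.random.default_rng(21)
        df = _mean_smr_frame(np.arange(14.0, 1.9, -1.0),
                             lambda t: 2.0 if t > 8.0 else 4.0)
        df["smr"] *= np.exp(rng.normal(0, 0.02, len(df)))
        fit = arrhenius_breakpoints(df)
        # independent exhaustive search over the same candidate set
        temps = df["temp_c"].to_numpy()
        x = 1.0 / (np.sort(temps) + 273.15)[::-1]
        y = np.log(df.sort_values("temp_c", ascending=False)["smr"].to_numpy())
        best = None
        for g in np.arange(2.1, 13.95, 0.1):
            g = round(g, 10)
            if (temps < g).sum() < 2 or (temps > g).sum() < 2:
                continue
            xb = 1.0 / (g + 273.15)
            X = np.column_stack([np.ones_like(x), x, np.maximum(x - xb, 0.0)])
            sse = float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
            if best is None or sse < best[0]:
                best = (sse, g)
        assert fit.breakpoint_c == pytest.approx(best[1], abs=0.1 + 1e-9)

    def test_fewer_than_five_points_yields_note(self):
        df = _mean_smr_frame([14.0, 8.0, 2.5], lambda t: 2.5)
        fit = arrhenius_breakpoints(df)
        assert not fit.has_breakpoint and "fewer than 5" in fit.note


class TestInjectedMrdMonotonicity:
    def test_noiseless_smr_q10_increases_with_suppression(self):
        fish = FishTruth("f", 100.0, 0.2, 0.01, 8.0)
        q_values = []
        for sup in (0.0, 0.2, 0.4, 0.6):
            cfg = SyntheticConfig(mrd_enabled=sup > 0, mrd_suppression=max(sup, 1e-6),
                                  mrd_threshold_c=8.0)
            q_values.append(q10(true_smr(fish, 2.5, cfg), 2.5,
                                true_smr(fish, 14.0, cfg), 14.0))
        assert all(b > a for a, b in zip(q_values, q_values[1:]))


class TestRoutineVsSmr:
    def test_no_activity_confound_means_equal_q10(self):
        # activity level independent of temperature, zero noise
        cfg = SyntheticConfig(n_fish=4, intervals_per_phase=10,
                              noise_sigma_mo2=0.0, dormancy_steepness=1e-9,
                              seed=2)
        pairs, _ = generate_pairs(cfg)
        est = estimate_all(pairs, band=None)
        tbl = q10_of_routine_vs_smr(est, default_intervals(cfg.temps_c,
                                                           has_acclimation=False))
        full = tbl[tbl["interval"] == "full_cooling"].set_index("method")
        assert full.loc["routine", "mean_q10"] == pytest.approx(
            full.loc["extrapolated_individual", "mean_q10"], rel=0.05)

    def test_activity_decline_inflates_routine_q10(self):
        # cooling-damped activity: routine Q10 exceeds SMR Q10 in >= 95% of
        # seeded replicates
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            cfg = SyntheticConfig(n_fish=6, intervals_per_phase=12, seed=seed)
            pairs, _ = generate_pairs(cfg)
            acute = pairs[pairs["condition"].str.startswith("acute")]
            est = estimate_all(acute, band=None)
            tbl = q10_of_routine_vs_smr(
                est, default_intervals(cfg.temps_c, has_acclimation=False))
            full = tbl[tbl["interval"] == "full_cooling"].set_index("method")
            wins += (full.loc["routine", "mean_q10"] >
                     full.loc["extrapolated_individual", "mean_q10"])
        assert wins >= 0.95 * n_rep
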