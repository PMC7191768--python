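"""FRAP: decay correction, percent recovery, half-time fits, group comparisons."""

import numpy as np
import pandas as pd
import pytest

from s10pos.frap import (
    compare_groups,
    correct_imaging_decay,
    fit_recovery,
    percent_recovery,
    population_stats,
)
from s10pos.simulate import simulate_frap_trace


def _trace(times, values, pre=None, length=4.0):
    t = np.asarray(times, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": "c",
            "role": "bleached",
            "cell_length_um": length,
            "time_ms": t,
            "fluorescence": np.asarray(values, dtype=float),
            "pre_bleach": (t < 0) if pre is None else pre,
        }
    )


class TestDecayCorrection:
    def test_constant_controls_identity(self):
        b = simulate_frap_trace(100.0, noise_sd=0.0)
        ctrl = _trace(b["time_ms"], np.full(len(b), 90.0))
        out = correct_imaging_decay(b, [ctrl])
        assert np.allclose(out["fluorescence"], b["fluorescence"])

    def test_linear_shared_decay_removed_exactly(self):
        b = simulate_frap_trace(100.0, noise_sd=0.0)
        drift = 0.01 * (b["time_ms"] - b["time_ms"].iloc[0])
        decayed = b.copy()
        decayed["fluorescence"] = b["fluorescence"] - drift
        ctrl = _trace(b["time_ms"], 90.0 - drift)
        out = correct_imaging_decay(decayed, [ctrl])
        assert np.allclose(out["fluorescence"], b["fluorescence"], atol=1e-9)

    def test_shared_decay_recovery_round_trip(self):
        # 10%/min multiplicative-style linear decay: endpoint recovery
        # within 2 points of the decay-free truth after correction
        b = simulate_frap_trace(100.0, duration_ms=60_000, dt_ms=200.0, noise_sd=0.0)
        truth = percent_recovery(b)
        rate = 0.10 * 100.0 / 60_000.0  # a.u. per ms, ~10% of F_pre per minute
        drift = rate * (b["time_ms"] - b["time_ms"].iloc[0])
        decayed = b.copy()
        decayed["fluorescence"] = b["fluorescence"] - drift
        ctrl = _trace(b["time_ms"], 100.0 - drift)
        corrected = correct_imaging_decay(decayed, [ctrl])
        assert percent_recovery(corrected) == pytest.approx(truth, abs=2.0)

    def test_misaligned_controls_rejected(self):
        b = simulate_frap_trace(100.0)
        ctrl = _trace(b["time_ms"] + 1000.0, np.full(len(b), 90.0))
        with pytest.raises(ValueError):
            correct_imaging_decay(b, [ctrl])

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError):
            correct_imaging_decay(simulate_frap_trace(100.0), [])


class TestPercentRecovery:
    def test_full_return_is_100(self):
        t = np.arange(-2, 10, dtype=float)
        f = np.where(t < 0, 100.0, np.where(t == 0, 20.0, 100.0))
        assert percent_recovery(_trace(t, f)) == pytest.approx(100.0)

    def test_no_recovery_is_0(self):
        t = np.arange(-2, 10, dtype=float)
        f = np.where(t < 0, 100.0, 20.0)
        assert percent_recovery(_trace(t, f)) == pytest.approx(0.0)

    def test_constructed_partial_recovery_level(self):
        # trace built to recover 53.8% of the bleached signal
        target = 53.8
        f_inf = 20.0 + target / 100.0 * (100.0 - 20.0)
        tr = simulate_frap_trace(
            5_000.0, F_pre=100.0, F_bleach=20.0, F_inf=f_inf,
            dt_ms=2_000.0, duration_ms=300_000.0, noise_sd=0.0,
        )
        assert percent_recovery(tr) == pytest.approx(target, abs=0.5)

    def test_degenerate_bleach_rejected(self):
        t = np.arange(-2, 10, dtype=float)
        f = np.where(t < 0, 20.0, 100.0)
        with pytest.raises(ValueError):
            percent_recovery(_trace(t, f))


class TestFitRecovery:
    def test_noiseless_exact(self):
        est = fit_recovery(simulate_frap_trace(250.0, noise_sd=0.0))
        assert est.tau_half == pytest.approx(250.0, rel=1e-6)
        assert est.r2 > 0.999999 and est.accepted

    def test_constant_trace_not_accepted(self):
        t = np.arange(-2_00, 3_000, 20, dtype=float)
        est = fit_recovery(_trace(t, np.full(len(t), 50.0)))
        assert not est.accepted and est.r2 <= 0.8

    def test_long_cell_rejected_regardless_of_fit(self):
        est = fit_recovery(simulate_frap_trace(100.0, cell_length_um=7.0))
        assert est.r2 > 0.99 and not est.accepted
        assert "length" in est.reason

    def test_affine_gain_offset_invariance(self):
        base = simulate_frap_trace(150.0, noise_sd=1.0, seed=3)
        scaled = base.copy()
        scaled["fluorescence"] = 2.5 * base["fluorescence"] + 40.0
        assert fit_recovery(scaled).tau_half == pytest.approx(
            fit_recovery(base).tau_half, rel=1e-6
        )

    def test_time_unit_conversion(self):
        base = simulate_frap_trace(150.0, noise_sd=0.0)
        in_s = base.copy()
        in_s["time_ms"] = base["time_ms"] / 1000.0
        assert fit_recovery(in_s).tau_half == pytest.approx(0.150, rel=1e-6)

    def test_immobile_fraction_reported(self):
        est = fit_recovery(simulate_frap_trace(100.0, noise_sd=0.0))
        # F_inf 80 recovers 75% of the 100 -> 20 bleach: immobile 25%
        assert est.immobile_fraction == pytest.approx(0.25, abs=1e-6)

    def test_too_few_frames_rejected(self):
        tr = simulate_frap_trace(100.0, dt_ms=1000.0, duration_ms=5000.0)
        with pytest.raises(ValueError):
            fit_recovery(tr.iloc[:12])


class TestPopulationStats:
    def test_degenerate_and_simple_sets(self):
        s = population_stats([100.0, 100.0, 100.0])
        assert s["mean"] == 100.0 and s["ci95"] == (100.0, 100.0)
        s2 = population_stats([80.0, 100.0, 120.0])
        assert s2["mean"] == 100.0 and s2["median"] == 100.0 and s2["n"] == 3

    def test_ci_coverage_on_lognormal(self, rng):
        mu_true = float(np.exp(0.5 + 0.25 / 2))  # lognormal(0.5, 0.5) mean
        cover = 0
        n_rep = 300
        for _ in range(n_rep):
            draws = rng.lognormal(0.5, 0.5, 200)
            lo, hi = population_stats(draws)["ci95"]
            cover += lo <= mu_true <= hi
        assert cover / n_rep == pytest.approx(0.95, abs=0.04)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            population_stats([1.0])


class TestCompareGroups:
    def test_hand_ranked_H(self):
        out = compare_groups({"a": np.array([1, 2, 3]), "b": np.array([4, 5, 6])})
        assert out["H"] == pytest.approx(3.857142857, abs=1e-6)

    def test_identical_groups_p_near_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = compare_groups({"a": x, "b": x})
        assert out["p"] > 0.9

    def test_all_constant_no_division_error(self):
        out = compare_groups({"a": np.array([5.0, 5.0]), "b": np.array([5.0, 5.0])})
        assert out["p"] == 1.0

    def test_power_against_shifted_group(self, rng):
        # 40 ms shift between n=100 groups with sd 30: detected nearly always
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            g = {
                "parental": rng.normal(140.0, 30.0, 100),
                "movant": rng.normal(100.0, 30.0, 100),
            }
            out = compare_groups(g, control="parental")
            if out["pairwise"][("parental", "movant")]["padj"] < 0.05:
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_control_restricts_pairs(self):
        g = {
            "parental": np.array([1.0, 2.0, 3.0]),
            "m1": np.array([4.0, 5.0, 6.0]),
            "m2": np.array([7.0, 8.0, 9.0]),
        }
        out = compare_groups(g, control="parental")
        assert set(out["pairwise"]) == {("parental", "m1"), ("parental", "m2")}
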