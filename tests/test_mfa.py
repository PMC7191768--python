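"""Marker-frequency analysis: normalisation, ter-ori-ter axis, slopes, zones."""

import numpy as np
import pytest

from s10pos.genome import CellCycleParams, GenomeLayout, Replicon, expected_profile
from s10pos.mfa import (
    CoverageTrack,
    analyze_profile,
    estimate_C_over_tau,
    fit_replichore_slope,
    normalize_genome,
    normalize_to_control,
    to_ter_ori_ter,
    zone_ratio,
)
from s10pos.simulate import SimulationConfig, simulate_mfa_coverage


def _track(counts, replicon="chr1", window_bp=1000, mask=None):
    counts = np.asarray(counts, dtype=float)
    return CoverageTrack(
        replicon=replicon,
        window_bp=window_bp,
        window_starts=np.arange(len(counts)) * window_bp,
        counts=counts,
        mask=mask,
    )


def _noiseless_profile(layout, params, window_bp=1000, replicon="chr1"):
    """Expected-frequency 'counts' normalised against a uniform control."""
    prof = expected_profile(layout, params, window_bp)
    sub = prof[prof["replicon"] == replicon]
    sample = _track(sub["freq"].to_numpy() * 100, replicon, window_bp)
    control = _track(np.full(len(sub), 100.0), replicon, window_bp)
    return to_ter_ori_ter(normalize_to_control(sample, control), layout)


class TestNormalizeToControl:
    def test_self_normalisation_gives_zero(self):
        t = _track([10, 20, 30, 40])
        prof = normalize_to_control(t, t)
        assert np.allclose(prof.log2_freq, 0.0)

    def test_total_scaling_cancels(self):
        a = _track([10, 20, 30, 40])
        b = _track([20, 40, 60, 80])
        assert np.allclose(normalize_to_control(b, a).log2_freq, 0.0)

    def test_zero_windows_masked_not_imputed(self):
        s = _track([10, 0, 30, 40])
        c = _track([10, 20, 0, 40])
        prof = normalize_to_control(s, c)
        assert prof.mask.tolist() == [False, True, True, False]
        assert np.isfinite(prof.log2_freq[~prof.mask]).all()

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_control(_track([1, 2, 3]), _track([1, 2, 3, 4]))
        with pytest.raises(ValueError):
            normalize_to_control(_track([1, 2]), _track([1, 2], window_bp=500))

    def test_all_zero_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_control(_track([1, 2]), _track([0, 0]))

    def test_masking_leaves_unmasked_values_unchanged(self):
        s = _track([10, 20, 30, 40])
        c = _track([10, 10, 10, 10])
        base = normalize_to_control(s, c)
        masked = normalize_to_control(
            _track([10, 20, 30, 40], mask=np.array([False, True, False, False])), c
        )
        keep = ~masked.mask
        assert np.array_equal(base.log2_freq[keep], masked.log2_freq[keep])


class TestTerOriTerAxis:
    def test_ori_window_maps_to_axis_centre(self, layout, params):
        prof = _noiseless_profile(layout, params)
        n = prof.n_windows
        assert prof.genomic_start[n // 2] == 0  # window containing ori1

    def test_ter_window_first(self, layout, params):
        prof = _noiseless_profile(layout, params)
        rep = layout.replicon("chr1")
        assert prof.genomic_start[0] == int(rep.ter_bp)

    def test_reordering_is_a_bijection(self, layout, params):
        prof_exp = expected_profile(layout, params, 1000)
        sub = prof_exp[prof_exp["replicon"] == "chr1"]
        sample = _track(sub["freq"].to_numpy() * 100)
        control = _track(np.full(len(sub), 100.0))
        before = normalize_to_control(sample, control)
        after = to_ter_ori_ter(before, layout)
        inverse = np.argsort(after.genomic_start)
        assert np.array_equal(after.genomic_start[inverse], before.genomic_start)
        assert np.allclose(after.log2_freq[inverse], before.log2_freq)


class TestReplichoreSlope:
    def test_noiseless_slope_recovered_exactly(self, layout, params):
        prof = _noiseless_profile(layout, params)
        expected = (params.C1_min / params.tau_min) / 1480.0
        for side in ("left", "right"):
            slope, _, r2 = fit_replichore_slope(prof, side)
            assert slope == pytest.approx(expected, abs=1e-7)
            assert r2 > 0.999

    def test_symmetric_profile_gives_equal_slopes(self, layout, params):
        prof = _noiseless_profile(layout, params)
        sl, _, _ = fit_replichore_slope(prof, "left")
        sr, _, _ = fit_replichore_slope(prof, "right")
        assert sl == pytest.approx(sr, rel=1e-6)

    def test_too_few_windows_rejected(self, layout, params):
        prof = _noiseless_profile(layout, params)
        starved = type(prof)(
            replicon=prof.replicon,
            window_bp=prof.window_bp,
            axis_kb=prof.axis_kb,
            log2_freq=prof.log2_freq,
            mask=np.ones_like(prof.mask),
            genomic_start=prof.genomic_start,
            ter_ori_ter=True,
        )
        with pytest.raises(ValueError):
            fit_replichore_slope(starved, "left")

    def test_stationary_null_slope_near_zero(self, layout, params):
        cfg_a = SimulationConfig(100, 1000, "stationary", seed=42)
        cfg_b = SimulationConfig(100, 1000, "stationary", seed=43)
        a = simulate_mfa_coverage(layout, params, cfg_a)["chr1"]
        b = simulate_mfa_coverage(layout, params, cfg_b)["chr1"]
        prof = to_ter_ori_ter(normalize_to_control(a, b), layout)
        sl, _, _ = fit_replichore_slope(prof, "left")
        sr, _, _ = fit_replichore_slope(prof, "right")
        assert abs((sl + sr) / 2) < 2e-5


class TestZoneRatio:
    def test_uniform_profile_ratio_one(self, layout, params):
        sub_n = 2960
        sample = _track(np.full(sub_n, 100.0))
        prof = to_ter_ori_ter(normalize_to_control(sample, sample), layout)
        assert zone_ratio(prof, prof.axis_kb[sub_n // 2]) == pytest.approx(1.0)

    def test_ori_zone_matches_windowed_integral(self, layout):
        # closed-form oracle: the zone means are window averages of
        # 2**((C/tau)(1-m)); compute them directly from the analytic profile
        p = CellCycleParams(tau_min=40.0, C1_min=40.0)  # C/tau = 1
        prof = _noiseless_profile(layout, p)
        n = prof.n_windows
        f = 2.0 ** prof.log2_freq
        ori_zone = f[n // 2 - 24 : n // 2 + 26].mean()
        ter_zone = np.concatenate([f[-24:], f[:26]]).mean()
        expected = ori_zone / ter_zone
        got = zone_ratio(prof, prof.axis_kb[n // 2])
        assert got == pytest.approx(expected, rel=1e-12)
        # and the windowing bias keeps it close to the exact ori/ter = 2
        assert got == pytest.approx(2.0, rel=0.02)

    def test_s10_zone_dosage_matches_closed_form(self, layout, params):
        # S10 at m = 0.5 on a noiseless profile has dosage 2**((C/tau)/2)
        prof = _noiseless_profile(layout, params)
        # axis index n/4 sits at m = 0.5 on the left arm (740 kb from ter)
        got = zone_ratio(prof, prof.axis_kb[prof.n_windows // 4], n_windows=14)
        assert got == pytest.approx(2 ** ((4 / 3) / 2), rel=0.01)

    def test_masked_only_zone_rejected(self, layout, params):
        prof = _noiseless_profile(layout, params)
        blocked = type(prof)(
            replicon=prof.replicon,
            window_bp=prof.window_bp,
            axis_kb=prof.axis_kb,
            log2_freq=prof.log2_freq,
            mask=np.ones_like(prof.mask),
            genomic_start=prof.genomic_start,
            ter_ori_ter=True,
        )
        with pytest.raises(ValueError):
            zone_ratio(blocked, 0.0)


class TestParameterRecovery:
    def test_estimate_C_over_tau_inverts_theoretical_slope(self):
        assert estimate_C_over_tau(9.009009e-4, 1480.0) == pytest.approx(4 / 3, rel=1e-6)
        assert estimate_C_over_tau(0.0, 1480.0) == 0.0

    @pytest.mark.parametrize("c_over_tau", [0.5, 1.0, 1.5, 2.0])
    def test_end_to_end_recovery_within_5_percent(self, layout, c_over_tau):
        p = CellCycleParams(tau_min=30.0, C1_min=30.0 * c_over_tau)
        est = []
        for seed in range(3):
            exp = simulate_mfa_coverage(
                layout, p, SimulationConfig(100, 1000, "exponential", seed)
            )
            stat = simulate_mfa_coverage(
                layout, p, SimulationConfig(100, 1000, "stationary", 100 + seed)
            )
            prof = to_ter_ori_ter(
                normalize_genome(exp, stat)["chr1"], layout
            )
            res = analyze_profile(prof, layout)
            est.append(estimate_C_over_tau(res.mean_slope, 1480.0))
        assert np.mean(est) == pytest.approx(c_over_tau, rel=0.05)

    def test_slope_and_zone_ratio_consistent(self, layout, params):
        ratios, slopes = [], []
        for seed in range(5):
            exp = simulate_mfa_coverage(
                layout, params, SimulationConfig(100, 1000, "exponential", seed)
            )
            stat = simulate_mfa_coverage(
                layout, params, SimulationConfig(100, 1000, "stationary", 100 + seed)
            )
            prof = to_ter_ori_ter(normalize_genome(exp, stat)["chr1"], layout)
            res = analyze_profile(prof, layout)
            ratios.append(res.ori_ter_ratio)
            slopes.append(res.mean_slope)
        implied = 2 ** (np.mean(slopes) * 1480.0)
        assert np.mean(ratios) == pytest.approx(implied, rel=0.03)

    def test_qc_flag_raised_for_poor_fit(self, layout, params):
        rng = np.random.default_rng(0)
        noisy = _track(rng.poisson(5.0, 2960).astype(float) + 1)
        control = _track(np.full(2960, 5.0))
        prof = to_ter_ori_ter(normalize_to_control(noisy, control), layout)
        res = analyze_profile(prof, layout)
        assert res.r2_left < 0.95 and len(res.qc_flags) == 2
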