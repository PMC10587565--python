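"""Depth-profile diagnostics: onset, concavity, SMTZ crossing, regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from smtzkit import profiles, synthetic
from smtzkit.io import DepthProfile


def make_profile(depth, ch4, so4=None, core_id="c1"):
    depth = np.asarray(depth, float)
    return DepthProfile(
        pd.DataFrame(
            {
                "core_id": core_id,
                "depth_cmbsf": depth,
                "ch4_mM": np.asarray(ch4, float),
                "so4_mM": so4 if so4 is not None else np.full_like(depth, 10.0),
                "h2s_uM": np.zeros_like(depth),
                "porosity": np.full_like(depth, 0.8),
            }
        )
    )


def ols_oracle(x, y):
    """Normal-equation OLS with slope t-statistic, coded independently."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - slope * x - intercept
    sse = np.sum(resid**2)
    sst = np.sum((y - y.mean()) ** 2)
    r2 = 1 - sse / sst if sst > 0 else 1.0
    se = np.sqrt(sse / (n - 2) / sxx)
    return slope, intercept, r2, slope / se


class TestMethaneOnset:
    def test_piecewise_linear_break_found_exactly(self):
        depth = np.arange(20, 42, 2.0)
        ch4 = np.where(depth >= 30, 0.1 + 0.2 * (depth - 30), 0.0)
        res = profiles.methane_onset(make_profile(depth, ch4), threshold_mM=0.1)
        assert res.onset_depth_cmbsf == 30.0

    def test_all_zero_methane_gives_absent_onset(self):
        depth = np.arange(0, 20, 2.0)
        res = profiles.methane_onset(make_profile(depth, np.zeros_like(depth)))
        assert not res.present
        assert res.onset_depth_cmbsf is None

    def test_sulfate_at_onset_interpolated(self):
        depth = np.arange(20, 42, 2.0)
        ch4 = np.where(depth >= 30, 0.5, 0.0)
        so4 = np.linspace(20, 0, depth.size)
        res = profiles.methane_onset(make_profile(depth, ch4, so4))
        assert res.so4_at_onset_mM == pytest.approx(
            np.interp(30.0, depth, so4)
        )

    def test_invariant_to_subthreshold_depths_above(self):
        depth = np.arange(20, 42, 2.0)
        ch4 = np.where(depth >= 30, 0.1 + 0.2 * (depth - 30), 0.0)
        base = profiles.methane_onset(make_profile(depth, ch4))
        extra_depth = np.concatenate([[2.0, 6.0, 10.0], depth])
        extra_ch4 = np.concatenate([[0.02, 0.05, 0.0], ch4])
        extended = profiles.methane_onset(make_profile(extra_depth, extra_ch4))
        assert extended.onset_depth_cmbsf == base.onset_depth_cmbsf

    def test_isolated_spike_does_not_trigger(self):
        depth = np.arange(20, 42, 2.0)
        ch4 = np.where(depth >= 34, 0.3 + 0.2 * (depth - 34), 0.0)
        ch4[2] = 0.15  # single noisy exceedance at 24 cm
        res = profiles.methane_onset(make_profile(depth, ch4))
        assert res.onset_depth_cmbsf == 34.0

    def test_too_few_depths_rejected(self):
        with pytest.raises(ValueError, match="4 depths"):
            profiles.methane_onset(make_profile([0, 2, 4], [0, 0, 0]))

    def test_synthetic_onset_recovery_100_seeds(self):
        """Generator cores with onset 32 cm and sigma = 0.02 mM recover the
        onset within one 2-cm section."""
        hits = 0
        for seed in range(100):
            prof, truth = synthetic.generate_core(
                synthetic.clb_preset(seed=seed, onset=32.0)
            )
            res = profiles.methane_onset(prof)
            if res.present and abs(res.onset_depth_cmbsf - 32.0) <= 2.0:
                hits += 1
        assert hits >= 90


class TestConcavity:
    def test_exact_linear_profile(self):
        depth = np.arange(0, 20, 2.0)
        res = profiles.methanocline_concavity(make_profile(depth, 0.05 * depth))
        assert res.classification == "linear"
        np.testing.assert_allclose(res.second_differences, 0.0, atol=1e-12)
        assert res.r_squared_linear == pytest.approx(1.0)

    def test_quadratic_profile_constant_curvature(self):
        """CH4 = a d^2 has second derivative exactly 2a at every interior node."""
        a = 3e-3
        depth = np.arange(0, 20, 2.0)
        res = profiles.methanocline_concavity(make_profile(depth, a * depth**2))
        assert res.classification == "concave_up"
        np.testing.assert_allclose(res.second_differences, 2 * a, rtol=1e-9)

    def test_sign_flip_antisymmetry(self):
        depth = np.arange(0, 20, 2.0)
        y = 1e-3 * depth**2
        up = profiles.methanocline_concavity(make_profile(depth, y))
        down = profiles.methanocline_concavity(make_profile(depth, y.max() - y))
        assert up.classification == "concave_up"
        assert down.classification == "concave_down"
        np.testing.assert_allclose(
            down.second_differences, -up.second_differences, rtol=1e-9
        )

    def test_irregular_grid_quadratic_still_exact(self):
        depth = np.array([0.0, 1.0, 3.0, 4.5, 7.0, 10.0])
        res = profiles.methanocline_concavity(make_profile(depth, 2e-3 * depth**2))
        np.testing.assert_allclose(res.second_differences, 4e-3, rtol=1e-9)

    def test_sigmoid_sign_pattern_about_inflection(self):
        """A sigmoidal methanocline is concave-up above its inflection and
        concave-down below."""
        scenario = synthetic.CoreScenario(
            profile_style="aom_sigmoidal",
            ch4_onset_cmbsf=20.0,
            sigmoid_width_cm=3.0,
            ch4_noise_sd_mM=0.0,
            so4_noise_sd_mM=0.0,
            h2s_noise_sd_uM=0.0,
            porosity_noise_sd=0.0,
        )
        prof, _ = synthetic.generate_core(scenario)
        midpoint = 20.0 + 3 * 3.0
        res = profiles.methanocline_concavity(prof)
        above = res.second_differences[res.depths < midpoint - 1]
        below = res.second_differences[res.depths > midpoint + 1]
        assert np.all(above > 0)
        assert np.all(below < 0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            profiles.methanocline_concavity(
                make_profile([0, 2, 4, 6], [0, 0, 0, 0]), below_depth=3
            )


class TestSmtzDepth:
    def test_symmetric_crossing(self):
        depth = np.arange(0, 42, 2.0)
        ch4 = np.interp(depth, [0, 40], [0, 2])
        so4 = np.interp(depth, [0, 40], [2, 0])
        assert profiles.smtz_depth(make_profile(depth, ch4, so4)) == pytest.approx(20.0)

    def test_no_crossing_when_sulfate_floored(self):
        """Methane capped at 1.5 mM with sulfate still ~5 mM: no SMTZ."""
        prof, _ = synthetic.generate_core(synthetic.clb_preset(seed=3))
        assert profiles.smtz_depth(prof) is None

    def test_dense_scan_agrees_with_analytic_crossing(self):
        depth = np.arange(0, 42, 2.0)
        ch4 = 1.8 / (1 + np.exp(-(depth - 25) / 3))
        so4 = 0.3 + 24 * np.exp(-0.12 * depth)
        analytic = profiles.smtz_depth(make_profile(depth, ch4, so4))
        # brute force on a dense piecewise-linear interpolation
        grid = np.linspace(depth[0], depth[-1], 200001)
        diff = np.interp(grid, depth, ch4) - np.interp(grid, depth, so4)
        brute = grid[np.argmax(diff >= 0)]
        assert analytic == pytest.approx(brute, abs=1e-3)


class TestLinearRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = profiles.linear_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.df == 8

    def test_five_point_normal_equation_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        y = np.array([2.1, 2.9, 5.2, 6.1, 8.3])
        res = profiles.linear_regression(x, y)
        slope, intercept, r2, t = ols_oracle(x, y)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        assert res.r_squared == pytest.approx(r2, rel=1e-10)
        assert res.t_value == pytest.approx(t, rel=1e-10)

    @given(
        seed=st.integers(0, 1000),
        n=st.integers(5, 40),
    )
    def test_randomized_inputs_match_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 1.5 * x + rng.normal(size=n)
        res = profiles.linear_regression(x, y)
        slope, intercept, r2, t = ols_oracle(x, y)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.r_squared == pytest.approx(r2, rel=1e-10)
        assert res.t_value == pytest.approx(t, rel=1e-10)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            profiles.linear_regression([1, 1, 1, 1], [1, 2, 3, 4])

    def test_synthetic_sulfate_sulfide_coupling_negative_t(self):
        """Sulfide rises stoichiometrically as sulfate falls, so the pooled
        regression has a strongly negative slope t."""
        prof1, _ = synthetic.generate_core(synthetic.clb_preset(seed=11, core_id="c1"))
        prof2, _ = synthetic.generate_core(
            synthetic.clb_preset(seed=12, core_id="c2", onset=34.0)
        )
        pooled = DepthProfile(
            pd.concat([prof1.data, prof2.data], ignore_index=True)
        )
        res = profiles.sulfate_sulfide_regression(pooled, pooled=True)["pooled"]
        assert res.t_value < -5
        assert res.r_squared > 0.6
        assert res.df == 40  # 2 cores x 21 sections - 2
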