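"""Stepping and compensation regressions: recovery, calibration, invariances."""

import numpy as np
import pytest

from gaitstab import (
    SimConfig,
    analyze_recording,
    compensation_regression,
    compute_fp_error,
    extract_midstance_state,
    fit_compensation,
    fit_stepping,
    normalize_percent_gait,
    simulate_walker,
    stepping_regression,
)
from gaitstab.regression import RegressionError, center_by_side


class TestNoiselessRecovery:
    def test_gains_and_r2_exact(self, walker_noiseless, analysis_noiseless):
        """Zero-noise walker: fitted gains equal the generator matrix."""
        cfg, *_ = walker_noiseless
        for direction, row in (("AP", 0), ("ML", 1)):
            reg = stepping_regression(analysis_noiseless, direction)
            assert np.allclose(reg.gains, cfg.stepping_gains[row], atol=1e-9)
            assert reg.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_errors_vanish_at_perfect_fit(self, analysis_noiseless):
        reg = stepping_regression(analysis_noiseless, "ML")
        err = compute_fp_error(reg)
        assert np.max(np.abs(err)) < 1e-9


class TestNoisyCalibration:
    def test_gain_estimates_cover_zero_truth(self):
        """With B = 0 the gain estimates stay within 2 SE of zero."""
        inside = total = 0
        for seed in range(20):
            cfg = SimConfig(
                n_strides=150, stepping_gains=np.zeros((2, 9)), seed=seed
            )
            kin, _, _ = simulate_walker(cfg)
            an = analyze_recording(kin, clock_offset=0.0)
            reg = stepping_regression(an, "AP")
            inside += int(np.sum(np.abs(reg.gains) < 2 * reg.se))
            total += len(reg.gains)
        assert inside / total >= 0.90

    def test_r2_matches_generator_analytic_value(self):
        """Fitted R^2 tracks signal variance / total variance."""
        cfg0 = SimConfig()
        b = cfg0.stepping_gains[1]
        sig = float(b @ cfg0.com_state_cov @ b)
        noise = np.sqrt(sig / 9.0)  # population R^2 = 0.9
        r2 = []
        for seed in range(8):
            cfg = SimConfig(n_strides=250, fp_noise_sd=noise, seed=seed)
            kin, _, _ = simulate_walker(cfg)
            an = analyze_recording(kin, clock_offset=0.0)
            r2.append(stepping_regression(an, "ML").r_squared)
        assert np.mean(r2) == pytest.approx(0.9, abs=0.03)

    def test_error_variance_matches_noise_level(self):
        cfg = SimConfig(n_strides=300, seed=9)
        kin, _, _ = simulate_walker(cfg)
        an = analyze_recording(kin, clock_offset=0.0)
        err = compute_fp_error(stepping_regression(an, "ML"))
        assert np.var(err) == pytest.approx(cfg.fp_noise_sd**2, rel=0.15)


class TestFitContracts:
    def _toy(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 9))
        beta = np.linspace(0.1, 0.9, 9)
        y = X @ beta + rng.normal(0, 0.05, n)
        fp = np.column_stack([y, y])
        sides = np.array(["L", "R"] * (n // 2))
        return X, fp, sides, beta

    def test_scale_equivariance(self):
        """Scaling one predictor column by c divides its gain by c."""
        X, fp, sides, _ = self._toy()
        base = fit_stepping(X, fp, sides, "AP")
        X2 = X.copy()
        X2[:, 4] *= 10.0
        scaled = fit_stepping(X2, fp, sides, "AP")
        assert scaled.gains[4] == pytest.approx(base.gains[4] / 10.0, rel=1e-9)
        assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-12)

    def test_rank_deficiency_names_columns(self):
        X, fp, sides, _ = self._toy()
        X[:, 3] = 2.0 * X[:, 1]
        with pytest.raises(RegressionError, match="pos_ml|vel_ap"):
            fit_stepping(X, fp, sides, "AP")

    def test_minimum_sample_size_enforced(self):
        X, fp, sides, _ = self._toy(n=20)
        with pytest.raises(RegressionError, match="at least 30"):
            fit_stepping(X, fp, sides, "AP")

    def test_error_requires_matching_step_count(self):
        X, fp, sides, _ = self._toy()
        reg = fit_stepping(X, fp, sides, "AP")
        with pytest.raises(RegressionError, match="fitted on"):
            compute_fp_error(reg, n_expected=10)

    def test_residuals_average_to_zero(self):
        X, fp, sides, _ = self._toy()
        reg = fit_stepping(X, fp, sides, "ML")
        assert np.mean(compute_fp_error(reg)) == pytest.approx(0.0, abs=1e-12)


class TestCompensation:
    def test_noiseless_recovery_exact(self):
        """compensation_noise_sd = 0: exact gains, R^2 = 1 end to end."""
        cfg = SimConfig(n_strides=30, compensation_noise_sd=0.0, seed=5)
        kin, insole, _ = simulate_walker(cfg)
        an = analyze_recording(kin, insole)
        comp = compensation_regression(an)
        assert comp.beta_ankle == pytest.approx(cfg.ankle_gain, abs=1e-9)
        assert comp.beta_trunk == pytest.approx(cfg.trunk_gain, abs=1e-9)
        assert comp.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_swapping_predictors_swaps_gains(self):
        rng = np.random.default_rng(2)
        c = rng.normal(0, 0.01, 80)
        w = rng.normal(0, 1.0, 80)
        e = 0.3 * c + 0.01 * w + rng.normal(0, 0.002, 80)
        a = fit_compensation(e, c, w)
        b = fit_compensation(e, w, c)
        assert a.beta_ankle == pytest.approx(b.beta_trunk, rel=1e-12)
        assert a.beta_trunk == pytest.approx(b.beta_ankle, rel=1e-12)

    def test_constant_predictor_rejected(self):
        rng = np.random.default_rng(3)
        e = rng.normal(size=40)
        with pytest.raises(RegressionError, match="constant predictor"):
            fit_compensation(e, np.zeros(40), rng.normal(size=40))

    def test_reports_significance_against_zero(self):
        cfg = SimConfig(n_strides=100, seed=6)
        kin, insole, _ = simulate_walker(cfg)
        an = analyze_recording(kin, insole)
        comp = compensation_regression(an)
        assert comp.pvalues.shape == (2,)
        # strong true trunk coupling must be detected
        assert comp.pvalues[1] < 0.05


class TestMidstanceState:
    def test_constant_velocity_recovered(self, walker_noiseless, analysis_noiseless):
        """A linear-ramp CoM yields the ramp slope at any midstance choice."""
        _, kin, _, _ = walker_noiseless
        s = normalize_percent_gait(kin, analysis_noiseless.slices[1])
        s.com_vel = np.tile([1.37, 0.0, 0.0], (s.n_points, 1))
        for placement in ("left", "right"):
            state = extract_midstance_state(s, placement)
            assert state[3] == pytest.approx(1.37, abs=1e-12)

    def test_matches_ground_truth_states(self, walker_noisy, analysis_noisy):
        """Pipeline midstance states equal the generator's injected states."""
        cfg, _, _, gt = walker_noisy
        from gaitstab.regression import STATE_NAMES

        measured = analysis_noisy.steps[
            [f"state_{n}" for n in STATE_NAMES]
        ].to_numpy()
        measured = center_by_side(measured, analysis_noisy.steps["side"].to_numpy())
        assert measured.shape == gt.states.shape
        assert np.allclose(measured, gt.states, atol=1e-9)

    def test_invalid_placement_label(self, walker_noiseless, analysis_noiseless):
        _, kin, _, _ = walker_noiseless
        s = normalize_percent_gait(kin, analysis_noiseless.slices[1])
        with pytest.raises(ValueError):
            extract_midstance_state(s, "middle")
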