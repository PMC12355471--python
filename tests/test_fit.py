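"""Model-fitting tests: hand-evaluated model values, exact recovery from
noiseless curves, calibration identities, replicate pooling, and
misspecification behavior."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nanofcs import (
    ConfocalCalibration,
    CorrelationCurve,
    DiffusionModelParams,
    FitResult,
    auto_init,
    calibrate_confocal,
    fit_curve,
    g_diffusion_3d,
    pool_replicates,
    synth_correlation_curve,
)


class TestModel:
    def test_zero_lag_is_offset_plus_inverse_occupancy(self):
        p = DiffusionModelParams(4.0, 1e-3, 5.0, offset=0.1)
        assert g_diffusion_3d(0.0, p) == pytest.approx(0.35, rel=1e-12)

    def test_hand_value_at_tau_d(self):
        p = DiffusionModelParams(1.0, 817e-6, 5.0)
        assert g_diffusion_3d(817e-6, p) == pytest.approx(
            0.5 * (1 + 1 / 25) ** -0.5, rel=1e-12
        )
        assert g_diffusion_3d(817e-6, p) == pytest.approx(0.4903, abs=5e-5)

    def test_long_lag_decays_to_offset(self):
        p = DiffusionModelParams(2.0, 1e-4, 5.0, offset=0.02)
        assert g_diffusion_3d(1e4, p) == pytest.approx(0.02, abs=1e-8)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DiffusionModelParams(0.0, 1e-3, 5.0)
        with pytest.raises(ValueError):
            DiffusionModelParams(1.0, -1e-3, 5.0)
        with pytest.raises(ValueError):
            DiffusionModelParams(1.0, 1e-3, 0.9)

    def test_triplet_factor_raises_short_lag_correlation(self):
        p = DiffusionModelParams(1.0, 1e-3, 5.0)
        plain = g_diffusion_3d(1e-6, p)
        with_triplet = g_diffusion_3d(
            1e-6, p, triplet_fraction=0.2, triplet_time=5e-6
        )
        assert with_triplet > plain
        # triplet relaxes away at long lags
        assert g_diffusion_3d(1e-1, p, triplet_fraction=0.2, triplet_time=5e-6) == (
            pytest.approx(g_diffusion_3d(1e-1, p), rel=1e-9)
        )


class TestFitRecovery:
    @pytest.mark.parametrize("occupancy", [0.05, 1.0, 50.0])
    @pytest.mark.parametrize("tau_d", [1e-5, 1e-3, 1e-2])
    def test_exact_recovery_from_noiseless_curve(self, occupancy, tau_d):
        truth = DiffusionModelParams(occupancy, tau_d, 5.0)
        lags = np.logspace(np.log10(tau_d) - 2.5, np.log10(tau_d) + 2.5, 64)
        curve = synth_correlation_curve(truth, lags)
        result = fit_curve(curve, auto_init(curve, 5.0), fix_s=True)
        assert result.params.occupancy == pytest.approx(occupancy, rel=1e-6)
        assert result.params.residence_time == pytest.approx(tau_d, rel=1e-6)

    def test_fit_is_deterministic(self):
        truth = DiffusionModelParams(2.0, 817e-6, 5.0)
        lags = np.logspace(-6, 0, 64)
        curve = synth_correlation_curve(truth, lags, noise_sigma=0.02, seed=1)
        a = fit_curve(curve, auto_init(curve, 5.0))
        b = fit_curve(curve, auto_init(curve, 5.0))
        assert a.params == b.params

    def test_fit_invariant_under_reordering_of_lag_points(self):
        truth = DiffusionModelParams(2.0, 5e-4, 5.0)
        lags = np.logspace(-6, -1, 40)
        curve = synth_correlation_curve(truth, lags, noise_sigma=0.03, seed=2)
        perm = np.random.default_rng(0).permutation(len(lags))
        order = np.argsort(lags[perm])
        permuted = CorrelationCurve(
            lags=lags[perm][order],
            values=curve.values[perm][order],
            sd=curve.sd[perm][order],
        )
        a = fit_curve(curve, auto_init(curve, 5.0))
        b = fit_curve(permuted, auto_init(permuted, 5.0))
        assert a.params.residence_time == pytest.approx(
            b.params.residence_time, rel=1e-10
        )

    def test_wrong_fixed_structure_parameter_degrades_fit(self):
        truth = DiffusionModelParams(2.0, 817e-6, 5.0)
        lags = np.logspace(-6, 0, 80)
        curve = synth_correlation_curve(truth, lags, noise_sigma=0.01, seed=3)
        good = fit_curve(curve, auto_init(curve, 5.0), fix_s=True)
        bad = fit_curve(curve, auto_init(curve, 4.0), fix_s=True)
        assert bad.reduced_chi_square > 2 * good.reduced_chi_square
        assert abs(bad.params.residence_time - 817e-6) > abs(
            good.params.residence_time - 817e-6
        )

    def test_too_few_lags_rejected(self):
        truth = DiffusionModelParams(1.0, 1e-4, 5.0)
        curve = synth_correlation_curve(truth, np.logspace(-6, -2, 5))
        with pytest.raises(ValueError, match="at least 8"):
            fit_curve(curve)

    def test_free_s_recovers_structure_parameter_from_clean_curve(self):
        truth = DiffusionModelParams(1.0, 5e-4, 6.0)
        lags = np.logspace(-6.5, 0, 96)
        curve = synth_correlation_curve(truth, lags)
        result = fit_curve(curve, auto_init(curve, 3.0), fix_s=False)
        assert result.params.structure_parameter == pytest.approx(6.0, rel=1e-4)


class TestCalibration:
    def test_hand_value(self):
        fit = FitResult(
            params=DiffusionModelParams(1.0, 30e-6, 5.0),
            uncertainties={},
            reduced_chi_square=1.0,
        )
        cal = calibrate_confocal(fit, dye_diffusion_coefficient=330.0)
        assert cal.beam_radius_xy == pytest.approx(np.sqrt(4 * 330 * 30e-6), rel=1e-12)
        assert cal.beam_radius_xy == pytest.approx(0.199, abs=5e-4)

    def test_quadrupled_residence_time_doubles_beam_radius(self):
        base = FitResult(DiffusionModelParams(1.0, 30e-6, 5.0), {}, 1.0)
        slow = FitResult(DiffusionModelParams(1.0, 120e-6, 5.0), {}, 1.0)
        w1 = calibrate_confocal(base, 330.0).beam_radius_xy
        w2 = calibrate_confocal(slow, 330.0).beam_radius_xy
        assert w2 == pytest.approx(2 * w1, rel=1e-12)

    def test_effective_volume_invariant(self):
        cal = ConfocalCalibration(beam_radius_xy=0.33, structure_parameter=5.0)
        assert cal.effective_volume == pytest.approx(
            np.pi**1.5 * 0.33**2 * 1.65, rel=1e-15
        )
        assert cal.effective_volume == pytest.approx(1.0, abs=0.01)  # ~1 fL

    @given(
        w=st.floats(min_value=0.1, max_value=0.5),
        d=st.floats(min_value=10.0, max_value=500.0),
    )
    def test_calibration_inverts_residence_time_relation(self, w, d):
        # tau_D = w^2/(4D) then calibrate_confocal must return w exactly
        tau = w**2 / (4 * d)
        fit = FitResult(DiffusionModelParams(1.0, tau, 5.0), {}, 1.0)
        cal = calibrate_confocal(fit, d)
        assert cal.beam_radius_xy == pytest.approx(w, rel=1e-12)

    def test_nonpositive_dye_d_rejected(self):
        fit = FitResult(DiffusionModelParams(1.0, 30e-6, 5.0), {}, 1.0)
        with pytest.raises(ValueError):
            calibrate_confocal(fit, 0.0)


class TestPooling:
    def _fit(self, tau):
        return FitResult(DiffusionModelParams(2.0, tau, 5.0), {}, 1.0, mean_rate=50.0)

    def test_three_point_mean_and_sd(self):
        pooled = pool_replicates([self._fit(t) for t in (800e-6, 817e-6, 834e-6)])
        assert pooled.params.residence_time == pytest.approx(817e-6, rel=1e-12)
        assert pooled.uncertainties["residence_time"] == pytest.approx(17e-6, rel=1e-12)
        assert not pooled.under_replicated

    def test_identical_fits_have_zero_sd(self):
        pooled = pool_replicates([self._fit(800e-6)] * 4)
        assert pooled.uncertainties["residence_time"] == 0.0

    def test_fewer_than_three_is_flagged(self):
        pooled = pool_replicates([self._fit(800e-6), self._fit(820e-6)])
        assert pooled.under_replicated
        assert pooled.n_replicates == 2

    def test_pooled_mean_converges_to_ground_truth(self):
        truth = DiffusionModelParams(2.0, 817e-6, 5.0)
        lags = np.logspace(-6, 0, 64)
        fits = [
            fit_curve(c, auto_init(c, 5.0), fix_s=True)
            for c in (
                synth_correlation_curve(truth, lags, noise_sigma=0.02, seed=s)
                for s in range(20)
            )
        ]
        few = pool_replicates(fits[:5])
        many = pool_replicates(fits)
        assert abs(many.params.residence_time - 817e-6) <= 3 * (
            many.uncertainties["residence_time"] / np.sqrt(20)
        )
        # more replicates: standard error of the mean shrinks
        assert many.uncertainties["residence_time"] / np.sqrt(20) < few.uncertainties[
            "residence_time"
        ] / np.sqrt(5)
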