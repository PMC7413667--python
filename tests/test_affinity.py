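"""Equilibrium affinity model: closed forms, fitting, and kinetics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitoloc.affinity import (
    AffinityModel,
    KineticsParams,
    affinity_to_free_energy,
    calibrate_effective_volume,
    competency_duration,
    fit_affinity,
    invert_localization,
    predict_condition,
    predict_localization,
)
from mitoloc.diffusion import BaselineCurve


def _curve(slope):
    return BaselineCurve(points=pd.DataFrame(), slope=slope, slope_ci=(slope, slope))


class TestClosedForm:
    @pytest.mark.parametrize(
        "A,r0,expected",
        [
            (1.0, 0.3, 0.3),
            (8.8, 0.2, 0.6875),
            (2.4, 0.1, 0.24 / 1.14),
            (5.0, 0.0, 0.0),
            (0.0, 0.4, 0.0),
        ],
    )
    def test_predict_hand_values(self, A, r0, expected):
        assert predict_localization(A, r0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "A,rp,expected", [(8.8, 0.6875, 0.2), (1.0, 0.42, 0.42), (2.4, 0.0, 0.0)]
    )
    def test_invert_hand_values(self, A, rp, expected):
        assert invert_localization(A, rp) == pytest.approx(expected, abs=1e-12)

    @given(
        st.floats(0.1, 100.0),
        st.floats(0.0, 0.99),
    )
    def test_round_trip_identity(self, A, r0):
        rp = predict_localization(A, r0)
        assert invert_localization(A, rp) == pytest.approx(r0, abs=1e-12)

    def test_mass_action_composition_identity(self):
        # R' = K[surf] / (1 + K[surf]) with K[surf] = A * R0/(1-R0)
        A_grid = np.logspace(-2, 2, 25)
        r0_grid = np.linspace(0.001, 0.95, 25)
        for A in A_grid:
            ks = A * r0_grid / (1.0 - r0_grid)
            direct = ks / (1.0 + ks)
            np.testing.assert_allclose(
                predict_localization(A, r0_grid), direct, atol=1e-12
            )

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0), st.floats(0.01, 0.99))
    def test_monotone_in_affinity(self, a1, a2, r0):
        lo, hi = sorted((a1, a2))
        assert predict_localization(lo, r0) <= predict_localization(hi, r0) + 1e-15

    @given(st.floats(1.0, 200.0), st.floats(0.01, 0.99))
    def test_affinity_above_one_enriches(self, A, r0):
        assert predict_localization(A, r0) >= r0 - 1e-15

    def test_saturation_limit(self):
        for r0 in (0.01, 0.1, 0.5):
            assert predict_localization(1e9, r0) == pytest.approx(1.0, abs=1e-6)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            predict_localization(-1.0, 0.5)
        with pytest.raises(ValueError):
            invert_localization(0.0, 0.3)
        with pytest.raises(ValueError):
            predict_localization(2.0, 1.5)


class TestFreeEnergy:
    def test_reference_values(self):
        assert affinity_to_free_energy(1.0) == 0.0
        assert affinity_to_free_energy(np.e) == pytest.approx(-1.0)
        assert affinity_to_free_energy(8.8) == pytest.approx(-2.1748, abs=1e-4)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            affinity_to_free_energy(0.0)


class TestEffectiveVolume:
    def test_equal_slopes_give_unity(self):
        assert calibrate_effective_volume(2.0, 2.0) == 1.0

    def test_ratio_reproduces_study_value(self):
        # brownian 2.0 vs observed 3.0303 -> effective volume ~66%
        assert calibrate_effective_volume(3.0303, 2.0) == pytest.approx(0.66, abs=1e-3)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            calibrate_effective_volume(0.0, 2.0)

    def test_shallow_observed_slope_warns(self):
        with pytest.warns(UserWarning, match="shallower"):
            calibrate_effective_volume(1.0, 1.5)


class TestCompetencyDuration:
    def test_reporter_exceeds_30s(self):
        d = competency_duration(KineticsParams(orf_length=300))
        assert d == pytest.approx(300 / 9.5)
        assert d > 30.0

    def test_exposure_offset(self):
        assert competency_duration(
            KineticsParams(orf_length=475, mts_exposure=95)
        ) == pytest.approx(40.0)

    def test_zero_length(self):
        assert competency_duration(KineticsParams(orf_length=0)) == 0.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            KineticsParams(orf_length=100, elongation_rate=0.0)
        with pytest.raises(ValueError):
            KineticsParams(orf_length=100, mts_exposure=150)


def _cells_from_model(A, slope, f, n_tracks, noiseless=True, rng=None):
    r0 = np.clip(slope * f, 0, 1)
    p = predict_localization(A, r0)
    if noiseless:
        k = np.round(p * n_tracks)
    else:
        k = rng.binomial(n_tracks, p)
    return pd.DataFrame(
        {"mito_volume_fraction": f, "n_tracks": n_tracks, "n_associated": k}
    )


class TestAffinityFit:
    slope = 1.5
    f = np.linspace(0.05, 0.35, 20)

    def test_noiseless_high_affinity_recovered(self):
        cells = _cells_from_model(8.8, self.slope, self.f, 1000)
        fit = fit_affinity(cells, _curve(self.slope))
        assert fit.A_hat == pytest.approx(8.8, rel=0.01)
        assert fit.ci_95[0] <= fit.A_hat <= fit.ci_95[1]

    def test_null_affinity_recovered_with_covering_ci(self):
        # enough tracks per cell that a single realization pins A near 1
        rng = np.random.default_rng(4)
        cells = _cells_from_model(
            1.0, self.slope, self.f, 500, noiseless=False, rng=rng
        )
        fit = fit_affinity(cells, _curve(self.slope))
        assert fit.A_hat == pytest.approx(1.0, rel=0.1)
        assert fit.ci_95[0] <= 1.0 <= fit.ci_95[1]

    def test_two_cells_rejected(self):
        cells = _cells_from_model(2.0, self.slope, self.f[:2], 30)
        with pytest.raises(ValueError, match=">= 3 cells"):
            fit_affinity(cells, _curve(self.slope))

    def test_fully_associated_data_flagged(self):
        cells = pd.DataFrame(
            {
                "mito_volume_fraction": self.f[:5],
                "n_tracks": 30,
                "n_associated": 30,
            }
        )
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_affinity(cells, _curve(self.slope))
        assert fit.at_boundary

    def test_eta_rescaling_changes_baseline(self):
        rng = np.random.default_rng(9)
        # generated with f already divided by eta
        eta = 0.66
        r0 = np.clip(self.slope * self.f / eta, 0, 1)
        k = rng.binomial(200, predict_localization(2.4, r0))
        cells = pd.DataFrame(
            {"mito_volume_fraction": self.f, "n_tracks": 200, "n_associated": k}
        )
        fit = fit_affinity(cells, _curve(self.slope), eta=eta)
        assert fit.A_hat == pytest.approx(2.4, rel=0.15)

    def test_parameter_recovery_with_ci_coverage(self):
        # median recovery within 10% and >= 90% CI coverage over replicates
        rng = np.random.default_rng(123)
        for A_true in (1.0, 2.4, 8.8):
            hats, covered = [], 0
            n_rep = 60
            for _ in range(n_rep):
                f = rng.uniform(0.05, 0.35, 30)
                cells = _cells_from_model(
                    A_true, self.slope, f, 30, noiseless=False, rng=rng
                )
                fit = fit_affinity(cells, _curve(self.slope))
                hats.append(fit.A_hat)
                covered += fit.ci_95[0] <= A_true <= fit.ci_95[1]
            assert np.median(hats) == pytest.approx(A_true, rel=0.10)
            assert covered / n_rep >= 0.90

    def test_least_squares_alternative_close_to_mle(self):
        cells = _cells_from_model(2.4, self.slope, self.f, 500)
        mle = fit_affinity(cells, _curve(self.slope))
        lsq = fit_affinity(cells, _curve(self.slope), method="least_squares")
        assert lsq.A_hat == pytest.approx(mle.A_hat, rel=0.05)


class TestPredictCondition:
    def test_zero_fraction_zero_band(self):
        model = AffinityModel(baseline=_curve(1.5))
        point, lo, hi = predict_condition(model, 0.0)
        assert point == 0.0 and lo == 0.0 and hi == 0.0

    def test_band_from_ci_endpoints(self):
        from mitoloc.affinity import AffinityFit

        fit = AffinityFit(
            A_hat=2.5, ci_95=(2.0, 3.0), log_likelihood=0.0, n_cells=10,
            delta_g_kT=-np.log(2.5),
        )
        model = AffinityModel(baseline=_curve(1.0), fit=fit, eta=1.0)
        point, lo, hi = predict_condition(model, 0.1)
        assert lo == pytest.approx(predict_localization(2.0, 0.1), abs=1e-12)
        assert hi == pytest.approx(predict_localization(3.0, 0.1), abs=1e-12)
        assert lo == pytest.approx(0.2 / 1.1, abs=1e-12)
        assert hi == pytest.approx(0.25, abs=1e-12)

    def test_unit_affinity_predicts_baseline(self):
        model = AffinityModel(baseline=_curve(1.5))
        point, _, _ = predict_condition(model, 0.2)
        assert point == pytest.approx(0.3, abs=1e-12)

    def test_extrapolation_warns(self):
        model = AffinityModel(baseline=_curve(1.0))
        with pytest.warns(UserWarning, match="extrapolates"):
            predict_condition(model, 0.7)
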