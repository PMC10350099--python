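"""Fitting: noise model, canonical-scaling test, translation law, gamma fits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msgnoise import (
    LN2,
    PowerLawFit,
    derive_efficiency_model,
    derive_noise_prediction,
    fit_gamma,
    fit_noise_model,
    fit_translation_model,
    generate_noise_dataset,
)
from msgnoise import test_canonical_scaling as canonical_scaling_lr_test


class TestNoiseModelFit:
    def test_noiseless_exact_recovery(self):
        """With zero scatter the fit inverts the model to >= 3 decimals."""
        df = generate_noise_dataset(0.48, 1.9, 0.01, 500, scatter_log10=0.0, seed=3)
        fit = fit_noise_model(df, "alternative")
        assert fit.exponent == pytest.approx(0.48, abs=1e-4)
        assert fit.amplitude == pytest.approx(1.9, abs=1e-4)
        assert fit.floor == pytest.approx(0.01, abs=1e-5)

    def test_canonical_data_recovers_unit_exponent(self):
        """a-hat lands within 2 SE of 1 on scattered canonical-scaling data."""
        df = generate_noise_dataset(1.0, 1.9, 0.005, 2000, scatter_log10=0.15, seed=11)
        fit = fit_noise_model(df, "alternative")
        assert abs(fit.exponent - 1.0) < 2 * fit.exponent_se

    def test_null_fixes_exponent(self):
        df = generate_noise_dataset(0.5, 1.9, 0.005, 200, scatter_log10=0.1, seed=4)
        fit = fit_noise_model(df, "null")
        assert fit.exponent == 1.0 and fit.fixed_a

    def test_nesting_alternative_never_worse(self):
        """The free-exponent fit cannot have lower likelihood than the null."""
        for seed in range(5):
            df = generate_noise_dataset(0.7, 1.5, 0.01, 300, scatter_log10=0.2, seed=seed)
            null = fit_noise_model(df, "null")
            alt = fit_noise_model(df, "alternative")
            assert alt.loglik >= null.loglik - 1e-6

    def test_threshold_excludes_low_abundance(self):
        df = generate_noise_dataset(0.5, 1.9, 0.01, 400, scatter_log10=0.1,
                                    mu_p_range=(0.1, 1e4), seed=5)
        fit = fit_noise_model(df, "alternative", abundance_threshold=10.0)
        assert fit.n + fit.n_excluded == 400
        assert fit.n_excluded > 0

    def test_empty_input_rejected(self):
        df = pd.DataFrame({"protein_mean": [], "protein_cv2": []})
        with pytest.raises(ValueError):
            fit_noise_model(df)

    def test_degenerate_single_abundance_rejected(self):
        df = pd.DataFrame({"protein_mean": [100.0] * 20,
                           "protein_cv2": np.linspace(0.01, 0.1, 20)})
        with pytest.raises(ValueError, match="degenerate"):
            fit_noise_model(df)

    def test_floor_at_bound_flagged(self):
        df = generate_noise_dataset(0.5, 1.9, 0.0, 300, scatter_log10=0.0, seed=6)
        fit = fit_noise_model(df, "alternative")
        assert fit.c_at_bound


class TestCanonicalScalingTest:
    def test_identical_fits_give_p_one(self):
        df = generate_noise_dataset(1.0, 1.9, 0.005, 500, scatter_log10=0.1, seed=9)
        null = fit_noise_model(df, "null")
        # an "alternative" with exactly the null's likelihood: zero statistic
        alt = dataclasses.replace(null, fixed_a=False)
        assert canonical_scaling_lr_test(null, alt) == 1.0

    def test_non_canonical_data_strongly_rejected(self):
        df = generate_noise_dataset(0.5, 1.9, 0.005, 3000, scatter_log10=0.15, seed=5)
        null = fit_noise_model(df, "null")
        alt = fit_noise_model(df, "alternative")
        assert canonical_scaling_lr_test(null, alt) < 1e-6

    def test_mismatched_records_rejected(self):
        df1 = generate_noise_dataset(1.0, 1.9, 0.005, 200, seed=1)
        df2 = generate_noise_dataset(1.0, 1.9, 0.005, 300, seed=2)
        null = fit_noise_model(df1, "null")
        alt = fit_noise_model(df2, "alternative")
        with pytest.raises(ValueError, match="record sets"):
            canonical_scaling_lr_test(null, alt)

    def test_swapped_arguments_rejected(self):
        df = generate_noise_dataset(1.0, 1.9, 0.005, 200, seed=1)
        null = fit_noise_model(df, "null")
        alt = fit_noise_model(df, "alternative")
        with pytest.raises(ValueError):
            canonical_scaling_lr_test(alt, null)


class TestTranslationModel:
    def test_noiseless_power_law_recovery(self):
        mu_m = np.logspace(-0.5, 2.0, 150)
        df = pd.DataFrame({"message_number": mu_m, "protein_mean": 8.0 * mu_m**2.1})
        fit = fit_translation_model(df)
        assert fit.amplitude == pytest.approx(8.0, rel=1e-10)
        assert fit.exponent == pytest.approx(2.1, abs=1e-12)

    def test_proportional_case_recovers_unit_exponent(self):
        """The bacterial regime: protein proportional to message number."""
        mu_m = np.logspace(0, 3, 60)
        df = pd.DataFrame({"message_number": mu_m, "protein_mean": 500.0 * mu_m})
        fit = fit_translation_model(df)
        assert fit.exponent == pytest.approx(1.0, abs=1e-12)
        assert derive_efficiency_model(fit).exponent == pytest.approx(0.0, abs=1e-12)

    def test_scattered_recovery_within_two_se(self):
        rng = np.random.default_rng(17)
        mu_m = 10.0 ** rng.uniform(-0.5, 2.0, 1000)
        mu_p = 8.0 * mu_m**2.1 * 10.0 ** (0.3 * rng.standard_normal(1000))
        fit = fit_translation_model(pd.DataFrame({"message_number": mu_m,
                                                  "protein_mean": mu_p}))
        assert abs(fit.exponent - 2.1) < 2 * fit.exponent_se
        assert abs(np.log10(fit.amplitude) - np.log10(8.0)) < 2 * fit.amplitude_log10_se

    def test_nonpositive_rows_excluded_and_counted(self):
        df = pd.DataFrame({"message_number": [1.0, 2.0, 4.0, 0.0, np.nan],
                           "protein_mean": [8.0, 34.3, 147.0, 5.0, 3.0]})
        fit = fit_translation_model(df)
        assert fit.n == 3 and fit.n_excluded == 2

    def test_all_excluded_is_error(self):
        df = pd.DataFrame({"message_number": [0.0, 0.0, 0.0],
                           "protein_mean": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            fit_translation_model(df)


class TestDerivedLaws:
    def test_yeast_coefficients(self):
        """(8.0, 2.1) composes to the ~(1.9, -0.48) noise law and (8.0, 1.1) efficiency."""
        tm = PowerLawFit(amplitude=8.0, exponent=2.1)
        noise = derive_noise_prediction(tm)
        assert noise.exponent == pytest.approx(-1.0 / 2.1)
        assert round(noise.exponent, 2) == -0.48
        assert noise.amplitude == pytest.approx(LN2 * 8.0 ** (1 / 2.1))
        assert noise.amplitude == pytest.approx(1.9, abs=0.05)
        eff = derive_efficiency_model(tm)
        assert (eff.amplitude, eff.exponent) == (8.0, pytest.approx(1.1))

    def test_unit_exponent_reduces_to_canonical(self):
        noise = derive_noise_prediction(PowerLawFit(amplitude=5.0, exponent=1.0))
        assert noise.amplitude == pytest.approx(5.0 * LN2)
        assert noise.exponent == -1.0
        noise = derive_noise_prediction(PowerLawFit(amplitude=1.0, exponent=1.0))
        assert noise.amplitude == pytest.approx(LN2)

    def test_zero_exponent_rejected(self):
        with pytest.raises(ValueError):
            derive_noise_prediction(PowerLawFit(amplitude=2.0, exponent=0.0))

    @settings(max_examples=100, derandomize=True)
    @given(
        amp=st.floats(min_value=0.1, max_value=100.0),
        expo=st.floats(min_value=0.2, max_value=4.0),
        mu_m=st.floats(min_value=0.01, max_value=1e4),
    )
    def test_joint_consistency_with_abundance_noise_law(self, amp, expo, mu_m):
        """Noise law at mu_p and efficiency law at mu_m agree: eps*ln2/mu_p = ln2/mu_m."""
        tm = PowerLawFit(amplitude=amp, exponent=expo)
        noise = derive_noise_prediction(tm)
        eff = derive_efficiency_model(tm)
        mu_p = tm(mu_m)
        assert noise(mu_p) == pytest.approx(eff(mu_m) * LN2 / mu_p, rel=1e-9)
        assert noise(mu_p) == pytest.approx(LN2 / mu_m, rel=1e-9)

    def test_composition_on_noiseless_fit_matches_analytic(self):
        mu_m = np.logspace(0, 2, 80)
        fit = fit_translation_model(
            pd.DataFrame({"message_number": mu_m, "protein_mean": 8.0 * mu_m**2.1})
        )
        noise = derive_noise_prediction(fit)
        assert noise.amplitude == pytest.approx(LN2 * 8.0 ** (1 / 2.1), abs=1e-6)
        assert noise.exponent == pytest.approx(-1.0 / 2.1, abs=1e-6)


class TestGammaFit:
    def test_known_distribution_recovery(self):
        rng = np.random.default_rng(0)
        g = fit_gamma(rng.gamma(5.0, 10.0, 100_000))
        assert g.shape == pytest.approx(5.0, rel=0.02)
        assert g.scale == pytest.approx(10.0, rel=0.02)

    def test_mle_refinement_close_to_moments(self):
        rng = np.random.default_rng(1)
        x = rng.gamma(3.0, 7.0, 20_000)
        mom, mle = fit_gamma(x, "moments"), fit_gamma(x, "mle")
        assert mle.shape == pytest.approx(mom.shape, rel=0.05)

    def test_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_gamma(np.full(100, 3.0))

    def test_too_few_positive_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma(np.concatenate([np.zeros(100), np.ones(10)]))

    @settings(max_examples=25, derandomize=True)
    @given(scale_factor=st.floats(min_value=0.01, max_value=100.0))
    def test_scale_equivariance(self, scale_factor):
        """Scaling samples scales theta-hat and leaves k-hat unchanged."""
        rng = np.random.default_rng(123)
        x = rng.gamma(4.0, 2.0, 5000)
        base = fit_gamma(x)
        scaled = fit_gamma(x * scale_factor)
        assert scaled.shape == pytest.approx(base.shape, rel=1e-9)
        assert scaled.scale == pytest.approx(base.scale * scale_factor, rel=1e-9)
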