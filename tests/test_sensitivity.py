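"""Regression sensitivity analysis: planted-coefficient recovery, nulls,
invariances, and logistic behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from skatrial.sensitivity import (linear_sensitivity, logistic_sensitivity,
                                  make_synthetic_linear,
                                  make_synthetic_logistic)

B_TRUE = {"g_sk": -0.6, "p_ca": 0.4, "ibar_ncx": -0.15, "vmax_serca": 0.05}


def _back_transform(res, factors, features):
    """Standardized coefficients -> raw log-log slopes."""
    sd_x = np.log(factors.to_numpy()).std(axis=0)
    sd_y = np.log(features.to_numpy()).std(axis=0)
    return res.coefficients * sd_y[None, :] / sd_x[:, None]


def test_noise_free_recovery_is_exact():
    factors, features = make_synthetic_linear(400, B_TRUE, noise_sd=0.0, seed=2)
    res = linear_sensitivity(factors, features)
    raw = _back_transform(res, factors, features)[:, 0]
    for k, b in zip(res.parameters, raw):
        assert b == pytest.approx(B_TRUE[k], abs=1e-6)
    assert res.diagnostics["r2_feature"] == pytest.approx(1.0, abs=1e-12)


def test_noisy_recovery_within_two_standard_errors():
    factors, features = make_synthetic_linear(600, B_TRUE, noise_sd=0.02, seed=3)
    res = linear_sensitivity(factors, features)
    raw = _back_transform(res, factors, features)[:, 0]
    sd_x = np.log(factors.to_numpy()).std(axis=0)
    sd_y = np.log(features.to_numpy()).std(axis=0)
    raw_se = res.stderr[:, 0] * sd_y[0] / sd_x
    for k, b, se in zip(res.parameters, raw, raw_se):
        assert abs(b - B_TRUE[k]) < 2.0 * se, k


def test_independent_feature_has_null_coefficients():
    rng = np.random.default_rng(4)
    factors, _ = make_synthetic_linear(500, B_TRUE, seed=4)
    features = pd.DataFrame({"noise": np.exp(rng.normal(0, 0.05, 500))})
    res = linear_sensitivity(factors, features)
    assert np.all(np.abs(res.coefficients[:, 0]) < 3.0 * res.stderr[:, 0])


def test_permutation_null_kills_coefficients():
    factors, features = make_synthetic_linear(500, B_TRUE, noise_sd=0.01, seed=5)
    rng = np.random.default_rng(6)
    shuffled = features.sample(frac=1.0, random_state=7).reset_index(drop=True)
    res = linear_sensitivity(factors, shuffled)
    assert np.all(np.abs(res.coefficients[:, 0]) < 3.0 * res.stderr[:, 0])


def test_scale_invariance_of_standardized_coefficients():
    factors, features = make_synthetic_linear(300, B_TRUE, noise_sd=0.01, seed=8)
    res1 = linear_sensitivity(factors, features)
    scaled = factors.copy()
    scaled["g_sk"] = scaled["g_sk"] * 37.5
    res2 = linear_sensitivity(scaled, features)
    np.testing.assert_allclose(res1.coefficients, res2.coefficients,
                               rtol=1e-10)


def test_rank_deficiency_names_collinear_column():
    factors, features = make_synthetic_linear(200, B_TRUE, seed=9)
    factors["dup"] = factors["g_sk"]
    with pytest.raises(ValueError, match="collinear"):
        linear_sensitivity(factors, features)


def test_logistic_recovery_within_two_standard_errors():
    b_true = {"g_sk": -1.2, "p_ca": 0.9, "ibar_ncx": 0.5}
    factors, y = make_synthetic_logistic(2000, b_true, intercept=-0.3, seed=10)
    res = logistic_sensitivity(factors, y, "dad")
    for k, b, se in zip(res.parameters, res.coefficients[:, 0],
                        res.stderr[:, 0]):
        assert abs(b - b_true[k]) < 2.0 * se, k
    assert abs(res.intercept[0] - (-0.3)) < 2.0 * 0.1


def test_logistic_null_intercept_is_logit_prevalence():
    rng = np.random.default_rng(12)
    factors, _ = make_synthetic_logistic(1500, {"g_sk": 0.0, "p_ca": 0.0},
                                         seed=12)
    y = (rng.uniform(size=1500) < 0.3).astype(float)
    res = logistic_sensitivity(factors, y, "dad")
    assert np.all(np.abs(res.coefficients[:, 0]) < 0.2)
    assert res.intercept[0] == pytest.approx(logit(y.mean()), abs=0.05)


def test_logistic_separation_falls_back_to_ridge():
    rng = np.random.default_rng(13)
    x = np.exp(rng.normal(0, 0.1, size=(120, 2)))
    factors = pd.DataFrame(x, columns=["a", "b"])
    y = (np.log(x[:, 0]) > 0).astype(float)      # perfectly separable
    res = logistic_sensitivity(factors, y, "sep")
    assert "separation_fallback_ridge" in res.diagnostics
    assert np.isfinite(res.coefficients).all()


def test_outcome_must_contain_both_classes():
    factors, _ = make_synthetic_logistic(50, {"a": 0.5}, seed=14)
    with pytest.raises(ValueError):
        logistic_sensitivity(factors, np.ones(50), "x")


def test_summary_lists_parameters_by_magnitude():
    factors, features = make_synthetic_linear(300, B_TRUE, seed=15)
    res = linear_sensitivity(factors, features)
    text = res.summary()
    assert "g_sk" in text and "linear sensitivity" in text
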