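"""Marginal survival families: baselines, links, densities, inversion, fitting."""

import numpy as np
import pytest

from copulasurv.margins import (
    Coefficients,
    MarginSpec,
    baseline_survival,
    fit_margin,
    invert_survival,
    log_density,
    log_survival,
    margin_density,
    margin_loglik,
    survival_given_covariates,
)

SPECS = [
    MarginSpec("weibull", 1.5, 2e-4),
    MarginSpec("weibull", 1.0, 0.01),
    MarginSpec("gompertz", 0.002, 5e-4),
    MarginSpec("gompertz", -0.001, 2e-3),
    MarginSpec("loglogistic", 2.5, 600.0),
]


# ------------------------------------------------------------- baselines

def test_baseline_survival_at_zero_is_one():
    for spec in SPECS:
        assert baseline_survival(spec, 0.0) == pytest.approx(1.0)


def test_exponential_special_case():
    spec = MarginSpec("weibull", 1.0, 0.01)
    assert baseline_survival(spec, 100.0) == pytest.approx(np.exp(-1), rel=1e-12)


def test_loglogistic_scale_is_median():
    spec = MarginSpec("loglogistic", 2.0, 500.0)
    assert baseline_survival(spec, 500.0) == pytest.approx(0.5, rel=1e-12)


def test_survival_nonincreasing_in_time():
    t = np.linspace(1.0, 4000.0, 200)
    rng = np.random.default_rng(3)
    for spec in SPECS:
        lp = float(rng.normal(0, 0.5))
        s = np.exp(log_survival(spec, lp, t))
        assert np.all(np.diff(s) <= 1e-14)


def test_gompertz_small_gamma_matches_exponential_limit():
    near = MarginSpec("gompertz", 1e-10, 1e-3)
    expo = MarginSpec("weibull", 1.0, 1e-3)
    t = np.array([10.0, 500.0, 2000.0])
    assert np.allclose(baseline_survival(near, t), baseline_survival(expo, t), rtol=1e-6)


def test_gompertz_negative_gamma_plateaus():
    spec = MarginSpec("gompertz", -0.002, 1e-3)
    # survival floor is exp(-lam/|gamma|) = exp(-0.5); below it inversion
    # has no finite solution
    floor = np.exp(-0.5)
    assert baseline_survival(spec, 1e7) == pytest.approx(floor, rel=1e-9)
    assert invert_survival(spec, 0.0, None, floor * 0.9) == np.inf


# -------------------------------------------------------------- links

def test_ph_power_identity():
    spec = MarginSpec("weibull", 1.3, 1e-4)
    coef = Coefficients([np.log(2.0)], ("x",))
    t = invert_survival(spec, 0.0, None, 0.9)  # baseline S0(t) = 0.9
    assert survival_given_covariates(spec, coef, [1.0], t) == pytest.approx(0.81, rel=1e-9)


def test_po_odds_identity():
    # at the baseline median, a failure odds ratio of 1.45 gives S = 1/2.45
    spec = MarginSpec("loglogistic", 2.0, 500.0)
    coef = Coefficients([np.log(1.45)], ("x",))
    assert survival_given_covariates(spec, coef, [1.0], 500.0) == pytest.approx(
        1 / 2.45, rel=1e-9)


def test_zero_linear_predictor_recovers_baseline():
    t = np.array([50.0, 700.0, 2500.0])
    for spec in SPECS:
        coef = Coefficients([0.7, -0.2], ("a", "b"))
        z = np.zeros(2)
        assert np.allclose(survival_given_covariates(spec, coef, z, t),
                           baseline_survival(spec, t), rtol=1e-12)


def test_ph_hazard_identity():
    """f/S equals the baseline hazard times exp(b'z) for PH families."""
    for spec in SPECS:
        if spec.link != "ph":
            continue
        lp = 0.4
        t = np.array([30.0, 400.0, 1500.0])
        haz = np.exp(log_density(spec, lp, t) - log_survival(spec, lp, t))
        if spec.family == "weibull":
            h0 = spec.scale * spec.shape * t ** (spec.shape - 1)
        else:
            h0 = spec.scale * np.exp(spec.shape * t)
        assert np.allclose(haz, h0 * np.exp(lp), rtol=1e-9)


def test_po_log_odds_shift():
    """log failure odds at fixed t shifts by exactly b'z from baseline."""
    spec = MarginSpec("loglogistic", 3.0, 800.0)
    lp = 0.62
    t = np.array([100.0, 800.0, 2000.0])
    s0 = baseline_survival(spec, t)
    s1 = np.exp(log_survival(spec, lp, t))
    shift = np.log((1 - s1) / s1) - np.log((1 - s0) / s0)
    assert np.allclose(shift, lp, rtol=1e-9)


# ------------------------------------------------------------- density

def test_density_matches_finite_difference():
    rng = np.random.default_rng(17)
    h = 1e-3
    for spec in SPECS:
        lp = float(rng.normal(0, 0.3))
        for t in rng.uniform(50, 1500, size=5):
            fd = -(np.exp(log_survival(spec, lp, t + h))
                   - np.exp(log_survival(spec, lp, t - h))) / (2 * h)
            assert np.exp(log_density(spec, lp, t)) == pytest.approx(fd, rel=1e-6, abs=1e-10)


def test_density_integrates_to_one():
    from scipy.integrate import quad

    for spec in [MarginSpec("weibull", 1.5, 2e-4),
                 MarginSpec("loglogistic", 2.5, 600.0)]:
        val, _ = quad(lambda t: float(np.exp(log_density(spec, 0.3, t))),
                      1e-9, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-5)


def test_exponential_density_value():
    spec = MarginSpec("weibull", 1.0, 0.01)
    coef = Coefficients([0.0], ("x",))
    assert margin_density(spec, coef, [0.0], 100.0) == pytest.approx(
        0.01 * np.exp(-1), rel=1e-12)


# ------------------------------------------------------------ inversion

def test_invert_survival_round_trip():
    rng = np.random.default_rng(23)
    for spec in SPECS:
        lp = rng.normal(0, 0.4, size=20)
        u = rng.uniform(0.02, 0.98, size=20)
        if spec.family == "gompertz" and spec.shape < 0:
            u = np.maximum(u, 0.8)  # stay above the cure-fraction floor
        t = invert_survival(spec, lp, None, u)
        assert np.allclose(np.exp(log_survival(spec, lp, t)), u, atol=1e-8)


def test_weibull_inversion_matches_root_finding():
    from scipy.optimize import brentq

    spec = MarginSpec("weibull", 1.7, 3e-5)
    lp, u = 0.3, 0.4
    t_closed = float(invert_survival(spec, lp, None, u))
    t_root = brentq(lambda t: float(np.exp(log_survival(spec, lp, t))) - u, 1e-6, 1e6)
    assert t_closed == pytest.approx(t_root, rel=1e-9)


def test_invert_rejects_bad_u():
    with pytest.raises(ValueError):
        invert_survival(SPECS[0], 0.0, None, 1.5)


# ----------------------------------------------------------- likelihood

def test_single_censored_record_contributes_log_survival():
    spec = MarginSpec("loglogistic", 2.0, 500.0)
    coef = Coefficients([0.5], ("x",))
    ll = margin_loglik(spec, coef, [300.0], [0], [[1.0]])
    assert ll == pytest.approx(float(log_survival(spec, 0.5, 300.0)))


def test_exponential_loglik_closed_form():
    """5-record toy set: loglik = sum(d) log(lam) - lam sum(t)."""
    lam = 0.004
    spec = MarginSpec("weibull", 1.0, lam)
    coef = Coefficients(np.array([]), ())
    t = np.array([100.0, 250.0, 80.0, 500.0, 40.0])
    d = np.array([1, 0, 1, 1, 0])
    ll = margin_loglik(spec, coef, t, d, np.zeros((5, 0)))
    assert ll == pytest.approx(3 * np.log(lam) - lam * t.sum(), rel=1e-12)


def test_duplicated_record_doubles_contribution():
    spec = MarginSpec("weibull", 1.2, 1e-3)
    coef = Coefficients([0.2], ("x",))
    one = margin_loglik(spec, coef, [150.0], [1], [[1.0]])
    two = margin_loglik(spec, coef, [150.0, 150.0], [1, 1], [[1.0], [1.0]])
    assert two == pytest.approx(2 * one, rel=1e-12)


def test_loglik_rejects_bad_records():
    spec = SPECS[0]
    coef = Coefficients([0.0], ("x",))
    with pytest.raises(ValueError, match="record 1"):
        margin_loglik(spec, coef, [10.0, -5.0], [1, 0], [[0.0], [0.0]])
    with pytest.raises(ValueError, match="record 0"):
        margin_loglik(spec, coef, [10.0], [2], [[0.0]])


# -------------------------------------------------------------- fitting

def _simulate_margin(spec, beta, n, seed, cens_scale):
    rng = np.random.default_rng(seed)
    Z = rng.integers(0, 2, size=(n, len(beta))).astype(float)
    lp = Z @ beta
    u = rng.uniform(1e-9, 1 - 1e-9, size=n)
    t = np.asarray(invert_survival(spec, lp, None, u))
    c = rng.exponential(cens_scale, size=n)
    return np.minimum(t, c), (t <= c).astype(int), Z


def test_exponential_mle_matches_closed_form():
    spec = MarginSpec("weibull", 1.0, 0.002)
    t, d, _ = _simulate_margin(spec, np.array([]), 400, 8, 800.0)
    fit = fit_margin("weibull", t, d, np.zeros((400, 0)), fix_shape=1.0)
    assert fit.spec.scale == pytest.approx(d.sum() / t.sum(), abs=1e-6)
    assert fit.spec.shape == 1.0


def test_weibull_parameter_recovery_within_3se():
    true = MarginSpec("weibull", 1.5, 0.002)
    beta = np.array([0.4])
    t, d, Z = _simulate_margin(true, beta, 2000, 12, 120.0)  # ~30% censored
    fit = fit_margin("weibull", t, d, Z)

    # test-side numerical Hessian as the SE oracle
    def nll(theta):
        spec = MarginSpec("weibull", np.exp(theta[0]), np.exp(theta[1]))
        return -margin_loglik(spec, Coefficients(theta[2:], ("x",)), t, d, Z)

    theta_hat = np.array([np.log(fit.spec.shape), np.log(fit.spec.scale),
                          fit.coef.beta[0]])
    k = len(theta_hat)
    H = np.zeros((k, k))
    h = 1e-5 * (1 + np.abs(theta_hat))
    for i in range(k):
        for j in range(k):
            ei, ej = np.zeros(k), np.zeros(k)
            ei[i], ej[j] = h[i], h[j]
            H[i, j] = (nll(theta_hat + ei + ej) - nll(theta_hat + ei - ej)
                       - nll(theta_hat - ei + ej) + nll(theta_hat - ei - ej)) / (4 * h[i] * h[j])
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    truth = np.array([np.log(true.shape), np.log(true.scale), beta[0]])
    assert np.all(np.abs(theta_hat - truth) < 3 * se)


def test_fit_is_invariant_to_record_order():
    true = MarginSpec("loglogistic", 2.2, 700.0)
    t, d, Z = _simulate_margin(true, np.array([0.5]), 500, 21, 1500.0)
    fit1 = fit_margin("loglogistic", t, d, Z)
    perm = np.random.default_rng(0).permutation(len(t))
    fit2 = fit_margin("loglogistic", t[perm], d[perm], Z[perm])
    assert fit1.spec.shape == pytest.approx(fit2.spec.shape, abs=1e-10)
    assert fit1.coef.beta[0] == pytest.approx(fit2.coef.beta[0], abs=1e-10)


def test_fit_requires_events():
    with pytest.raises(ValueError, match="unidentifiable"):
        fit_margin("weibull", [100.0, 200.0], [0, 0], np.zeros((2, 0)))


def test_fitted_optimum_is_local_max():
    true = MarginSpec("weibull", 1.4, 1e-3)
    t, d, Z = _simulate_margin(true, np.array([0.3]), 800, 5, 2000.0)
    fit = fit_margin("weibull", t, d, Z)
    base = fit.loglik
    for dshape, dscale, dbeta in [(0.05, 0, 0), (-0.05, 0, 0), (0, 0.1, 0),
                                  (0, -0.1, 0), (0, 0, 0.05), (0, 0, -0.05)]:
        spec = MarginSpec("weibull", fit.spec.shape * (1 + dshape),
                          fit.spec.scale * (1 + dscale))
        coef = Coefficients(fit.coef.beta + dbeta, fit.coef.names)
        assert margin_loglik(spec, coef, t, d, Z) < base


def test_spec_validation():
    with pytest.raises(ValueError):
        MarginSpec("weibull", -1.0, 0.01)
    with pytest.raises(ValueError):
        MarginSpec("loglogistic", 2.0, 0.0)
    with pytest.raises(ValueError):
        MarginSpec("gamma", 1.0, 1.0)
    # gompertz shape may be negative
    assert MarginSpec("gompertz", -0.01, 1e-3).link == "ph"
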