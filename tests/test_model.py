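"""Joint four-pattern likelihood, two-stage estimation and Wald inference."""

import numpy as np
import pandas as pd
import pytest

from copulasurv import CopulaSurvivalModel, wald_inference
from copulasurv.copulas import get_copula
from copulasurv.margins import Coefficients, MarginSpec, margin_loglik
from copulasurv.model import joint_loglik
from copulasurv.simulate import (
    COVARIATE_ORDER,
    STUDY_BETA,
    SimConfig,
    default_config,
    generate_cohort,
)

M1 = MarginSpec("loglogistic", 3.2, 2300.0)
M2 = MarginSpec("loglogistic", 3.7, 2600.0)


def _cohort(n, seed, **kw):
    cfg = default_config(n=n, seed=seed)
    for k, v in kw.items():
        setattr(cfg, k, v)
    return generate_cohort(cfg)


# ------------------------------------------------------------ likelihood

def test_independence_factorizes_into_margins():
    df, _ = _cohort(200, 5)
    Z = df[list(COVARIATE_ORDER)].to_numpy()
    coef = Coefficients(default_config().beta_vector(), COVARIATE_ORDER)
    jl = joint_loglik(get_copula("clayton", 1e-8), M1, M2, coef,
                      df.y1, df.d1, df.y2, df.d2, Z)
    ml = (margin_loglik(M1, coef, df.y1, df.d1, Z)
          + margin_loglik(M2, coef, df.y2, df.d2, Z))
    assert jl == pytest.approx(ml, abs=1e-4)


def test_fully_censored_record_contributes_log_cdf():
    cop = get_copula("clayton", 1.4)
    coef = Coefficients([0.3], ("x",))
    y1, y2, z = 400.0, 900.0, np.array([[1.0]])
    ll = joint_loglik(cop, M1, M2, coef, [y1], [0], [y2], [0], z)
    from copulasurv.margins import log_survival

    u = np.exp(log_survival(M1, 0.3, y1))
    v = np.exp(log_survival(M2, 0.3, y2))
    assert ll == pytest.approx(float(cop.logcdf(u, v)), abs=1e-12)


def test_double_event_record_matches_mixed_derivative_oracle():
    """(1,1) contribution equals d2 C(S1(t1), S2(t2)) / dt1 dt2 by nested FD."""
    cop = get_copula("clayton", 2.0)
    m = MarginSpec("weibull", 1.0, 1e-3)  # exponential margins
    coef = Coefficients(np.array([]), ())
    t1, t2 = 600.0, 900.0
    z = np.zeros((1, 0))
    ll = joint_loglik(cop, m, m, coef, [t1], [1], [t2], [1], z)

    def S(spec, t):
        return float(np.exp(-spec.scale * t))

    def joint_surv(a, b):
        return float(cop.cdf(S(m, a), S(m, b)))

    h = 0.05
    fd = (joint_surv(t1 + h, t2 + h) - joint_surv(t1 + h, t2 - h)
          - joint_surv(t1 - h, t2 + h) + joint_surv(t1 - h, t2 - h)) / (4 * h * h)
    assert np.exp(ll) == pytest.approx(fd, rel=1e-5)


def test_likelihood_exchangeable_on_mirrored_data():
    df, _ = _cohort(150, 9)
    Z = df[list(COVARIATE_ORDER)].to_numpy()
    coef = Coefficients(default_config().beta_vector(), COVARIATE_ORDER)
    cop = get_copula("gumbel", 1.8)
    ll = joint_loglik(cop, M1, M2, coef, df.y1, df.d1, df.y2, df.d2, Z)
    ll_sw = joint_loglik(cop, M2, M1, coef, df.y2, df.d2, df.y1, df.d1, Z)
    assert ll == pytest.approx(ll_sw, abs=1e-9)


def test_joint_loglik_rejects_invalid_record():
    coef = Coefficients([0.0], ("x",))
    cop = get_copula("clayton", 1.4)
    with pytest.raises(ValueError, match="record 1"):
        joint_loglik(cop, M1, M2, coef, [10.0, -1.0], [1, 1], [5.0, 5.0],
                     [0, 0], [[0.0], [0.0]])


def test_truth_beats_perturbed_parameters_on_large_sample():
    df, _ = _cohort(5000, 77)
    cfg = default_config()
    Z = df[list(COVARIATE_ORDER)].to_numpy()
    coef = Coefficients(cfg.beta_vector(), COVARIATE_ORDER)
    cop = get_copula("clayton", cfg.eta)
    m_true = cfg.margin
    args = (df.y1, df.d1, df.y2, df.d2, Z)
    ll_true = joint_loglik(cop, m_true, m_true, coef, *args)
    perturbed = [
        (get_copula("clayton", cfg.eta * 1.6), m_true, coef),
        (cop, MarginSpec("loglogistic", m_true.shape * 1.3, m_true.scale), coef),
        (cop, m_true, Coefficients(cfg.beta_vector() + 0.3, COVARIATE_ORDER)),
    ]
    for cop_p, m_p, coef_p in perturbed:
        assert joint_loglik(cop_p, m_p, m_p, coef_p, *args) < ll_true


# --------------------------------------------------------------- fitting

def test_two_stage_recovery_at_n2000(covariates):
    df, _ = _cohort(2000, 3)
    res = CopulaSurvivalModel.from_dataframe(df, covariates=covariates).fit()
    cfg = default_config()
    truth = {**STUDY_BETA, "eta": cfg.eta}
    table = res.wald_table()
    for name in list(COVARIATE_ORDER) + ["eta"]:
        est, se = table.loc[name, "estimate"], table.loc[name, "se"]
        assert abs(est - truth[name]) < 3 * se, name
    assert res.llf >= res.stage2_llf - 1e-9


def test_refit_on_permuted_data_reproduces_estimates(covariates):
    df, _ = _cohort(800, 9)
    r1 = CopulaSurvivalModel.from_dataframe(df, covariates=covariates).fit(
        compute_se=False)
    perm = np.random.default_rng(0).permutation(len(df))
    dfp = df.iloc[perm].reset_index(drop=True)
    r2 = CopulaSurvivalModel.from_dataframe(dfp, covariates=covariates).fit(
        compute_se=False)
    assert np.allclose(r1.params.to_numpy(), r2.params.to_numpy(), atol=1e-8)


def test_fit_requires_events_in_each_margin():
    df = pd.DataFrame({"y1": [100.0, 200.0], "d1": [1, 0],
                       "y2": [150.0, 250.0], "d2": [0, 0], "x": [0, 1]})
    model = CopulaSurvivalModel.from_dataframe(df, covariates=["x"])
    with pytest.raises(ValueError, match="at least one observed event"):
        model.fit()


def test_ci_coverage_for_eta_across_replicates():
    """Empirical 95%-CI coverage for eta lies in [0.90, 0.99].

    Reduced harness: n = 250 per replicate, three active covariates (the
    others' true effects set to zero and excluded from the fit so the
    fitted model stays correctly specified).
    """
    active = ["male", "hypertension", "age_56_plus"]
    beta = {k: (STUDY_BETA[k] if k in active else 0.0) for k in STUDY_BETA}
    hits, total = 0, 200
    eta_true = default_config().eta
    for rep in range(total):
        cfg = default_config(n=250, seed=20_000 + rep)
        cfg.beta = beta
        df, _ = generate_cohort(cfg)
        res = CopulaSurvivalModel.from_dataframe(df, covariates=active).fit()
        se = res.bse["eta"]
        if abs(res.eta - eta_true) < 1.96 * se:
            hits += 1
    coverage = hits / total
    assert 0.90 <= coverage <= 0.99, coverage


# ---------------------------------------------------------- wald reporting

def test_wald_table_arithmetic(fitted_small):
    t = wald_inference(fitted_small)
    beta = fitted_small.beta
    se = fitted_small.bse
    for name in beta.index:
        assert t.loc[name, "or"] == pytest.approx(np.exp(beta[name]), rel=1e-12)
        assert t.loc[name, "ci_low"] == pytest.approx(
            np.exp(beta[name] - 1.96 * se[name]), rel=1e-3)
        assert t.loc[name, "ci_low"] < t.loc[name, "ci_high"]
        assert t.loc[name, "or"] > 0
    assert t.loc["eta", "estimate"] == pytest.approx(fitted_small.eta)


def test_zero_coefficient_maps_to_unit_or():
    # OR = exp(0) = 1 with a CI symmetric about 1 on the log scale
    b, se = 0.0, 0.18
    lo, hi = np.exp(b - 1.96 * se), np.exp(b + 1.96 * se)
    assert np.exp(b) == 1.0
    assert lo * hi == pytest.approx(1.0, rel=1e-12)


def test_results_ic_consistency(fitted_small):
    res = fitted_small
    assert res.aic == pytest.approx(-2 * res.llf + 2 * res.k_ic, abs=1e-9)
    assert res.bic == pytest.approx(-2 * res.llf + res.k_ic * np.log(res.nobs), abs=1e-9)
    assert res.tau == pytest.approx(res.eta / (res.eta + 2.0), abs=1e-12)
    assert res.k_ic == len(res.model.covariate_names) + 1


def test_summary_and_serialization(fitted_small, tmp_path):
    s = fitted_small.summary()
    assert "Kendall tau" in s and "eta" in s
    fitted_small.to_json(tmp_path / "fit.json")
    fitted_small.to_tsv(tmp_path / "fit.tsv")
    out = pd.read_csv(tmp_path / "fit.tsv", sep="\t")
    assert list(out.columns)[:4] == ["Variable", "Estimate", "SE", "z"]
    assert len(out) == len(fitted_small.model.covariate_names) + 1
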