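"""Parametric marginal survival regressions for the paired failure times.

Three baseline families are supported, each with the covariate link the
field uses for it:

* **Weibull**, proportional hazards (PH): baseline cumulative hazard
  ``H0(t) = lam * t**a`` with shape ``a > 0`` and rate ``lam > 0``.
* **Gompertz**, PH: baseline hazard ``h0(t) = lam * exp(gamma * t)`` with
  rate ``lam > 0`` and shape ``gamma`` real (``gamma < 0`` gives a
  plateauing survival curve — allowed, the cure fraction is documented);
  ``|gamma| -> 0`` is evaluated through the exponential limit.
* **Log-logistic**, proportional odds (PO): baseline survival
  ``S0(t) = 1 / (1 + (t/b)**a)`` with shape ``a > 0`` and scale ``b > 0``
  (the scale is the baseline median).

Under PH, ``S(t|z) = S0(t) ** exp(b'z)``; under PO the failure odds are
multiplied, ``S(t|z) = 1 / (1 + exp(b'z) * (t/b)**a)``, so ``exp(beta)``
is an odds ratio.  Time is measured in days throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "MarginSpec",
    "Coefficients",
    "MarginFit",
    "MARGIN_FAMILIES",
    "baseline_survival",
    "baseline_cumhaz",
    "survival_given_covariates",
    "log_survival",
    "margin_density",
    "log_density",
    "invert_survival",
    "margin_loglik",
    "fit_margin",
]

MARGIN_FAMILIES = ("weibull", "gompertz", "loglogistic")
_LINKS = {"weibull": "ph", "gompertz": "ph", "loglogistic": "po"}
_GOMPERTZ_TINY = 1e-8


@dataclass(frozen=True)
class MarginSpec:
    """One margin's baseline family and parameters.

    ``scale`` is the rate ``lam`` for weibull/gompertz and the scale ``b``
    (baseline median) for loglogistic; ``shape`` is ``a`` (weibull,
    loglogistic) or ``gamma`` (gompertz).
    """

    family: str
    shape: float
    scale: float

    def __post_init__(self):
        if self.family not in MARGIN_FAMILIES:
            raise ValueError(
                f"unknown margin family {self.family!r}; choose from {MARGIN_FAMILIES}"
            )
        if self.family != "gompertz" and not self.shape > 0:
            raise ValueError(f"{self.family} shape must be > 0")
        if not self.scale > 0:
            raise ValueError(f"{self.family} scale must be > 0")

    @property
    def link(self) -> str:
        """'ph' (weibull, gompertz) or 'po' (loglogistic); fixed by family."""
        return _LINKS[self.family]


@dataclass(frozen=True)
class Coefficients:
    """Regression coefficients with their covariate labels."""

    beta: np.ndarray
    names: tuple

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.beta) != len(self.names):
            raise ValueError("beta and covariate names must have equal length")


@dataclass
class MarginFit:
    """Result of a single-margin maximum-likelihood fit."""

    spec: MarginSpec
    coef: Coefficients
    loglik: float
    converged: bool
    n_restarts: int = 0


def _stable_sum(x) -> float:
    """Sum with sorted contributions: exactly invariant to record order."""
    return float(np.sum(np.sort(np.asarray(x, dtype=float).ravel())))


def _check_time(t, allow_zero=True):
    t = np.asarray(t, dtype=float)
    bad = t < 0 if allow_zero else t <= 0
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"time must be {'>= 0' if allow_zero else '> 0'} (record {idx})")
    return t


def baseline_cumhaz(spec: MarginSpec, t):
    """Baseline cumulative hazard H0(t) (PH families) or (t/b)**a odds (PO)."""
    t = _check_time(t)
    if spec.family == "weibull":
        return spec.scale * np.power(t, spec.shape)
    if spec.family == "gompertz":
        g = spec.shape
        if abs(g) < _GOMPERTZ_TINY:
            return spec.scale * t * (1.0 + 0.5 * g * t)
        with np.errstate(over="ignore"):  # inf H0 -> -inf loglik, guarded upstream
            return spec.scale * np.expm1(g * t) / g
    # loglogistic: the "cumulative odds of failure" plays H0's role
    return np.power(t / spec.scale, spec.shape)


def baseline_survival(spec: MarginSpec, t):
    """Baseline survival S0(t); S0(0) = 1, nonincreasing."""
    t = _check_time(t)
    if spec.link == "ph":
        return np.exp(-baseline_cumhaz(spec, t))
    return 1.0 / (1.0 + baseline_cumhaz(spec, t))


def log_survival(spec: MarginSpec, lp, t):
    """log S(t | z) with linear predictor lp = beta'z."""
    t = _check_time(t)
    lp = np.asarray(lp, dtype=float)
    if spec.link == "ph":
        return -baseline_cumhaz(spec, t) * np.exp(lp)
    # PO: S = 1/(1 + e^lp (t/b)^a); log S = -log1p(exp(m)), m = lp + a log(t/b)
    with np.errstate(divide="ignore"):
        m = lp + spec.shape * (np.log(t) - np.log(spec.scale))
    return -np.logaddexp(0.0, m)


def survival_given_covariates(spec: MarginSpec, coef: Coefficients, z, t):
    """S(t | z) for covariate row(s) z matching coef's ordering."""
    lp = _linear_predictor(coef, z)
    return np.exp(log_survival(spec, lp, t))


def log_density(spec: MarginSpec, lp, t):
    """log f(t | z) = log(-dS/dt); requires t > 0."""
    t = _check_time(t, allow_zero=False)
    lp = np.asarray(lp, dtype=float)
    if spec.family == "weibull":
        log_h0 = np.log(spec.scale * spec.shape) + (spec.shape - 1.0) * np.log(t)
        return log_h0 + lp - baseline_cumhaz(spec, t) * np.exp(lp)
    if spec.family == "gompertz":
        log_h0 = np.log(spec.scale) + spec.shape * t
        return log_h0 + lp - baseline_cumhaz(spec, t) * np.exp(lp)
    # loglogistic PO: f = a e^lp t^(a-1) / b^a / (1 + e^lp (t/b)^a)^2
    a, b = spec.shape, spec.scale
    m = lp + a * (np.log(t) - np.log(b))
    return np.log(a) + lp + (a - 1.0) * np.log(t) - a * np.log(b) - 2.0 * np.logaddexp(0.0, m)


def margin_density(spec: MarginSpec, coef: Coefficients, z, t):
    """f(t | z) = -dS(t|z)/dt (per day)."""
    lp = _linear_predictor(coef, z)
    return np.exp(log_density(spec, lp, t))


def invert_survival(spec: MarginSpec, coef_or_lp, z, u=None):
    """Time t with S(t | z) = u; closed form for every family/link.

    Call either ``invert_survival(spec, coef, z, u)`` or
    ``invert_survival(spec, lp, None, u)`` with a precomputed linear
    predictor.
    """
    if z is None:
        lp = np.asarray(coef_or_lp, dtype=float)
    else:
        lp = _linear_predictor(coef_or_lp, z)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    if spec.link == "po":
        a, b = spec.shape, spec.scale
        # S = u  <=>  e^lp (t/b)^a = (1-u)/u
        return b * np.exp((np.log1p(-u) - np.log(u) - lp) / a)
    target = -np.log(u) * np.exp(-lp)  # required H0(t)
    if spec.family == "weibull":
        return np.power(target / spec.scale, 1.0 / spec.shape)
    g, lam = spec.shape, spec.scale
    if abs(g) < _GOMPERTZ_TINY:
        return target / lam
    arg = g * target / lam
    with np.errstate(invalid="ignore"):
        out = np.log1p(arg) / g
    # gamma < 0 plateaus: survival never reaches u -> event never happens
    return np.where(arg <= -1.0, np.inf, out)


def _linear_predictor(coef: Coefficients, z):
    z = np.asarray(z, dtype=float)
    if z.ndim == 1 and len(coef.beta) != 1:
        if z.shape[0] != len(coef.beta):
            raise ValueError(
                f"covariate vector of length {z.shape[0]} does not match "
                f"{len(coef.beta)} coefficients"
            )
        return float(z @ coef.beta)
    z = np.atleast_2d(z)
    if z.shape[1] != len(coef.beta):
        raise ValueError(
            f"design matrix with {z.shape[1]} columns does not match "
            f"{len(coef.beta)} coefficients"
        )
    return z @ coef.beta


def margin_loglik(spec: MarginSpec, coef: Coefficients, t, d, Z) -> float:
    """Right-censored log-likelihood sum_i [d_i log f + (1-d_i) log S]."""
    t = _check_time(t, allow_zero=False)
    d = np.asarray(d)
    if not np.all(np.isin(d, (0, 1))):
        idx = int(np.flatnonzero(~np.isin(d, (0, 1)))[0])
        raise ValueError(f"event indicator must be 0/1 (record {idx})")
    d = d.astype(bool)
    lp = np.broadcast_to(np.atleast_1d(_linear_predictor(coef, Z)), t.shape)
    total = 0.0
    if np.any(d):
        total += _stable_sum(log_density(spec, lp[d], t[d]))
    if np.any(~d):
        total += _stable_sum(log_survival(spec, lp[~d], t[~d]))
    return total


# ---------------------------------------------------------------------------
# fitting


def _pack(spec: MarginSpec, beta):
    if spec.family == "gompertz":
        base = [spec.shape, np.log(spec.scale)]
    else:
        base = [np.log(spec.shape), np.log(spec.scale)]
    return np.concatenate([base, np.atleast_1d(beta)])


def _unpack(family: str, theta):
    if family == "gompertz":
        spec = MarginSpec(family, float(theta[0]), float(np.exp(theta[1])))
    else:
        spec = MarginSpec(family, float(np.exp(theta[0])), float(np.exp(theta[1])))
    return spec, np.asarray(theta[2:], dtype=float)


def _start_values(family: str, t, d, p: int) -> np.ndarray:
    rate = max(np.sum(d), 1) / _stable_sum(t)
    if family == "weibull":
        base = [0.0, np.log(rate)]  # a = 1, lam = events/exposure
    elif family == "gompertz":
        base = [0.0, np.log(rate)]  # gamma = 0 (exponential start)
    else:
        base = [0.0, np.log(np.median(t))]  # a = 1, b = median time
    return np.concatenate([base, np.zeros(p)])


def fit_margin(family: str, t, d, Z, names=None, start=None,
               max_restarts: int = 3, seed: int = 0,
               fix_shape: float | None = None) -> MarginFit:
    """Maximum-likelihood fit of one margin's censored regression.

    Positive parameters are optimized on the log scale (Gompertz gamma is
    unconstrained); convergence requires the quasi-Newton optimizer to
    report success, with up to ``max_restarts`` jittered restarts.
    ``fix_shape`` freezes the shape parameter (e.g. ``fix_shape=1.0`` with
    family="weibull" fits the exponential submodel).
    """
    t = _check_time(t, allow_zero=False)
    d = np.asarray(d, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != t.shape[0]:
        Z = Z.T
    p = Z.shape[1]
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    if np.sum(d) < 1:
        raise ValueError("no events observed: the margin model is unidentifiable")

    def nll(theta):
        if fix_shape is not None:
            fixed = fix_shape if family == "gompertz" else np.log(fix_shape)
            theta = np.concatenate([[fixed], theta])
        try:
            spec, beta = _unpack(family, theta)
            ll = margin_loglik(spec, Coefficients(beta, names), t, d, Z)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    theta0 = np.asarray(start, dtype=float) if start is not None else \
        _start_values(family, t, d, p)
    if fix_shape is not None and start is None:
        theta0 = theta0[1:]
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        x0 = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.3, size=theta0.shape)
        res = minimize(nll, x0, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    if not best.success and best.fun >= 1e11:
        raise RuntimeError(f"margin fit failed to converge: {best.message}")
    x = best.x
    if fix_shape is not None:
        fixed = fix_shape if family == "gompertz" else np.log(fix_shape)
        x = np.concatenate([[fixed], x])
    spec, beta = _unpack(family, x)
    return MarginFit(spec, Coefficients(beta, names), -float(best.fun),
                     bool(best.success), attempt)
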