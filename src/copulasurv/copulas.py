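"""Archimedean copula families for positive dependence: Clayton, Gumbel, Joe.

Each family is a one-parameter exchangeable copula ``C_eta(u, v)`` on the
unit square.  The dependence parameter ``eta`` maps to Kendall's tau by a
family-specific closed form (Clayton, Gumbel) or series (Joe); all three
families reach independence at the lower end of their parameter range
(``eta -> 0+`` for Clayton, ``eta = 1`` for Gumbel and Joe) and cover the
full positive-dependence range ``tau in [0, 1)``.

The likelihood of bivariate right-censored data needs four objects per
family — the CDF, the density ``c = d2C/dudv`` and the two first partials
``dC/du``, ``dC/dv`` — so every family exposes those on both the natural
and the log scale.  Log-scale forms are written with ``expm1``/``log1p``
so that the near-independence limit (Clayton ``eta ~ 1e-8``) and extreme
arguments are evaluated without catastrophic cancellation.

Conditional inversion ``v = h^{-1}(w | u)`` (solving dC/du = w) drives
both simulation and the scatter diagnostics: closed form for Clayton,
bracketed root-finding for Gumbel and Joe.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ArchimedeanCopula",
    "ClaytonCopula",
    "GumbelCopula",
    "JoeCopula",
    "get_copula",
    "tau_from_eta",
    "eta_from_tau",
    "FAMILIES",
]

# Clamp used by likelihood callers; evaluation functions themselves reject
# exact 0/1 for density/partials (the caller must clamp).
UNIT_EPS = 1e-12


def _as_unit(x, name, open_interval):
    x = np.asarray(x, dtype=float)
    if open_interval:
        if np.any((x <= 0.0) | (x >= 1.0)):
            raise ValueError(f"{name} must lie strictly inside (0, 1); clamp before calling")
    else:
        if np.any((x < 0.0) | (x > 1.0)):
            raise ValueError(f"{name} must lie in [0, 1]")
    return x


class ArchimedeanCopula:
    """Base class: a one-parameter exchangeable Archimedean copula."""

    family: str = ""

    def __init__(self, eta: float):
        eta = float(eta)
        self._validate_eta(eta)
        self.eta = eta

    # -- family contracts -------------------------------------------------
    def _validate_eta(self, eta: float) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def logcdf(self, u, v):
        raise NotImplementedError

    def logpdf(self, u, v):
        raise NotImplementedError

    def log_partial_u(self, u, v):
        """log dC/du; the conditional distribution of V given U=u, logged."""
        raise NotImplementedError

    def tau(self) -> float:
        raise NotImplementedError

    @classmethod
    def from_tau(cls, tau: float) -> "ArchimedeanCopula":
        return cls(eta_from_tau(cls.family, tau))

    # -- derived surface ---------------------------------------------------
    def cdf(self, u, v):
        """C(u, v); boundaries handled exactly (grounded, uniform margins)."""
        u = _as_unit(u, "u", open_interval=False)
        v = _as_unit(v, "v", open_interval=False)
        u, v = np.broadcast_arrays(u, v)
        out = np.empty(u.shape, dtype=float)
        interior = (u > 0) & (u < 1) & (v > 0) & (v < 1)
        out[~interior] = np.minimum(u, v)[~interior]  # exact on the boundary
        if np.any(interior):
            out[interior] = np.exp(self.logcdf(u[interior], v[interior]))
        return out if out.shape else float(out)

    def pdf(self, u, v):
        u = _as_unit(u, "u", open_interval=True)
        v = _as_unit(v, "v", open_interval=True)
        out = np.exp(self.logpdf(u, v))
        return out if np.ndim(out) else float(out)

    def partial_u(self, u, v):
        """dC/du in [0, 1]; v may sit on the boundary (0 -> 0, 1 -> 1)."""
        u = _as_unit(u, "u", open_interval=True)
        v = _as_unit(v, "v", open_interval=False)
        u, v = np.broadcast_arrays(u, v)
        out = np.empty(u.shape, dtype=float)
        lo, hi = v <= 0.0, v >= 1.0
        out[lo] = 0.0
        out[hi] = 1.0
        mid = ~(lo | hi)
        if np.any(mid):
            out[mid] = np.exp(self.log_partial_u(u[mid], v[mid]))
        return out if out.shape else float(out)

    def partial_v(self, u, v):
        """dC/dv, by exchangeability the mirror of ``partial_u``."""
        return self.partial_u(v, u)

    def log_partial_v(self, u, v):
        return self.log_partial_u(v, u)

    def inverse_partial_u(self, u, w):
        """Solve dC/du (u, v) = w for v (the conditional quantile h^{-1})."""
        u = _as_unit(u, "u", open_interval=True)
        w = _as_unit(w, "w", open_interval=True)
        u, w = np.broadcast_arrays(np.atleast_1d(u), np.atleast_1d(w))
        out = np.array([self._invert_one(float(ui), float(wi))
                        for ui, wi in zip(u.ravel(), w.ravel())])
        out = out.reshape(u.shape)
        return out if out.size > 1 else out.item()

    def _invert_one(self, u: float, w: float) -> float:
        lo, hi = UNIT_EPS, 1.0 - UNIT_EPS

        def f(v):
            return np.exp(self.log_partial_u(u, v)) - w

        flo, fhi = f(lo), f(hi)
        if flo >= 0.0:
            return lo
        if fhi <= 0.0:
            return hi
        return brentq(f, lo, hi, xtol=1e-13, rtol=1e-14)

    def conditional_sample(self, u, w):
        """The conditional quantile v with P(V <= v | U = u) = w.

        Pairs (u, conditional_sample(u, w)) with u, w iid uniform are
        distributed according to the copula; alias of
        :meth:`inverse_partial_u`.
        """
        return self.inverse_partial_u(u, w)

    def sample(self, n: int, rng) -> np.ndarray:
        """Draw n pairs with copula C via conditional inversion; shape (n, 2)."""
        u = rng.uniform(UNIT_EPS, 1.0 - UNIT_EPS, size=n)
        w = rng.uniform(UNIT_EPS, 1.0 - UNIT_EPS, size=n)
        v = np.atleast_1d(self.inverse_partial_u(u, w))
        return np.column_stack([u, v])

    def __repr__(self) -> str:
        return f"{type(self).__name__}(eta={self.eta:g})"


class ClaytonCopula(ArchimedeanCopula):
    """Clayton: C = (u^-eta + v^-eta - 1)^(-1/eta), eta > 0.

    Lower-tail dependent; tau = eta / (eta + 2); independence as eta -> 0+.
    """

    family = "clayton"

    def _validate_eta(self, eta):
        if not eta > 0.0:
            raise ValueError("clayton requires eta > 0 (independence is the limit eta -> 0+)")

    def _logs(self, u, v):
        # s = u^-eta + v^-eta - 1 - 1 computed as expm1 sum for stability
        lu, lv = np.log(u), np.log(v)
        s = np.expm1(-self.eta * lu) + np.expm1(-self.eta * lv)
        return lu, lv, np.log1p(s)

    def logcdf(self, u, v):
        _, _, ls = self._logs(u, v)
        return -ls / self.eta

    def log_partial_u(self, u, v):
        lu, _, ls = self._logs(u, v)
        return -(self.eta + 1.0) * lu - (1.0 + 1.0 / self.eta) * ls

    def logpdf(self, u, v):
        lu, lv, ls = self._logs(u, v)
        return (np.log1p(self.eta) - (self.eta + 1.0) * (lu + lv)
                - (2.0 + 1.0 / self.eta) * ls)

    def tau(self):
        return self.eta / (self.eta + 2.0)

    def inverse_partial_u(self, u, w):
        # closed form: v = [u^-eta (w^(-eta/(1+eta)) - 1) + 1]^(-1/eta)
        u = _as_unit(u, "u", open_interval=True)
        w = _as_unit(w, "w", open_interval=True)
        e = self.eta
        t = np.expm1(-e / (1.0 + e) * np.log(w))
        inner = np.exp(-e * np.log(u)) * t + 1.0
        out = np.exp(-np.log(inner) / e)
        return out if np.ndim(out) else float(out)


class GumbelCopula(ArchimedeanCopula):
    """Gumbel–Hougaard: C = exp(-[(-ln u)^eta + (-ln v)^eta]^(1/eta)), eta >= 1.

    Upper-tail dependent; tau = (eta - 1) / eta; independence at eta = 1.
    """

    family = "gumbel"

    def _validate_eta(self, eta):
        if not eta >= 1.0:
            raise ValueError("gumbel requires eta >= 1 (eta = 1 is independence)")

    def _logs(self, u, v):
        x, y = -np.log(u), -np.log(v)
        lx, ly = np.log(x), np.log(y)
        # log A = log(x^eta + y^eta) via logaddexp
        la = np.logaddexp(self.eta * lx, self.eta * ly)
        return x, y, lx, ly, la

    def logcdf(self, u, v):
        *_, la = self._logs(u, v)
        return -np.exp(la / self.eta)

    def log_partial_u(self, u, v):
        x, y, lx, ly, la = self._logs(u, v)
        e = self.eta
        return -np.exp(la / e) + (e - 1.0) * lx + (1.0 / e - 1.0) * la + x

    def logpdf(self, u, v):
        x, y, lx, ly, la = self._logs(u, v)
        e = self.eta
        a_pow = np.exp(la / e)  # A^(1/eta) = -log C
        return (-a_pow + (e - 1.0) * (lx + ly) + (1.0 / e - 2.0) * la
                + x + y + np.log(a_pow + e - 1.0))

    def tau(self):
        return (self.eta - 1.0) / self.eta


class JoeCopula(ArchimedeanCopula):
    """Joe: C = 1 - [x^eta + y^eta - x^eta y^eta]^(1/eta), x=1-u, y=1-v, eta >= 1.

    Strong upper-tail dependence; tau by series; independence at eta = 1.
    """

    family = "joe"

    def _validate_eta(self, eta):
        if not eta >= 1.0:
            raise ValueError("joe requires eta >= 1 (eta = 1 is independence)")

    def _logs(self, u, v):
        # carry 1-a, 1-b and log t = log(1 - (1-a)(1-b)) in stable form;
        # t itself underflows to 1.0 in double when u, v are both near 0
        x, y = 1.0 - u, 1.0 - v
        la, lb = self.eta * np.log(x), self.eta * np.log(y)
        one_m_a, one_m_b = -np.expm1(la), -np.expm1(lb)
        p = one_m_a * one_m_b  # 1 - t
        with np.errstate(divide="ignore"):  # p -> 1 only at clamped corners
            log_t = np.log1p(-p)
        return x, y, one_m_a, one_m_b, p, log_t

    def logcdf(self, u, v):
        *_, log_t = self._logs(u, v)
        # C = 1 - t^(1/eta) = -expm1(log t / eta), stable when C is tiny
        return np.log(-np.expm1(log_t / self.eta))

    def log_partial_u(self, u, v):
        x, y, one_m_a, one_m_b, p, log_t = self._logs(u, v)
        e = self.eta
        return (e - 1.0) * np.log(x) + np.log(one_m_b) + (1.0 / e - 1.0) * log_t

    def logpdf(self, u, v):
        x, y, one_m_a, one_m_b, p, log_t = self._logs(u, v)
        e = self.eta
        bracket = (e - 1.0) * p + e * (1.0 - p)
        return ((e - 1.0) * (np.log(x) + np.log(y))
                + (1.0 / e - 2.0) * log_t + np.log(bracket))

    def tau(self):
        return _joe_tau(self.eta)


def _joe_tau(eta: float, tol: float = 1e-12) -> float:
    """Joe tau = 1 - 4 sum_{k>=1} 1 / [k (eta k + 2)(eta (k-1) + 2)].

    The series is truncated once a term drops below ``tol``; at eta = 1 it
    telescopes to 1/4, giving tau = 0 (the independence limit).
    """
    if eta == 1.0:
        return 0.0
    total = 0.0
    k = 1
    while True:
        term = 1.0 / (k * (eta * k + 2.0) * (eta * (k - 1.0) + 2.0))
        total += term
        if term < tol:
            break
        k += 1
        if k > 10_000_000:  # pragma: no cover - safety valve
            break
    return 1.0 - 4.0 * total


FAMILIES = {
    "clayton": ClaytonCopula,
    "gumbel": GumbelCopula,
    "joe": JoeCopula,
}


def get_copula(family: str, eta: float) -> ArchimedeanCopula:
    """Construct a copula by its lowercase family name."""
    try:
        cls = FAMILIES[family.lower()]
    except KeyError:
        raise ValueError(
            f"unknown copula family {family!r}; choose from {sorted(FAMILIES)}"
        ) from None
    return cls(eta)


def tau_from_eta(family: str, eta: float) -> float:
    """Kendall's tau implied by the dependence parameter eta."""
    return get_copula(family, eta).tau()


def eta_from_tau(family: str, tau: float) -> float:
    """Dependence parameter eta implied by Kendall's tau (inverse map)."""
    family = family.lower()
    if family == "clayton":
        if not 0.0 < tau < 1.0:
            raise ValueError("clayton requires tau in (0, 1)")
        return 2.0 * tau / (1.0 - tau)
    if family == "gumbel":
        if not 0.0 <= tau < 1.0:
            raise ValueError("gumbel requires tau in [0, 1)")
        return 1.0 / (1.0 - tau)
    if family == "joe":
        if not 0.0 <= tau < 1.0:
            raise ValueError("joe requires tau in [0, 1)")
        if tau == 0.0:
            return 1.0
        lo, hi = 1.0, 2.0
        while _joe_tau(hi) < tau:
            hi *= 2.0
            if hi > 1e6:  # pragma: no cover
                raise ValueError("tau too close to 1 for the Joe family")
        return brentq(lambda e: _joe_tau(e) - tau, lo, hi, xtol=1e-12)
    raise ValueError(f"unknown copula family {family!r}; choose from {sorted(FAMILIES)}")
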