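"""Graphical-adequacy diagnostics: linearization plots and copula scatter.

Marginal adequacy is checked by transforming the Kaplan–Meier estimate so
that the candidate baseline family becomes a straight line:

* Weibull:       log cumulative hazard vs log time (slope = shape a)
* Gompertz:      log hazard vs time (slope = shape gamma), with the
  hazard estimated from a life table over the observed range
* log-logistic:  log failure odds vs log time (slope = shape a)

Copula adequacy is checked visually by overlaying pairs simulated from
the fitted copula on the observed pseudo-observations
(S1_hat(y1), S2_hat(y2)); a condensed overlap — summarized here by the
agreement of the two empirical Kendall's taus — indicates the family fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import kendalltau

from . import margins as mg
from .copulas import get_copula

__all__ = ["KMEstimate", "DiagnosticSeries", "ScatterDiagnostic",
           "km_survival", "linearization_coords", "copula_scatter"]


@dataclass
class KMEstimate:
    """Product-limit survival estimate evaluated after each event time."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S_hat just after each event time
    n_events: int

    def __call__(self, t):
        """Step-function evaluation of S_hat(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return out if out.shape else float(out)


def km_survival(times, indicators) -> KMEstimate:
    """Kaplan–Meier estimator of the marginal survival function.

    S_hat(0) = 1, nonincreasing, dropping only at event times.  With no
    events the estimate is flat at 1 (a warning is emitted).
    """
    times = np.asarray(times, dtype=float)
    indicators = np.asarray(indicators)
    if np.any(times <= 0):
        raise ValueError("times must be positive")
    n_events = int(np.sum(indicators))
    if n_events == 0:
        warnings.warn("no events: Kaplan-Meier estimate is identically 1",
                      RuntimeWarning)
        return KMEstimate(np.array([]), np.array([]), 0)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=indicators)
    sf = kmf.survival_function_
    event_times = np.unique(times[np.asarray(indicators, dtype=bool)])
    s_after = sf.loc[event_times].to_numpy().ravel()
    return KMEstimate(event_times, s_after, n_events)


@dataclass
class DiagnosticSeries:
    """One linearization series: (x, y) coordinates plus a straightness score."""

    label: str
    x: np.ndarray
    y: np.ndarray
    straightness: float      # squared Pearson correlation of (x, y)
    slope: float
    intercept: float
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.label, "x": self.x, "y": self.y})


def _fit_line(x, y):
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return float(slope), float(intercept), float(r * r)


def linearization_coords(family: str, times, indicators,
                         intervals: int = 10) -> DiagnosticSeries:
    """Coordinates of the straight-line adequacy plot for one baseline family.

    ``intervals`` controls the life-table resolution of the Gompertz
    hazard estimate; the Weibull and log-logistic transforms act directly
    on the Kaplan–Meier estimate at event times.  Points whose transform
    is undefined (S_hat at 0 or 1) are dropped and counted.
    """
    times = np.asarray(times, dtype=float)
    indicators = np.asarray(indicators)
    if family not in mg.MARGIN_FAMILIES:
        raise ValueError(f"unknown margin family {family!r}")

    if family == "gompertz":
        x, y, dropped = _life_table_hazard(times, indicators, intervals)
    else:
        km = km_survival(times, indicators)
        s = km.survival
        keep = (s > 0.0) & (s < 1.0)
        dropped = int(np.sum(~keep))
        t, s = km.times[keep], s[keep]
        if family == "weibull":
            x, y = np.log(t), np.log(-np.log(s))
        else:  # loglogistic: log failure odds vs log time
            x, y = np.log(t), np.log((1.0 - s) / s)
    if len(x) < 3:
        raise ValueError(
            f"fewer than 3 usable points for the {family} linearization")
    slope, intercept, r2 = _fit_line(x, y)
    return DiagnosticSeries(family, x, y, r2, slope, intercept, dropped)


def _life_table_hazard(times, indicators, intervals):
    """Discrete hazard d_i / (n_i * width) on equal-width intervals; log vs midpoint."""
    lo, hi = float(np.min(times)), float(np.max(times))
    edges = np.linspace(lo, hi, intervals + 1)
    width = edges[1] - edges[0]
    ind = np.asarray(indicators, dtype=bool)
    xs, ys = [], []
    dropped = 0
    for a, b in zip(edges[:-1], edges[1:]):
        at_risk = np.sum(times >= a)
        events = np.sum(ind & (times >= a) & (times < b))
        if b == edges[-1]:
            events = np.sum(ind & (times >= a) & (times <= b))
        if at_risk == 0 or events == 0:
            dropped += 1
            continue
        haz = events / (at_risk * width)
        xs.append(0.5 * (a + b))
        ys.append(np.log(haz))
    return np.asarray(xs), np.asarray(ys), dropped


@dataclass
class ScatterDiagnostic:
    """Simulated copula pairs vs observed pseudo-observations."""

    simulated: np.ndarray          # (n_sim, 2) pairs from the fitted copula
    observed: np.ndarray           # (n, 2) pseudo-observations
    tau_simulated: float
    tau_observed: float
    family: str = ""
    eta: float = field(default=np.nan)

    def to_frame(self) -> pd.DataFrame:
        sim = pd.DataFrame(self.simulated, columns=["u", "v"])
        sim["source"] = "simulated"
        obs = pd.DataFrame(self.observed, columns=["u", "v"])
        obs["source"] = "observed"
        return pd.concat([sim, obs], ignore_index=True)


def copula_scatter(results, n_sim: int = 5000, seed: int = 0,
                   pseudo: str = "parametric") -> ScatterDiagnostic:
    """Scatter diagnostic for the fitted copula family.

    Pairs are simulated by conditional inversion at the fitted eta;
    observed pseudo-observations are the marginal survival probabilities
    at each subject's observed times — from the fitted parametric margins
    (default, consistent with checking the copula given accepted margins)
    or, with ``pseudo="nonparametric"``, from the covariate-free
    Kaplan-Meier estimates.  The empirical Kendall's tau of both clouds
    is reported; output is deterministic under a fixed seed.
    """
    model = results.model
    cop = get_copula(model.copula_family, results.eta)
    rng = np.random.default_rng(seed)
    sim = cop.sample(n_sim, rng)

    if pseudo == "parametric":
        p = results.params
        m1 = mg.MarginSpec(model.margin_family, p["shape1"], p["scale1"])
        m2 = mg.MarginSpec(model.margin_family, p["shape2"], p["scale2"])
        lp = model.exog @ results.beta.to_numpy()
        u_obs = np.exp(mg.log_survival(m1, lp, model.y1))
        v_obs = np.exp(mg.log_survival(m2, lp, model.y2))
    elif pseudo == "nonparametric":
        u_obs = km_survival(model.y1, model.d1)(model.y1)
        v_obs = km_survival(model.y2, model.d2)(model.y2)
    else:
        raise ValueError("pseudo must be 'parametric' or 'nonparametric'")
    obs = np.column_stack([u_obs, v_obs])

    tau_sim = float(kendalltau(sim[:, 0], sim[:, 1]).statistic)
    tau_obs = float(kendalltau(u_obs, v_obs).statistic)
    return ScatterDiagnostic(sim, obs, tau_sim, tau_obs,
                             family=model.copula_family, eta=results.eta)


def plot_linearization(series_list, path=None):  # pragma: no cover - thin layer
    """Render linearization panels (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(series_list), figsize=(4 * len(series_list), 3.5))
    axes = np.atleast_1d(axes)
    for ax, s in zip(axes, series_list):
        ax.plot(s.x, s.y, "o", ms=3)
        xs = np.array([s.x.min(), s.x.max()])
        ax.plot(xs, s.intercept + s.slope * xs, "-")
        ax.set_title(f"{s.label} (r2={s.straightness:.3f})")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_scatter(diag: ScatterDiagnostic, path=None):  # pragma: no cover - thin layer
    """Render the copula scatter overlay (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(diag.simulated[:, 0], diag.simulated[:, 1], ".", ms=2, alpha=0.3,
            label=f"simulated (tau={diag.tau_simulated:.2f})")
    ax.plot(diag.observed[:, 0], diag.observed[:, 1], "o", ms=4, alpha=0.7,
            label=f"observed (tau={diag.tau_observed:.2f})")
    ax.set_xlabel("u = S1(y1)")
    ax.set_ylabel("v = S2(y2)")
    ax.legend()
    ax.set_title(f"{diag.family} copula, eta={diag.eta:.2f}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
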