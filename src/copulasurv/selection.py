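"""Model selection: information criteria, the 3x3 family grid, covariate screening.

The analysis fits every combination of marginal baseline family
(Weibull, Gompertz, log-logistic) with every Archimedean copula family
(Clayton, Gumbel, Joe) and ranks the nine models by AIC, with BIC and
the final joint log-likelihood as tie-breakers.  Before the multivariable
fit, covariates are screened one at a time and kept when their Wald P
value falls below a permissive threshold (0.25 by convention).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .margins import MARGIN_FAMILIES
from .copulas import FAMILIES as COPULA_FAMILIES
from .model import CopulaSurvivalModel

__all__ = ["information_criteria", "compare_grid", "select_best",
           "screen_univariable"]


def information_criteria(llk: float, K: int, n: int):
    """AIC = -2 llk + 2K and BIC = -2 llk + K ln n.

    K is the number of estimated parameters counted by the criterion and
    n the number of subjects.
    """
    if not K >= 1:
        raise ValueError("K must be a positive integer")
    if not n >= 1:
        raise ValueError("n must be a positive integer")
    aic = -2.0 * llk + 2.0 * K
    bic = -2.0 * llk + K * np.log(n)
    return float(aic), float(bic)


def compare_grid(df: pd.DataFrame, covariates, margins=MARGIN_FAMILIES,
                 copulas=tuple(sorted(COPULA_FAMILIES)), compute_se: bool = False,
                 ic_param_count: str = "regression_plus_copula") -> pd.DataFrame:
    """Fit every (margin family, copula family) combination and tabulate.

    The stage-1 (independence) margin fit depends only on the margin
    family, so it is computed once per margin family and shared by the
    three copulas.  A failed fit is recorded in its row (NaN criteria,
    ``converged=False``); the grid is still returned in full.

    Returns a DataFrame with one row per combination: margin, copula,
    aic, bic, loglik, tau, K, n, converged — sorted in grid order.
    """
    rows = []
    for margin in margins:
        stage1 = None
        try:
            probe = CopulaSurvivalModel.from_dataframe(
                df, covariates=covariates, margin=margin, copula=copulas[0],
                ic_param_count=ic_param_count)
            stage1, _ = probe.fit_margins_independent()
        except Exception as exc:  # stage-1 failure poisons the margin row block
            warnings.warn(f"stage-1 fit failed for margin {margin!r}: {exc}",
                          RuntimeWarning)
        for copula in copulas:
            row = {"margin": margin, "copula": copula, "aic": np.nan,
                   "bic": np.nan, "loglik": np.nan, "tau": np.nan,
                   "K": np.nan, "n": len(df), "converged": False}
            if stage1 is not None:
                try:
                    model = CopulaSurvivalModel.from_dataframe(
                        df, covariates=covariates, margin=margin, copula=copula,
                        ic_param_count=ic_param_count)
                    res = model.fit(compute_se=compute_se, stage1=stage1)
                    row.update(aic=res.aic, bic=res.bic, loglik=res.llf,
                               tau=res.tau, K=res.k_ic,
                               converged=bool(res.converged))
                except Exception as exc:
                    warnings.warn(
                        f"fit failed for ({margin}, {copula}): {exc}", RuntimeWarning)
            rows.append(row)
    return pd.DataFrame(rows)


def select_best(grid: pd.DataFrame) -> pd.Series:
    """Row with the lowest AIC; ties broken by BIC, then by log-likelihood."""
    ok = grid.dropna(subset=["aic"])
    if ok.empty:
        raise ValueError("no successful fit in the comparison grid")
    ok = ok.sort_values(["aic", "bic", "loglik"],
                        ascending=[True, True, False], kind="mergesort")
    return ok.iloc[0]


def screen_univariable(df: pd.DataFrame, covariates, margin: str = "loglogistic",
                       copula: str = "clayton", alpha: float = 0.25) -> pd.DataFrame:
    """Univariable screen: joint model with one covariate at a time.

    Each covariate is fitted alone; those with Wald P < ``alpha`` are
    flagged ``retained``.  Covariates constant in the data are excluded
    with a warning rather than aborting the screen.
    """
    rows = []
    for cov in covariates:
        x = df[cov].to_numpy()
        if np.all(x == x[0]):
            warnings.warn(f"covariate {cov!r} is constant; excluded from the screen",
                          RuntimeWarning)
            rows.append({"covariate": cov, "estimate": np.nan, "se": np.nan,
                         "p_value": np.nan, "retained": False,
                         "note": "constant"})
            continue
        try:
            model = CopulaSurvivalModel.from_dataframe(
                df, covariates=[cov], margin=margin, copula=copula)
            res = model.fit()
            row = res.wald_table().loc[cov]
            p = float(row["p_value"])
            rows.append({"covariate": cov, "estimate": float(row["estimate"]),
                         "se": float(row["se"]), "p_value": p,
                         "retained": bool(p < alpha), "note": ""})
        except Exception as exc:
            warnings.warn(f"univariable fit failed for {cov!r}: {exc}",
                          RuntimeWarning)
            rows.append({"covariate": cov, "estimate": np.nan, "se": np.nan,
                         "p_value": np.nan, "retained": False, "note": "failed"})
    return pd.DataFrame(rows).set_index("covariate")
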