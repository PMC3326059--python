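"""Latitude regressions, Studentized-residual outlier screening and delta-delta-Ct.

A cline is modelled as ordinary least squares of a population-level value
(relative expression or allele frequency) on latitude in signed degrees.
Outliers are screened with externally Studentized residuals (leave-one-out
variance, t distribution with n-3 df) under a Bonferroni correction over the
n points — the standard single-outlier regression test. qPCR tables are
reduced to relative expression with the conventional delta-delta-Ct method
assuming amplification efficiency exactly 2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    n: int
    residuals: np.ndarray
    table: pd.DataFrame
    model: object  # fitted statsmodels results


def latitude_regression(table: pd.DataFrame, value_col: str = "value",
                        latitude_col: str = "latitude") -> RegressionResult:
    """OLS of value on latitude; slope p-value from t with n-2 df."""
    if len(table) < 3:
        raise ValueError("need >= 3 populations")
    lat = table[latitude_col].to_numpy(dtype=float)
    if np.var(lat) == 0:
        raise ValueError("zero latitude variance")
    y = table[value_col].to_numpy(dtype=float)
    X = sm.add_constant(lat)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]), intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared), p_slope=float(fit.pvalues[1]),
        n=len(table), residuals=np.asarray(fit.resid), table=table.reset_index(drop=True),
        model=fit,
    )


def studentized_outliers(result: RegressionResult,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Externally Studentized residuals with Bonferroni-adjusted p-values.

    Returns a per-point table ``student_resid, unadj_p, bonf_p, flagged``
    (plus the population id when present). Points with leverage 1 have an
    undefined residual and are flagged ``degenerate``.
    """
    if result.n < 4:
        raise ValueError("need >= 4 points for the outlier test")
    influence = OLSInfluence(result.model)
    resid = influence.resid_studentized_external
    test = np.asarray(result.model.outlier_test(method="bonf"))
    out = pd.DataFrame(
        {"student_resid": np.asarray(resid),
         "unadj_p": test[:, 1],
         "bonf_p": np.minimum(test[:, 2], 1.0)}
    )
    leverage = np.asarray(influence.hat_matrix_diag)
    out["degenerate"] = ~np.isfinite(out["student_resid"]) | (leverage >= 1.0 - 1e-12)
    out["flagged"] = (out["bonf_p"] < alpha) & ~out["degenerate"]
    if "population_id" in result.table.columns:
        out.insert(0, "population_id", result.table["population_id"].to_numpy())
    return out


def refit_excluding(table: pd.DataFrame, excluded: Iterable[str],
                    value_col: str = "value", latitude_col: str = "latitude",
                    id_col: str = "population_id") -> RegressionResult:
    """Re-run the latitude regression with the listed populations removed."""
    excluded = set(excluded)
    kept = table[~table[id_col].isin(excluded)]
    if len(kept) < 3:
        raise ValueError("fewer than 3 populations remain after exclusion")
    return latitude_regression(kept, value_col=value_col, latitude_col=latitude_col)


def relative_expression_ddct(ct: pd.DataFrame) -> pd.DataFrame:
    """Conventional delta-delta-Ct relative expression.

    ``ct`` needs columns ``sample_id, ct_target, ct_reference, calibrator``
    (boolean; at least one calibrator sample). Per sample,
    dCt = ct_target - ct_reference, ddCt = dCt - mean(dCt over calibrators),
    relative expression = 2**(-ddCt).
    """
    required = {"sample_id", "ct_target", "ct_reference", "calibrator"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if ct[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("missing Ct values")
    if (ct[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    if not ct["calibrator"].any():
        raise ValueError("no calibrator sample present")
    dct = ct["ct_target"].to_numpy(dtype=float) - ct["ct_reference"].to_numpy(dtype=float)
    ddct = dct - dct[ct["calibrator"].to_numpy(dtype=bool)].mean()
    return pd.DataFrame(
        {"sample_id": ct["sample_id"].to_numpy(), "delta_ct": dct,
         "delta_delta_ct": ddct, "relative_expression": np.power(2.0, -ddct)}
    )


def cline_report(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Fit, screen for outliers, and refit excluding flagged populations.

    Returns a JSON-serializable dict with the full fit, the outlier table and
    (when any point is flagged) the refit without the flagged populations.
    """
    fit = latitude_regression(table)
    outliers = studentized_outliers(fit, alpha=alpha)
    report = {
        "n": fit.n,
        "slope": fit.slope, "intercept": fit.intercept,
        "r_squared": fit.r_squared, "p_slope": fit.p_slope,
        "outliers": outliers.to_dict(orient="records"),
    }
    flagged = list(outliers.loc[outliers["flagged"], "population_id"]) \
        if "population_id" in outliers.columns else []
    if flagged:
        refit = refit_excluding(table, flagged)
        report["excluded"] = flagged
        report["refit"] = {
            "n": refit.n, "slope": refit.slope, "intercept": refit.intercept,
            "r_squared": refit.r_squared, "p_slope": refit.p_slope,
        }
    return report
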