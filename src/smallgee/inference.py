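"""Wald inference: z tests, odds ratios, confidence intervals, method grids.

Inference is on the standard-normal reference: z = estimate/SE, two-sided
p = 2(1 - Phi(|z|)), OR = exp(estimate) and CI = exp(estimate +/- z_{a/2} SE).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .bcgee import fit_bcgee
from .covariance import METHODS, CovarianceResult, estimate_covariance
from .data_model import DesignData
from .errors import SmallGeeError
from .gee import GEEFit, fit_gee
from .pgee import fit_pgee

__all__ = ["summarize", "all_combinations", "BETA_METHODS"]

BETA_METHODS = ("GEE", "BCGEE", "PGEE")

_FITTERS = {"GEE": fit_gee, "BCGEE": fit_bcgee, "PGEE": fit_pgee}

COEF_COLUMNS = ["term", "estimate", "se", "z", "p_value"]
OR_COLUMNS = ["term", "odds_ratio", "ci_lower", "ci_upper"]


def summarize(
    fit: GEEFit, cov: CovarianceResult, conf_level: float = 0.95
) -> pd.DataFrame:
    """Coefficient table with Wald tests and odds-ratio confidence intervals."""
    if not (0.0 < conf_level < 1.0):
        raise ValueError(f"conf_level must be in (0, 1); got {conf_level}")
    zq = norm.ppf(0.5 + conf_level / 2.0)
    est = fit.beta
    se = cov.se
    with np.errstate(invalid="ignore", divide="ignore"):
        z = est / se
        pval = 2.0 * norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "term": fit.column_names,
            "estimate": est,
            "se": se,
            "z": z,
            "p_value": pval,
            "odds_ratio": np.exp(est),
            "ci_lower": np.exp(est - zq * se),
            "ci_upper": np.exp(est + zq * se),
        }
    )
    table.attrs.update(
        beta_method=fit.method_tag,
        se_method=cov.method,
        corstr=fit.corr.kind,
        K=fit.n_clusters,
        max_ni=fit.max_ni,
        conf_level=conf_level,
        converged=fit.converged,
        scale=fit.phi,
        iterations=fit.iterations,
    )
    return table


def all_combinations(
    design: DesignData,
    corstr: str = "independence",
    conf_level: float = 0.95,
    maxitr: int = 50,
    tol: float = 1e-5,
    scale_fix: bool = False,
):
    """Fit every estimating method and apply every covariance estimator.

    Each of the three estimating methods is fitted once and reused across its
    12 covariance estimators (36 combinations per coefficient).  Per-combination
    failures are recorded in the ``status`` column without aborting the grid.

    Returns
    -------
    (coef_table, or_table) : two DataFrames.  The first holds coefficients,
    standard errors, z statistics and p-values; the second odds ratios with
    confidence limits.
    """
    coef_rows, or_rows = [], []
    for bm in BETA_METHODS:
        fit = None
        fit_err = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = _FITTERS[bm](
                    design, corstr=corstr, maxitr=maxitr, tol=tol, scale_fix=scale_fix
                )
            except SmallGeeError as exc:
                fit_err = str(exc)
        for sm in METHODS:
            if fit is None:
                for name in design.column_names:
                    base = dict(beta_method=bm, se_method=sm, term=name,
                                status=f"failed: {fit_err}")
                    coef_rows.append(base | dict.fromkeys(
                        ("estimate", "se", "z", "p_value"), np.nan))
                    or_rows.append(base | dict.fromkeys(
                        ("odds_ratio", "ci_lower", "ci_upper"), np.nan))
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cov = estimate_covariance(fit, sm)
                tab = summarize(fit, cov, conf_level)
                status = "ok" if fit.converged else "not converged"
            except SmallGeeError as exc:
                for name in design.column_names:
                    base = dict(beta_method=bm, se_method=sm, term=name,
                                status=f"failed: {exc}")
                    coef_rows.append(base | dict.fromkeys(
                        ("estimate", "se", "z", "p_value"), np.nan))
                    or_rows.append(base | dict.fromkeys(
                        ("odds_ratio", "ci_lower", "ci_upper"), np.nan))
                continue
            for _, row in tab.iterrows():
                base = dict(beta_method=bm, se_method=sm, term=row["term"], status=status)
                coef_rows.append(base | {k: row[k] for k in ("estimate", "se", "z", "p_value")})
                or_rows.append(base | {k: row[k] for k in ("odds_ratio", "ci_lower", "ci_upper")})
    coef_table = pd.DataFrame(coef_rows)
    or_table = pd.DataFrame(or_rows)
    for t in (coef_table, or_table):
        t.attrs.update(corstr=corstr, conf_level=conf_level)
    return coef_table, or_table
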