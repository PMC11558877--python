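"""Bias-corrected GEE (one-step second-order bias subtraction).

M-estimators carry an O(1/K) bias expressible through cumulants of the
estimating function U and its derivatives:

    kappa_rs    = E[dU_r/dbeta_s]             kappa_r,s  = E[U_r U_s]
    kappa_rsu   = E[d2U_r/dbeta_s dbeta_u]    kappa_rs,u = E[(dU_r/dbeta_s) U_u]
    kappa_rs(u) = d kappa_rs / dbeta_u

    b_r = sum_s k^{rs} sum_{u,v} [ kappa_su,v
            - 1/2 sum_{k,l} k^{kl} kappa_svl kappa_u,k ] k^{uv},

with k^{rs} the inverse of [kappa_rs].  The corrected estimate is
beta_BC = beta_hat - b, applied once (no re-iteration).  The mixed cumulants
kappa_r,s / kappa_rs,u are evaluated empirically from per-cluster residual
products, so the correction stays valid when the working correlation
structure is misspecified; the purely model-based pieces replace Y by mu-hat
(under which kappa_rs = -Phi for the canonical logit link).

Closed forms per cluster (W = V^{-1}, c_s = a' * x_s, C_s = diag(c_s)):

    centered dU/dbeta_s = T_s eps,  T_s = 1/2 X'(C_s W - A W C_s A^{-1})
    kappa_rsu = sum_i [ -T_s (a * x_u) - (dPhi/dbeta_u)[:, s] ]_r
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import DesignData
from .errors import CovarianceWarning, NumericalError
from .gee import GEEFit, fit_gee, score_and_information
from .pgee import information_derivatives
from .working_correlation import CorrelationModel

__all__ = ["CumulantSet", "compute_cumulants", "bias_vector", "fit_bcgee"]


@dataclass
class CumulantSet:
    """Cumulant arrays of the estimating function at the fitted coefficients."""

    k_rs: np.ndarray      # p x p, model-based E[dU_r/dbeta_s] (= -Phi)
    k_r_s: np.ndarray     # p x p, empirical E[U_r U_s]
    k_rsu: np.ndarray     # p x p x p, model-based E[d2U_r/dbeta_s dbeta_u]
    k_rs_u: np.ndarray    # p x p x p, empirical E[(dU_r/dbeta_s) U_u], centered
    k_rs_du: np.ndarray   # p x p x p, d kappa_rs / dbeta_u (retained, unused in b)
    k_inv: np.ndarray     # inverse of k_rs


def _apply_T(q, X, s: int, v: np.ndarray) -> np.ndarray:
    """T_s v = 1/2 X'(c_s*(Wv) - a*(W(c_s/a * v))) for one cluster."""
    c = q.aprime * X[:, s]
    Wv = q.Vinv @ v
    inner = c * Wv - q.a * (q.Vinv @ (c / q.a * v))
    return 0.5 * (X.T @ inner)


def compute_cumulants(fit: GEEFit) -> CumulantSet:
    """Evaluate all cumulant arrays at beta-hat with alpha-hat, phi-hat fixed."""
    p = fit.p
    beta = fit.beta
    corr = fit.corr
    U_vec, Phi, quants = score_and_information(beta, fit.blocks, corr)
    pen = information_derivatives(beta, fit.blocks, corr)  # reuses dPhi closed form

    k_rs = -Phi
    k_r_s = np.zeros((p, p))
    k_rsu = np.zeros((p, p, p))
    k_rs_u = np.zeros((p, p, p))

    for block, q in zip(fit.blocks, quants):
        X = block.X
        U_i = q.D.T @ (q.Vinv @ q.eps)
        k_r_s += np.outer(U_i, U_i)
        for s in range(p):
            Ts_eps = _apply_T(q, X, s, q.eps)
            # centered dU_r/dbeta_s times U_u
            k_rs_u[:, s, :] += np.outer(Ts_eps, U_i)
            for u in range(p):
                k_rsu[:, s, u] += -_apply_T(q, X, s, q.a * X[:, u])
    for u in range(p):
        k_rsu[:, :, u] -= pen.dPhi[u]  # the -(dPhi/dbeta_u)[:, s] term, all s at once

    k_rs_du = np.stack([-dp for dp in pen.dPhi], axis=2)  # d(-Phi)/dbeta_u

    try:
        k_inv = np.linalg.inv(k_rs)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("[kappa_rs] is singular; bias not computable") from exc
    if not np.all(np.isfinite(k_rsu)) or not np.all(np.isfinite(k_rs_u)):
        raise NumericalError("non-finite cumulant entries; bias not computable")
    return CumulantSet(
        k_rs=k_rs, k_r_s=k_r_s, k_rsu=k_rsu, k_rs_u=k_rs_u,
        k_rs_du=k_rs_du, k_inv=k_inv,
    )


def bias_vector(cum: CumulantSet) -> np.ndarray:
    """Second-order bias b of the estimating-equation solution."""
    inner = cum.k_rs_u - 0.5 * np.einsum(
        "kl,svl,uk->suv", cum.k_inv, cum.k_rsu, cum.k_r_s
    )
    return np.einsum("rs,suv,uv->r", cum.k_inv, inner, cum.k_inv)


def fit_bcgee(
    design: DesignData,
    corstr: str = "independence",
    init: np.ndarray | None = None,
    maxitr: int = 50,
    tol: float = 1e-5,
    scale_fix: bool = False,
) -> GEEFit:
    """Conventional GEE fit followed by one-step bias subtraction.

    After subtracting b, all per-cluster quantities, the information matrix
    and the nuisance parameters are re-evaluated at the corrected
    coefficients so downstream covariance estimators use them consistently.
    If the bias cannot be computed the uncorrected fit is returned with a
    warning.
    """
    fit = fit_gee(design, corstr=corstr, init=init, maxitr=maxitr, tol=tol,
                  scale_fix=scale_fix)
    try:
        cum = compute_cumulants(fit)
        b = bias_vector(cum)
    except NumericalError as exc:
        warnings.warn(
            f"bias correction failed ({exc}); returning uncorrected estimate",
            CovarianceWarning,
            stacklevel=2,
        )
        fit.method_tag = "BCGEE"
        return fit

    beta_bc = fit.beta - b
    corr = fit.corr
    # refresh nuisance parameters and cluster quantities at the corrected beta
    from .gee import _refresh_nuisance  # shared cycle

    U, Phi, quants = score_and_information(beta_bc, fit.blocks, corr)
    _refresh_nuisance(fit.p, fit.blocks, quants, corr)
    U, Phi, quants = score_and_information(beta_bc, fit.blocks, corr)
    return GEEFit(
        beta=beta_bc,
        corr=corr,
        info=Phi,
        cluster_quantities=quants,
        blocks=fit.blocks,
        column_names=fit.column_names,
        iterations=fit.iterations,
        converged=fit.converged,
        method_tag="BCGEE",
        score=U,
        bias=b,
    )
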