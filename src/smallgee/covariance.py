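"""Sandwich covariance estimation with small-sample corrections.

The unadjusted ("SA") sandwich Phi^{-1} { sum_i D_i'V_i^{-1} e_i e_i' V_i^{-1}D_i } Phi^{-1}
is consistent but downward-biased when the number of clusters K is small.
Eleven corrections are implemented alongside it:

=====  =======================================================================
SA     unadjusted robust sandwich
MK     MacKinnon-White style inflation K/(K-p) * SA
KC     Kauermann-Carroll: residuals premultiplied by (I - H_ii)^{-1/2}
MD     Mancl-DeRouen: residuals premultiplied by (I - H_ii)^{-1}
FG     Fay-Graubard: bias factors F_i on the meat contributions
PA     Pan: residual covariance pooled across clusters
GS     Gosho et al.: K/(K-p) * PA
MB     Morel-Bokossa-Neerchal: Phi^{-1} {Psi + g1 g2 Phi} Phi^{-1}
WL     Wang-Long: pooled PA form with MD leverage adjustment
WB     Westgate-Burchett: pooled PA form with KC leverage adjustment
FW     Ford-Westgate: average of KC and MD
FZ     Fan et al.: MD-style bread minus cross-cluster leverage terms
=====  =======================================================================

H_ij = D_i Phi^{-1} D_j' V_j^{-1} is the cluster leverage.  All estimators are
evaluated at the fitted coefficients of whichever estimating method produced
the fit (conventional, bias-corrected or penalized), using that fit's own
residuals and nuisance parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import CovarianceWarning, NumericalError
from .gee import GEEFit

__all__ = ["METHODS", "CovarianceResult", "LeverageSet", "estimate_covariance", "leverage"]

METHODS = ("SA", "MK", "KC", "MD", "FG", "PA", "GS", "MB", "WL", "WB", "FW", "FZ")

DEFAULT_DELTA = 0.75  # Fay-Graubard bound on the per-element bias factor


@dataclass
class CovarianceResult:
    """p x p covariance of the coefficient estimates under a named estimator."""

    method: str
    covb: np.ndarray
    se: np.ndarray


@dataclass
class LeverageSet:
    """Cluster leverage matrices H_ij = D_i Phi^{-1} D_j' V_j^{-1}."""

    H: dict
    n_clusters: int


def leverage(fit: GEEFit, pairs: str = "diagonal") -> LeverageSet:
    """Compute cluster leverages; ``pairs='all'`` fills the full K x K grid."""
    Phi_inv = _phi_inv(fit)
    q = fit.cluster_quantities
    K = fit.n_clusters
    H = {}
    for i in range(K):
        H[(i, i)] = q[i].D @ Phi_inv @ q[i].D.T @ q[i].Vinv
    if pairs == "all":
        for i in range(K):
            for j in range(K):
                if i != j:
                    H[(i, j)] = q[i].D @ Phi_inv @ q[j].D.T @ q[j].Vinv
    elif pairs != "diagonal":
        raise ValueError("pairs must be 'all' or 'diagonal'")
    return LeverageSet(H=H, n_clusters=K)


def _phi_inv(fit: GEEFit) -> np.ndarray:
    try:
        return np.linalg.inv(fit.info)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("Fisher information is singular") from exc


def _inv_ImH(Hii: np.ndarray, cid) -> np.ndarray:
    ImH = np.eye(Hii.shape[0]) - Hii
    try:
        return np.linalg.inv(ImH)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"(I - H_ii) is singular for cluster {cid!r}") from exc


def _sqrtm_real(M: np.ndarray, cid) -> np.ndarray:
    """Principal square root; errors if a genuinely complex root appears."""
    S = scipy.linalg.sqrtm(M)
    if np.iscomplexobj(S):
        if np.max(np.abs(S.imag)) > 1e-8:
            raise NumericalError(
                f"matrix square root for cluster {cid!r} is not real"
            )
        S = S.real
    return S


def _pooled_outer(fit: GEEFit, adjust: str) -> np.ndarray:
    """T x T pooled matrix of (adjusted) standardized residual products.

    adjust: 'none' (Pan), 'inv' (Wang-Long), 'invsqrt' (Westgate-Burchett).
    With balanced clusters this is the plain 1/K average of the displays; with
    unequal occasion patterns each entry is averaged over the clusters
    actually observed at both occasions.
    """
    T = max(int(b.positions.max()) + 1 for b in fit.blocks)
    S = np.zeros((T, T))
    C = np.zeros((T, T))
    Phi_inv = _phi_inv(fit) if adjust != "none" else None
    for b, q in zip(fit.blocks, fit.cluster_quantities):
        e = q.eps
        if adjust != "none":
            Hii = q.D @ Phi_inv @ q.D.T @ q.Vinv
            M = _inv_ImH(Hii, b.cluster_id)
            if adjust == "invsqrt":
                M = _sqrtm_real(M, b.cluster_id)
            e = M @ e
        z = e / np.sqrt(q.a)
        ix = np.ix_(b.positions, b.positions)
        S[ix] += np.outer(z, z)
        C[ix] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(C > 0, S / np.maximum(C, 1), 0.0)
    return out


def _sandwich(Phi_inv: np.ndarray, meat: np.ndarray) -> np.ndarray:
    cov = Phi_inv @ meat @ Phi_inv
    return 0.5 * (cov + cov.T)


def estimate_covariance(
    fit: GEEFit, method: str = "MB", delta: float = DEFAULT_DELTA
) -> CovarianceResult:
    """Covariance of the fitted coefficients under a named estimator."""
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown SE method {method!r}; choose from {METHODS}")
    Phi = fit.info
    Phi_inv = _phi_inv(fit)
    q = fit.cluster_quantities
    blocks = fit.blocks
    K = fit.n_clusters
    p = fit.p
    d = [qq.D.T @ (qq.Vinv @ qq.eps) for qq in q]  # d_i = D'V^{-1}e

    if method in ("SA", "MK"):
        meat = sum(np.outer(di, di) for di in d)
        cov = _sandwich(Phi_inv, meat)
        if method == "MK":
            cov = K / (K - p) * cov
    elif method in ("KC", "MD", "FW", "FZ"):
        vs_kc, vs_md = [], []
        invs = []
        for b, qq in zip(blocks, q):
            Hii = qq.D @ Phi_inv @ qq.D.T @ qq.Vinv
            Minv = _inv_ImH(Hii, b.cluster_id)
            invs.append(Minv)
            VD = qq.Vinv @ qq.D  # (V^{-1} D), so D'V^{-1} x = VD.T @ x
            if method in ("KC", "FW"):
                G = _sqrtm_real(Minv, b.cluster_id)
                vs_kc.append(VD.T @ (G @ qq.eps))
            if method in ("MD", "FW", "FZ"):
                vs_md.append(VD.T @ (Minv @ qq.eps))
        if method == "KC":
            meat = sum(np.outer(v, v) for v in vs_kc)
            cov = _sandwich(Phi_inv, meat)
        elif method == "MD":
            meat = sum(np.outer(v, v) for v in vs_md)
            cov = _sandwich(Phi_inv, meat)
        elif method == "FW":
            kc = _sandwich(Phi_inv, sum(np.outer(v, v) for v in vs_kc))
            md = _sandwich(Phi_inv, sum(np.outer(v, v) for v in vs_md))
            cov = 0.5 * (kc + md)
        else:  # FZ
            # sum_{j != i} H_ij e_j e_j' H_ij' = D_i Phi^{-1} (S_d - d_i d_i') Phi^{-1} D_i'
            Sd = sum(np.outer(di, di) for di in d)
            meat = np.zeros((p, p))
            for i, (b, qq) in enumerate(zip(blocks, q)):
                core = Sd - np.outer(d[i], d[i])
                cross = qq.D @ Phi_inv @ core @ Phi_inv @ qq.D.T
                inner = np.outer(qq.eps, qq.eps) - cross
                B = qq.D.T @ qq.Vinv @ invs[i]
                meat += B @ inner @ B.T
            cov = _sandwich(Phi_inv, meat)
    elif method == "FG":
        meat = np.zeros((p, p))
        for qq, di in zip(q, d):
            N = qq.D.T @ qq.Vinv @ qq.D @ Phi_inv
            f = 1.0 / np.sqrt(1.0 - np.minimum(delta, np.diag(N)))
            v = f * di
            meat += np.outer(v, v)
        cov = _sandwich(Phi_inv, meat)
    elif method in ("PA", "GS", "WL", "WB"):
        adjust = {"PA": "none", "GS": "none", "WL": "inv", "WB": "invsqrt"}[method]
        Omega = _pooled_outer(fit, adjust)
        meat = np.zeros((p, p))
        for b, qq in zip(blocks, q):
            sub = Omega[np.ix_(b.positions, b.positions)]
            sq = np.sqrt(qq.a)
            # D'V^{-1} A^{1/2} Omega A^{1/2} V^{-1} D
            C = qq.D.T @ (qq.Vinv * sq[None, :])
            meat += C @ sub @ C.T
        cov = _sandwich(Phi_inv, meat)
        if method == "GS":
            cov = K / (K - p) * cov
    elif method == "MB":
        dbar = sum(d) / K
        n_tot = fit.n_obs
        Psi = sum(np.outer(di - dbar, di - dbar) for di in d)
        Psi *= (n_tot - 1) / (n_tot - p) * K / (K - 1)
        g1 = min(0.5, p / (K - p))
        g2 = max(1.0, np.trace(Phi_inv @ Psi) / p)
        cov = _sandwich(Phi_inv, Psi + g1 * g2 * Phi)
    else:  # pragma: no cover
        raise AssertionError(method)

    diag = np.diag(cov).copy()
    if (diag < 0).any():
        warnings.warn(
            f"{method} covariance has negative diagonal entries; the affected "
            "standard errors are reported as NaN",
            CovarianceWarning,
            stacklevel=2,
        )
        diag = np.where(diag < 0, np.nan, diag)
    se = np.sqrt(diag)
    return CovarianceResult(method=method, covb=cov, se=se)
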