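"""Estimating-equation engine for marginal logistic models.

The conventional GEE estimate solves

    U(beta) = sum_i D_i' V_i^{-1} (Y_i - mu_i) = 0,

with D_i = d mu_i / d beta' and working covariance
V_i = phi A_i^{1/2} R_i(alpha) A_i^{1/2}, A_i = diag(mu(1-mu)).  The solver is
Fisher scoring, beta <- beta + Phi^{-1} U with Phi = sum_i D_i' V_i^{-1} D_i,
interleaved with moment updates of phi and alpha after each beta step.  The
same loop also solves the Firth-type penalized equation (see :mod:`.pgee`)
when a penalty callback is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .data_model import ClusterBlock, DesignData
from .errors import (
    ConvergenceWarning,
    NumericalError,
    SeparationWarning,
    SingularDesignError,
)
from .working_correlation import (
    CorrelationModel,
    build_matrix,
    estimate_alpha,
    estimate_scale,
)

__all__ = [
    "ClusterQuantities",
    "GEEFit",
    "link_inverse_and_derivatives",
    "score_and_information",
    "fit_gee",
    "logistic_mle",
    "firth_logistic",
]

_ETA_CLIP = 30.0  # linear predictors beyond this are saturated anyway
_BETA_SEP = 50.0  # surveillance threshold for separation drift


def link_inverse_and_derivatives(eta: np.ndarray):
    """Logit-link inverse mu(eta) and its first three derivatives.

    mu   = expit(eta)
    mu'  = mu(1-mu)          (= variance function v(mu) for Bernoulli)
    mu'' = mu(1-mu)(1-2mu)
    mu'''= mu(1-mu)(1-6mu+6mu^2)

    Saturates smoothly for large |eta|; no overflow.
    """
    eta = np.asarray(eta, dtype=float)
    mu = expit(eta)
    a = mu * (1.0 - mu)
    d2 = a * (1.0 - 2.0 * mu)
    d3 = a * (1.0 - 6.0 * mu + 6.0 * mu * mu)
    return mu, a, d2, d3


@dataclass
class ClusterQuantities:
    """Per-cluster working quantities at the current coefficient value.

    A is kept as its diagonal vector ``a`` = mu(1-mu); D = A X for the logit
    link; Vinv = V_i^{-1}; eps = Y - mu.  ``aprime`` is the eta-derivative of
    ``a`` (needed by the penalized score and the bias cumulants) and ``Rinv``
    the inverse working correlation.
    """

    mu: np.ndarray
    a: np.ndarray
    aprime: np.ndarray
    D: np.ndarray
    Vinv: np.ndarray
    Rinv: np.ndarray
    eps: np.ndarray

    @property
    def pearson(self) -> np.ndarray:
        return self.eps / np.sqrt(self.a)


@dataclass
class GEEFit:
    """Converged (or stopped) estimating-equation fit."""

    beta: np.ndarray
    corr: CorrelationModel
    info: np.ndarray
    cluster_quantities: list[ClusterQuantities]
    blocks: list[ClusterBlock]
    column_names: list[str]
    iterations: int
    converged: bool
    method_tag: str = "GEE"
    score: np.ndarray | None = None
    bias: np.ndarray | None = None

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def n_clusters(self) -> int:
        return len(self.blocks)

    @property
    def phi(self) -> float:
        return self.corr.phi

    @property
    def alpha(self):
        return self.corr.alpha

    @property
    def n_obs(self) -> int:
        return int(sum(b.n for b in self.blocks))

    @property
    def max_ni(self) -> int:
        return int(max(b.n for b in self.blocks))

    @property
    def fitted_values(self) -> np.ndarray:
        return np.concatenate([q.mu for q in self.cluster_quantities])

    @property
    def residuals(self) -> np.ndarray:
        return np.concatenate([q.eps for q in self.cluster_quantities])

    @property
    def linear_predictors(self) -> np.ndarray:
        return np.concatenate([b.X @ self.beta for b in self.blocks])

    def working_correlation(self) -> np.ndarray:
        """Realized R(alpha-hat) for the largest observed occasion pattern."""
        widest = max(self.blocks, key=lambda b: b.n)
        return build_matrix(self.corr, widest.positions)


def _cluster_quantities(
    block: ClusterBlock, beta: np.ndarray, corr: CorrelationModel, rinv_cache: dict
) -> ClusterQuantities:
    eta = np.clip(block.X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu, a, d2, _ = link_inverse_and_derivatives(eta)
    key = tuple(block.positions.tolist())
    Rinv = rinv_cache.get(key)
    if Rinv is None:
        R = build_matrix(corr, block.positions)
        try:
            Rinv = np.linalg.inv(R)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"singular working correlation for cluster {block.cluster_id!r}"
            ) from exc
        rinv_cache[key] = Rinv
    sq = np.sqrt(a)
    Vinv = Rinv / np.outer(sq, sq) / corr.phi
    return ClusterQuantities(
        mu=mu, a=a, aprime=d2, D=a[:, None] * block.X, Vinv=Vinv, Rinv=Rinv,
        eps=block.y - mu,
    )


def score_and_information(
    beta: np.ndarray, blocks: list[ClusterBlock], corr: CorrelationModel
):
    """Estimating function U, Fisher information Phi, per-cluster quantities."""
    p = len(beta)
    U = np.zeros(p)
    Phi = np.zeros((p, p))
    quants = []
    cache: dict = {}
    for block in blocks:
        q = _cluster_quantities(block, beta, corr, cache)
        WD = q.Vinv @ q.D
        U += WD.T @ q.eps
        Phi += q.D.T @ WD
        quants.append(q)
    return U, Phi, quants


# ---------------------------------------------------------------------------
# independence-model initializers

def logistic_mle(y, X, maxitr=50, tol=1e-10):
    """Ordinary logistic regression by Newton's method (no penalty).

    On separated data the coefficients drift without converging; the last
    iterate is returned (callers treat this as the expected divergence path).
    """
    beta = np.zeros(X.shape[1])
    for _ in range(maxitr):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = mu * (1 - mu)
        H = X.T @ (w[:, None] * X)
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def firth_logistic(y, X, maxitr=100, tol=1e-10):
    """Firth-penalized logistic regression (modified score X'(y - mu + h(1/2 - mu))).

    Finite even under complete separation; used for penalized-fit starting values.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(maxitr):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        w = mu * (1 - mu)
        Xw = np.sqrt(w)[:, None] * X
        H = Xw.T @ Xw
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            break
        h = np.einsum("ij,jk,ik->i", Xw, Hinv, Xw)
        g = X.T @ (y - mu + h * (0.5 - mu))
        step = np.linalg.solve(H, g)
        # damp long steps: the penalized score is bounded but not globally concave
        norm = np.max(np.abs(step))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


# ---------------------------------------------------------------------------
# main solver

def _refresh_nuisance(design_p, blocks, quants, corr: CorrelationModel):
    """Moment updates of phi then alpha from current Pearson residuals."""
    res = [(q.pearson, b.positions) for q, b in zip(quants, blocks)]
    pooled = np.concatenate([e for e, _ in res])
    corr.phi = estimate_scale(pooled, design_p, corr.scale_fixed)
    if corr.kind != "independence":
        corr.alpha = estimate_alpha(
            res, corr.kind, corr.phi, design_p, corr.n_occasions
        )


def solve_estimating_equation(
    blocks: list[ClusterBlock],
    column_names: list[str],
    corr: CorrelationModel,
    init: np.ndarray,
    penalty=None,
    maxitr: int = 50,
    tol: float = 1e-5,
    method_tag: str = "GEE",
) -> GEEFit:
    """Fisher-scoring loop with interleaved phi/alpha refresh.

    ``penalty(Phi, blocks, quants, corr) -> p-vector`` adds a score adjustment
    (the Firth-type term for PGEE); ``None`` solves the plain equation.
    Step-halving (up to 10 halvings) guards steps that increase the score norm.
    """
    p = len(column_names)
    X_all = np.vstack([b.X for b in blocks])
    if np.linalg.matrix_rank(X_all) < p:
        raise SingularDesignError("design matrix is rank deficient across clusters")

    beta = np.asarray(init, dtype=float).copy()
    converged = False
    it = 0

    def total_score(b):
        U, Phi, quants = score_and_information(b, blocks, corr)
        if penalty is not None:
            U = U + penalty(Phi, blocks, quants, corr)
        return U, Phi, quants

    # moment-estimate the nuisance parameters at the starting values first:
    # otherwise a start at the independence solution with alpha still 0 would
    # satisfy the step criterion without the correlation ever being estimated
    _, _, quants0 = score_and_information(beta, blocks, corr)
    _refresh_nuisance(p, blocks, quants0, corr)
    U, Phi, quants = total_score(beta)
    for it in range(1, maxitr + 1):
        try:
            step = np.linalg.solve(Phi, U)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular Fisher information during iteration") from exc
        norm0 = np.max(np.abs(U))
        new_beta = beta + step
        U_new, Phi_new, quants_new = total_score(new_beta)
        for _ in range(10):
            if np.max(np.abs(U_new)) <= norm0 or np.max(np.abs(step)) < tol:
                break
            step = 0.5 * step
            new_beta = beta + step
            U_new, Phi_new, quants_new = total_score(new_beta)
        delta = np.max(np.abs(step))
        beta, U, Phi, quants = new_beta, U_new, Phi_new, quants_new
        _refresh_nuisance(p, blocks, quants, corr)
        # nuisance values changed: recompute score at the same beta
        U, Phi, quants = total_score(beta)
        if method_tag != "PGEE" and np.max(np.abs(beta)) > _BETA_SEP:
            warnings.warn(
                "coefficients exceed 50 in magnitude; the data may be separated "
                "- consider beta_method='PGEE'",
                SeparationWarning,
                stacklevel=2,
            )
        if delta < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"{method_tag} did not converge in {maxitr} iterations "
            f"(last max|step| {delta:.3g})",
            ConvergenceWarning,
            stacklevel=2,
        )
    return GEEFit(
        beta=beta,
        corr=corr,
        info=Phi,
        cluster_quantities=quants,
        blocks=blocks,
        column_names=list(column_names),
        iterations=it,
        converged=converged,
        method_tag=method_tag,
        score=U,
    )


def fit_gee(
    design: DesignData,
    corstr: str = "independence",
    init: np.ndarray | None = None,
    maxitr: int = 50,
    tol: float = 1e-5,
    scale_fix: bool = False,
) -> GEEFit:
    """Fit the conventional GEE for a prepared design.

    Starting values default to the ordinary logistic regression treating all
    observations as independent.
    """
    corr = CorrelationModel(
        kind=corstr, scale_fixed=scale_fix, n_occasions=design.n_occasions
    )
    if init is None:
        init = logistic_mle(design.y, design.X)
    return solve_estimating_equation(
        design.blocks, design.column_names, corr, init,
        penalty=None, maxitr=maxitr, tol=tol, method_tag="GEE",
    )
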