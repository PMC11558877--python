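"""Working correlation structures and moment estimation of their parameters.

The marginal model only specifies the mean and variance of each observation;
the within-cluster association is handled through a *working* correlation
matrix R(alpha).  Consistency of the coefficient estimates does not require
R to be correct, but a reasonable choice improves efficiency.  Supported
structures: independence, exchangeable, AR(1) over categorical occasion
positions, and unstructured over the pooled occasion set.

The scale parameter phi and the correlation parameters alpha are estimated
from Pearson residuals by the classical moment formulas with a degrees-of-
freedom correction of p (the number of regression coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ClampingWarning,
    InsufficientDataError,
    NumericalError,
    ParameterRangeError,
    StructureInfeasibleError,
)

__all__ = ["CorrelationModel", "build_matrix", "estimate_scale", "estimate_alpha"]

STRUCTURES = ("independence", "exchangeable", "ar1", "unstructured")

# out-of-range moment estimates are pulled to this fraction of the boundary
_CLAMP = 0.99


@dataclass
class CorrelationModel:
    """Working correlation structure with its current parameter values.

    Parameters
    ----------
    kind : str
        One of ``independence``, ``exchangeable``, ``ar1``, ``unstructured``.
    alpha : None, float or ndarray
        No parameter (independence), a scalar (exchangeable, ar1) or a
        symmetric T x T matrix over the pooled occasion set (unstructured).
    phi : float
        Scale (overdispersion) parameter; fixed at 1 when ``scale_fixed``.
    n_occasions : int
        Size T of the pooled occasion set (needed for unstructured and for
        the admissible range of exchangeable alpha).
    """

    kind: str
    alpha: object = None
    phi: float = 1.0
    scale_fixed: bool = False
    n_occasions: int = 0

    def __post_init__(self):
        if self.kind not in STRUCTURES:
            raise ParameterRangeError(
                f"unknown correlation structure {self.kind!r}; "
                f"choose from {STRUCTURES}"
            )
        if self.scale_fixed:
            self.phi = 1.0
        if self.alpha is None and self.kind in ("exchangeable", "ar1"):
            self.alpha = 0.0
        if self.alpha is None and self.kind == "unstructured" and self.n_occasions:
            self.alpha = np.eye(self.n_occasions)


def _check_scalar_alpha(kind: str, alpha: float, n_max: int) -> None:
    if kind == "ar1" and not (-1.0 < alpha < 1.0):
        raise ParameterRangeError(f"ar1 alpha must lie in (-1, 1); got {alpha}")
    if kind == "exchangeable":
        lo = -1.0 / (n_max - 1) if n_max > 1 else -1.0
        if not (lo < alpha < 1.0):
            raise ParameterRangeError(
                f"exchangeable alpha must lie in ({lo:.4g}, 1); got {alpha}"
            )


def build_matrix(model: CorrelationModel, positions: np.ndarray) -> np.ndarray:
    """Realize R_i(alpha) for a cluster observed at the given occasion positions.

    Positions are indices into the pooled occasion set; AR(1) decays with the
    positional lag |s - t| and unstructured selects the submatrix of the pooled
    T x T estimate.
    """
    positions = np.asarray(positions)
    n = len(positions)
    if model.kind == "independence":
        return np.eye(n)
    if model.kind == "exchangeable":
        a = float(model.alpha)
        _check_scalar_alpha("exchangeable", a, n)
        R = np.full((n, n), a)
        np.fill_diagonal(R, 1.0)
    elif model.kind == "ar1":
        a = float(model.alpha)
        _check_scalar_alpha("ar1", a, n)
        lag = np.abs(positions[:, None] - positions[None, :])
        R = a ** lag.astype(float)
    elif model.kind == "unstructured":
        A = np.asarray(model.alpha)
        if positions.max(initial=-1) >= A.shape[0]:
            raise ParameterRangeError(
                "cluster occasion outside the pooled occasion set of the "
                "unstructured correlation estimate"
            )
        R = A[np.ix_(positions, positions)]
    else:  # pragma: no cover - guarded in CorrelationModel
        raise ParameterRangeError(f"unknown structure {model.kind!r}")

    if n > 1:
        w = np.linalg.eigvalsh(R)
        if w.min() <= 1e-10:
            raise NumericalError(
                f"working correlation matrix for structure {model.kind!r} "
                f"is not positive definite (min eigenvalue {w.min():.3g})"
            )
    return R


def estimate_scale(residuals: np.ndarray, p: int, scale_fixed: bool = False) -> float:
    """Moment estimate of the scale phi from pooled Pearson residuals.

    phi-hat = sum(e^2) / (N - p) with N the total observation count; returns
    exactly 1 when the scale is fixed.
    """
    if scale_fixed:
        return 1.0
    residuals = np.asarray(residuals, dtype=float)
    N = residuals.size
    if N <= p:
        raise InsufficientDataError(
            f"scale estimation needs more observations ({N}) than coefficients ({p})"
        )
    return float(residuals @ residuals) / (N - p)


def _clamped(value: float, lo: float, hi: float, what: str) -> float:
    if lo < value < hi:
        return value
    clamped = min(max(value, _CLAMP * lo), _CLAMP * hi)
    warnings.warn(
        f"{what} moment estimate {value:.4g} outside ({lo:.4g}, {hi:.4g}); "
        f"clamped to {clamped:.4g}",
        ClampingWarning,
        stacklevel=3,
    )
    return clamped


def estimate_alpha(
    residual_blocks: list[tuple[np.ndarray, np.ndarray]],
    kind: str,
    phi: float,
    p: int,
    n_occasions: int = 0,
):
    """Moment estimate of the working correlation parameter(s).

    Parameters
    ----------
    residual_blocks : list of (e_i, positions_i)
        Per-cluster Pearson residual vectors with their occasion positions.
    kind, phi, p : structure name, current scale, coefficient count.
    n_occasions : pooled occasion count T (required for unstructured).

    Returns the scalar alpha-hat (exchangeable, ar1), the pooled T x T matrix
    (unstructured), or None (independence).  Estimates falling outside the
    admissible range are clamped to 0.99 of the boundary with a warning.
    """
    if kind == "independence":
        return None
    sizes = [len(e) for e, _ in residual_blocks]
    n_max = max(sizes)
    if n_max < 2:
        raise StructureInfeasibleError(
            f"structure {kind!r} needs clusters with at least two observations"
        )

    if kind == "exchangeable":
        num, pairs = 0.0, 0
        for e, _ in residual_blocks:
            n = len(e)
            if n < 2:
                continue
            s = e.sum()
            num += (s * s - e @ e) / 2.0
            pairs += n * (n - 1) // 2
        denom = phi * (pairs - p)
        if denom <= 0:
            raise InsufficientDataError(
                f"exchangeable alpha needs more residual pairs ({pairs}) than p={p}"
            )
        lo = -1.0 / (n_max - 1)
        return _clamped(num / denom, lo, 1.0, "exchangeable alpha")

    if kind == "ar1":
        num, pairs = 0.0, 0
        for e, pos in residual_blocks:
            if len(e) < 2:
                continue
            adj = np.flatnonzero(np.diff(pos) == 1)
            num += float(e[adj] @ e[adj + 1])
            pairs += len(adj)
        denom = phi * (pairs - p)
        if denom <= 0:
            raise InsufficientDataError(
                f"ar1 alpha needs more adjacent residual pairs ({pairs}) than p={p}"
            )
        return _clamped(num / denom, -1.0, 1.0, "ar1 alpha")

    if kind == "unstructured":
        T = n_occasions
        if T < 2:
            raise StructureInfeasibleError("unstructured needs a pooled occasion set T >= 2")
        num = np.zeros((T, T))
        cnt = np.zeros((T, T), dtype=int)
        for e, pos in residual_blocks:
            op = np.outer(e, e)
            ix = np.ix_(pos, pos)
            num[ix] += op
            cnt[ix] += 1
        R = np.eye(T)
        for t in range(T):
            for u in range(t + 1, T):
                denom = phi * (cnt[t, u] - p)
                if denom <= 0:
                    raise InsufficientDataError(
                        f"unstructured alpha({t},{u}) needs more clusters observed at "
                        f"both occasions ({cnt[t, u]}) than p={p}"
                    )
                val = num[t, u] / denom
                R[t, u] = R[u, t] = min(max(val, -_CLAMP), _CLAMP)
        # entrywise clamping does not guarantee PD; shrink toward identity if needed
        lam = 1.0
        for _ in range(200):
            if np.linalg.eigvalsh(R).min() > 1e-8:
                break
            lam *= 0.9
            R = lam * R + (1 - lam) * np.eye(T)
            np.fill_diagonal(R, 1.0)
        else:  # pragma: no cover
            raise NumericalError("unstructured correlation estimate cannot be made PD")
        if lam < 1.0:
            warnings.warn(
                f"unstructured correlation estimate shrunk toward identity "
                f"(factor {lam:.3g}) to restore positive definiteness",
                ClampingWarning,
                stacklevel=2,
            )
        return R

    raise ParameterRangeError(f"unknown structure {kind!r}")
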