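"""Correlated binary longitudinal data with known marginal logistic structure.

Outcomes are generated by the latent-threshold (Emrich-Piedmonte)
construction: within a cluster, a multivariate normal vector Z with unit
variances is thresholded at z_t = ndtri(mu_t), so the marginal means satisfy
logit(mu_t) = x_t' beta exactly, and the latent pairwise correlation is solved
(by bisection) so the *binary-scale* correlation of each outcome pair matches
the requested exchangeable or AR(1) value rho - the same quantity the moment
estimator of the working correlation targets.

The default covariate layout emulates a small longitudinal design: a
cluster-level binary exposure plus a categorical occasion effect, the schema
of a classic 16-child wheeze study (four annual visits at ages 9-12).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import multivariate_normal

from .errors import FeasibilityError

__all__ = ["SimulationSpec", "generate", "wheeze_like_fixture", "simulation_study"]

_BISECT_TOL = 1e-10
_latent_cache: dict = {}


def _bvn_cdf(h: float, k: float, r: float) -> float:
    return float(
        multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]).cdf([h, k])
    )


def _latent_corr(p1: float, p2: float, rho: float) -> float:
    """Latent normal correlation giving binary correlation rho for margins p1, p2."""
    if rho == 0.0:
        return 0.0
    key = (round(p1, 12), round(p2, 12), round(rho, 12))
    if key in _latent_cache:
        return _latent_cache[key]
    s = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    target = p1 * p2 + rho * s  # required P(Y1=1, Y2=1)
    lo_f, hi_f = max(0.0, p1 + p2 - 1.0), min(p1, p2)
    if not (lo_f - 1e-12 <= target <= hi_f + 1e-12):
        lo_r = (lo_f - p1 * p2) / s
        hi_r = (hi_f - p1 * p2) / s
        raise FeasibilityError(
            f"binary correlation {rho:.4g} infeasible for margins "
            f"({p1:.4g}, {p2:.4g}); attainable range [{lo_r:.4g}, {hi_r:.4g}]"
        )
    z1, z2 = ndtri(p1), ndtri(p2)
    lo, hi = -0.999999, 0.999999
    if _bvn_cdf(z1, z2, lo) > target or _bvn_cdf(z1, z2, hi) < target:
        raise FeasibilityError(
            f"no latent correlation achieves binary correlation {rho:.4g} "
            f"for margins ({p1:.4g}, {p2:.4g})"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if hi - lo < _BISECT_TOL:
            break
        if _bvn_cdf(z1, z2, mid) < target:
            lo = mid
        else:
            hi = mid
    r = 0.5 * (lo + hi)
    _latent_cache[key] = r
    return r


@dataclass
class SimulationSpec:
    """Conditions for one synthetic dataset.

    Parameters
    ----------
    K : number of clusters.
    n : common cluster size, or a per-cluster list of sizes.
    beta : true coefficients for (intercept, cluster-binary x1[, occasion
        dummies 2..n when ``occasion_effect``]).
    kind : 'exchangeable' or 'ar1' binary-scale outcome correlation.
    rho : target pairwise binary correlation (0 = independent outcomes).
    occasion_effect : include treatment-coded occasion dummies in the mean
        model (wheeze-like design); requires equal cluster sizes.
    x1_prob : success probability of the cluster-level binary covariate.
    seed : RNG seed; fully determines the output (PCG64 generator).
    """

    K: int
    n: object
    beta: np.ndarray
    kind: str = "exchangeable"
    rho: float = 0.0
    occasion_effect: bool = True
    x1_prob: float = 0.5
    seed: int = 0

    def sizes(self) -> np.ndarray:
        if np.isscalar(self.n):
            return np.full(self.K, int(self.n), dtype=int)
        sizes = np.asarray(self.n, dtype=int)
        if len(sizes) != self.K:
            raise ValueError("per-cluster size list must have length K")
        return sizes

    @property
    def formula(self) -> str:
        return "y ~ x1 + C(occasion)" if self.occasion_effect else "y ~ x1"


def _target_R(kind: str, rho: float, n: int) -> np.ndarray:
    if kind == "exchangeable":
        R = np.full((n, n), rho)
    elif kind == "ar1":
        lag = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        R = rho ** lag.astype(float)
    else:
        raise ValueError(f"correlation kind must be 'exchangeable' or 'ar1', got {kind!r}")
    np.fill_diagonal(R, 1.0)
    return R


def _draw_cluster(mu: np.ndarray, R_target: np.ndarray, rng) -> np.ndarray:
    n = len(mu)
    if n == 1 or np.all(R_target[~np.eye(n, dtype=bool)] == 0.0):
        return (rng.random(n) < mu).astype(float)
    Sigma = np.eye(n)
    for j in range(n):
        for k in range(j + 1, n):
            r = _latent_corr(mu[j], mu[k], R_target[j, k])
            Sigma[j, k] = Sigma[k, j] = r
    w = np.linalg.eigvalsh(Sigma)
    if w.min() < 1e-10:
        raise FeasibilityError(
            "latent correlation matrix for the requested rho is not positive "
            f"definite (min eigenvalue {w.min():.3g}); lower |rho|"
        )
    L = np.linalg.cholesky(Sigma)
    z = L @ rng.standard_normal(n)
    return (z <= ndtri(mu)).astype(float)


def generate(spec: SimulationSpec) -> pd.DataFrame:
    """One synthetic dataset in long format (columns id, occasion, y, x1)."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.sizes()
    if spec.occasion_effect and len(set(sizes.tolist())) != 1:
        raise ValueError("occasion_effect requires equal cluster sizes")
    beta = np.asarray(spec.beta, dtype=float)
    rows = []
    draw_cache: dict = {}
    for i, n_i in enumerate(sizes):
        x1 = float(rng.random() < spec.x1_prob)
        X = np.ones((n_i, 2 + (n_i - 1 if spec.occasion_effect else 0)))
        X[:, 1] = x1
        if spec.occasion_effect:
            X[:, 2:] = 0.0
            for t in range(1, n_i):
                X[t, 1 + t] = 1.0
        if X.shape[1] != len(beta):
            raise ValueError(
                f"beta has length {len(beta)}; design implies {X.shape[1]} columns"
            )
        mu = expit(X @ beta)
        key = (n_i, x1)
        R_target = draw_cache.get(key)
        if R_target is None:
            R_target = _target_R(spec.kind, spec.rho, n_i)
            draw_cache[key] = R_target
        y = _draw_cluster(mu, R_target, rng)
        for t in range(n_i):
            rows.append((i + 1, t + 1, y[t], x1))
    return pd.DataFrame(rows, columns=["id", "occasion", "y", "x1"])


def wheeze_like_fixture(seed: int = 0) -> pd.DataFrame:
    """Synthetic stand-in with the classic wheeze-study schema.

    16 clusters (children) x 4 annual visits at ages 9-12 with columns
    ID, Wheeze, City, Age, Smoke.  The values are synthetic - generated from
    a marginal logistic model with AR(1) outcome correlation - not the
    copyrighted study data; externally supplied real data flows through the
    same reader path and schema.
    """
    beta = np.array([-0.3, 0.4, -0.15, -0.3, -0.45])  # odds decrease with age
    spec = SimulationSpec(
        K=16, n=4, beta=beta, kind="ar1", rho=0.3,
        occasion_effect=True, x1_prob=0.5, seed=seed,
    )
    df = generate(spec)
    rng = np.random.default_rng(seed + 1)
    out = pd.DataFrame(
        {
            "ID": df["id"],
            "Wheeze": df["y"].astype(int),
            "City": df["x1"].astype(int),
            "Age": df["occasion"] + 8,  # visits at ages 9, 10, 11, 12
            "Smoke": rng.integers(0, 3, size=len(df)),
        }
    )
    return out


def simulation_study(
    spec: SimulationSpec,
    reps: int,
    methods=("GEE",),
    estimators=("SA",),
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Repeated-sampling summary of estimator performance.

    For every (method, estimator, coefficient) combination the table reports
    the mean estimate, bias, empirical SD of the estimates, mean standard
    error and Wald CI coverage of the true value, along with the number of
    replicates excluded (fit failure or non-convergence).

    Seeded and reproducible: replicate r uses seed spec.seed + r.
    """
    from scipy.stats import norm

    from .api import fit as _fit

    if reps < 1:
        raise ValueError("reps must be >= 1")
    beta_true = np.asarray(spec.beta, dtype=float)
    zq = norm.ppf(0.5 + conf_level / 2.0)
    est = {m: [] for m in methods}
    ses = {(m, s): [] for m in methods for s in estimators}
    failed = {m: 0 for m in methods}
    column_names = None
    import dataclasses
    import warnings as _warnings

    for r in range(reps):
        df = generate(dataclasses.replace(spec, seed=spec.seed + r))
        for m in methods:
            try:
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    res = _fit(
                        df, spec.formula, id="id", repeated="occasion",
                        corstr=spec.kind, beta_method=m, se_method=estimators[0],
                    )
                if not res.fit.converged:
                    raise RuntimeError("not converged")
                column_names = res.fit.column_names
                est[m].append(res.fit.beta)
                ses[(m, estimators[0])].append(res.cov.se)
                for s in estimators[1:]:
                    with _warnings.catch_warnings():
                        _warnings.simplefilter("ignore")
                        from .covariance import estimate_covariance

                        ses[(m, s)].append(estimate_covariance(res.fit, s).se)
            except Exception:
                failed[m] += 1

    # fitted column order comes from the formula machinery (categorical terms
    # may precede numeric ones); map the true coefficients by column name
    terms = column_names if column_names else []

    def _true_index(name: str) -> int:
        if name == "Intercept":
            return 0
        if name == "x1":
            return 1
        # C(occasion)[T.k] -> generator beta index k (intercept, x1, occ2..occn)
        k = int(name.split("[T.")[1].rstrip("]"))
        return k

    order = [_true_index(t) for t in terms]
    beta_true = beta_true[order]
    rows = []
    for m in methods:
        B = np.array(est[m]) if est[m] else np.empty((0, len(beta_true)))
        for s in estimators:
            S = np.array(ses[(m, s)]) if ses[(m, s)] else np.empty((0, len(beta_true)))
            for j, term in enumerate(terms):
                if len(B):
                    cover = float(
                        np.mean(np.abs(B[:, j] - beta_true[j]) <= zq * S[:, j])
                    )
                else:
                    cover = np.nan
                rows.append(
                    dict(
                        method=m,
                        estimator=s,
                        term=term,
                        true=beta_true[j],
                        mean_estimate=B[:, j].mean() if len(B) else np.nan,
                        bias=B[:, j].mean() - beta_true[j] if len(B) else np.nan,
                        empirical_sd=B[:, j].std(ddof=1) if len(B) > 1 else np.nan,
                        mean_se=S[:, j].mean() if len(S) else np.nan,
                        coverage=cover,
                        n_used=len(B),
                        n_failed=failed[m],
                    )
                )
    return pd.DataFrame(rows)
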