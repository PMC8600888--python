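"""Latent profile analysis over continuous resilience indicators.

Finite Gaussian mixtures with class-specific mean profiles and (by
default) a diagonal within-class covariance shared across classes — the
convention of mainstream mixture software for profile analysis.  Models
for K = 1..5 classes are enumerated and compared on information
criteria, relative entropy, and a Lo–Mendell–Rubin-style adjusted
likelihood-ratio test of K vs K-1 classes; a parametric-bootstrap LRT is
available as the more trustworthy (if slower) backend, since the
adjusted approximation's small-sample behavior is contested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "LPASolution",
    "LMRResult",
    "fit_lpa",
    "relative_entropy",
    "lmr_lrt",
    "bootstrap_lrt",
    "enumerate_classes",
    "simulate_from_solution",
]


@dataclass
class LPASolution:
    K: int
    weights: np.ndarray
    means: np.ndarray  # (K, p)
    variances: np.ndarray  # (p,) shared or (K, p) class-varying
    posterior: np.ndarray  # (n, K)
    loglik: float
    n_params: int
    n_obs: int
    entropy: float
    n_starts_used: int
    seed: int
    loglik_trace: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * np.log(self.n_obs)

    def assignments(self) -> np.ndarray:
        return self.posterior.argmax(axis=1)


@dataclass
class LMRResult:
    K_full: int
    K_reduced: int
    statistic: float
    p_value: float
    backend: str = "lmr"


def _log_gauss_diag(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Log-density of each row of x under a diagonal Gaussian."""
    return (
        -0.5 * np.sum(np.log(2 * np.pi * var))
        - 0.5 * np.sum((x - mean) ** 2 / var, axis=1)
    )


def _mixture_logdens(x, weights, means, variances):
    K = len(weights)
    parts = np.empty((x.shape[0], K))
    for k in range(K):
        var_k = variances[k] if variances.ndim == 2 else variances
        parts[:, k] = np.log(weights[k]) + _log_gauss_diag(x, means[k], var_k)
    return parts


def _em_run(x, K, rng, shared_variance, max_iter=300, tol=1e-7):
    n, p = x.shape
    km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(x)
    means = km.cluster_centers_.copy()
    weights = np.bincount(labels, minlength=K) / n
    weights = np.clip(weights, 1e-3, None)
    weights /= weights.sum()
    resid = x - means[labels]
    if shared_variance:
        variances = np.maximum(resid.var(axis=0), 1e-6)
    else:
        variances = np.tile(np.maximum(resid.var(axis=0), 1e-6), (K, 1))
    trace = []
    ll = -np.inf
    for _ in range(max_iter):
        parts = _mixture_logdens(x, weights, means, variances)
        m = parts.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(parts - m).sum(axis=1))
        new_ll = float(lse.sum())
        W = np.exp(parts - lse[:, None])
        trace.append(new_ll)
        nk = W.sum(axis=0)
        if (nk < 1.0 / (10.0 * n) * n).any() or (nk < 1e-8).any():
            return None  # degenerate class, caller restarts
        weights = nk / n
        means = (W.T @ x) / nk[:, None]
        if shared_variance:
            sq = np.zeros(p)
            for k in range(K):
                sq += W[:, k] @ (x - means[k]) ** 2
            variances = np.maximum(sq / n, 1e-8)
        else:
            variances = np.vstack(
                [np.maximum((W[:, k] @ (x - means[k]) ** 2) / nk[k], 1e-8) for k in range(K)]
            )
        if new_ll - ll < tol * max(1.0, abs(new_ll)) and new_ll >= ll:
            ll = new_ll
            break
        ll = new_ll
    parts = _mixture_logdens(x, weights, means, variances)
    m = parts.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(parts - m).sum(axis=1))
    W = np.exp(parts - lse[:, None])
    return float(lse.sum()), weights, means, variances, W, trace


def fit_lpa(
    indicators: np.ndarray,
    K: int,
    n_starts: int = 50,
    seed: int = 0,
    shared_variance: bool = True,
) -> LPASolution:
    """Fit a K-class Gaussian profile mixture by EM from k-means starts.

    The best solution over ``n_starts`` random starts is returned, with
    classes sorted by profile mean for label stability.  Classes whose
    expected size falls below ``1/(10n)`` of the sample are treated as
    degenerate and trigger a restart.
    """
    x = np.atleast_2d(np.asarray(indicators, dtype=float))
    n, p = x.shape
    if n <= K:
        raise ValueError("need more observations than classes")
    if K == 1:
        mean = x.mean(axis=0, keepdims=True)
        var = np.maximum(x.var(axis=0), 1e-12)
        ll = float(_log_gauss_diag(x, mean[0], var).sum())
        return LPASolution(
            K=1, weights=np.array([1.0]), means=mean, variances=var,
            posterior=np.ones((n, 1)), loglik=ll,
            n_params=2 * p, n_obs=n, entropy=np.nan,
            n_starts_used=1, seed=seed, loglik_trace=[ll],
        )
    rng = np.random.default_rng(seed)
    best = None
    used = 0
    for _ in range(n_starts):
        used += 1
        out = _em_run(x, K, rng, shared_variance)
        if out is None:
            continue
        if best is None or out[0] > best[0]:
            best = out
    if best is None:
        raise RuntimeError(f"all {n_starts} EM starts degenerated for K={K}")
    ll, weights, means, variances, W, trace = best
    order = np.argsort(means.mean(axis=1))
    weights = weights[order]
    means = means[order]
    if variances.ndim == 2:
        variances = variances[order]
    W = W[:, order]
    if shared_variance:
        n_params = K * p + p + (K - 1)
    else:
        n_params = K * p + K * p + (K - 1)
    return LPASolution(
        K=K, weights=weights, means=means, variances=variances,
        posterior=W, loglik=ll, n_params=n_params, n_obs=n,
        entropy=relative_entropy(W), n_starts_used=used, seed=seed,
        loglik_trace=trace,
    )


def relative_entropy(posterior: np.ndarray) -> float:
    """Normalized classification certainty: ``1 - sum(-p ln p) / (n ln K)``.

    1 means every posterior is 0/1 (perfect separation); 0 means all
    posteriors are uniform.  Undefined (raises) for a single class.
    """
    W = np.atleast_2d(np.asarray(posterior, dtype=float))
    n, K = W.shape
    if K < 2:
        raise ValueError("relative entropy is undefined for K = 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(W > 0, -W * np.log(W), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(K)))


def lmr_lrt(sol_full: LPASolution, sol_reduced: LPASolution, n: int | None = None) -> LMRResult:
    """Adjusted likelihood-ratio comparison of K vs K-1 classes.

    The raw ``2 * dLL`` is shrunk by the parameter-count correction
    ``c = 1 + dq / ln n`` and referred to a chi-square with ``dq``
    degrees of freedom — a deliberately conservative stand-in for the
    intractable mixture reference distribution.  Prefer
    :func:`bootstrap_lrt` when runtime allows.
    """
    if sol_full.K != sol_reduced.K + 1:
        raise ValueError("models must differ by exactly one class")
    n = n or sol_full.n_obs
    d_ll = sol_full.loglik - sol_reduced.loglik
    dq = max(sol_full.n_params - sol_reduced.n_params, 1)
    if d_ll <= 0:
        return LMRResult(sol_full.K, sol_reduced.K, 0.0, 1.0)
    c = 1.0 + dq / np.log(n)
    statistic = 2.0 * d_ll / c
    p = float(stats.chi2.sf(statistic, dq))
    return LMRResult(sol_full.K, sol_reduced.K, float(statistic), p)


def simulate_from_solution(sol: LPASolution, n: int, seed: int) -> np.ndarray:
    """Parametric draw of an indicator matrix from a fitted mixture."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(sol.K, size=n, p=sol.weights)
    if sol.variances.ndim == 2:
        sd = np.sqrt(sol.variances)[labels]
    else:
        sd = np.sqrt(sol.variances)[None, :]
    return sol.means[labels] + rng.normal(size=(n, sol.means.shape[1])) * sd


def bootstrap_lrt(
    indicators: np.ndarray,
    K_reduced: int,
    n_boot: int = 50,
    n_starts: int = 10,
    seed: int = 0,
    shared_variance: bool = True,
) -> LMRResult:
    """Parametric-bootstrap LRT of K_reduced + 1 vs K_reduced classes."""
    x = np.atleast_2d(np.asarray(indicators, dtype=float))
    rng = np.random.default_rng(seed)
    red = fit_lpa(x, K_reduced, n_starts, int(rng.integers(2**31)), shared_variance)
    full = fit_lpa(x, K_reduced + 1, n_starts, int(rng.integers(2**31)), shared_variance)
    obs = 2.0 * max(full.loglik - red.loglik, 0.0)
    exceed = 0
    for _ in range(n_boot):
        xb = simulate_from_solution(red, x.shape[0], int(rng.integers(2**31)))
        try:
            red_b = fit_lpa(xb, K_reduced, n_starts, int(rng.integers(2**31)), shared_variance)
            full_b = fit_lpa(xb, K_reduced + 1, n_starts, int(rng.integers(2**31)), shared_variance)
        except RuntimeError:
            continue
        if 2.0 * max(full_b.loglik - red_b.loglik, 0.0) >= obs:
            exceed += 1
    p = (1.0 + exceed) / (n_boot + 1.0)
    return LMRResult(K_reduced + 1, K_reduced, obs, p, backend="bootstrap")


def enumerate_classes(
    indicators: np.ndarray,
    K_range=range(1, 6),
    n_starts: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
    entropy_min: float = 0.8,
    shared_variance: bool = True,
) -> tuple[pd.DataFrame, int, dict[int, LPASolution]]:
    """Fit every K and recommend a class count.

    Rule: the smallest K at which the (K+1)-class test is non-significant,
    subject to relative entropy >= ``entropy_min`` (vacuous for K = 1)
    and BIC being a local minimum; if no K qualifies, the K with the
    smallest BIC is recommended.  The full table is returned so the rule
    is auditable.
    """
    Ks = sorted(K_range)
    rng = np.random.default_rng(seed)
    sols: dict[int, LPASolution] = {}
    for K in Ks:
        sols[K] = fit_lpa(indicators, K, n_starts, int(rng.integers(2**31)), shared_variance)
    rows = []
    lmr_p: dict[int, float] = {}
    for K in Ks:
        s = sols[K]
        row = {
            "K": K, "loglik": s.loglik, "n_params": s.n_params,
            "aic": s.aic, "bic": s.bic, "entropy": s.entropy,
        }
        if K - 1 in sols:
            res = lmr_lrt(s, sols[K - 1])
            row["lmr_stat"] = res.statistic
            row["lmr_p"] = res.p_value
            lmr_p[K] = res.p_value
        else:
            row["lmr_stat"] = np.nan
            row["lmr_p"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    bics = {K: sols[K].bic for K in Ks}

    def bic_local_min(K):
        left_ok = (K - 1 not in bics) or bics[K] <= bics[K - 1]
        right_ok = (K + 1 not in bics) or bics[K] <= bics[K + 1]
        return left_ok and right_ok

    recommended = None
    for K in Ks:
        next_p = lmr_p.get(K + 1)
        nonsig_above = (K == Ks[-1]) or (next_p is not None and next_p >= alpha)
        entropy_ok = (K == 1) or (sols[K].entropy >= entropy_min)
        if nonsig_above and entropy_ok and bic_local_min(K):
            recommended = K
            break
    if recommended is None:
        recommended = min(bics, key=bics.get)
    return table, recommended, sols
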