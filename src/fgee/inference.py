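"""Variance estimation and confidence bands for the one-step estimator.

The sandwich variance is Var(theta-hat) = N^{-1} H^{-1} M H^{-1} with bread
H = N^{-1} sum_i D_i^T V_i^{-1} D_i + Lambda S and meat
M = N^{-1} sum_i U_i U_i^T built from the penalized estimating function
U_i = D_i^T V_i^{-1} (Y_i - mu_i) - Lambda S theta. It is asymptotically
valid even under working-correlation misspecification.

Joint (simultaneous) bands are beta_r(s) +/- q_r sigma_r(s) where q_r is the
(1-alpha) quantile of the max statistic max_s |beta-tilde_r(s)| / sigma_r(s)
over draws beta-tilde from the estimated sampling distribution - parametric
Gaussian draws of theta, or centered fast-cluster-bootstrap draws.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

__all__ = [
    "sandwich_from_summaries", "sandwich_variance", "fast_cluster_bootstrap",
    "pointwise_ci", "joint_ci",
]


def sandwich_from_summaries(W: np.ndarray, b: np.ndarray, P: np.ndarray,
                            theta: np.ndarray) -> np.ndarray:
    """Sandwich covariance from per-cluster summaries W_i, b_i at theta.

    ``P`` is the expanded penalty Lambda S (p x p). Returns the p x p
    covariance of theta-hat, symmetrized.
    """
    N = W.shape[0]
    H = W.mean(axis=0) + P
    U = b - (P @ theta)[None, :]
    M = (U.T @ U) / N
    cf = cho_factor(H, lower=True)
    HinvM = cho_solve(cf, M)
    V = cho_solve(cf, HinvM.T).T / N
    return 0.5 * (V + V.T)


def sandwich_variance(dataset, basis, theta, cov, lam, family=None,
                      use_dispersion: bool = True) -> np.ndarray:
    """Sandwich covariance computed from scratch at theta (convenience API)."""
    from .model import _penalty
    from .working_cov import cluster_summaries, residual_stats

    stats = residual_stats(dataset, basis, theta, family)
    if not use_dispersion:
        stats = dict(stats, phi=np.ones_like(stats["phi"]))
    W, b = cluster_summaries(dataset, basis, theta, cov, stats=stats)
    P = _penalty(basis.S_block, lam, dataset.q + 1)
    return sandwich_from_summaries(W, b, P, theta)


def fast_cluster_bootstrap(theta0, W, b, lam1, S_block, n, T: int = 1000,
                           seed=None, indices=None) -> dict:
    """Fast cluster bootstrap: resample clusters, re-use the Hessian factor.

    Each draw is
    theta_t = theta0 + (mean W_i + Lambda1 S)^{-1}
              (N^{-1} ntilde_t sum_{i in R_t} b_i - Lambda1 S theta0)
    with R_t a with-replacement sample of N cluster indices and
    ntilde_t = sum_i n_i / sum_{i in R_t} n_i. An identity resample
    reproduces the one-step estimate exactly.

    Returns ``{"draws": (T, p), "cov": (p, p), "indices": (T, N)}``.
    """
    from .model import _factor, _penalty

    theta0 = np.asarray(theta0, dtype=float)
    N, p = b.shape
    q1 = p // S_block.shape[0]
    P = _penalty(S_block, lam1, q1)
    H = W.mean(axis=0) + P
    cf = _factor(H)
    if indices is None:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, N, size=(T, N))
    else:
        idx = np.asarray(indices, dtype=int).reshape(-1, N)
    n = np.asarray(n, dtype=float)
    ntilde = n.sum() / n[idx].sum(axis=1)               # (T,)
    scores = ntilde[:, None] * b[idx].sum(axis=1) / N - (P @ theta0)[None, :]
    draws = theta0[None, :] + cho_solve(cf, scores.T).T
    dc = draws - draws.mean(axis=0, keepdims=True)
    cov = dc.T @ dc / max(T - 1, 1)
    return {"draws": draws, "cov": cov, "indices": idx, "ntilde": ntilde}


def pointwise_ci(beta: np.ndarray, se: np.ndarray, alpha: float = 0.05):
    """Normal-quantile pointwise intervals; shape (q+1, L, 2)."""
    z = norm.ppf(1.0 - alpha / 2.0)
    return np.stack([beta - z * se, beta + z * se], axis=-1)


def _psd_root(Sigma: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (Sigma + Sigma.T))
    return V * np.sqrt(np.clip(w, 0.0, None))


def joint_ci(beta: np.ndarray, cov_blocks, B: np.ndarray, alpha: float = 0.05,
             T: int = 1000, mode: str = "parametric", seed=None, draws=None,
             m: int | None = None, space: str = "beta") -> dict:
    """Per-coefficient simultaneous bands beta_r(s) +/- q_r sigma_r(s).

    ``cov_blocks`` holds the m x m covariance of each theta_r block. In
    parametric mode, T draws theta-tilde ~ N(0, Sigma_r) calibrate the max
    statistic; in nonparametric mode, centered bootstrap ``draws`` (T, p) are
    used. ``space`` selects the studentization: "beta" (default) takes
    max_s |B theta-tilde|(s) / sigma_r(s); "theta" takes
    max_d |theta-tilde_d| / sqrt(Sigma_r[d, d]).

    The quantile is floored at the pointwise z so joint bands always nest
    pointwise CIs. Degenerate (zero) covariance blocks yield the degenerate
    pointwise interval.
    """
    rng = np.random.default_rng(seed)
    z = norm.ppf(1.0 - alpha / 2.0)
    q1, L = beta.shape
    lower = np.empty_like(beta)
    upper = np.empty_like(beta)
    qtilde = np.empty(q1)
    for r, Sigma in enumerate(cov_blocks):
        sigma_beta = np.sqrt(np.maximum(
            np.einsum("lc,cd,ld->l", B, Sigma, B), 0.0))
        if np.all(sigma_beta == 0.0):
            qtilde[r] = z
            lower[r] = upper[r] = beta[r]
            continue
        if mode == "parametric":
            A = _psd_root(Sigma)
            tdraws = rng.standard_normal((T, Sigma.shape[0])) @ A.T
        elif mode == "nonparametric":
            if draws is None:
                raise ValueError("nonparametric mode requires bootstrap draws")
            mm = m if m is not None else Sigma.shape[0]
            block = draws[:, r * mm:(r + 1) * mm]
            tdraws = block - block.mean(axis=0, keepdims=True)
        else:
            raise ValueError("mode must be 'parametric' or 'nonparametric'")
        if space == "beta":
            curves = tdraws @ B.T
            safe = np.where(sigma_beta > 0, sigma_beta, np.inf)
            stats = np.max(np.abs(curves) / safe[None, :], axis=1)
        elif space == "theta":
            sd = np.sqrt(np.maximum(np.diag(Sigma), 0.0))
            safe = np.where(sd > 0, sd, np.inf)
            stats = np.max(np.abs(tdraws) / safe[None, :], axis=1)
        else:
            raise ValueError("space must be 'beta' or 'theta'")
        q = max(float(np.quantile(stats, 1.0 - alpha)), z)
        qtilde[r] = q
        lower[r] = beta[r] - q * sigma_beta
        upper[r] = beta[r] + q * sigma_beta
    return {"lower": lower, "upper": upper, "qtilde": qtilde, "alpha": alpha}
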