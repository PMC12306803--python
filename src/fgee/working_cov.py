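"""Working covariance structures and fast inverse applications.

The working covariance of a cluster is block diagonal over grid points,
V_i = bdiag(V_i(s_1), ..., V_i(s_L)) with V_i(s) = A_i(s)^{1/2} R_i(s)
A_i(s)^{1/2}, where A_i(s) holds the working variances and R_i(s) is an
independence, exchangeable, or AR(1) correlation matrix with a per-point
correlation parameter rho(s). Inverses are applied in O(n_i) (exchangeable,
closed form) or via a Toeplitz solve (AR1) without ever materializing an
n_i L x n_i L matrix.

rho(s) is estimated from Pearson residuals standardized by a per-point
dispersion (mean squared Pearson residual), so the moment and Yule-Walker
estimators below expect unit-scale inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_toeplitz

from .basis import BasisSystem, coef_curves
from .families import get_family

__all__ = [
    "WorkingCovModel", "residual_stats", "estimate_rho_exchangeable",
    "estimate_rho_ar1", "smooth_rho", "apply_inverse_exchangeable",
    "apply_inverse_ar1", "cluster_summaries",
]

STRUCTURES = ("independence", "exchangeable", "ar1")


@dataclass
class WorkingCovModel:
    """Correlation kind, per-point correlation, and truncation bound."""

    kind: str = "independence"
    rho: np.ndarray | None = None
    eps: float = 1e-3
    smooth: bool = False

    def __post_init__(self):
        if self.kind not in STRUCTURES:
            raise ValueError(f"kind must be one of {STRUCTURES}")

    def rho_at(self, L: int) -> np.ndarray:
        if self.kind == "independence" or self.rho is None:
            return np.zeros(L)
        return np.asarray(self.rho, dtype=float)

    def estimate(self, e_std: np.ndarray, n: np.ndarray) -> "WorkingCovModel":
        """Return a copy with rho(s) estimated from standardized residuals."""
        if self.kind == "independence":
            rho = np.zeros(e_std.shape[1])
        elif self.kind == "exchangeable":
            rho = estimate_rho_exchangeable(e_std, n, eps=self.eps)
        else:
            rho = estimate_rho_ar1(e_std, n, eps=self.eps)
        if self.smooth:
            rho = smooth_rho(rho, kind=self.kind, eps=self.eps)
        return WorkingCovModel(self.kind, rho, self.eps, self.smooth)


def residual_stats(dataset, basis: BasisSystem, theta, family=None):
    """Model quantities at theta: eta, mu, dmu, Pearson residuals, dispersion.

    Returns a dict with (M, L) arrays ``eta, mu, dmu, resid, var`` plus the
    per-point dispersion ``phi`` (L,) and standardized residuals ``e_std``
    (Pearson residuals divided by sqrt(phi(s))).
    """
    fam = get_family(family or dataset.family)
    C = dataset.covariate_tensor()
    beta = coef_curves(basis, theta)
    eta = np.einsum("mal,al->ml", C, beta)
    mu = fam.inverse_link(eta)
    if not np.all(np.isfinite(mu)):
        bad = np.where(~np.isfinite(mu).all(axis=1))[0][0]
        i = np.searchsorted(dataset.offsets, bad, side="right") - 1
        raise FloatingPointError(
            f"non-finite fitted mean in cluster {dataset.cluster_ids[i]!r}")
    dmu = fam.dmu_deta(eta)
    v = fam.variance(fam.clamp_mu(mu))
    resid = dataset.Y - mu
    e = resid / np.sqrt(v)
    phi = np.maximum(np.mean(e * e, axis=0), 1e-12)
    return {
        "eta": eta, "mu": mu, "dmu": dmu, "resid": resid, "var": v,
        "phi": phi, "e_std": e / np.sqrt(phi)[None, :],
    }


def _cluster_blocks(e: np.ndarray, n: np.ndarray):
    offsets = np.concatenate([[0], np.cumsum(n)])
    for i, ni in enumerate(n):
        yield i, e[offsets[i]:offsets[i + 1]]


def estimate_rho_exchangeable(e_std: np.ndarray, n, eps: float = 1e-3) -> np.ndarray:
    """Moment estimator of the exchangeable correlation at each grid point.

    For each cluster, averages e_j(s) e_k(s) over the n_i(n_i - 1) ordered
    pairs j != k, then averages over clusters and truncates to
    [-1 + eps, 1 - eps]. Clusters with n_i < 2 carry no pair information and
    are excluded with a warning.
    """
    e_std = np.asarray(e_std, dtype=float)
    n = np.asarray(n, dtype=int)
    usable = n >= 2
    if not np.all(usable):
        warnings.warn(
            f"{int((~usable).sum())} cluster(s) with n_i < 2 excluded from "
            "the exchangeable correlation estimator", stacklevel=2)
    if not usable.any():
        raise ValueError("exchangeable rho requires at least one cluster with n_i >= 2")
    total = np.zeros(e_std.shape[1])
    count = 0
    for i, block in _cluster_blocks(e_std, n):
        ni = n[i]
        if ni < 2:
            continue
        sums = block.sum(axis=0)
        sq = (block * block).sum(axis=0)
        total += (sums * sums - sq) / (ni * (ni - 1))
        count += 1
    rho = total / count
    return np.clip(rho, -1.0 + eps, 1.0 - eps)


def estimate_rho_ar1(e_std: np.ndarray, n, eps: float = 1e-3) -> np.ndarray:
    """Lag-1 Yule-Walker estimate of the AR(1) correlation at each grid point.

    Per cluster: rho_i(s) = sum_j e_j(s) e_{j+1}(s) / sum_j e_j(s)^2, for
    equally spaced longitudinal observations; the cluster estimates are
    averaged and truncated to [0, 1 - eps]. Clusters whose residual series is
    identically zero at a point contribute 0 there.
    """
    e_std = np.asarray(e_std, dtype=float)
    n = np.asarray(n, dtype=int)
    if np.any(n < 2):
        raise ValueError("AR1 rho estimation requires n_i >= 2 for every cluster")
    acc = np.zeros(e_std.shape[1])
    warned = False
    for i, block in _cluster_blocks(e_std, n):
        num = (block[:-1] * block[1:]).sum(axis=0)
        den = (block * block).sum(axis=0)
        zero = den <= 0
        if zero.any() and not warned:
            warnings.warn("all-zero residual series treated as rho_i = 0",
                          stacklevel=2)
            warned = True
        den = np.where(zero, 1.0, den)
        acc += np.where(zero, 0.0, num / den)
    return np.clip(acc / len(n), 0.0, 1.0 - eps)


def smooth_rho(rho: np.ndarray, window: int | None = None,
               kind: str = "exchangeable", eps: float = 1e-3) -> np.ndarray:
    """Centered running-mean smoother over the functional domain.

    Default window is max(5, round(L/10)), forced odd; edges use reflect
    padding so constants are preserved. Output is re-truncated to the valid
    range of the correlation structure.
    """
    rho = np.asarray(rho, dtype=float)
    L = rho.shape[0]
    if L < 5:
        raise ValueError("smoothing requires L >= 5")
    if window is None:
        window = max(5, int(round(L / 10)))
    window = int(window) | 1  # odd
    half = window // 2
    padded = np.pad(rho, half, mode="reflect")
    out = np.convolve(padded, np.ones(window) / window, mode="valid")
    lo = 0.0 if kind == "ar1" else -1.0 + eps
    return np.clip(out, lo, 1.0 - eps)


def apply_inverse_exchangeable(r: np.ndarray, rho: float, a: np.ndarray) -> np.ndarray:
    """V(s)^{-1} r for exchangeable correlation, in O(n) via the closed form

    V^{-1} = (1-rho)^{-1} A^{-1}
             - rho [(1-rho)(1 + (n-1) rho)]^{-1} A^{-1/2} 11^T A^{-1/2}.

    ``r`` may be a vector (n,) or a matrix (n, k) of right-hand sides.
    """
    r = np.asarray(r, dtype=float)
    a = np.asarray(a, dtype=float)
    n = r.shape[0]
    if (n > 1 and rho <= -1.0 / (n - 1)) or rho >= 1.0:
        raise ValueError(
            f"rho={rho} outside (-1/(n-1), 1) leaves R not positive definite; "
            "truncate rho upstream")
    sqa = np.sqrt(a)
    z = (r.T / sqa).T  # A^{-1/2} r
    denom = (1.0 - rho) * (1.0 - rho + n * rho)
    w = z / (1.0 - rho) - (rho / denom) * z.sum(axis=0, keepdims=True)
    return (w.T / sqa).T


def apply_inverse_ar1(r: np.ndarray, rho: float, a: np.ndarray) -> np.ndarray:
    """V(s)^{-1} r for AR(1) correlation via a Toeplitz (Levinson) solve.

    The correlation matrix has entries rho^{|j-j'|}; the n x n matrix is
    never formed densely. Requires rho in [0, 1).
    """
    r = np.asarray(r, dtype=float)
    a = np.asarray(a, dtype=float)
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"AR1 requires rho in [0, 1); got {rho}")
    n = r.shape[0]
    sqa = np.sqrt(a)
    z = (r.T / sqa).T
    if rho == 0.0 or n == 1:
        w = z
    else:
        col = rho ** np.arange(n)
        w = solve_toeplitz(col, z)
    return (w.T / sqa).T


def _apply_rinv_grouped(Z: np.ndarray, kind: str, rho_s: float) -> np.ndarray:
    """R(s)^{-1} Z for a stack of clusters with equal n: Z is (G, n, c)."""
    if kind == "independence" or rho_s == 0.0:
        return Z
    G, n, c = Z.shape
    if kind == "exchangeable":
        if n > 1 and rho_s <= -1.0 / (n - 1):
            raise ValueError(
                f"rho={rho_s} <= -1/(n-1) leaves R not positive definite; "
                "truncate rho upstream")
        denom = (1.0 - rho_s) * (1.0 - rho_s + n * rho_s)
        return Z / (1.0 - rho_s) - (rho_s / denom) * Z.sum(axis=1, keepdims=True)
    # ar1
    if not 0.0 <= rho_s < 1.0:
        raise ValueError(f"AR1 requires rho in [0, 1); got {rho_s}")
    col = rho_s ** np.arange(n)
    flat = Z.transpose(1, 0, 2).reshape(n, G * c)
    out = solve_toeplitz(col, flat)
    return out.reshape(n, G, c).transpose(1, 0, 2)


def cluster_summaries(dataset, basis: BasisSystem, theta, cov: WorkingCovModel,
                      family=None, stats=None):
    """Per-cluster quadratic forms W_i = D_i^T V_i^{-1} D_i and scores
    b_i = D_i^T V_i^{-1} (Y_i - mu_i), exploiting the block structure over s.

    D_i(s) has rows dmu(eta_{ij}(s)) * [B(s), X_{ij,1} B(s), ...], which
    factors as a row-wise Kronecker of a small n_i x (q+1) matrix with B(s);
    each W_i(s) is therefore a (q+1)x(q+1) quadratic form Kronecker the
    m x m outer product B(s) B(s)^T. Cost is O(L (n_i (q+1)^2 + solve)) per
    cluster with O(n_i (q+2)) working memory per point.

    Returns ``(W, b)`` with shapes (N, p, p) and (N, p).
    """
    if stats is None:
        stats = residual_stats(dataset, basis, theta, family)
    C = dataset.covariate_tensor()
    dmu, resid = stats["dmu"], stats["resid"]
    # independence keeps the bare variance function (standard GLM weighting);
    # correlated structures carry the per-point dispersion into A(s)
    if cov.kind == "independence":
        a = stats["var"]
    else:
        a = stats["var"] * stats["phi"][None, :]
    n = dataset.n
    offsets = dataset.offsets
    N, L, q1 = dataset.N, dataset.L, dataset.q + 1
    rho = cov.rho_at(L)

    # group clusters by size so each grid point needs one solve per group
    groups: list[tuple[int, np.ndarray, np.ndarray]] = []
    for size in np.unique(n):
        idx = np.where(n == size)[0]
        rows = np.concatenate(
            [np.arange(offsets[i], offsets[i + 1]) for i in idx])
        groups.append((int(size), idx, rows))

    K = np.zeros((N, L, q1, q1))
    gvec = np.zeros((N, L, q1))
    c = q1 + 1
    for s in range(L):
        G = dmu[:, s][:, None] * C[:, :, s]              # (M, q+1)
        Z = np.concatenate([G, resid[:, s][:, None]], axis=1)
        Zs = Z / np.sqrt(a[:, s])[:, None]
        for size, idx, rows in groups:
            block = Zs[rows].reshape(len(idx), size, c)
            U = _apply_rinv_grouped(block, cov.kind, float(rho[s]))
            quad = np.einsum("gnc,gnd->gcd", block, U)
            K[idx, s] = quad[:, :q1, :q1]
            gvec[idx, s] = quad[:, :q1, -1]

    B = basis.B
    m = basis.m
    W = np.einsum("ilab,lc,ld->iacbd", K, B, B).reshape(N, q1 * m, q1 * m)
    b = np.einsum("ila,lc->iac", gvec, B).reshape(N, q1 * m)
    return W, b


# convenience field mirroring the rho truncation default used across the package
DEFAULT_RHO_EPS = 1e-3
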