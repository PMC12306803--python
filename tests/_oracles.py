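"""Independent dense-linear-algebra oracles used to cross-check the fast paths.

Everything here assembles the full n_i L x n_i L working covariance and the
stacked derivative matrices directly from their definitions (s-major row
order), deliberately avoiding the package's blockwise shortcuts.
"""

import numpy as np
from scipy.linalg import block_diag

from fgee.families import get_family
from fgee.working_cov import residual_stats


def correlation_matrix(kind: str, rho: float, n: int) -> np.ndarray:
    if kind == "independence":
        return np.eye(n)
    if kind == "exchangeable":
        return (1.0 - rho) * np.eye(n) + rho * np.ones((n, n))
    if kind == "ar1":
        idx = np.arange(n)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    raise ValueError(kind)


def dense_cluster_matrices(dataset, basis, theta, cov, i: int,
                           use_dispersion: bool | None = None):
    """Dense D_i, V_i and the s-major stacked residual for cluster i."""
    fam = get_family(dataset.family)
    stats = residual_stats(dataset, basis, theta, fam)
    if use_dispersion is None:
        use_dispersion = cov.kind != "independence"
    phi = stats["phi"] if use_dispersion else np.ones(dataset.L)
    rho = cov.rho_at(dataset.L)
    rows = dataset.cluster_rows(i)
    C = dataset.covariate_tensor()[rows]
    dmu = stats["dmu"][rows]
    var = stats["var"][rows]
    resid = stats["resid"][rows]
    n_i = dataset.n[i]
    B = basis.B
    p = basis.m * (dataset.q + 1)

    D_blocks, V_blocks, r_parts = [], [], []
    for s in range(dataset.L):
        G = dmu[:, s][:, None] * C[:, :, s]             # (n_i, q+1)
        D_blocks.append(np.einsum("ja,c->jac", G, B[s]).reshape(n_i, p))
        a = phi[s] * var[:, s]
        R = correlation_matrix(cov.kind, float(rho[s]), n_i)
        V_blocks.append(np.sqrt(a)[:, None] * R * np.sqrt(a)[None, :])
        r_parts.append(resid[:, s])
    D = np.vstack(D_blocks)
    V = block_diag(*V_blocks)
    r = np.concatenate(r_parts)
    return D, V, r


def dense_summaries(dataset, basis, theta, cov, use_dispersion=None):
    """Oracle W_i, b_i via explicit dense assembly for every cluster."""
    Ws, bs = [], []
    for i in range(dataset.N):
        D, V, r = dense_cluster_matrices(dataset, basis, theta, cov, i,
                                         use_dispersion)
        Vinv = np.linalg.inv(V)
        Ws.append(D.T @ Vinv @ D)
        bs.append(D.T @ Vinv @ r)
    return np.array(Ws), np.array(bs)
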