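"""Synthetic longitudinal functional data generators and replication studies.

Two designs are provided. The Gaussian design ("sim1") has outcome

    Y_ij(s) = beta0(s) + X1_i beta1(s) + X2_ij beta2(s) + W_ij(s) + eps_ij(s)

with W_ij(s) = sum_k (xi_ik + zeta_ijk) psi_k(s) built from two orthonormal
functional principal components (psi1 = 1, psi2 = sqrt(2) sin(2 pi s)), so
outcomes are correlated in both the longitudinal and functional directions
(exchangeable across j at each s through the cluster-level scores xi).

The binary design ("sim2") has logit E[Y_ij(s) | X] = beta0(s) + X1_i beta1(s)
+ X2_ij beta2(s); within each (cluster, grid point) the outcomes are
correlated across j through a latent Gaussian AR(1) copula with lag-1
correlation rho, which leaves the marginal success probabilities exactly
expit(eta). The binary-scale correlation is not exactly rho^|j-j'| (the
latent correlation is).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .benchmarks import fit_gls, fosr_sandwich
from .data import FunctionalDataset
from .model import FunctionalGEE

__all__ = [
    "Sim1Config", "Sim2Config", "sim1_coefficients", "sim2_coefficients",
    "gen_sim1", "gen_sim2", "true_coefficients", "run_replicates",
    "summarize_replicates",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coefficient functions
# ---------------------------------------------------------------------------

def _phi(x):
    """Standard normal density."""
    return norm.pdf(x)


def sim1_coefficients(s):
    """True coefficient curves of the Gaussian design on s in [0, 1]."""
    s = np.asarray(s, dtype=float)
    b0 = 3.0 + np.sin(np.pi * s) + 2.0 * np.cos(3.0 * np.pi * s)
    b1 = 3.0 + np.cos(2.0 * np.pi * s) + 2.0 * np.cos(3.0 * np.pi * s)
    b2 = ((_phi((s - 0.2) / 0.1) + _phi((s - 0.1) / 0.07)) / 60.0
          - _phi((s - 0.35) / 0.1) / 200.0
          - _phi((s - 0.65) / 0.06) / 250.0)
    return b0, b1, b2


def sim2_coefficients(s):
    """True coefficient curves of the binary design on s in [0, 1]."""
    s = np.asarray(s, dtype=float)
    b0 = 1.0 + np.sin(np.pi * s) / 3.0 + 2.0 * np.cos(3.0 * np.pi * s) / 3.0
    b1 = 1.0 + np.cos(2.0 * np.pi * s) / 3.0 + 2.0 * np.cos(3.0 * np.pi * s) / 3.0
    b2 = (5.0 / 3.0) * (_phi((s - 0.35) / 0.1) - _phi((s - 0.65) / 0.2))
    return b0, b1, b2


def true_coefficients(design: str, s) -> np.ndarray:
    """(3, L) array of true curves for a design tag."""
    fn = sim1_coefficients if design == "sim1" else sim2_coefficients
    return np.stack(fn(s))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

@dataclass
class Sim1Config:
    """Gaussian design parameters (variances, not standard deviations)."""

    N: int = 50
    n_i: int = 25
    L: int = 100
    alpha: float = 0.7           # AR coefficient of the X2 covariate noise
    var_xi: tuple = (3.0, 2.0)   # cluster-level FPC score variances
    var_zeta: tuple = (1.5, 1.0)  # observation-level FPC score variances
    var_eps: float = 1.5         # white-noise variance
    seed: int | None = None


@dataclass
class Sim2Config:
    """Binary design parameters."""

    N: int = 50
    n_i: int = 25
    L: int = 100
    rho: float = 0.5             # latent AR(1) lag-1 correlation across j
    alpha: float = 0.7
    seed: int | None = None


def _covariates(rng, N: int, n_i: int, alpha: float):
    """X1_i ~ N(0,1); X2_ij = j + e_ij with e an AR(1), e_i0 = 0."""
    x1 = rng.standard_normal(N)
    innov = rng.standard_normal((N, n_i))
    e = np.zeros((N, n_i))
    prev = np.zeros(N)
    for j in range(n_i):
        prev = alpha * prev + innov[:, j]
        e[:, j] = prev
    x2 = np.arange(1, n_i + 1)[None, :] + e
    return x1, x2


def _fpc_basis(s):
    return np.ones_like(s), np.sqrt(2.0) * np.sin(2.0 * np.pi * s)


def gen_sim1(config: Sim1Config) -> FunctionalDataset:
    """Generate one Gaussian-design dataset (deterministic under seed)."""
    rng = np.random.default_rng(config.seed)
    N, n_i, L = config.N, config.n_i, config.L
    s = np.linspace(0.0, 1.0, L)
    b0, b1, b2 = sim1_coefficients(s)
    x1, x2 = _covariates(rng, N, n_i, config.alpha)

    psi1, psi2 = _fpc_basis(s)
    sd_xi = np.sqrt(config.var_xi)
    sd_zeta = np.sqrt(config.var_zeta)
    xi = rng.standard_normal((N, 2)) * sd_xi[None, :]
    zeta = rng.standard_normal((N, n_i, 2)) * sd_zeta[None, None, :]
    eps = rng.standard_normal((N, n_i, L)) * np.sqrt(config.var_eps)

    scores = xi[:, None, :] + zeta                     # (N, n_i, 2)
    W = scores[..., 0, None] * psi1[None, None, :] \
        + scores[..., 1, None] * psi2[None, None, :]
    mean = (b0[None, None, :]
            + x1[:, None, None] * b1[None, None, :]
            + x2[:, :, None] * b2[None, None, :])
    Y = (mean + W + eps).reshape(N * n_i, L)

    X = np.empty((N * n_i, 2))
    X[:, 0] = np.repeat(x1, n_i)
    X[:, 1] = x2.ravel()
    return FunctionalDataset(
        grid=s, cluster_ids=np.arange(N), n=np.full(N, n_i), Y=Y, X=X,
        family="gaussian", covariate_names=["x1", "x2"])


def gen_sim2(config: Sim2Config) -> FunctionalDataset:
    """Generate one binary-design dataset via the latent AR(1) Gaussian copula.

    X2 is centered and scaled to unit sample variance before entering the
    linear predictor so the logits stay in a numerically sane range for large
    cluster sizes.
    """
    if not 0.0 <= config.rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(config.seed)
    N, n_i, L = config.N, config.n_i, config.L
    s = np.linspace(0.0, 1.0, L)
    b0, b1, b2 = sim2_coefficients(s)
    x1, x2raw = _covariates(rng, N, n_i, config.alpha)
    x2 = (x2raw - x2raw.mean()) / x2raw.std()

    eta = (b0[None, None, :]
           + x1[:, None, None] * b1[None, None, :]
           + x2[:, :, None] * b2[None, None, :])
    prob = 1.0 / (1.0 + np.exp(-eta))

    # latent standard-normal AR(1) across j, independent across (i, s)
    rho = config.rho
    innov = rng.standard_normal((N, n_i, L))
    z = np.empty((N, n_i, L))
    z[:, 0, :] = innov[:, 0, :]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, n_i):
        z[:, j, :] = rho * z[:, j - 1, :] + scale * innov[:, j, :]
    u = norm.cdf(z)
    Y = (u <= prob).astype(float).reshape(N * n_i, L)

    X = np.empty((N * n_i, 2))
    X[:, 0] = np.repeat(x1, n_i)
    X[:, 1] = x2.ravel()
    return FunctionalDataset(
        grid=s, cluster_ids=np.arange(N), n=np.full(N, n_i), Y=Y, X=X,
        family="binomial", covariate_names=["x1", "x2"])


def generate(design: str, N: int, n_i: int, seed=None, rho: float = 0.5,
             L: int = 100) -> FunctionalDataset:
    """Generate a dataset for a design tag."""
    if design == "sim1":
        return gen_sim1(Sim1Config(N=N, n_i=n_i, L=L, seed=seed))
    if design == "sim2":
        return gen_sim2(Sim2Config(N=N, n_i=n_i, L=L, rho=rho, seed=seed))
    raise ValueError("design must be 'sim1' or 'sim2'")


# ---------------------------------------------------------------------------
# replication studies
# ---------------------------------------------------------------------------

class _OracleResults:
    """Truth-returning pseudo-estimator used to validate the metric code."""

    def __init__(self, truth, grid):
        self._truth = truth
        self._grid = grid

    def coef_curves(self):
        return self._truth

    def se_curves(self):
        return np.ones_like(self._truth)

    def conf_int(self, alpha=0.05):
        from .inference import pointwise_ci
        return pointwise_ci(self._truth, self.se_curves(), alpha)

    def conf_band(self, alpha=0.05, **kw):
        ci = self.conf_int(alpha)
        return {"lower": ci[:, :, 0], "upper": ci[:, :, 1],
                "qtilde": np.full(self._truth.shape[0], np.nan)}


def _default_corstr(design: str) -> str:
    return "exchangeable" if design == "sim1" else "ar1"


def _fit_one(name: str, dataset, design: str, seed, K: int, m: int,
             truth: np.ndarray):
    if name == "onestep":
        return FunctionalGEE(dataset, corstr=_default_corstr(design), m=m).fit(
            seed=seed, K=K)
    if name.startswith("onestep-"):
        return FunctionalGEE(dataset, corstr=name.split("-", 1)[1], m=m).fit(
            seed=seed, K=K)
    if name == "fosr":
        return fosr_sandwich(dataset, m=m)
    if name == "gls-ex":
        return fit_gls(dataset, "exchangeable", m=m, K=K, seed=seed)
    if name == "gls-ind":
        return fit_gls(dataset, "independence", m=m, K=K, seed=seed)
    if name == "oracle":
        return _OracleResults(truth, dataset.grid)
    raise ValueError(f"unknown estimator {name!r}")


def run_replicates(design: str, estimators=("onestep", "fosr"), R: int = 100,
                   seed: int = 0, N: int = 50, n_i: int = 25,
                   rho: float = 0.5, L: int = 100, m: int = 13, K: int = 10,
                   alpha: float = 0.05, T_joint: int = 1000,
                   joint: bool = True) -> pd.DataFrame:
    """Monte Carlo replication study of the estimators on a design.

    For each replicate t (dataset seed = ``seed + t``) and estimator, records
    the per-replicate RMSE over all coefficients and grid points,

        RMSE_t = sqrt( mean_{r,s} (beta_r(s) - betahat_r^t(s))^2 ),

    the pointwise CI coverage fraction over (r, s), and the joint-band
    full-curve coverage fraction over r. Failed fits are logged and excluded
    (count reported in ``df.attrs["excluded"]``).
    """
    rows = []
    excluded = 0
    for t in range(R):
        ds_seed = seed + t
        dataset = generate(design, N=N, n_i=n_i, seed=ds_seed, rho=rho, L=L)
        truth = true_coefficients(design, dataset.grid)
        rng = np.random.default_rng(np.random.SeedSequence([seed, t, 977]))
        for name in estimators:
            fit_seed = int(rng.integers(2 ** 31))
            band_seed = int(rng.integers(2 ** 31))
            try:
                res = _fit_one(name, dataset, design, fit_seed, K, m, truth)
                beta = res.coef_curves()
                ci = res.conf_int(alpha)
                covered = (ci[:, :, 0] <= truth) & (truth <= ci[:, :, 1])
                rec = {
                    "replicate": t, "estimator": name,
                    "rmse": float(np.sqrt(np.mean((beta - truth) ** 2))),
                    "pointwise": float(covered.mean()),
                }
                if joint:
                    band = res.conf_band(alpha=alpha, T=T_joint,
                                         seed=band_seed)
                    inside = ((band["lower"] <= truth)
                              & (truth <= band["upper"])).all(axis=1)
                    rec["joint"] = float(inside.mean())
                rows.append(rec)
            except Exception:  # noqa: BLE001 - a replicate may fail, log it
                logger.exception("estimator %s failed on replicate %d", name, t)
                excluded += 1
    df = pd.DataFrame(rows)
    df.attrs["excluded"] = excluded
    df.attrs["config"] = {"design": design, "R": R, "seed": seed, "N": N,
                          "n_i": n_i, "rho": rho, "L": L}
    return df


def summarize_replicates(df: pd.DataFrame, reference: str = "fosr") -> pd.DataFrame:
    """Aggregate a replicate table: mean RMSE, coverage, and RMSE ratios.

    The RMSE ratio of an estimator against ``reference`` is the mean of the
    per-replicate ratios (an estimator against itself gives exactly 1).
    """
    agg = df.groupby("estimator").agg(
        rmse=("rmse", "mean"),
        pointwise=("pointwise", "mean"),
        **({"joint": ("joint", "mean")} if "joint" in df.columns else {}),
    )
    if reference in df["estimator"].unique():
        wide = df.pivot(index="replicate", columns="estimator", values="rmse")
        ratios = wide.div(wide[reference], axis=0).mean(axis=0)
        agg["rmse_ratio"] = ratios
    else:
        warnings.warn(f"reference estimator {reference!r} absent; no ratios")
    return agg
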