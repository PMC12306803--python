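"""One-step penalized functional GEE: model and results objects.

The estimator proceeds in two passes. A penalized working-independence
function-on-scalar regression (penalized IRLS with GCV-selected smoothing
parameters Lambda0) gives a consistent initial estimate theta0. A single
Newton-Raphson update of the penalized estimating equation with an
exchangeable or AR(1) working correlation,

    theta1 = theta0 + (W_bar + Lambda1 S)^{-1} (b_bar - Lambda1 S theta0),

with W_bar = N^{-1} sum_i D_i^T V_i^{-1} D_i and
b_bar = N^{-1} sum_i D_i^T V_i^{-1} (Y_i - mu_i) evaluated at theta0, is
asymptotically as efficient as the fully iterated fit. Lambda1 is tuned by a
fast K-fold cluster cross-validation that re-uses the full-sample Hessian
across folds, so the entire CV pass needs exactly one p x p factorization per
candidate Lambda1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from . import inference
from .basis import BasisSystem, build_basis, coef_curves
from .data import FunctionalDataset
from .families import get_family
from .working_cov import WorkingCovModel, cluster_summaries, residual_stats

__all__ = [
    "FunctionalGEE", "FGEEResults", "fit_initial", "one_step_update",
    "make_folds", "fold_estimate", "cv_score", "tune_lambda1",
    "inversion_counter",
]


class InversionCounter:
    """Counts p x p Hessian factorizations (efficiency instrumentation)."""

    def __init__(self):
        self.count = 0

    def reset(self):
        self.count = 0

    def bump(self):
        self.count += 1


inversion_counter = InversionCounter()


def _penalty(S_block: np.ndarray, lam, q1: int) -> np.ndarray:
    """Block-diagonal Lambda S with lam_r scaling block r."""
    lam = np.asarray(lam, dtype=float)
    m = S_block.shape[0]
    P = np.zeros((q1 * m, q1 * m))
    for r in range(q1):
        sl = slice(r * m, (r + 1) * m)
        P[sl, sl] = lam[r] * S_block
    return P


def _factor(H: np.ndarray):
    inversion_counter.bump()
    try:
        return cho_factor(H, lower=True)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "penalized Hessian is singular; increase the smoothing parameters "
            "or reduce the number of basis functions") from err


# ---------------------------------------------------------------------------
# initial working-independence fit (penalized IRLS with GCV)
# ---------------------------------------------------------------------------

def _irls_arrays(dataset, basis, C, theta, fam):
    """Working weights/response for one IRLS step at theta (canonical links)."""
    beta = coef_curves(basis, theta)
    eta = np.einsum("mal,al->ml", C, beta)
    mu = fam.inverse_link(eta)
    dmu = np.maximum(fam.dmu_deta(eta), 1e-10)
    v = fam.variance(fam.clamp_mu(mu))
    w = dmu * dmu / v
    z = eta + (dataset.Y - mu) / dmu
    return w, z, mu


def _normal_equations(C, B, w, z):
    """X^T W X, X^T W z and z^T W z via the Kronecker row structure."""
    q1 = C.shape[1]
    m = B.shape[1]
    Ml = np.einsum("ml,mal,mbl->lab", w, C, C)
    XtWX = np.einsum("lab,lc,ld->acbd", Ml, B, B).reshape(q1 * m, q1 * m)
    XtWz = np.einsum("ml,mal,lc->ac", w * z, C, B).reshape(q1 * m)
    zWz = float(np.sum(w * z * z))
    return XtWX, XtWz, zWz


def _gcv_select(XtWX, XtWz, zWz, S_block, q1, n_points, lam,
                n_grid=17, sweeps=2):
    """Coordinate-descent GCV over a log grid, one lambda per coefficient."""
    m = S_block.shape[0]
    ref = np.trace(XtWX) / max(np.trace(S_block) * q1, 1e-12)
    grid = ref * np.logspace(-8.0, 8.0, n_grid)

    def gcv(lam_vec):
        H = XtWX + _penalty(S_block, lam_vec, q1)
        try:
            cf = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, None
        theta = cho_solve(cf, XtWz)
        edf = float(np.trace(cho_solve(cf, XtWX)))
        rss = zWz - 2.0 * theta @ XtWz + theta @ (XtWX @ theta)
        denom = max(n_points - edf, 1.0)
        return n_points * max(rss, 0.0) / denom ** 2, theta

    lam = np.asarray(lam, dtype=float).copy()
    for _ in range(sweeps):
        for r in range(q1):
            best_score, best_val = np.inf, lam[r]
            for val in grid:
                trial = lam.copy()
                trial[r] = val
                score, _ = gcv(trial)
                if score < best_score or (score == best_score and val > best_val):
                    best_score, best_val = score, val
            lam[r] = best_val
    _, theta = gcv(lam)
    return lam, theta


def fit_initial(dataset: FunctionalDataset, basis: BasisSystem,
                lambda0="auto", max_iter: int = 100, tol: float = 1e-8):
    """Penalized working-independence fit (the FoSR initial estimate).

    Solves sum_i X_i^T (Y_i - mu_i) = Lambda0 S theta by penalized IRLS.
    With ``lambda0="auto"`` each coefficient's smoothing parameter is chosen
    by GCV on the working linearized problem within the performance
    iteration (re-selected during the first iterations, then frozen).

    Returns ``(theta0, lambda0_vec, n_iter)``.
    """
    fam = get_family(dataset.family)
    C = dataset.covariate_tensor()
    B = basis.B
    q1 = dataset.q + 1
    p = q1 * basis.m
    n_points = dataset.Y.size
    auto = isinstance(lambda0, str) and lambda0 == "auto"
    lam = np.ones(q1) if auto else np.asarray(lambda0, dtype=float) * np.ones(q1)

    theta = np.zeros(p)
    dev_prev = np.inf
    for it in range(1, max_iter + 1):
        w, z, _ = _irls_arrays(dataset, basis, C, theta, fam)
        XtWX, XtWz, zWz = _normal_equations(C, B, w, z)
        if auto and it <= 5:
            lam, theta_new = _gcv_select(XtWX, XtWz, zWz, basis.S_block,
                                         q1, n_points, lam)
        else:
            H = XtWX + _penalty(basis.S_block, lam, q1)
            theta_new = cho_solve(cho_factor(H, lower=True), XtWz)
        # step-halving against divergence of the working deviance
        step = 1.0
        for _ in range(20):
            cand = theta + step * (theta_new - theta)
            beta = coef_curves(basis, cand)
            mu = fam.inverse_link(np.einsum("mal,al->ml", C, beta))
            dev = float(np.sum(fam.neg_loglik(dataset.Y, mu)))
            if np.isfinite(dev):
                break
            step *= 0.5
        else:
            raise RuntimeError("IRLS diverged: non-finite deviance persisted "
                               "through step-halving")
        delta = np.linalg.norm(cand - theta) / (1.0 + np.linalg.norm(theta))
        theta, dev_prev = cand, dev
        if delta < tol and (not auto or it > 5):
            break
    return theta, lam, it


# ---------------------------------------------------------------------------
# one-step update and fast K-fold cluster CV
# ---------------------------------------------------------------------------

def one_step_update(theta0, W, b, lam1, S_block, return_factor=False):
    """Single Newton step from theta0 using precomputed cluster summaries.

    theta1 = theta0 + (mean(W_i) + Lambda1 S)^{-1} (mean(b_i) - Lambda1 S theta0)
    with exactly one p x p factorization.
    """
    theta0 = np.asarray(theta0, dtype=float)
    q1 = theta0.size // S_block.shape[0]
    P = _penalty(S_block, lam1, q1)
    H = W.mean(axis=0) + P
    cf = _factor(H)
    theta1 = theta0 + cho_solve(cf, b.mean(axis=0) - P @ theta0)
    if return_factor:
        return theta1, cf, P
    return theta1


def make_folds(N: int, K: int, rng) -> list[np.ndarray]:
    """Random partition of cluster indices into K folds of near-equal size."""
    if K > N:
        raise ValueError(f"K={K} folds exceed N={N} clusters")
    if K < 2:
        raise ValueError("K must be at least 2")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(N)
    return [np.sort(part) for part in np.array_split(perm, K)]


def fold_estimate(theta0, cf, P, b, n, fold) -> np.ndarray:
    """Fold-k one-step estimate re-using the full-sample Hessian factor.

    Uses the held-in score N^{-1} sum_{i not in fold} ntilde_k b_i with
    ntilde_k = sum_i n_i / sum_{i not in fold} n_i, so an empty fold
    reduces exactly to the full one-step estimate.
    """
    N = b.shape[0]
    mask = np.ones(N, dtype=bool)
    mask[np.asarray(fold, dtype=int)] = False
    if not mask.any():
        raise ValueError("fold leaves no held-in clusters")
    ntilde = float(n.sum()) / float(n[mask].sum())
    score = ntilde * b[mask].sum(axis=0) / N - P @ theta0
    return theta0 + cho_solve(cf, score)


def cv_score(dataset, basis, theta, fold, family=None) -> float:
    """Mean negative working log-likelihood on held-out clusters."""
    fam = get_family(family or dataset.family)
    offsets = dataset.offsets
    rows = np.concatenate(
        [np.arange(offsets[i], offsets[i + 1]) for i in np.asarray(fold)])
    C = dataset.covariate_tensor()[rows]
    beta = coef_curves(basis, theta)
    mu = fam.inverse_link(np.einsum("mal,al->ml", C, beta))
    return float(np.mean(fam.neg_loglik(dataset.Y[rows], mu)))


def tune_lambda1(dataset, basis, theta0, W, b, anchor, K: int = 10,
                 seed=None, n_grid: int = 15, grid_span=(-4.0, 4.0),
                 coordinate_sweeps: int = 2):
    """Two-stage fast K-fold cluster CV for the one-step smoothing parameters.

    Stage 1 searches a shared multiplier c on the anchor vector over a
    log-spaced grid (default 15 points spanning 1e-4..1e4); stage 2 refines
    each coefficient's lambda_r by local 3-point coordinate moves (at most
    ``coordinate_sweeps`` sweeps). Ties break toward the larger (smoother)
    lambda. Each candidate costs exactly one p x p factorization; the fold
    estimates share it.

    Returns ``(lambda1, cv_table)`` where cv_table records candidate scores.
    """
    rng = np.random.default_rng(seed)
    folds = make_folds(dataset.N, K, rng)
    anchor = np.asarray(anchor, dtype=float)
    n = dataset.n
    records = []

    def evaluate(lam_vec):
        P = _penalty(basis.S_block, lam_vec, dataset.q + 1)
        H = W.mean(axis=0) + P
        cf = _factor(H)
        scores = [cv_score(dataset, basis,
                           fold_estimate(theta0, cf, P, b, n, fold), fold)
                  for fold in folds]
        return float(np.mean(scores))

    # stage 1: shared multiplier
    cs = np.logspace(grid_span[0], grid_span[1], n_grid)
    stage1 = []
    for c in cs:
        score = evaluate(c * anchor)
        stage1.append(score)
        records.append({"stage": 1, "multiplier": c, "score": score})
    stage1 = np.asarray(stage1)
    if stage1.max() - stage1.min() <= 1e-12 * (abs(stage1.min()) + 1.0):
        warnings.warn("flat CV profile; returning the smoothest candidate",
                      stacklevel=2)
    best = np.flatnonzero(stage1 == stage1.min()).max()  # ties -> larger c
    lam = cs[best] * anchor
    best_score = stage1[best]

    # stage 2: per-coefficient local refinement
    moves = (10.0 ** -0.5, 1.0, 10.0 ** 0.5)
    for _ in range(coordinate_sweeps):
        improved = False
        for r in range(dataset.q + 1):
            cand_scores = []
            for f in moves:
                trial = lam.copy()
                trial[r] = lam[r] * f
                score = best_score if f == 1.0 else evaluate(trial)
                cand_scores.append((score, trial[r]))
                records.append({"stage": 2, "coef": r, "lambda_r": trial[r],
                                "score": score})
            score_best = min(s for s, _ in cand_scores)
            # among ties prefer the larger lambda
            val = max(v for s, v in cand_scores if s == score_best)
            if val != lam[r]:
                improved = True
            lam[r] = val
            best_score = score_best
        if not improved:
            break
    return lam, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class FunctionalGEE:
    """Marginal function-on-scalar regression fit by one-step penalized GEE.

    Parameters
    ----------
    dataset : FunctionalDataset
        Long-format clustered functional data (see :mod:`fgee.data`).
    corstr : {"independence", "exchangeable", "ar1"}
        Working longitudinal correlation at each grid point.
    m, spline_order, diff_order :
        B-spline basis dimension per coefficient (default 13, i.e. cubic
        splines on ten uniform knots spanning the domain) and the order of
        the difference penalty.
    smooth_rho : bool
        Apply a running-mean smoother to rho(s) over the functional domain.
    rho_eps : float
        Truncation bound keeping rho(s) inside the valid range.
    """

    def __init__(self, dataset: FunctionalDataset, corstr: str = "exchangeable",
                 m: int = 13, spline_order: int = 4, diff_order: int = 2,
                 smooth_rho: bool = False, rho_eps: float = 1e-3):
        self.data = dataset
        self.family = get_family(dataset.family)
        self.corstr = corstr
        self.basis = build_basis(dataset.grid, m=m, order=spline_order,
                                 diff_order=diff_order)
        self.smooth_rho = smooth_rho
        self.rho_eps = rho_eps

    @classmethod
    def from_dataframe(cls, df, family, cluster="cluster", obs="obs", arg="s",
                       outcome="y", covariates=None, **kwargs):
        ds = FunctionalDataset.from_long(df, family=family, cluster=cluster,
                                         obs=obs, arg=arg, outcome=outcome,
                                         covariates=covariates)
        return cls(ds, **kwargs)

    @property
    def p(self) -> int:
        return self.basis.m * (self.data.q + 1)

    def _cov_model(self) -> WorkingCovModel:
        return WorkingCovModel(kind=self.corstr, eps=self.rho_eps,
                               smooth=self.smooth_rho)

    def fit(self, lambda0="auto", lambda1="cv", K: int = 10, seed=None,
            variance: str = "sandwich") -> "FGEEResults":
        """Run the full one-step pipeline and return a results object.

        Parameters
        ----------
        lambda0 : "auto" (GCV) or per-coefficient values for the initial fit.
        lambda1 : "cv" (fast K-fold cluster CV), "initial" (carry the
            initial-fit smoothing over, rescaled to the one-step's
            normalization), or explicit per-coefficient values.
        K : folds for the CV tuning.
        seed : seed for fold assignment (and any downstream resampling).
        variance : "sandwich" (default) or "none".
        """
        data, basis = self.data, self.basis
        theta0, lam0, n_iter = fit_initial(data, basis, lambda0=lambda0)

        stats0 = residual_stats(data, basis, theta0, self.family)
        cov0 = self._cov_model().estimate(stats0["e_std"], data.n)
        W, b = cluster_summaries(data, basis, theta0, cov0, stats=stats0)

        # anchor Lambda1 at the initial-fit scale translated to the
        # N-normalized, dispersion-weighted one-step estimating equation
        anchor = lam0 / (data.N * float(np.mean(stats0["phi"])))
        anchor = np.maximum(anchor, 1e-12)
        cv_table = None
        if isinstance(lambda1, str) and lambda1 == "cv":
            lam1, cv_table = tune_lambda1(data, basis, theta0, W, b, anchor,
                                          K=K, seed=seed)
        elif isinstance(lambda1, str) and lambda1 == "initial":
            lam1 = anchor
        else:
            lam1 = np.asarray(lambda1, dtype=float) * np.ones(data.q + 1)

        theta1 = one_step_update(theta0, W, b, lam1, basis.S_block)

        # second rho pass at theta1 for the variance estimate
        stats1 = residual_stats(data, basis, theta1, self.family)
        cov1 = self._cov_model().estimate(stats1["e_std"], data.n)
        W1, b1 = cluster_summaries(data, basis, theta1, cov1, stats=stats1)
        P1 = _penalty(basis.S_block, lam1, data.q + 1)
        cov_theta = None
        if variance == "sandwich":
            cov_theta = inference.sandwich_from_summaries(W1, b1, P1, theta1)

        return FGEEResults(
            model=self, theta=theta1, theta_initial=theta0,
            lambda0=lam0, lambda1=np.asarray(lam1, dtype=float),
            rho_initial=cov0.rho_at(data.L), rho_final=cov1.rho_at(data.L),
            phi=stats1["phi"], cov_theta=cov_theta,
            summaries=(W, b), cv_table=cv_table,
            diagnostics={"irls_iterations": n_iter,
                         "corstr": self.corstr, "seed": seed},
        )


@dataclass
class FGEEResults:
    """Fitted one-step functional GEE: estimates, uncertainty, diagnostics."""

    model: FunctionalGEE
    theta: np.ndarray
    theta_initial: np.ndarray
    lambda0: np.ndarray
    lambda1: np.ndarray
    rho_initial: np.ndarray
    rho_final: np.ndarray
    phi: np.ndarray
    cov_theta: np.ndarray | None
    summaries: tuple = field(repr=False, default=None)
    cv_table: pd.DataFrame | None = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict)
    _joint_band: dict | None = field(default=None, repr=False)

    # -- point estimates ----------------------------------------------------
    @property
    def basis(self) -> BasisSystem:
        return self.model.basis

    @property
    def coef_names(self) -> list[str]:
        names = self.model.data.covariate_names or [
            f"x{r + 1}" for r in range(self.model.data.q)]
        return ["intercept"] + list(names)

    def coef_curves(self) -> np.ndarray:
        """(q+1, L) fitted coefficient curves beta_r(s) = B theta_r."""
        return coef_curves(self.basis, self.theta)

    def se_curves(self) -> np.ndarray:
        """(q+1, L) pointwise standard errors of the coefficient curves."""
        if self.cov_theta is None:
            raise ValueError("fit was run without a variance estimate")
        m, B = self.basis.m, self.basis.B
        q1 = self.model.data.q + 1
        se = np.empty((q1, B.shape[0]))
        for r in range(q1):
            Sg = self.cov_theta[r * m:(r + 1) * m, r * m:(r + 1) * m]
            se[r] = np.sqrt(np.maximum(np.einsum("lc,cd,ld->l", B, Sg, B), 0.0))
        return se

    def coef_cov_blocks(self) -> list[np.ndarray]:
        """Per-coefficient m x m covariance blocks of theta-hat."""
        m = self.basis.m
        q1 = self.model.data.q + 1
        return [self.cov_theta[r * m:(r + 1) * m, r * m:(r + 1) * m]
                for r in range(q1)]

    # -- inference ----------------------------------------------------------
    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Pointwise normal CIs; shape (q+1, L, 2)."""
        return inference.pointwise_ci(self.coef_curves(), self.se_curves(), alpha)

    def conf_band(self, alpha: float = 0.05, T: int = 1000,
                  mode: str = "parametric", seed=None,
                  space: str = "beta") -> dict:
        """Joint (simultaneous) confidence bands via max-statistic calibration.

        Returns ``{"lower", "upper", "qtilde"}``; also cached so the band is
        included by :meth:`to_frame` / :func:`fgee.data.write_fit`.
        """
        draws = None
        if mode == "nonparametric":
            draws = self.bootstrap(T=T, seed=seed)["draws"]
        band = inference.joint_ci(
            self.coef_curves(), self.coef_cov_blocks(), self.basis.B,
            alpha=alpha, T=T, mode=mode, seed=seed, draws=draws,
            m=self.basis.m, space=space)
        self._joint_band = band
        return band

    def bootstrap(self, T: int = 1000, seed=None) -> dict:
        """Fast cluster bootstrap of theta-hat (one solve per draw)."""
        W, b = self.summaries
        return inference.fast_cluster_bootstrap(
            self.theta_initial, W, b, self.lambda1, self.basis.S_block,
            self.model.data.n, T=T, seed=seed)

    # -- reporting ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Coefficient table, one row per (coefficient, grid point)."""
        beta = self.coef_curves()
        se = self.se_curves()
        ci = self.conf_int()
        grid = self.model.data.grid
        q1, L = beta.shape
        out = {
            "coefficient": np.repeat(self.coef_names, L),
            "s": np.tile(grid, q1),
            "estimate": beta.ravel(),
            "se": se.ravel(),
            "pw_lower": ci[:, :, 0].ravel(),
            "pw_upper": ci[:, :, 1].ravel(),
        }
        if self._joint_band is not None:
            out["joint_lower"] = self._joint_band["lower"].ravel()
            out["joint_upper"] = self._joint_band["upper"].ravel()
        return pd.DataFrame(out)

    def summary(self, alpha: float = 0.05) -> str:
        data = self.model.data
        rho = self.rho_final
        lines = [
            "One-step penalized functional GEE",
            "=" * 46,
            f"family:        {data.family}",
            f"working corr:  {self.model.corstr}",
            f"clusters N:    {data.N}   obs per cluster: "
            f"min {data.n.min()} / max {data.n.max()}",
            f"grid points L: {data.L}   basis dim m: {self.basis.m}",
            f"lambda0 (initial): "
            + ", ".join(f"{v:.3g}" for v in np.atleast_1d(self.lambda0)),
            f"lambda1 (one-step): "
            + ", ".join(f"{v:.3g}" for v in np.atleast_1d(self.lambda1)),
            f"rho(s):        mean {rho.mean():.3f}  "
            f"range [{rho.min():.3f}, {rho.max():.3f}]",
            "-" * 46,
            f"{'coefficient':<14}{'min':>9}{'max':>9}{'mean se':>10}",
        ]
        beta = self.coef_curves()
        se = self.se_curves()
        for name, bcurve, scurve in zip(self.coef_names, beta, se):
            lines.append(f"{name:<14}{bcurve.min():>9.3f}{bcurve.max():>9.3f}"
                         f"{scurve.mean():>10.3f}")
        return "\n".join(lines)

    def plot(self, alpha: float = 0.05, joint: bool = False, ax=None):
        """Coefficient curves with pointwise (and cached joint) bands."""
        import matplotlib.pyplot as plt

        beta = self.coef_curves()
        ci = self.conf_int(alpha)
        grid = self.model.data.grid
        q1 = beta.shape[0]
        if ax is None:
            _, axes = plt.subplots(1, q1, figsize=(4 * q1, 3), squeeze=False)
            axes = axes[0]
        else:
            axes = np.atleast_1d(ax)
        for r, axr in enumerate(axes[:q1]):
            axr.plot(grid, beta[r], color="C0")
            axr.fill_between(grid, ci[r, :, 0], ci[r, :, 1],
                             alpha=0.3, color="C0")
            if joint and self._joint_band is not None:
                axr.plot(grid, self._joint_band["lower"][r], "C1--", lw=0.8)
                axr.plot(grid, self._joint_band["upper"][r], "C1--", lw=0.8)
            axr.set_title(self.coef_names[r])
            axr.set_xlabel("s")
        return axes[0].figure
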