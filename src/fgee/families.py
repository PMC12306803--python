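"""Marginal model families: link functions and variance functions.

The marginal mean model is g(E[Y_{i,j}(s) | X_{i,j}]) = eta_{i,j}(s) with a
variance function v(mu) describing Var(Y | X) up to dispersion. Only the
canonical links are supported: identity (gaussian), logit (binomial) and
log (poisson).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Family", "get_family", "FAMILIES"]

# clamp for binomial means so v(mu)=mu(1-mu) stays bounded away from zero
_MU_EPS = 1e-6


class Family:
    """Link g, inverse link, its derivative, and variance function."""

    name: str = ""

    def link(self, mu):
        raise NotImplementedError

    def inverse_link(self, eta):
        raise NotImplementedError

    def dmu_deta(self, eta):
        """Derivative of the inverse link, d g^{-1}(eta) / d eta."""
        raise NotImplementedError

    def variance(self, mu):
        raise NotImplementedError

    def clamp_mu(self, mu):
        return mu

    def neg_loglik(self, y, mu):
        """Per-point negative working log-likelihood (dispersion 1, no constants)."""
        raise NotImplementedError

    def validate_outcome(self, y) -> None:
        pass


class Gaussian(Family):
    name = "gaussian"

    def link(self, mu):
        return np.asarray(mu, dtype=float)

    def inverse_link(self, eta):
        return np.asarray(eta, dtype=float)

    def dmu_deta(self, eta):
        return np.ones_like(np.asarray(eta, dtype=float))

    def variance(self, mu):
        return np.ones_like(np.asarray(mu, dtype=float))

    def neg_loglik(self, y, mu):
        return 0.5 * (y - mu) ** 2


class Binomial(Family):
    name = "binomial"

    def link(self, mu):
        mu = self.clamp_mu(mu)
        return np.log(mu / (1.0 - mu))

    def inverse_link(self, eta):
        # numerically stable expit
        out = np.empty_like(eta, dtype=float)
        pos = eta >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
        ex = np.exp(eta[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out

    def dmu_deta(self, eta):
        mu = self.inverse_link(eta)
        return mu * (1.0 - mu)

    def variance(self, mu):
        mu = self.clamp_mu(mu)
        return mu * (1.0 - mu)

    def clamp_mu(self, mu):
        return np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)

    def neg_loglik(self, y, mu):
        mu = self.clamp_mu(mu)
        return -(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu))

    def validate_outcome(self, y) -> None:
        vals = np.unique(np.asarray(y))
        if not np.all(np.isin(vals, (0.0, 1.0))):
            bad = vals[~np.isin(vals, (0.0, 1.0))][:5]
            raise ValueError(
                f"binomial outcomes must be in {{0,1}}; found values {bad}"
            )


class Poisson(Family):
    name = "poisson"

    def link(self, mu):
        return np.log(self.clamp_mu(mu))

    def inverse_link(self, eta):
        return np.exp(np.minimum(eta, 700.0))

    def dmu_deta(self, eta):
        return self.inverse_link(eta)

    def variance(self, mu):
        return self.clamp_mu(mu)

    def clamp_mu(self, mu):
        return np.maximum(mu, _MU_EPS)

    def neg_loglik(self, y, mu):
        mu = self.clamp_mu(mu)
        return mu - y * np.log(mu)

    def validate_outcome(self, y) -> None:
        y = np.asarray(y)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("poisson outcomes must be non-negative integers")


FAMILIES = {f.name: f for f in (Gaussian(), Binomial(), Poisson())}


def get_family(family) -> Family:
    """Resolve a family tag or instance to a :class:`Family`."""
    if isinstance(family, Family):
        return family
    try:
        return FAMILIES[str(family).lower()]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(FAMILIES)}"
        ) from None
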