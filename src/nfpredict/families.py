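"""Likelihood families for the outcome models.

Four families cover the trial's outcomes: negative binomial with log link
(binge counts), Bernoulli with logit link (abstinence), beta with logit
mean link (quality-of-life scores mapped to (0,1)), and Gaussian with
identity link (z-standardised questionnaire scores).

Each family exposes the pointwise log likelihood and its analytic
gradients with respect to the linear predictor eta and, where present, the
log of the auxiliary parameter (NB dispersion, beta precision, Gaussian
residual SD). All functions are vectorised over observations and accept a
batch axis for eta/log_aux, which the Hamiltonian sampler relies on.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln

__all__ = ["get_family", "Family", "FAMILIES", "squeeze_to_unit"]


def _log1pexp(x):
    return np.logaddexp(0.0, x)


def _clip_logaux(log_aux):
    # keep exp() finite during early warmup excursions
    return np.clip(log_aux, -15.0, 15.0)


def _clip_eta(eta):
    # log-link linear predictor: bound exp(eta) during warmup excursions
    return np.clip(eta, -30.0, 30.0)


class Family:
    """Interface: y (n,), eta (..., n), log_aux (...,) broadcastable."""

    name: str = ""
    has_aux: bool = False
    aux_name: str | None = None

    def check_outcome(self, y: np.ndarray) -> None:
        raise NotImplementedError

    def loglik(self, y, eta, log_aux=None) -> np.ndarray:
        raise NotImplementedError

    def d_eta(self, y, eta, log_aux=None) -> np.ndarray:
        raise NotImplementedError

    def d_logaux(self, y, eta, log_aux) -> np.ndarray:
        raise NotImplementedError

    def mean(self, eta) -> np.ndarray:
        raise NotImplementedError

    def resid_variance(self, eta, log_aux=None) -> np.ndarray:
        """Expected response-scale residual variance per observation
        (used by the Bayesian R-squared)."""
        raise NotImplementedError


class Gaussian(Family):
    name = "gaussian"
    has_aux = True
    aux_name = "sigma"

    def check_outcome(self, y):
        if np.ptp(y) == 0:
            raise ValueError("constant Gaussian outcome")

    def loglik(self, y, eta, log_aux=None):
        sigma2 = np.exp(2.0 * _clip_logaux(log_aux))[..., None]
        return -0.5 * np.log(2 * np.pi * sigma2) - 0.5 * (y - eta) ** 2 / sigma2

    def d_eta(self, y, eta, log_aux=None):
        return (y - eta) / np.exp(2.0 * _clip_logaux(log_aux))[..., None]

    def d_logaux(self, y, eta, log_aux):
        return -1.0 + (y - eta) ** 2 / np.exp(2.0 * _clip_logaux(log_aux))[..., None]

    def mean(self, eta):
        return eta

    def resid_variance(self, eta, log_aux=None):
        return np.broadcast_to(np.exp(2.0 * _clip_logaux(log_aux))[..., None],
                               eta.shape)


class BernoulliLogit(Family):
    name = "bernoulli_logit"
    has_aux = False

    def check_outcome(self, y):
        if not np.isin(y, (0, 1)).all():
            raise ValueError("Bernoulli outcome must be 0/1")
        if np.ptp(y) == 0:
            raise ValueError("constant Bernoulli outcome")

    def loglik(self, y, eta, log_aux=None):
        return y * eta - _log1pexp(eta)

    def d_eta(self, y, eta, log_aux=None):
        return y - expit(eta)

    def mean(self, eta):
        return expit(eta)

    def resid_variance(self, eta, log_aux=None):
        p = expit(eta)
        return p * (1 - p)


class NegativeBinomial(Family):
    """NB2 parameterisation: Var = mu + mu^2 / k with dispersion k."""

    name = "negative_binomial"
    has_aux = True
    aux_name = "dispersion"

    def check_outcome(self, y):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("negative binomial outcome must be counts")
        if np.ptp(y) == 0:
            raise ValueError("constant count outcome")

    def loglik(self, y, eta, log_aux=None):
        k = np.exp(_clip_logaux(log_aux))[..., None]
        eta = _clip_eta(eta)
        mu = np.exp(eta)
        return (gammaln(y + k) - gammaln(k) - gammaln(y + 1.0)
                + k * (_clip_logaux(log_aux)[..., None] - np.log(k + mu))
                + y * (eta - np.log(k + mu)))

    def d_eta(self, y, eta, log_aux=None):
        k = np.exp(_clip_logaux(log_aux))[..., None]
        mu = np.exp(_clip_eta(eta))
        return (y - mu) * k / (k + mu)

    def d_logaux(self, y, eta, log_aux):
        k = np.exp(_clip_logaux(log_aux))[..., None]
        mu = np.exp(_clip_eta(eta))
        return k * (digamma(y + k) - digamma(k)
                    + np.log(k) - np.log(k + mu)
                    + 1.0 - (y + k) / (k + mu))

    def mean(self, eta):
        return np.exp(_clip_eta(eta))

    def resid_variance(self, eta, log_aux=None):
        mu = np.exp(_clip_eta(eta))
        return mu + mu ** 2 / np.exp(_clip_logaux(log_aux))[..., None]


class Beta(Family):
    """Beta regression: mean expit(eta), precision phi; Var = mu(1-mu)/(1+phi)."""

    name = "beta"
    has_aux = True
    aux_name = "precision"

    def check_outcome(self, y):
        if np.any(y <= 0) or np.any(y >= 1):
            raise ValueError("beta outcome must lie strictly in (0, 1)")

    def loglik(self, y, eta, log_aux=None):
        phi = np.exp(_clip_logaux(log_aux))[..., None]
        mu = expit(eta)
        a, b = mu * phi, (1 - mu) * phi
        return (gammaln(phi) - gammaln(a) - gammaln(b)
                + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y))

    def d_eta(self, y, eta, log_aux=None):
        phi = np.exp(_clip_logaux(log_aux))[..., None]
        mu = expit(eta)
        dmu = mu * (1 - mu)
        return phi * dmu * (digamma((1 - mu) * phi) - digamma(mu * phi)
                            + np.log(y) - np.log1p(-y))

    def d_logaux(self, y, eta, log_aux):
        phi = np.exp(_clip_logaux(log_aux))[..., None]
        mu = expit(eta)
        return phi * (digamma(phi) - mu * digamma(mu * phi)
                      - (1 - mu) * digamma((1 - mu) * phi)
                      + mu * np.log(y) + (1 - mu) * np.log1p(-y))

    def mean(self, eta):
        return expit(eta)

    def resid_variance(self, eta, log_aux=None):
        mu = expit(eta)
        return mu * (1 - mu) / (1.0 + np.exp(_clip_logaux(log_aux))[..., None])


FAMILIES = {f.name: f for f in (Gaussian(), BernoulliLogit(),
                                NegativeBinomial(), Beta())}


def get_family(name: str) -> Family:
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; "
                         f"choose from {sorted(FAMILIES)}") from None


def squeeze_to_unit(y: np.ndarray, lower: float, upper: float) -> np.ndarray:
    """Map a bounded score linearly to (0,1) with the n-dependent boundary
    squeeze (y' * (n-1) + 0.5) / n, so beta regression applies."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    u = (y - lower) / (upper - lower)
    return (u * (n - 1) + 0.5) / n
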