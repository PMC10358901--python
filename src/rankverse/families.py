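"""Count-family log-likelihoods for dyadic interaction models.

Three observation families cover the four interaction types: zero-inflated
Poisson (aggression, supplants), plain Poisson (proximity), and zero-inflated
negative binomial (grooming minutes). Zero inflation is intercept-only: a
single structural-zero probability ``pi`` mixes a point mass at zero with the
count distribution, modelling dyads that simply never interact.

All functions are vectorised over observations and, besides the log-pmf,
expose first and second derivatives with respect to the log-rate linear
predictor ``eta`` (lambda = exp(eta), mu = exp(eta)). The derivatives feed the
Newton inner solver and the Hamiltonian sampler in :mod:`rankverse.inference`.

The negative binomial uses the mean--dispersion parameterisation:
``var = mu + mu**2 / phi``; larger ``phi`` means less overdispersion and
``phi -> inf`` recovers the Poisson.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

FAMILIES = ("poisson", "zip", "zinb")

__all__ = [
    "FAMILIES",
    "loglik_poisson",
    "loglik_zip",
    "loglik_zinb",
    "family_loglik",
    "eta_derivatives",
    "family_mean_var",
]


def _check_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    return y


def loglik_poisson(y, eta):
    """Poisson log-pmf at counts ``y`` with log-rate ``eta``."""
    y = _check_counts(y)
    eta = np.asarray(eta, dtype=float)
    return y * eta - np.exp(eta) - gammaln(y + 1.0)


def loglik_zip(y, eta, pi):
    """Zero-inflated Poisson log-pmf.

    P(0) = pi + (1 - pi) * exp(-lambda); P(y > 0) = (1 - pi) * Pois(y; lambda),
    with lambda = exp(eta) and 0 <= pi < 1.
    """
    y = _check_counts(y)
    eta = np.asarray(eta, dtype=float)
    if not (0.0 <= pi < 1.0):
        raise ValueError("zero-inflation probability must lie in [0, 1)")
    lam = np.exp(eta)
    ll = np.where(
        y == 0,
        np.logaddexp(np.log(pi) if pi > 0 else -np.inf, np.log1p(-pi) - lam),
        np.log1p(-pi) + y * eta - lam - gammaln(y + 1.0),
    )
    return ll


def _nb_logpmf(y, eta, phi):
    mu = np.exp(eta)
    if phi > 1e6:
        # stable evaluation of lgamma(y + phi) - lgamma(phi) for huge phi:
        # sum_{i<y} log(phi + i) = y log(phi) + y(y-1)/(2 phi) + O(y^3/phi^2)
        lg_ratio = y * np.log(phi) + y * (y - 1.0) / (2.0 * phi)
    else:
        lg_ratio = gammaln(y + phi) - gammaln(phi)
    return (
        lg_ratio
        - gammaln(y + 1.0)
        + phi * (np.log(phi) - np.log(phi + mu))
        + y * (eta - np.log(phi + mu))
    )


def loglik_zinb(y, eta, phi, pi):
    """Zero-inflated negative-binomial log-pmf (mean-dispersion NB)."""
    y = _check_counts(y)
    eta = np.asarray(eta, dtype=float)
    if phi <= 0:
        raise ValueError("dispersion phi must be positive")
    if not (0.0 <= pi < 1.0):
        raise ValueError("zero-inflation probability must lie in [0, 1)")
    mu = np.exp(eta)
    log_p0 = phi * (np.log(phi) - np.log(phi + mu))  # log NB(0; mu, phi)
    ll = np.where(
        y == 0,
        np.logaddexp(np.log(pi) if pi > 0 else -np.inf, np.log1p(-pi) + log_p0),
        np.log1p(-pi) + _nb_logpmf(y, eta, phi),
    )
    return ll


def family_loglik(family: str, y, eta, pi: float = 0.0, phi: float = 1.0):
    """Dispatch the log-pmf for one of the three supported families."""
    if family == "poisson":
        return loglik_poisson(y, eta)
    if family == "zip":
        return loglik_zip(y, eta, pi)
    if family == "zinb":
        return loglik_zinb(y, eta, phi, pi)
    raise ValueError(f"unknown family {family!r}")


def eta_derivatives(family: str, y, eta, pi: float = 0.0, phi: float = 1.0):
    """First and second derivatives of the log-pmf w.r.t. eta.

    Returns ``(g, h)`` with ``g = d loglik / d eta`` and
    ``h = d2 loglik / d eta2``, both arrays of shape ``y.shape``. These are the
    exact observed-information contributions used by the Newton solver; for
    the zero-inflated families the zero cell has non-trivial curvature.
    """
    shape = np.broadcast_shapes(np.shape(y), np.shape(eta))
    y = np.broadcast_to(_check_counts(y).astype(float), shape).ravel()
    eta = np.broadcast_to(np.asarray(eta, dtype=float), shape).ravel()
    if family == "poisson":
        lam = np.exp(eta)
        return (y - lam).reshape(shape), (-lam).reshape(shape)

    if family == "zip":
        lam = np.exp(eta)
        g = y - lam
        h = -lam
        if pi > 0:
            zero = y == 0
            lam0 = lam[zero]
            u = (1.0 - pi) * np.exp(-lam0)
            a = pi + u
            # d/deta of (-u*lam/a); d(u*lam)/deta = u*lam*(1-lam), dA/deta = -u*lam
            g[zero] = -u * lam0 / a
            h[zero] = -u * lam0 * ((1.0 - lam0) * a + u * lam0) / a**2
        return g.reshape(shape), h.reshape(shape)

    if family == "zinb":
        mu = np.exp(eta)
        # y > 0 branch (also the pi = 0 zero branch): NB curvature
        g = y - mu * (y + phi) / (phi + mu)
        h = -(y + phi) * phi * mu / (phi + mu) ** 2
        zero = y == 0
        if pi > 0 and np.any(zero):
            mu0 = mu[zero]
            c = phi * mu0 / (phi + mu0)
            dc = phi**2 * mu0 / (phi + mu0) ** 2
            log_p0 = phi * (np.log(phi) - np.log(phi + mu0))
            u = (1.0 - pi) * np.exp(log_p0)
            a = pi + u
            g[zero] = -u * c / a
            h[zero] = -((-u * c * c + u * dc) * a + u**2 * c**2) / a**2
        return g.reshape(shape), h.reshape(shape)

    raise ValueError(f"unknown family {family!r}")


def family_mean_var(family: str, eta, pi: float = 0.0, phi: float = 1.0):
    """Mean and variance of the observation given the linear predictor.

    Used for Bayesian R^2 (model-based residual variance) and for
    posterior-predictive summaries.
    """
    lam = np.exp(np.asarray(eta, dtype=float))
    if family == "poisson":
        return lam, lam
    if family == "zip":
        mean = (1.0 - pi) * lam
        var = (1.0 - pi) * lam * (1.0 + pi * lam)
        return mean, var
    if family == "zinb":
        mean = (1.0 - pi) * lam
        var = (1.0 - pi) * lam * (1.0 + lam / phi + pi * lam)
        return mean, var
    raise ValueError(f"unknown family {family!r}")


def sample_family(family: str, eta, rng: np.random.Generator,
                  pi: float = 0.0, phi: float = 1.0):
    """Draw counts from the family at log-rate ``eta`` (generative mirror)."""
    lam = np.exp(np.asarray(eta, dtype=float))
    if family == "poisson":
        return rng.poisson(lam)
    if family == "zip":
        y = rng.poisson(lam)
    elif family == "zinb":
        if phi <= 0:
            raise ValueError("dispersion phi must be positive")
        rate = rng.gamma(shape=phi, scale=lam / phi)
        y = rng.poisson(rate)
    else:
        raise ValueError(f"unknown family {family!r}")
    if pi > 0:
        y = np.where(rng.random(lam.shape) < pi, 0, y)
    return y
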