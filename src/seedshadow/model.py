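"""The seed-shadow data-generating model.

Counts in trap ``s`` and year ``t`` are conditionally Poisson,

    y_st ~ Poisson(A_s * lambda_st),   lambda_st = sum_i S_si * f_it,

with effort ``A`` (trap area x fraction of fruiting season, m^2 yr), the
2Dt seed-shadow matrix ``S`` (kernel module), and per-tree fecundity

    f_it = rho_i * psi_it,     rho in {0,1} the maturation status,
    log psi_it = beta0 + beta_D*log(DBH) + beta_L*[logged]
                 + beta_HL*[hunted+logged] + a_i + gamma_tg + eps_it,

where ``a_i ~ N(0, sigma_a^2)`` are individual random effects,
``gamma_tg ~ N(0, sigma_g^2)`` year effects shared within a disturbance
regime (coherent within, not among, regimes), and ``eps ~ N(0, sigma_e^2)``
residual tree-year variation.  Random and year effects make the marginal
counts overdispersed even though the observation layer is Poisson.

Maturation is a time-static probit on log diameter:
``P(rho=1) = Phi((log DBH - mu_m) / sigma_m)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ndtr

__all__ = [
    "FIXED_EFFECT_NAMES",
    "MaturationModel",
    "PriorSpec",
    "design_matrix",
    "linear_predictor",
    "maturation_probability",
    "trap_intensity",
    "log_likelihood",
    "log_prior",
]

#: order of columns in the fixed-effect design matrix
FIXED_EFFECT_NAMES = ("intercept", "diameter", "logging", "hunting_logging")


@dataclass
class MaturationModel:
    """Probit maturation threshold on the log-diameter scale."""

    mu_log_cm: float = float(np.log(20.0))
    sigma_log: float = 0.5

    def __post_init__(self):
        if self.sigma_log <= 0:
            raise ValueError("maturation sigma must be positive")


@dataclass
class PriorSpec:
    """Priors: flat (bounded uniform) on u; N(0, tau^2) on beta;
    inverse-gamma with fixed shape on the variance components."""

    u_min: float = float((2.0 / np.pi) ** 2)          # mean distance 1 m
    u_max: float = float((300.0 / np.pi) ** 2)        # mean distance 150 m
    beta_sd: float = 10.0
    ig_shape: float = 2.0
    ig_scale: float = 0.25

    def __post_init__(self):
        if not (0 < self.u_min < self.u_max):
            raise ValueError("need 0 < u_min < u_max")


def design_matrix(trees, center_log_dbh: float | None = None) -> np.ndarray:
    """Fixed-effect design: intercept, log DBH (optionally centred), and
    regime indicators with *protected* as the reference level."""
    logd = np.log(np.asarray(trees["dbh_cm"], dtype=float))
    if center_log_dbh is not None:
        logd = logd - center_log_dbh
    regime = np.asarray(trees["regime"])
    X = np.column_stack([
        np.ones_like(logd),
        logd,
        (regime == "logged").astype(float),
        (regime == "hunted_logged").astype(float),
    ])
    return X


def linear_predictor(X, beta, a=None, gamma=None):
    """eta_it on the log-fecundity scale.

    ``X`` is (n, p); ``beta`` (p,); ``a`` optional per-tree intercepts (n,);
    ``gamma`` optional per-year effects, scalar, (T,), or (n, T).  Returns
    (n,) without gamma of year dimension, else (n, T).
    """
    eta = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    if a is not None:
        eta = eta + np.asarray(a, dtype=float)
    if gamma is None:
        return eta
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim <= 1:
        return eta[:, None] + gamma[None, :] if gamma.ndim == 1 else eta + gamma
    return eta[:, None] + gamma


def maturation_probability(dbh_cm, m: MaturationModel):
    """Phi((log DBH - mu_m)/sigma_m); nondecreasing in DBH."""
    dbh = np.asarray(dbh_cm, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("dbh_cm must be positive")
    out = ndtr((np.log(dbh) - m.mu_log_cm) / m.sigma_log)
    return out if out.ndim else float(out)


def trap_intensity(S, f) -> np.ndarray:
    """Expected seed density per trap: lambda = S @ f (linear in fecundity).

    ``f`` may be (n_trees,) for one year or (n_trees, n_years).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("fecundity must be non-negative")
    return np.asarray(S, dtype=float) @ f


def log_likelihood(y, effort, lam) -> float:
    """Poisson log likelihood sum_s [y log(A lam) - A lam - log y!].

    Returns -inf when some y > 0 has lam = 0 (impossible data), and treats
    y = 0, lam = 0 terms as exactly 0 (a certain event).
    """
    y = np.asarray(y, dtype=float)
    A = np.asarray(effort, dtype=float)
    lam = np.asarray(lam, dtype=float)
    y, A, lam = np.broadcast_arrays(y, A, lam)
    mu = A * lam
    pos = y > 0
    if np.any(mu[pos] == 0):
        return -np.inf
    ll = -np.sum(mu) - np.sum(gammaln(y[pos] + 1.0))
    ll += np.sum(y[pos] * np.log(mu[pos]))
    return float(ll)


def log_prior(beta, u, sigma_a2, sigma_g2, prior: PriorSpec, sigma_e2=None) -> float:
    """Joint log prior density; -inf outside support.

    Flat on each u within [u_min, u_max]; N(0, beta_sd^2) on beta;
    inverse-gamma(shape, scale) on each variance component.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any(u < prior.u_min) or np.any(u > prior.u_max):
        return -np.inf
    lp = 0.0
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    lp += float(np.sum(-0.5 * (beta / prior.beta_sd) ** 2
                       - np.log(prior.beta_sd) - 0.5 * np.log(2 * np.pi)))
    sh, sc = prior.ig_shape, prior.ig_scale
    for v in (sigma_a2, sigma_g2, sigma_e2):
        if v is None:
            continue
        if v <= 0:
            return -np.inf
        lp += float(sh * np.log(sc) - gammaln(sh) - (sh + 1) * np.log(v) - sc / v)
    return lp
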