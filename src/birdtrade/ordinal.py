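"""Maximum-likelihood cumulative-link (proportional-odds) regression.

The model relates an ordinal response T in {1..5} (the real trade score) to a
single predictor E (the expected geopolitical score, 0-8) through

    P(T <= k | E) = logistic(theta_k - beta * E),   k = 1..4,

with one shared slope beta ("proportional odds") and strictly increasing
thresholds theta_1 < ... < theta_4.  A positive beta shifts probability mass
toward higher categories as E grows.

Fitting maximises the log-likelihood by quasi-Newton descent on an
unconstrained reparameterisation (theta_1 free, later thresholds as
cumulative exponentials of free increments), with a deterministic start:
beta = 0 and thresholds at the marginal cumulative logits.  Standard errors
come from the inverse observed information at the optimum.  The null model
(thresholds only) has the closed-form multinomial maximum, which anchors the
Cox-Snell / Nagelkerke and McFadden pseudo-R2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .errors import DomainError

N_CATEGORIES = 5
N_THRESHOLDS = N_CATEGORIES - 1


@dataclass
class CLMData:
    """Paired (expected score, trade-score category) observations."""

    E: np.ndarray
    T: np.ndarray
    role: str | None = None
    period: str | None = None

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.T = np.asarray(self.T, dtype=int)
        if self.E.shape != self.T.shape or self.E.ndim != 1:
            raise ValueError("E and T must be 1-d arrays of equal length")
        if ((self.T < 1) | (self.T > N_CATEGORIES)).any():
            raise ValueError(f"categories must lie in 1..{N_CATEGORIES}")

    @property
    def n(self) -> int:
        return len(self.T)


@dataclass
class CLMFit:
    """A fitted cumulative-link model with Wald inference and pseudo-R2."""

    beta: float
    theta: np.ndarray
    se_beta: float
    z: float
    p_value: float
    loglik: float
    loglik_null: float
    nagelkerke_r2: float
    mcfadden_r2: float
    n: int
    converged: bool
    role: str | None = None
    period: str | None = None
    se_theta: np.ndarray = field(default=None, repr=False)


def _category_probs(beta: float, theta: np.ndarray, E: np.ndarray) -> np.ndarray:
    """n x 5 matrix of P(T = k | E) from consecutive cumulative differences."""
    eta = theta[None, :] - beta * np.asarray(E, dtype=float)[:, None]
    cum = expit(eta)  # P(T <= k), k = 1..4
    ones = np.ones((cum.shape[0], 1))
    return np.diff(np.concatenate([np.zeros_like(ones), cum, ones], axis=1), axis=1)


def clm_loglik(beta: float, theta, E, T) -> float:
    """Log-likelihood of (beta, theta) for observations (E, T).

    Uses theta_0 = -inf and theta_5 = +inf implicitly; raises
    :class:`DomainError` if the thresholds are not strictly increasing.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (N_THRESHOLDS,) or (np.diff(theta) <= 0).any():
        raise DomainError("thresholds must be 4 strictly increasing reals")
    T = np.asarray(T, dtype=int)
    probs = _category_probs(beta, theta, E)[np.arange(len(T)), T - 1]
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(probs)))


def _null_loglik(T: np.ndarray) -> float:
    """Closed-form maximum of the thresholds-only (intercept) model."""
    counts = np.bincount(T, minlength=N_CATEGORIES + 1)[1:]
    n = counts.sum()
    nz = counts[counts > 0]
    return float(np.sum(nz * np.log(nz / n)))


def _pack(beta: float, theta: np.ndarray) -> np.ndarray:
    """(beta, theta) -> unconstrained (beta, theta1, log increments)."""
    incr = np.diff(theta)
    return np.concatenate([[beta, theta[0]], np.log(incr)])


def _unpack(phi: np.ndarray) -> tuple[float, np.ndarray]:
    beta, t1 = phi[0], phi[1]
    theta = t1 + np.concatenate([[0.0], np.cumsum(np.exp(phi[2:]))])
    return float(beta), theta


def _start_values(T: np.ndarray) -> np.ndarray:
    """Deterministic start: beta = 0, thresholds at marginal cumulative logits."""
    n = len(T)
    counts = np.bincount(T, minlength=N_CATEGORIES + 1)[1:]
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 1.0 / (n + 1), 1.0 - 1.0 / (n + 1))
    theta = np.log(cum / (1 - cum))
    # enforce strictly increasing starts even when a category is empty
    for k in range(1, N_THRESHOLDS):
        theta[k] = max(theta[k], theta[k - 1] + 1e-3)
    return _pack(0.0, theta)


def _neg_loglik(phi: np.ndarray, E: np.ndarray, T: np.ndarray, ridge: float) -> float:
    beta, theta = _unpack(phi)
    probs = _category_probs(beta, theta, E)[np.arange(len(T)), T - 1]
    probs = np.maximum(probs, 1e-300)
    return -float(np.sum(np.log(probs))) + ridge * beta * beta


def _neg_loglik_grad(phi: np.ndarray, E: np.ndarray, T: np.ndarray, ridge: float) -> np.ndarray:
    """Analytic gradient of :func:`_neg_loglik` in the unconstrained space."""
    beta, theta = _unpack(phi)
    n = len(T)
    eta = theta[None, :] - beta * E[:, None]
    cum = expit(eta)
    dens = cum * (1.0 - cum)  # logistic density at each threshold
    upper = np.concatenate([cum, np.ones((n, 1))], axis=1)[np.arange(n), T - 1]
    lower = np.concatenate([np.zeros((n, 1)), cum], axis=1)[np.arange(n), T - 1]
    f_upper = np.concatenate([dens, np.zeros((n, 1))], axis=1)[np.arange(n), T - 1]
    f_lower = np.concatenate([np.zeros((n, 1)), dens], axis=1)[np.arange(n), T - 1]
    p = np.maximum(upper - lower, 1e-300)

    d_beta = np.sum(E * (f_upper - f_lower) / p)  # d(-l)/d(beta)
    # d(l)/d(theta_k): +f(eta_k)/p when k is the upper threshold, -f/p when lower
    g_theta = np.zeros(N_THRESHOLDS)
    for k in range(N_THRESHOLDS):
        is_upper = (T - 1) == k
        is_lower = (T - 2) == k
        g_theta[k] = np.sum(dens[is_upper, k] / p[is_upper]) - np.sum(
            dens[is_lower, k] / p[is_lower]
        )
    # chain rule through theta = t1 + cumsum([0, exp(phi_2..4)])
    grad = np.empty_like(phi)
    grad[0] = d_beta + 2.0 * ridge * beta
    grad[1] = -np.sum(g_theta)
    for j in range(2, len(phi)):
        grad[j] = -np.exp(phi[j]) * np.sum(g_theta[j - 1 :])
    return grad


def _observed_information(beta: float, theta: np.ndarray, E, T) -> np.ndarray:
    """Numeric Hessian of the negative log-likelihood in (beta, theta)."""
    x0 = np.concatenate([[beta], theta])

    def nll(x):
        probs = _category_probs(x[0], x[1:], E)[np.arange(len(T)), T - 1]
        return -float(np.sum(np.log(np.maximum(probs, 1e-300))))

    k = len(x0)
    h = 1e-5 * np.maximum(1.0, np.abs(x0))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = nll(x0 + ei + ej)
            fpm = nll(x0 + ei - ej)
            fmp = nll(x0 - ei + ej)
            fmm = nll(x0 - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return hess


def pseudo_r2(loglik_null: float, loglik_full: float, n: int) -> tuple[float, float]:
    """Nagelkerke and McFadden pseudo-R2 from the two log-likelihoods.

    Cox-Snell = 1 - exp(2 (l0 - l1) / n); Nagelkerke rescales it by its
    maximum 1 - exp(2 l0 / n); McFadden = 1 - l1 / l0.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_full < loglik_null - 1e-8:
        raise ValueError("full-model log-likelihood below null log-likelihood")
    if loglik_null == 0.0:
        raise DomainError("null log-likelihood is zero; McFadden R2 undefined")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    max_cs = 1.0 - np.exp(2.0 * loglik_null / n)
    nagelkerke = float(cox_snell / max_cs)
    mcfadden = float(1.0 - loglik_full / loglik_null)
    return nagelkerke, mcfadden


def fit_clm(data: CLMData, ridge: float = 0.0) -> CLMFit:
    """Fit the cumulative-link model by maximum likelihood.

    Non-convergence is flagged on the returned fit, never silent.  Under
    complete separation (the slope diverging), the fit is retried with a tiny
    ridge penalty (1e-6) on beta and a warning is issued.
    """
    E, T = data.E, data.T
    if np.unique(E).size < 2 or np.unique(T).size < 2:
        raise ValueError("both E and T must vary to fit the model")
    phi0 = _start_values(T)
    res = minimize(
        _neg_loglik, phi0, args=(E, T, ridge), method="BFGS",
        jac=_neg_loglik_grad, options={"gtol": 1e-8, "maxiter": 500},
    )
    beta, theta = _unpack(res.x)
    # BFGS can stop on precision loss with the gradient already at the noise
    # floor of the double-precision objective; accept a relative criterion
    converged = bool(
        res.success
        or (np.isfinite(res.fun) and np.abs(res.jac).max() <= 1e-8 * max(1.0, abs(res.fun)))
    )
    if ridge == 0.0 and (not np.isfinite(beta) or abs(beta) > 15.0):
        warnings.warn(
            "apparent complete separation; refitting with ridge penalty 1e-6 on beta",
            stacklevel=2,
        )
        return fit_clm(data, ridge=1e-6)

    loglik = clm_loglik(beta, theta, E, T)
    loglik_null = _null_loglik(T)
    nagelkerke, mcfadden = pseudo_r2(loglik_null, max(loglik, loglik_null), data.n)

    info = _observed_information(beta, theta, E, T)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se_beta, se_theta = float(se[0]), se[1:]
    except np.linalg.LinAlgError:
        se_beta, se_theta = np.nan, np.full(N_THRESHOLDS, np.nan)
    z = beta / se_beta if se_beta > 0 else np.nan
    p = float(2.0 * norm.sf(abs(z))) if np.isfinite(z) else np.nan

    return CLMFit(
        beta=beta,
        theta=theta,
        se_beta=se_beta,
        z=float(z),
        p_value=p,
        loglik=loglik,
        loglik_null=loglik_null,
        nagelkerke_r2=nagelkerke,
        mcfadden_r2=mcfadden,
        n=data.n,
        converged=converged,
        role=data.role,
        period=data.period,
        se_theta=se_theta,
    )


def predict_category_probs(fit: CLMFit, E) -> np.ndarray:
    """P(T = 1..5 | E) under a fitted model; rows sum to 1.

    ``E`` may be a scalar in 0..8 or an array of such scores.
    """
    E_arr = np.atleast_1d(np.asarray(E, dtype=float))
    if ((E_arr < 0) | (E_arr > 8)).any():
        raise ValueError("expected score must lie in 0..8")
    probs = _category_probs(fit.beta, fit.theta, E_arr)
    return probs[0] if np.isscalar(E) or np.ndim(E) == 0 else probs
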