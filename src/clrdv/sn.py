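"""Skew-normal distribution: direct/centered parametrizations and (penalized) MLE.

The skew-normal density with direct parameters (DP) xi (location),
omega > 0 (scale) and alpha (shape) is

    f(x) = (2/omega) * phi(z) * Phi(alpha * z),   z = (x - xi) / omega,

reducing to N(xi, omega^2) at alpha = 0.  The centered parametrization (CP)
re-expresses the distribution through its mean mu, standard deviation sigma
and skewness gamma, whose admissible range is |gamma| < k with

    k = sqrt(2) * (4 - pi) / (pi - 2)^{3/2}  ~  0.9953.

CP is the natural coordinate system for inference here: the Fisher
information is singular in DP at alpha = 0 but well behaved in CP, and the
quantity under test downstream is sigma itself.

Estimation ladder
-----------------
1. direct maximum likelihood in DP coordinates from method-of-moments
   starting values;
2. if the optimizer fails, the shape estimate diverges (|alpha| > 50) or the
   observed information is not usable, refit with a logarithmic penalty on
   the shape, -c1*log(1 + c2*alpha^2) (c1 = 0.87591, c2 = 0.85625), from a
   small grid of shape starts;
3. as a last resort, fall back to the normal submodel (gamma = 0) with
   closed-form standard errors.

Standard errors always come from the observed information of the
log-likelihood expressed in CP coordinates (numerical Hessian).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr
from statsmodels.tools.numdiff import approx_hess3

__all__ = [
    "SKEWNESS_BOUND",
    "DirectParams",
    "CenteredParams",
    "SNFit",
    "sn_logpdf",
    "sn_cdf",
    "dp_to_cp",
    "cp_to_dp",
    "fit_sn_cp",
    "se_sigma_cp",
]

#: upper bound of |gamma|: sqrt(2)(4-pi)/(pi-2)^(3/2)
SKEWNESS_BOUND: float = math.sqrt(2.0) * (4.0 - math.pi) / (math.pi - 2.0) ** 1.5

_B = math.sqrt(2.0 / math.pi)  # E|Z| for standard normal Z
_LOG2 = math.log(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

# shape-penalty constants of the "Q" logarithmic penalty
_Q_C1 = 0.87591
_Q_C2 = 0.85625

#: shape estimates beyond this are treated as boundary divergence
ALPHA_CAP = 50.0


@dataclass(frozen=True)
class DirectParams:
    """Direct parameters (xi, omega, alpha); omega > 0."""

    xi: float
    omega: float
    alpha: float

    def __post_init__(self):
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")


@dataclass(frozen=True)
class CenteredParams:
    """Centered parameters (mu, sigma, gamma); sigma > 0, |gamma| < k."""

    mu: float
    sigma: float
    gamma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not abs(self.gamma) < SKEWNESS_BOUND:
            raise ValueError(
                f"|gamma| must be < {SKEWNESS_BOUND:.4f}, got {self.gamma}"
            )


@dataclass
class SNFit:
    """Result of a skew-normal fit in centered coordinates.

    ``se`` holds the standard errors of (mu, sigma, gamma) from the inverse
    observed information in CP coordinates; ``var_sigma`` is se[1]**2.
    ``method`` is one of ``"mle"``, ``"penalized_q"``, ``"normal"``.
    """

    cp: CenteredParams | None
    se: tuple | None
    var_sigma: float
    loglik: float
    method: str
    converged: bool

    @property
    def dp(self) -> DirectParams | None:
        return cp_to_dp(self.cp) if self.cp is not None else None


def sn_logpdf(x, dp: DirectParams):
    """Log-density of the skew-normal at ``x`` (scalar or array)."""
    z = (np.asarray(x, dtype=float) - dp.xi) / dp.omega
    return (
        _LOG2
        - math.log(dp.omega)
        - _LOG_SQRT_2PI
        - 0.5 * z * z
        + log_ndtr(dp.alpha * z)
    )


def sn_cdf(x, dp: DirectParams):
    """CDF of the skew-normal (via scipy's skewnorm)."""
    from scipy.stats import skewnorm

    return skewnorm.cdf(x, dp.alpha, loc=dp.xi, scale=dp.omega)


def dp_to_cp(dp: DirectParams) -> CenteredParams:
    """Map direct to centered parameters (moment relations)."""
    delta = dp.alpha / math.sqrt(1.0 + dp.alpha * dp.alpha)
    u = _B * delta  # mean of the standardized skew-normal
    v = 1.0 - u * u  # its variance
    mu = dp.xi + dp.omega * u
    sigma = dp.omega * math.sqrt(v)
    gamma = 0.5 * (4.0 - math.pi) * u**3 / v**1.5
    # rounding can push |gamma| one ulp onto the open boundary at huge |alpha|
    bound = np.nextafter(SKEWNESS_BOUND, 0.0)
    gamma = min(max(gamma, -bound), bound)
    return CenteredParams(mu, sigma, gamma)


def cp_to_dp(cp: CenteredParams) -> DirectParams:
    """Map centered to direct parameters; exact inverse of :func:`dp_to_cp`."""
    r = np.cbrt(2.0 * cp.gamma / (4.0 - math.pi))
    u = r / math.sqrt(1.0 + r * r)  # = b * delta
    delta = u / _B
    # |gamma| < k guarantees |delta| < 1
    alpha = delta / math.sqrt(1.0 - delta * delta)
    omega = cp.sigma / math.sqrt(1.0 - u * u)
    xi = cp.mu - omega * u
    return DirectParams(xi, omega, alpha)


# ---------------------------------------------------------------------------
# likelihood machinery (internal; theta = (xi, log omega, alpha))


def _nll(theta, x, penalized):
    xi, logw, a = theta
    z = (x - xi) * math.exp(-logw)
    ll = np.sum(-0.5 * z * z + log_ndtr(a * z)) + x.size * (
        _LOG2 - logw - _LOG_SQRT_2PI
    )
    if penalized:
        ll -= _Q_C1 * math.log1p(_Q_C2 * a * a)
    return -ll


def _nll_grad(theta, x, penalized):
    xi, logw, a = theta
    w_inv = math.exp(-logw)
    z = (x - xi) * w_inv
    az = a * z
    # inverse Mills ratio phi(t)/Phi(t), stable through log space
    mills = np.exp(-_LOG_SQRT_2PI - 0.5 * az * az - log_ndtr(az))
    d_xi = np.sum(z * w_inv - a * w_inv * mills)
    d_logw = np.sum(z * z - az * mills) - x.size
    d_a = np.sum(z * mills)
    if penalized:
        d_a -= 2.0 * _Q_C1 * _Q_C2 * a / (1.0 + _Q_C2 * a * a)
    return -np.array([d_xi, d_logw, d_a])


def _nll_cp(cp_vec, x):
    """Negative log-likelihood as a function of (mu, sigma, gamma)."""
    mu, sigma, gamma = cp_vec
    if sigma <= 0 or abs(gamma) >= SKEWNESS_BOUND:
        return np.inf
    dp = cp_to_dp(CenteredParams(mu, sigma, gamma))
    return -float(np.sum(sn_logpdf(x, dp)))


def _cp_cov(x, cp: CenteredParams):
    """Inverse observed information in CP coordinates, or None if unusable."""
    point = np.array([cp.mu, cp.sigma, cp.gamma])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            hess = approx_hess3(point, _nll_cp, args=(x,))
        except Exception:
            return None
    if not np.all(np.isfinite(hess)):
        return None
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None
    diag = np.diag(cov)
    if not np.all(np.isfinite(diag)) or np.any(diag <= 0):
        return None
    return cov


def se_sigma_cp(values, cp: CenteredParams) -> float:
    """Standard error of sigma-hat from the observed information in CP.

    ``cp`` must be the maximum-likelihood point for ``values``; the returned
    value is the square root of the sigma diagonal element of the inverse
    observed information.
    """
    x = np.asarray(values, dtype=float)
    cov = _cp_cov(x, cp)
    if cov is None:
        raise ValueError("singular or non-finite observed information matrix")
    return float(math.sqrt(cov[1, 1]))


def _moment_start(x):
    m = float(np.mean(x))
    s = float(np.std(x))
    z = (x - m) / s
    g1 = float(np.mean(z**3))
    g1 = max(min(g1, 0.95 * SKEWNESS_BOUND), -0.95 * SKEWNESS_BOUND)
    dp = cp_to_dp(CenteredParams(m, s, g1))
    return np.array([dp.xi, math.log(dp.omega), dp.alpha])


def _optimize(x, start, penalized):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(
            _nll,
            start,
            args=(x, penalized),
            jac=_nll_grad,
            method="BFGS",
            options={"gtol": 1e-8 * x.size, "maxiter": 500},
        )
    if not np.all(np.isfinite(res.x)):
        return None
    return res


def _finish(x, theta, method):
    """Build an SNFit from an optimizer solution, or None if SEs unusable."""
    dp = DirectParams(theta[0], math.exp(theta[1]), theta[2])
    cp = dp_to_cp(dp)
    cov = _cp_cov(x, cp)
    if cov is None:
        return None
    se = tuple(float(v) for v in np.sqrt(np.diag(cov)))
    loglik = float(np.sum(sn_logpdf(x, dp)))
    return SNFit(
        cp=cp,
        se=se,
        var_sigma=se[1] ** 2,
        loglik=loglik,
        method=method,
        converged=True,
    )


def _normal_fallback(x):
    n = x.size
    m = float(np.mean(x))
    s = float(np.std(x))
    se = (s / math.sqrt(n), s / math.sqrt(2.0 * n), math.sqrt(6.0 / n))
    loglik = float(-n * (_LOG_SQRT_2PI + math.log(s)) - 0.5 * n)
    return SNFit(
        cp=CenteredParams(m, s, 0.0),
        se=se,
        var_sigma=se[1] ** 2,
        loglik=loglik,
        method="normal",
        converged=True,
    )


def fit_sn_cp(values, min_n: int = 20, warn_n: int = 50) -> SNFit:
    """Fit a skew-normal by (penalized) maximum likelihood; CP estimates.

    Parameters
    ----------
    values : array-like
        Observations (at least ``min_n``; a warning is issued below
        ``warn_n``, where the scale estimate is unreliable).

    Returns
    -------
    SNFit
        Centered estimates, CP standard errors, log-likelihood, the ladder
        rung that produced the fit, and a convergence flag.  If every rung
        fails, ``converged`` is False and the estimate fields are None/NaN.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if x.size < warn_n:
        warnings.warn(
            f"n = {x.size} < {warn_n}: scale estimation may be unreliable",
            stacklevel=2,
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0:
        raise ValueError("constant input: zero variance")

    start = _moment_start(x)

    # rung 1: plain MLE
    res = _optimize(x, start, penalized=False)
    if res is not None and abs(res.x[2]) <= ALPHA_CAP:
        fit = _finish(x, res.x, "mle")
        if fit is not None:
            return fit

    # rung 2: penalized likelihood from a grid of shape starts
    best = None
    starts = [start] + [
        np.array([start[0], start[1], a0]) for a0 in (-5.0, -1.0, 1.0, 5.0)
    ]
    for s0 in starts:
        res = _optimize(x, s0, penalized=True)
        if res is None or abs(res.x[2]) > ALPHA_CAP:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is not None:
        fit = _finish(x, best.x, "penalized_q")
        if fit is not None:
            return fit

    # rung 3: normal submodel
    try:
        return _normal_fallback(x)
    except (ValueError, FloatingPointError):
        return SNFit(
            cp=None,
            se=None,
            var_sigma=float("nan"),
            loglik=float("nan"),
            method="failed",
            converged=False,
        )
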