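"""Beta regression with logit link on copula-scale data.

The regression engine behind copula directional dependence: the response
``V`` given the covariate ``U = u`` is Beta(mu kappa, (1-mu) kappa) with
``logit(mu) = beta0 + beta1 u`` and constant precision ``kappa``.  Both
series live on the copula scale, i.e. strictly inside (0, 1), usually via
the empirical probability integral transform :func:`empirical_pit`.

Serial correlation left over by the marginal beta model can optionally be
absorbed by a Gaussian-copula AR(1) correction: the per-observation beta
CDF values are mapped to normal scores which are given an AR(1) joint
density (a marginal/copula regression model in the Guolo-Varin spirit).
The correction mainly affects standard errors and the likelihood; the
fitted mean curve, which is what directional dependence uses, is nearly
unchanged, so ``serial="none"`` is the default and is what all closed-form
cross-checks use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "BetaRegFit",
    "FitConvergenceError",
    "empirical_pit",
    "beta_log_density",
    "fit_beta_regression",
    "regression_curve",
]

_SERIAL_OPTIONS = ("none", "ar1")


class FitConvergenceError(RuntimeError):
    """Raised when the likelihood optimizer fails after bounded restarts.

    Carries the best parameter vector and log-likelihood seen, for
    diagnostics.
    """

    def __init__(self, message: str, params=None, loglik=None):
        super().__init__(message)
        self.params = params
        self.loglik = loglik


@dataclass
class BetaRegFit:
    """Converged maximum-likelihood beta regression fit.

    ``logit(fitted_means) = beta0 + beta1 * u`` holds exactly; ``kappa`` is
    the precision (> 0).  ``ar1`` and ``ar1_se`` are populated only when the
    Gaussian-copula AR(1) serial correction was requested.
    """

    beta0: float
    beta1: float
    kappa: float
    fitted_means: np.ndarray
    loglik: float
    serial_model: str = "none"
    beta0_se: float | None = None
    beta1_se: float | None = None
    ar1: float | None = None
    ar1_se: float | None = None
    n_obs: int = 0


def empirical_pit(x) -> np.ndarray:
    """Empirical probability integral transform, ``(rank - 0.5) / n``.

    Average ranks for ties; the output is strictly inside (0, 1) with mean
    exactly 0.5, and is invariant to strictly increasing transforms of the
    input.  A constant series has no usable ranks and raises.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("empirical_pit expects a one-dimensional series")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("constant series: ranks carry no dependence information")
    ranks = stats.rankdata(x, method="average")
    return (ranks - 0.5) / len(x)


def beta_log_density(v, mu, kappa):
    """Log density of Beta(mu*kappa, (1-mu)*kappa) at ``v``.

    Boundary values of ``v`` yield ``-inf`` (not an exception) whenever the
    corresponding shape parameter exceeds one.
    """
    v = np.asarray(v, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any((mu <= 0) | (mu >= 1)):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(np.asarray(kappa) <= 0):
        raise ValueError("kappa must be positive")
    a = mu * kappa
    b = (1.0 - mu) * kappa
    with np.errstate(divide="ignore"):
        out = (a - 1.0) * np.log(v) + (b - 1.0) * np.log1p(-v) - special.betaln(a, b)
    if np.ndim(out) == 0:
        return float(out)
    return out


def _check_unit_series(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return x


def fit_beta_regression(u, v, serial: str = "none", max_restarts: int = 5) -> BetaRegFit:
    """Maximum-likelihood fit of the logit-link beta regression of v on u.

    ``serial="none"`` maximizes the product of beta densities;
    ``serial="ar1"`` adds the Gaussian-copula AR(1) term.  The optimizer is
    polished with Newton steps so that the score at the optimum is
    numerically zero; up to ``max_restarts`` jittered restarts are tried
    before :class:`FitConvergenceError` is raised.
    """
    u = _check_unit_series(u, "u")
    v = _check_unit_series(v, "v")
    if len(u) != len(v):
        raise ValueError("u and v must have equal length")
    if len(u) < 10:
        raise ValueError("need at least 10 observations")
    if serial not in _SERIAL_OPTIONS:
        raise ValueError(f"serial must be one of {_SERIAL_OPTIONS}")

    base = _fit_marginal(u, v, max_restarts)
    if serial == "none":
        return base
    return _fit_ar1(u, v, base, max_restarts)


def _fit_marginal(u: np.ndarray, v: np.ndarray, max_restarts: int) -> BetaRegFit:
    n = len(u)
    exog = np.column_stack([np.ones(n), u])
    model = BetaModel(v, exog)
    start = _start_params(u, v)
    best = None
    # fast path: Newton straight from the moment-based start
    try:
        params = _newton_polish(model, start)
        llf = float(model.loglike(params))
        if np.isfinite(llf) and _score_ok(model, params):
            best = (params, llf)
    except (np.linalg.LinAlgError, ValueError):
        pass
    rng = np.random.default_rng(0)
    for attempt in range(max_restarts + 1):
        if best is not None:
            break
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(start_params=start, disp=False, maxiter=500)
            params = _newton_polish(model, np.asarray(res.params, dtype=float))
            llf = float(model.loglike(params))
            if np.isfinite(llf) and _score_ok(model, params):
                best = (params, llf)
        except (np.linalg.LinAlgError, ValueError):
            pass
        start = _start_params(u, v) + rng.normal(scale=0.3, size=3)
    if best is None:
        raise FitConvergenceError("beta regression failed to converge")
    params, llf = best
    if not _score_ok(model, params, tol=1e-4):
        raise FitConvergenceError(
            "beta regression score did not vanish after restarts",
            params=params,
            loglik=llf,
        )
    beta0, beta1 = params[0], params[1]
    kappa = float(np.exp(params[2]))
    mu = special.expit(beta0 + beta1 * u)
    se0 = se1 = None
    try:
        cov = np.linalg.inv(-model.hessian(params))
        d = np.diag(cov)
        if np.all(d[:2] > 0):
            se0, se1 = float(np.sqrt(d[0])), float(np.sqrt(d[1]))
    except np.linalg.LinAlgError:
        pass
    return BetaRegFit(
        beta0=float(beta0),
        beta1=float(beta1),
        kappa=kappa,
        fitted_means=mu,
        loglik=llf,
        serial_model="none",
        beta0_se=se0,
        beta1_se=se1,
        n_obs=n,
    )


def _start_params(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    # linear fit on the logit scale plus a method-of-moments precision
    y = special.logit(v)
    X = np.column_stack([np.ones_like(u), u])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu0 = special.expit(X @ coef)
    resid_var = max(np.var(v - mu0), 1e-6)
    kappa0 = max(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0)
    return np.array([coef[0], coef[1], np.log(kappa0)])


def _newton_polish(model: BetaModel, params: np.ndarray, n_steps: int = 12) -> np.ndarray:
    best = params
    for _ in range(n_steps):
        score = model.score(best)
        if np.max(np.abs(score)) < 1e-10 * model.nobs:
            break
        hess = model.hessian(best)
        try:
            step = np.linalg.solve(hess, score)
        except np.linalg.LinAlgError:
            break
        cand = best - step
        if not np.isfinite(model.loglike(cand)):
            break
        best = cand
    return best


def _score_ok(model: BetaModel, params: np.ndarray, tol: float = 1e-7) -> bool:
    return bool(np.max(np.abs(model.score(params))) < tol * model.nobs)


# ---------------------------------------------------------------------------
# Gaussian-copula AR(1) serial correction

_Z_CLIP = 1e-10


def _ar1_negloglik(theta: np.ndarray, u: np.ndarray, v: np.ndarray) -> float:
    beta0, beta1, log_kappa, phi_raw = theta
    kappa = np.exp(log_kappa)
    phi = np.tanh(phi_raw)
    mu = special.expit(beta0 + beta1 * u)
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    ll = float(np.sum(beta_log_density(v, mu, kappa)))
    cdf = np.clip(stats.beta.cdf(v, mu * kappa, (1 - mu) * kappa), _Z_CLIP, 1 - _Z_CLIP)
    z = special.ndtri(cdf)
    resid = z[1:] - phi * z[:-1]
    one_m = 1.0 - phi * phi
    ll += -0.5 * np.sum(resid**2) / one_m + 0.5 * np.sum(z[1:] ** 2)
    ll += -0.5 * (len(z) - 1) * np.log(one_m)
    if not np.isfinite(ll):
        return 1e12
    return -ll


def _fit_ar1(u: np.ndarray, v: np.ndarray, base: BetaRegFit, max_restarts: int) -> BetaRegFit:
    n = len(u)
    # initial AR coefficient from the lag-1 autocorrelation of the normal
    # scores at the marginal fit
    cdf = np.clip(
        stats.beta.cdf(v, base.fitted_means * base.kappa, (1 - base.fitted_means) * base.kappa),
        _Z_CLIP,
        1 - _Z_CLIP,
    )
    z = special.ndtri(cdf)
    phi0 = float(np.clip(np.corrcoef(z[1:], z[:-1])[0, 1], -0.9, 0.9))
    x0 = np.array([base.beta0, base.beta1, np.log(base.kappa), np.arctanh(phi0)])

    rng = np.random.default_rng(1)
    best = None
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            _ar1_negloglik, x0, args=(u, v), method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if best is not None and best.success:
            break
        x0 = x0 + rng.normal(scale=0.2, size=4)
    if best is None or not np.isfinite(best.fun):
        raise FitConvergenceError("AR(1) beta regression failed to converge")

    theta = best.x
    se = _numeric_se(_ar1_negloglik, theta, (u, v))
    phi = float(np.tanh(theta[3]))
    # delta method through tanh for the AR coefficient's standard error
    phi_se = se[3] * (1.0 - phi * phi) if se is not None else None
    mu = special.expit(theta[0] + theta[1] * u)
    return BetaRegFit(
        beta0=float(theta[0]),
        beta1=float(theta[1]),
        kappa=float(np.exp(theta[2])),
        fitted_means=mu,
        loglik=float(-best.fun),
        serial_model="ar1",
        ar1=phi,
        ar1_se=phi_se,
        n_obs=n,
    )


def _numeric_se(f, theta: np.ndarray, args, h: float = 1e-4):
    k = len(theta)
    H = np.zeros((k, k))
    f0 = f(theta, *args)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(theta + ei + ej, *args)
                - f(theta + ei, *args)
                - f(theta + ej, *args)
                + f0
            ) / (h * h)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    d = np.diag(cov)
    if np.any(d <= 0):
        return None
    return np.sqrt(d)


def regression_curve(fit: BetaRegFit, u_grid) -> np.ndarray:
    """Fitted mean curve inverse-logit(beta0 + beta1 u) on a grid."""
    u_grid = np.asarray(u_grid, dtype=float)
    return special.expit(fit.beta0 + fit.beta1 * u_grid)
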