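"""Synthetic-data generators used to validate copula directional dependence.

Two generators are provided:

* an asymmetric bivariate copula built from two Plackett copulas with
  powered arguments (Durante construction), pushed through a Gaussian
  hemodynamic response function (HRF) and subsampled at the scanner
  repetition time to emulate BOLD measurements of two coupled regions;
* a three-region VAR(1) process observed at a low sampling rate
  (1-in-``L`` subsampling), under which lag-based directionality reverses
  while the noise asymmetry - the signal the copula method exploits -
  survives.

All sampling routines take an explicit integer seed and use an isolated
``numpy.random.Generator``, so every simulated data set is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, special

__all__ = [
    "AsymCopulaSpec",
    "BOLDSimSpec",
    "VARSpec",
    "plackett_cdf",
    "asym_copula_cdf",
    "sample_asym_copula",
    "gaussianize",
    "simulate_bold",
    "simulate_var",
    "var_power_matrix",
    "var_stationary_cov",
    "cyclic_var_matrix",
]

#: below this distance from theta = 1 the Plackett closed form is replaced
#: by its independence limit u*v (the closed form divides by theta - 1)
_PLACKETT_INDEP_TOL = 1e-8

#: finite-difference step for the conditional CDF of the asymmetric copula
_COND_FD_STEP = 1e-6

#: bisection tolerance when inverting the conditional CDF
_COND_INV_TOL = 1e-9


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class AsymCopulaSpec:
    """Parameters of the asymmetric copula C(u,v) = A_t1(u^a, v^b) A_t2(u^(1-a), v^(1-b)).

    ``theta1`` and ``theta2`` are Plackett odds-ratio parameters (> 0);
    ``alpha`` and ``beta`` are the exponents in [0, 1].  ``alpha != beta``
    makes the copula asymmetric, which induces a directional dependence.
    """

    theta1: float
    theta2: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.theta1 > 0 and self.theta2 > 0):
            raise ValueError("Plackett parameters theta1, theta2 must be positive")
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("exponents alpha, beta must lie in [0, 1]")

    @property
    def alpha_bar(self) -> float:
        return 1.0 - self.alpha

    @property
    def beta_bar(self) -> float:
        return 1.0 - self.beta


@dataclass(frozen=True)
class BOLDSimSpec:
    """Measurement model for simulated BOLD data.

    A latent series on a fine grid with step ``a`` seconds is convolved with
    a Gaussian HRF of full width at half maximum ``fwhm`` seconds, then
    subsampled every ``tr`` seconds (the repetition time).  The latent
    length is ``n = T_minutes * 60 / a``; the output length is
    ``T_minutes * 60 / tr``.
    """

    T_minutes: float
    a: float = 0.1
    fwhm: float = 4.0
    tr: float = 2.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("accuracy step a must be positive")
        if self.fwhm < 0:
            raise ValueError("fwhm must be nonnegative")
        step = self.tr / self.a
        if abs(step - round(step)) > 1e-9 or round(step) < 1:
            raise ValueError("tr must be a positive integer multiple of a")
        n = self.T_minutes * 60.0 / self.a
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError("T_minutes*60/a must be a positive integer")

    @property
    def n_latent(self) -> int:
        return int(round(self.T_minutes * 60.0 / self.a))

    @property
    def subsample_step(self) -> int:
        return int(round(self.tr / self.a))


@dataclass(frozen=True)
class VARSpec:
    """Three-region VAR(1) y_t = A y_{t-1} + e_t with 1-in-L subsampling.

    ``noise_model`` selects the innovation distribution:

    * ``"independent"`` - three i.i.d. N(0,1) components;
    * ``"dependent"``   - (e1, e2) bivariate normal with unit variances and
      correlation ``r12``; e3 ~ N(0,1);
    * ``"asymmetric"``  - (e1, e2) drawn from ``copula_spec`` (uniform
      margins, used as drawn); e3 ~ N(0,1).
    """

    A: np.ndarray
    noise_model: str = "independent"
    r12: float = 0.56
    copula_spec: AsymCopulaSpec | None = None
    n: int = 10000
    L: int = 5
    burn_in: int = 1000

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        object.__setattr__(self, "A", A)
        if np.max(np.abs(np.linalg.eigvals(A))) >= 1.0:
            raise ValueError("A must have spectral radius < 1 (stationarity)")
        if self.noise_model not in ("independent", "dependent", "asymmetric"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_model == "asymmetric" and self.copula_spec is None:
            raise ValueError("asymmetric noise model requires copula_spec")
        if not (isinstance(self.L, (int, np.integer)) and self.L >= 1):
            raise ValueError("subsampling factor L must be an integer >= 1")
        if self.n < 1:
            raise ValueError("series length n must be positive")


def cyclic_var_matrix(c: float = 0.5) -> np.ndarray:
    """Three-region cyclic coupling matrix with entries c at (1,2), (2,3), (3,1).

    The implied lag-one influences are 2->1, 3->2, 1->3; after 1-in-L
    subsampling (L = 2, 5, 8, ...) the effective coefficient matrix ``A**L``
    has its nonzeros at (1,3), (2,1), (3,2), i.e. every influence reverses.
    """
    A = np.zeros((3, 3))
    A[0, 1] = A[1, 2] = A[2, 0] = c
    return A


# ---------------------------------------------------------------------------
# copulas


def plackett_cdf(u, v, theta: float):
    """Plackett copula CDF A_theta(u, v).

    Closed form ``[S - sqrt(S^2 - 4 theta (theta-1) u v)] / (2 (theta-1))``
    with ``S = 1 + (theta-1)(u+v)``; the removable singularity at
    ``theta = 1`` is handled by the independence limit ``u v``.
    """
    if theta <= 0:
        raise ValueError("Plackett parameter theta must be positive")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u < 0) | (u > 1)) or np.any((v < 0) | (v > 1)):
        raise ValueError("copula arguments must lie in [0, 1]")
    if abs(theta - 1.0) < _PLACKETT_INDEP_TOL:
        out = u * v
    else:
        tm1 = theta - 1.0
        s = 1.0 + tm1 * (u + v)
        disc = s * s - 4.0 * theta * tm1 * u * v
        out = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * tm1)
        out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


def asym_copula_cdf(u, v, spec: AsymCopulaSpec):
    """Asymmetric copula C(u,v) = A_t1(u^alpha, v^beta) * A_t2(u^(1-alpha), v^(1-beta))."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any((u < 0) | (u > 1)) or np.any((v < 0) | (v > 1)):
        raise ValueError("copula arguments must lie in [0, 1]")
    first = plackett_cdf(u**spec.alpha, v**spec.beta, spec.theta1)
    second = plackett_cdf(u**spec.alpha_bar, v**spec.beta_bar, spec.theta2)
    out = np.asarray(first) * np.asarray(second)
    if out.ndim == 0:
        return float(out)
    return out


def _conditional_cdf(u: np.ndarray, v: np.ndarray, spec: AsymCopulaSpec) -> np.ndarray:
    """Conditional CDF C(v | u) = dC(u,v)/du by central finite differences."""
    h = _COND_FD_STEP
    uc = np.clip(u, h, 1.0 - h)
    num = asym_copula_cdf(uc + h, v, spec) - asym_copula_cdf(uc - h, v, spec)
    return np.clip(np.asarray(num) / (2.0 * h), 0.0, 1.0)


def sample_asym_copula(n: int, spec: AsymCopulaSpec, seed: int | None = None) -> np.ndarray:
    """Draw ``n`` i.i.d. pairs from the asymmetric copula.

    Uses the conditional-distribution method: U is uniform, and V solves
    ``C(v | U) = W`` for an independent uniform W, inverted by bisection on
    (0, 1).  Returns an ``(n, 2)`` array with uniform margins.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return _sample_asym_copula(n, spec, rng)


def _sample_asym_copula(n: int, spec: AsymCopulaSpec, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(size=n)
    w = rng.uniform(size=n)
    lo = np.zeros(n)
    hi = np.ones(n)
    # bisection: interval halves each step, so ~35 steps reach the tolerance
    n_steps = int(np.ceil(-np.log2(_COND_INV_TOL))) + 1
    for _ in range(n_steps):
        mid = 0.5 * (lo + hi)
        below = _conditional_cdf(u, mid, spec) < w
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    v = 0.5 * (lo + hi)
    return np.column_stack([u, v])


# ---------------------------------------------------------------------------
# BOLD measurement model


def gaussianize(u_series) -> np.ndarray:
    """Map a copula-scale series through the standard normal quantile function."""
    u = np.asarray(u_series, dtype=float)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ValueError("gaussianize requires values strictly inside (0, 1)")
    return special.ndtri(u)


def _hrf_kernel(fwhm: float, a: float) -> np.ndarray:
    """Gaussian HRF kernel at step ``a``, truncated at +/- 4 sigma, sum 1."""
    if fwhm <= 0:
        return np.array([1.0])
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(4.0 * sigma / a))
    t = np.arange(-half, half + 1) * a
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def _convolve_reflect(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    pad = len(kernel) // 2
    if pad == 0:
        return x * kernel[0]
    padded = np.pad(x, pad, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def simulate_bold(x, y, bold_spec: BOLDSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two latent series with the Gaussian HRF and subsample at TR.

    Input length must equal ``bold_spec.n_latent``; the outputs have length
    ``n_latent // (tr/a)``.  Kernel weights sum to one, so a constant input
    stays constant, and the series start is reflection-padded to avoid an
    onset transient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != bold_spec.n_latent or len(y) != bold_spec.n_latent:
        raise ValueError(
            f"input length must be T_minutes*60/a = {bold_spec.n_latent}, "
            f"got {len(x)} and {len(y)}"
        )
    kernel = _hrf_kernel(bold_spec.fwhm, bold_spec.a)
    step = bold_spec.subsample_step
    xs = _convolve_reflect(x, kernel)[::step]
    ys = _convolve_reflect(y, kernel)[::step]
    return xs, ys


# ---------------------------------------------------------------------------
# subsampled VAR


def simulate_var(spec: VARSpec, seed: int | None = None) -> np.ndarray:
    """Simulate the VAR(1), discard burn-in, keep every L-th observation.

    Returns an array of shape ``(n // L, k)``.  The retained rows are the
    observations at times L, 2L, ... of the post-burn-in path, so the
    subsampled series is itself a VAR(1) with coefficient ``A**L``.
    """
    rng = np.random.default_rng(seed)
    k = spec.A.shape[0]
    total = spec.burn_in + spec.n
    eps = _draw_var_noise(spec, total, rng)
    y = np.zeros((total, k))
    state = np.zeros(k)
    A = spec.A
    for t in range(total):
        state = A @ state + eps[t]
        y[t] = state
    path = y[spec.burn_in :]
    return path[spec.L - 1 :: spec.L]


def _draw_var_noise(spec: VARSpec, m: int, rng: np.random.Generator) -> np.ndarray:
    k = spec.A.shape[0]
    if spec.noise_model == "independent":
        return rng.standard_normal((m, k))
    if k < 2:
        raise ValueError("dependent noise models need at least two components")
    eps = rng.standard_normal((m, k))
    if spec.noise_model == "dependent":
        chol = np.linalg.cholesky(np.array([[1.0, spec.r12], [spec.r12, 1.0]]))
        eps[:, :2] = eps[:, :2] @ chol.T
    else:
        # asymmetric: copula pair standardized to zero mean, unit variance
        # (uniform margins have variance 1/12; leaving them unscaled would
        # drown the pair's dependence under the unit-variance third noise)
        uv = _sample_asym_copula(m, spec.copula_spec, rng)
        eps[:, :2] = (uv - 0.5) * np.sqrt(12.0)
    return eps


def var_power_matrix(A, L: int) -> np.ndarray:
    """Coefficient matrix ``A**L`` of the 1-in-L subsampled VAR(1)."""
    if not (isinstance(L, (int, np.integer)) and L >= 1):
        raise ValueError("L must be an integer >= 1")
    return np.linalg.matrix_power(np.asarray(A, dtype=float), int(L))


def var_stationary_cov(A, Q) -> np.ndarray:
    """Stationary covariance of a VAR(1): the solution of S = A S A' + Q.

    Analytic oracle for the simulator - the sample covariance of a long
    simulated path must match this discrete-Lyapunov solution.
    """
    A = np.asarray(A, dtype=float)
    Q = np.asarray(Q, dtype=float)
    return linalg.solve_discrete_lyapunov(A, Q)
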