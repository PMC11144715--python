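"""Stationary Gaussian process regression on one coordinate within one time segment.

The observation model for one leaf of the partition (or the whole track in
the stationary case) is

    y | beta, sigma2 ~ N(F beta, sigma2 * (C(d, p) + g I))

where ``F = [1, t]`` is a linear-in-time mean design, ``C`` is the isotropic
power-exponential correlation ``C_ij = exp(-|t_i - t_j|^p / d)``, ``g`` is the
nugget (observation-noise-to-signal variance ratio, absorbing GPS error) and
``sigma2`` is the process variance.  Conjugate priors -- a normal prior on the
mean coefficients scaled by ``sigma2`` and an inverse-gamma prior on
``sigma2`` -- are integrated out analytically, so the marginal likelihood of a
leaf and its posterior predictive are multivariate Student-t distributions
conditional only on the correlation hyperparameters ``(d, g)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

logger = logging.getLogger(__name__)

#: Jitter policy: start here, escalate by x10 up to _JITTER_MAX before failing.
_JITTER_START = 1e-10
_JITTER_MAX = 1e-6


class NumericalError(RuntimeError):
    """A correlation matrix could not be factorized even after jitter."""


@dataclass(frozen=True)
class GPHyperParams:
    """Correlation hyperparameters of one leaf GP.

    d : correlation range on standardized time (larger = smoother).
    g : nugget, the ratio of observation-noise variance to process variance.
    p : power-exponential exponent, fixed per run; p=2 gives the Gaussian kernel.
    """

    d: float
    g: float
    p: float = 2.0

    def __post_init__(self) -> None:
        if not (self.d > 0 and np.isfinite(self.d)):
            raise ValueError(f"range d must be positive and finite, got {self.d}")
        if not (self.g > 0 and np.isfinite(self.g)):
            raise ValueError(f"nugget g must be positive and finite, got {self.g}")
        if not (0 < self.p <= 2):
            raise ValueError(f"power p must lie in (0, 2], got {self.p}")


@dataclass(frozen=True)
class GPPriorConfig:
    """Priors for one leaf GP, on the standardized scale.

    The mean coefficients beta = (intercept, slope) have prior
    N(mean_coef_mean, sigma2 / mean_coef_precision * I); the process variance
    sigma2 has an inverse-gamma(scale_shape, scale_rate) prior; d and g have
    independent log-normal hyperpriors.  Defaults are weakly informative for
    data standardized to zero mean / unit variance on a [0, 1] time domain.
    """

    mean_coef_mean: tuple[float, float] = (0.0, 0.0)
    mean_coef_precision: float = 0.01
    scale_shape: float = 2.0
    scale_rate: float = 1.0
    d_log_mu: float = math.log(0.1)
    d_log_sigma: float = 1.5
    g_log_mu: float = math.log(0.01)
    g_log_sigma: float = 2.0

    def __post_init__(self) -> None:
        for name in ("mean_coef_precision", "scale_shape", "scale_rate",
                     "d_log_sigma", "g_log_sigma"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def log_hyperprior(self, hyper: GPHyperParams) -> float:
        """Log density of (d, g) under the log-normal hyperpriors."""
        return (_lognorm_logpdf(hyper.d, self.d_log_mu, self.d_log_sigma)
                + _lognorm_logpdf(hyper.g, self.g_log_mu, self.g_log_sigma))

    def draw_hyperparams(self, rng: np.random.Generator, p: float = 2.0) -> GPHyperParams:
        """One draw of (d, g) from the hyperprior."""
        d = float(np.exp(self.d_log_mu + self.d_log_sigma * rng.standard_normal()))
        g = float(np.exp(self.g_log_mu + self.g_log_sigma * rng.standard_normal()))
        return GPHyperParams(d=d, g=g, p=p)


@dataclass(frozen=True)
class LeafData:
    """Observations of one coordinate falling in one partition cell.

    times are standardized to [0, 1] and pairwise distinct (the partition
    machinery always supplies them sorted; the GP density itself is
    exchangeable in the observation order); values are the centered/scaled
    coordinate observations.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        if t.size > 1 and np.unique(t).size != t.size:
            raise ValueError("times must be pairwise distinct")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PredictiveDistribution:
    """Joint Student-t posterior predictive at a set of prediction times.

    mean has shape (m,); cov is the (m, m) Student-t scale matrix (the
    covariance is cov * df / (df - 2) for df > 2); df are the degrees of
    freedom; includes_nugget records whether observation noise is included
    (True targets a new observation, False the latent path).
    """

    mean: np.ndarray
    cov: np.ndarray
    df: float
    includes_nugget: bool

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        c = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "cov", c)
        if self.df <= 0:
            raise ValueError("degrees of freedom must be positive")

    @property
    def scale(self) -> np.ndarray:
        """Per-time marginal scale (square root of the scale-matrix diagonal)."""
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def logpdf(self, values: np.ndarray) -> float:
        """Joint log density of ``values`` under the multivariate Student-t."""
        values = np.asarray(values, dtype=float)
        m = self.mean.size
        if m == 0:
            return 0.0
        L = _chol_with_jitter(self.cov)
        resid = np.linalg.solve(L, values - self.mean)
        quad = float(resid @ resid)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        nu = self.df
        return float(
            gammaln((nu + m) / 2.0) - gammaln(nu / 2.0)
            - 0.5 * m * math.log(nu * math.pi) - 0.5 * logdet
            - 0.5 * (nu + m) * math.log1p(quad / nu)
        )


def _lognorm_logpdf(x: float, mu: float, sigma: float) -> float:
    if x <= 0:
        return -np.inf
    z = (math.log(x) - mu) / sigma
    return -math.log(x * sigma) - 0.5 * math.log(2 * math.pi) - 0.5 * z * z


def correlation_matrix(times: np.ndarray, hyper: GPHyperParams) -> np.ndarray:
    """Power-exponential correlation matrix with nugget on the diagonal.

    Entry (i, j) is ``exp(-|t_i - t_j|^p / d) + g * 1[i == j]``; the diagonal
    is exactly ``1 + g``.
    """
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    dt = np.abs(t[:, None] - t[None, :])
    K = np.exp(-(dt ** hyper.p) / hyper.d)
    np.fill_diagonal(K, 1.0 + hyper.g)
    return K


def _chol_with_jitter(mat: np.ndarray) -> np.ndarray:
    """Cholesky factor with diagonal jitter.

    A base jitter of 1e-10 is always added (the Gaussian kernel is routinely
    near-singular at machine precision); on failure it escalates by x10 up to
    1e-6 with a logged warning before raising :class:`NumericalError`.
    """
    jitter = _JITTER_START
    eye = np.eye(mat.shape[0])
    while jitter <= _JITTER_MAX:
        try:
            L = np.linalg.cholesky(mat + jitter * eye)
            if jitter > _JITTER_START:
                logger.warning("correlation matrix required escalated jitter %.1e",
                               jitter)
            return L
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise NumericalError(
        f"matrix of size {mat.shape[0]} not positive definite after jitter up to {_JITTER_MAX:g}"
    )


def _design(times: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(times), times])


def log_marginal_likelihood(leaf: LeafData, hyper: GPHyperParams,
                            prior: GPPriorConfig) -> float:
    """Log marginal likelihood of a leaf with mean coefficients and variance
    integrated out.

    Marginally ``y ~ t_{2a}(F m0, (b/a) (K + F V0 F'))`` with ``a, b`` the
    inverse-gamma shape/rate, ``V0 = I / tau`` the prior coefficient
    covariance scaling and ``K`` the nugget-augmented correlation matrix.
    """
    n = leaf.n
    K = correlation_matrix(leaf.times, hyper)
    F = _design(leaf.times)
    m0 = np.asarray(prior.mean_coef_mean, dtype=float)
    V0 = np.eye(2) / prior.mean_coef_precision
    Sigma = K + F @ V0 @ F.T
    nu = 2.0 * prior.scale_shape
    S = (prior.scale_rate / prior.scale_shape) * Sigma
    L = _chol_with_jitter(S)
    resid = np.linalg.solve(L, leaf.values - F @ m0)
    quad = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    out = (gammaln((nu + n) / 2.0) - gammaln(nu / 2.0)
           - 0.5 * n * math.log(nu * math.pi) - 0.5 * logdet
           - 0.5 * (nu + n) * math.log1p(quad / nu))
    if not np.isfinite(out):
        raise NumericalError("non-finite marginal likelihood")
    return float(out)


def _posterior_sufficient(leaf: LeafData, hyper: GPHyperParams, prior: GPPriorConfig):
    """Posterior quantities for (beta, sigma2) given the leaf: returns
    (Kinv_y, Kinv_F, m_n, V_n, a_n, b_n, L) with L the Cholesky of K."""
    K = correlation_matrix(leaf.times, hyper)
    F = _design(leaf.times)
    y = leaf.values
    L = _chol_with_jitter(K)
    Kinv_y = _chol_solve(L, y)
    Kinv_F = _chol_solve(L, F)
    m0 = np.asarray(prior.mean_coef_mean, dtype=float)
    V0inv = prior.mean_coef_precision * np.eye(2)
    Vn_inv = V0inv + F.T @ Kinv_F
    Vn = np.linalg.inv(Vn_inv)
    mn = Vn @ (V0inv @ m0 + F.T @ Kinv_y)
    an = prior.scale_shape + 0.5 * leaf.n
    bn = prior.scale_rate + 0.5 * float(
        y @ Kinv_y + m0 @ V0inv @ m0 - mn @ Vn_inv @ mn
    )
    bn = max(bn, 1e-300)
    return Kinv_y, Kinv_F, mn, Vn, an, bn, L


def _chol_solve(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.linalg.solve(L.T, np.linalg.solve(L, b))


def posterior_predictive(leaf: LeafData, hyper: GPHyperParams, prior: GPPriorConfig,
                         new_times: np.ndarray, include_nugget: bool = False
                         ) -> PredictiveDistribution:
    """Joint Student-t posterior predictive at ``new_times``, conditional on
    the correlation hyperparameters, with mean coefficients and process
    variance marginalized.

    With ``include_nugget=False`` the target is the latent path (GPS error
    excluded); with True it is a new noisy observation.
    """
    tnew = np.asarray(new_times, dtype=float)
    if tnew.size == 0:
        return PredictiveDistribution(mean=np.empty(0), cov=np.empty((0, 0)),
                                      df=2.0 * prior.scale_shape + leaf.n,
                                      includes_nugget=include_nugget)
    Kinv_y, Kinv_F, mn, Vn, an, bn, L = _posterior_sufficient(leaf, hyper, prior)
    F = _design(leaf.times)
    Fs = _design(tnew)
    dt = np.abs(tnew[:, None] - leaf.times[None, :])
    Rs = np.exp(-(dt ** hyper.p) / hyper.d)          # cross-correlation, no nugget
    dts = np.abs(tnew[:, None] - tnew[None, :])
    Css = np.exp(-(dts ** hyper.p) / hyper.d)
    if include_nugget:
        Css = Css + hyper.g * np.eye(tnew.size)
    mean = Fs @ mn + Rs @ (Kinv_y - Kinv_F @ mn)
    H = Fs - Rs @ Kinv_F
    cond_cov = Css - Rs @ _chol_solve(L, Rs.T) + H @ Vn @ H.T
    cond_cov = 0.5 * (cond_cov + cond_cov.T)
    scale_mat = (bn / an) * cond_cov
    return PredictiveDistribution(mean=mean, cov=scale_mat, df=2.0 * an,
                                  includes_nugget=include_nugget)


def draw_predictive(dist: PredictiveDistribution, rng: np.random.Generator) -> np.ndarray:
    """One joint draw from a multivariate Student-t predictive.

    Drawn as ``mean + L z * sqrt(df / w)`` with ``z`` standard normal,
    ``w ~ chi-square(df)`` and ``L`` the Cholesky factor of the scale matrix.
    A zero scale matrix returns the mean exactly.
    """
    m = dist.mean.size
    if m == 0:
        return np.empty(0)
    if np.allclose(dist.cov, 0.0):
        return dist.mean.copy()
    L = _chol_with_jitter(dist.cov)
    z = rng.standard_normal(m)
    w = rng.chisquare(dist.df)
    return dist.mean + (L @ z) * math.sqrt(dist.df / w)


def update_hyperparameters(leaf: LeafData, hyper: GPHyperParams, prior: GPPriorConfig,
                           rng: np.random.Generator, step_d: float = 0.5,
                           step_g: float = 0.5, loglik=None) -> GPHyperParams:
    """One Metropolis-Hastings sweep over (log d, log g).

    Component-wise Gaussian random-walk proposals on the log scale; the
    target is the marginal posterior of (d, g) given the leaf.  ``loglik``
    may override the likelihood term (used by prior-recovery diagnostics).
    """
    if loglik is None:
        loglik = lambda h: log_marginal_likelihood(leaf, h, prior)

    def posterior(h: GPHyperParams) -> float:
        return loglik(h) + prior.log_hyperprior(h)

    cur = hyper
    cur_lp = posterior(cur)
    for name, step in (("d", step_d), ("g", step_g)):
        # draw even when step==0 to keep the stream advance deterministic
        eps = rng.standard_normal()
        u = rng.random()
        if step == 0.0:
            continue
        prop_val = float(getattr(cur, name) * math.exp(step * eps))
        prop = replace(cur, **{name: prop_val})
        try:
            prop_lp = posterior(prop)
        except NumericalError:
            continue
        # log-scale random walk: proposal asymmetry cancels against the
        # Jacobian, so the log acceptance ratio needs the log(x'/x) term
        log_alpha = prop_lp - cur_lp + math.log(prop_val) - math.log(getattr(cur, name))
        if math.log(u) < log_alpha:
            cur, cur_lp = prop, prop_lp
    return cur
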