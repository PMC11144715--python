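import numpy as np
import pytest

from tgpmove.gp_core import GPHyperParams, GPPriorConfig, LeafData


@pytest.fixture
def prior() -> GPPriorConfig:
    return GPPriorConfig()


@pytest.fixture
def hyper() -> GPHyperParams:
    return GPHyperParams(d=0.3, g=0.1, p=2.0)


@pytest.fixture
def oracle_prior() -> GPPriorConfig:
    """Moderately informative prior under which the Gauss-Hermite oracle is
    fully resolved (a very diffuse coefficient prior needs impractically many
    nodes; the closed form is the same algebra either way)."""
    return GPPriorConfig(mean_coef_precision=1.0, scale_shape=2.5, scale_rate=1.5)


@pytest.fixture
def tiny_leaf() -> LeafData:
    return LeafData(times=np.array([0.2, 0.7]), values=np.array([0.5, -0.3]))


@pytest.fixture
def small_leaf() -> LeafData:
    rng = np.random.default_rng(42)
    t = np.sort(rng.uniform(0, 1, 12))
    return LeafData(times=t, values=np.sin(4 * t) + 0.1 * rng.standard_normal(12))


def marginal_likelihood_quadrature(times, values, hyper, prior, n_gh=96,
                                   n_s2=800, log_s2_range=(-15.0, 10.0)):
    """Independent numeric-integration oracle for the leaf marginal likelihood.

    Integrates the conditional Gaussian density over the conjugate priors:
    a 2-D Gauss-Hermite rule over the mean coefficients (Gaussian given
    sigma2) nested inside a dense log-grid trapezoid rule over sigma2 under
    its inverse-gamma prior.  Everything — kernel, Gaussian density,
    priors — is recomputed from first principles, independently of the
    implementation under test.
    """
    from scipy.stats import invgamma
    from numpy.polynomial.hermite_e import hermegauss

    times = np.asarray(times, float)
    values = np.asarray(values, float)
    n = times.size
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = np.exp(-abs(times[i] - times[j]) ** hyper.p / hyper.d)
            if i == j:
                K[i, j] += hyper.g
    Kinv = np.linalg.inv(K)
    _, logdetK = np.linalg.slogdet(K)
    F = np.column_stack([np.ones(n), times])
    m0 = np.asarray(prior.mean_coef_mean, float)
    tau = prior.mean_coef_precision

    nodes, weights = hermegauss(n_gh)  # weight exp(-z^2/2)
    weights = weights / np.sqrt(2 * np.pi)
    Z = np.stack(np.meshgrid(nodes, nodes, indexing="ij"), axis=-1).reshape(-1, 2)
    W = np.outer(weights, weights).ravel()

    log_s2 = np.linspace(*log_s2_range, n_s2)
    s2 = np.exp(log_s2)
    inner = np.empty(n_s2)
    for idx, s in enumerate(s2):
        beta = m0 + np.sqrt(s / tau) * Z            # (n_gh^2, 2)
        resid = values[None, :] - beta @ F.T        # (n_gh^2, n)
        quad = np.einsum("ij,jk,ik->i", resid, Kinv, resid) / s
        log_norm = -0.5 * (n * np.log(2 * np.pi * s) + logdetK)
        inner[idx] = float(W @ np.exp(log_norm - 0.5 * quad))
    integrand = invgamma.pdf(s2, prior.scale_shape, scale=prior.scale_rate) \
        * inner * s2  # s2 factor: Jacobian of the log substitution
    return np.log(np.trapezoid(integrand, log_s2))
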