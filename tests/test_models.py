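"""Log-posterior and gradient correctness for both outcome models."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

from bintrial import ModelSpec, grad_log_posterior, log_posterior
from bintrial.errors import ShapeError

from conftest import finite_difference_gradient, tiny_gaussian_spec, tiny_logistic_spec


def test_gaussian_origin_closed_form():
    """At theta = 0 with y = x = 0, n = k = 1, every term is evaluable by
    hand: zero likelihood deviance and two half-normal scale terms."""
    spec = ModelSpec(kind="gaussian", X=np.zeros((1, 1)), y=np.zeros(1),
                     center_index=np.zeros(1, int), k=1)
    theta = np.zeros(spec.dim)
    # likelihood: -n log sigma - r^2/2 = 0; priors: beta 0, c_raw 0,
    # sigma_c and sigma each -sigma^2/2 + log sigma = -1/2 at sigma = 1
    assert log_posterior(spec, theta) == pytest.approx(-1.0, abs=1e-12)


def test_bernoulli_likelihood_dominates_at_extreme_group_effect():
    """Intervention-arm events force the log posterior to -inf as the
    group coefficient heads to minus infinity."""
    n = 20
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
    y = np.ones(n)  # events in both arms
    spec = ModelSpec(kind="bernoulli_logit", X=X, y=y)
    values = [log_posterior(spec, np.array([0.0, b2])) for b2 in (0, -10, -100)]
    assert values[0] > values[1] > values[2]
    assert values[2] < -1000


def test_matches_direct_summation_oracle():
    """Term-by-term scipy.stats evaluation agrees to 1e-10 relative.

    The package drops additive constants, so the comparison is on log
    density *differences* between two parameter points.
    """

    def oracle(spec, theta):
        beta, c, log_sc, log_s = spec.unpack(theta)
        sigma_c = np.exp(log_sc)
        eta = spec.X @ beta + (sigma_c * c)[spec.center_index]
        if spec.kind == "bernoulli_logit":
            p = 1 / (1 + np.exp(-eta))
            ll = stats.bernoulli.logpmf(spec.y.astype(int), p).sum()
        else:
            sigma = np.exp(log_s)
            ll = stats.norm.logpdf(spec.y, eta, sigma).sum()
        lp = stats.norm.logpdf(beta, 0, spec.prior_sd_beta).sum()
        lp += stats.norm.logpdf(c, 0, 1).sum()
        lp += stats.halfnorm.logpdf(sigma_c, scale=spec.prior_sd_scales) + log_sc
        if spec.kind == "gaussian":
            lp += stats.halfnorm.logpdf(np.exp(log_s),
                                        scale=spec.prior_sd_scales) + log_s
        return ll + lp

    rng = np.random.default_rng(7)
    for maker in (tiny_logistic_spec, tiny_gaussian_spec):
        spec = maker(n=12, k=2, seed=3)
        t1 = rng.normal(size=spec.dim) * 0.7
        t2 = rng.normal(size=spec.dim) * 0.7
        ours = log_posterior(spec, t1) - log_posterior(spec, t2)
        ref = oracle(spec, t1) - oracle(spec, t2)
        assert ours == pytest.approx(ref, rel=1e-10)


@pytest.mark.parametrize("maker", [tiny_logistic_spec, tiny_gaussian_spec])
@pytest.mark.parametrize("parameterization", ["noncentered", "centered"])
def test_gradient_matches_finite_differences(maker, parameterization):
    spec = maker(n=15, k=3, seed=11, parameterization=parameterization)
    rng = np.random.default_rng(5)
    for _ in range(5):
        theta = rng.normal(size=spec.dim) * 0.5
        g = grad_log_posterior(spec, theta)
        fd = finite_difference_gradient(lambda t: log_posterior(spec, t), theta)
        np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-6)


def test_prior_only_gradient_vanishes_at_mode():
    """With no data rows the stationary point sits at beta = c = 0 and the
    scale coordinates at the transformed prior mode (log sigma = 0)."""
    for kind in ("bernoulli_logit", "gaussian"):
        spec = ModelSpec(kind=kind, X=np.empty((0, 3)), y=np.empty(0),
                         center_index=np.empty(0, int), k=2)
        g = grad_log_posterior(spec, np.zeros(spec.dim))
        np.testing.assert_allclose(g, 0.0, atol=1e-12)


def test_gradient_sign_equivariance_gaussian():
    """Negating the outcome together with beta and c negates the matching
    gradient coordinates and leaves the scale coordinates untouched."""
    spec = tiny_gaussian_spec(n=10, k=2, seed=2)
    flipped = ModelSpec(kind="gaussian", X=spec.X, y=-spec.y,
                        center_index=spec.center_index, k=spec.k)
    theta = np.random.default_rng(1).normal(size=spec.dim) * 0.4
    theta_f = theta.copy()
    theta_f[:4] *= -1  # beta (2) and c_raw (2); scales untouched
    g = grad_log_posterior(spec, theta)
    g_f = grad_log_posterior(flipped, theta_f)
    np.testing.assert_allclose(g_f[:4], -g[:4], rtol=1e-12)
    np.testing.assert_allclose(g_f[4:], g[4:], rtol=1e-12)


def test_flat_prior_map_equals_ml_logistic():
    """With diffuse coefficient priors and no random intercepts the
    posterior mode is the ML logistic fit (statsmodels IRLS oracle)."""
    rng = np.random.default_rng(17)
    n = 200
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.5, n)])
    eta = X @ np.array([0.3, -0.8, 0.5])
    y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
    spec = ModelSpec(kind="bernoulli_logit", X=X, y=y, prior_sd_beta=1e6)
    res = optimize.minimize(
        lambda t: -log_posterior(spec, t),
        np.zeros(spec.dim),
        jac=lambda t: -grad_log_posterior(spec, t),
        method="BFGS", options={"gtol": 1e-10},
    )
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(res.x, glm.params, rtol=1e-6)


def test_dimension_mismatch_raises_shape_error():
    spec = tiny_logistic_spec()
    with pytest.raises(ShapeError):
        log_posterior(spec, np.zeros(spec.dim + 1))
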