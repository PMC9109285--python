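"""Sampler correctness on known targets, diagnostics, reproducibility."""

import numpy as np
import pytest

from bintrial import ModelSpec, SamplerConfig, sample
from bintrial.errors import (
    ConfigError,
    DiagnosticUnavailableError,
    InitializationError,
)
from bintrial.hmc import PosteriorDraws, diagnose, sample_logdensity

from conftest import tiny_logistic_spec


def _iid_pseudo_draws(rng, n_chains=4, n_iter=500, loc=None):
    loc = loc or [0.0] * n_chains
    draws = np.concatenate(
        [rng.normal(m, 1.0, size=(n_iter, 1)) for m in loc]
    )
    return PosteriorDraws(
        draws=draws, columns=["x"],
        chain_id=np.repeat(np.arange(n_chains), n_iter),
        n_chains=n_chains, n_iter=n_iter, divergences=0, accept_rate=1.0,
    )


def test_standard_normal_target_moments():
    """Known target: kept-draw mean within 4/sqrt(ESS) of 0 and variance
    within 10% of 1 for every coordinate."""
    dim = 3
    logp = lambda q: -0.5 * float(q @ q)
    grad = lambda q: -q
    out = sample_logdensity(
        logp, grad, dim,
        SamplerConfig(n_chains=2, n_iter=4000, warmup=1000, seed=1),
    )
    diag = diagnose(out)
    for j, name in enumerate(out.columns):
        ess = diag.loc[name, "ess_bulk"]
        assert abs(out.draws[:, j].mean()) < 4.0 / np.sqrt(ess)
        assert out.draws[:, j].var() == pytest.approx(1.0, rel=0.10)


def test_correlated_gaussian_covariance_recovery():
    """Detailed-balance smoke test: the empirical covariance of a
    2-parameter correlated Gaussian matches the analytic covariance to
    under 5% Frobenius error at 40,000 kept draws."""
    cov = np.array([[1.0, 0.6], [0.6, 1.5]])
    prec = np.linalg.inv(cov)
    logp = lambda q: -0.5 * float(q @ prec @ q)
    grad = lambda q: -(prec @ q)
    out = sample_logdensity(
        logp, grad, 2,
        SamplerConfig(n_chains=4, n_iter=10000, warmup=1500, seed=2),
    )
    emp = np.cov(out.draws.T)
    err = np.linalg.norm(emp - cov) / np.linalg.norm(cov)
    assert err < 0.05


def test_seed_reproducibility_and_variation():
    spec = tiny_logistic_spec(n=30, k=2, seed=4)
    cfg = SamplerConfig(n_chains=2, n_iter=200, warmup=200, seed=9)
    d1 = sample(spec, cfg)
    d2 = sample(spec, cfg)
    np.testing.assert_array_equal(d1.draws, d2.draws)
    d3 = sample(spec, SamplerConfig(n_chains=2, n_iter=200, warmup=200, seed=10))
    assert not np.array_equal(d1.draws, d3.draws)


def test_probability_estimates_consistent_across_seeds():
    """P(beta_group-like coefficient < 0) agrees between two independent
    seeds to within 3 combined Monte-Carlo standard errors."""
    spec = tiny_logistic_spec(n=40, k=2, seed=8)
    estimates, ses = [], []
    for seed in (11, 12):
        out = sample(spec, SamplerConfig(n_chains=2, n_iter=2500,
                                         warmup=1000, seed=seed))
        ind = (out.column("beta_x1") < 0).astype(float)
        diag_ess = max(diagnose(out).loc["beta_x1", "ess_bulk"], 10.0)
        p = ind.mean()
        estimates.append(p)
        ses.append(np.sqrt(max(p * (1 - p), 1e-4) / diag_ess))
    combined = np.hypot(*ses)
    assert abs(estimates[0] - estimates[1]) < 3 * combined


def test_centered_and_noncentered_agree():
    """Both parameterizations induce the same posterior: P(beta_group < 0)
    agrees within 3 combined Monte-Carlo SEs on a small dataset."""
    results = []
    for param in ("noncentered", "centered"):
        spec = tiny_logistic_spec(n=60, k=3, seed=6, parameterization=param)
        out = sample(spec, SamplerConfig(n_chains=2, n_iter=8000, warmup=4000,
                                         seed=3, target_accept=0.95))
        p = (out.column("beta_x1") < 0).mean()
        ess = max(diagnose(out).loc["beta_x1", "ess_bulk"], 10.0)
        results.append((p, np.sqrt(max(p * (1 - p), 1e-4) / ess)))
    (p1, s1), (p2, s2) = results
    assert abs(p1 - p2) < 3 * np.hypot(s1, s2)


def test_scale_columns_strictly_positive():
    spec = tiny_logistic_spec(n=30, k=2, seed=4)
    out = sample(spec, SamplerConfig(n_chains=2, n_iter=300, warmup=300, seed=5))
    assert (out.column("sigma_c") > 0).all()
    assert out.draws.shape[0] == 2 * 300


def test_rhat_near_one_for_exchangeable_chains():
    draws = _iid_pseudo_draws(np.random.default_rng(0))
    report = diagnose(draws)
    assert 0.99 <= report.loc["x", "rhat"] <= 1.01
    assert not report["flagged"].any()


def test_rhat_flags_separated_chains():
    draws = _iid_pseudo_draws(np.random.default_rng(1), loc=[0, 0, 5, 5])
    report = diagnose(draws)
    assert report.loc["x", "rhat"] > 1.5
    assert report["flagged"].all()


def test_ess_of_iid_draws_near_total():
    draws = _iid_pseudo_draws(np.random.default_rng(2), n_chains=4, n_iter=1000)
    report = diagnose(draws)
    assert report.loc["x", "ess_bulk"] == pytest.approx(4000, rel=0.20)


def test_single_chain_diagnostics_unavailable():
    draws = _iid_pseudo_draws(np.random.default_rng(3), n_chains=1)
    draws.n_chains = 1
    with pytest.raises(DiagnosticUnavailableError):
        diagnose(draws)


def test_initialization_failure_raises():
    logp = lambda q: -np.inf
    grad = lambda q: np.zeros(1)
    with pytest.raises(InitializationError):
        sample_logdensity(logp, grad, 1,
                          SamplerConfig(n_chains=1, n_iter=10, warmup=10, seed=0))


def test_invalid_sampler_config_rejected():
    with pytest.raises(ConfigError):
        SamplerConfig(n_chains=0)
    with pytest.raises(ConfigError):
        SamplerConfig(target_accept=1.5)


def test_draws_csv_round_trip(tmp_path):
    spec = tiny_logistic_spec(n=20, k=2, seed=4)
    out = sample(spec, SamplerConfig(n_chains=2, n_iter=150, warmup=150, seed=7))
    path = tmp_path / "draws.csv"
    out.to_csv(path)
    back = PosteriorDraws.from_csv(path, kind="bernoulli_logit")
    assert back.columns == out.columns
    np.testing.assert_allclose(back.draws, out.draws, rtol=0, atol=1e-12)
    assert back.n_chains == 2 and back.n_iter == 150
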