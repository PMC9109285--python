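"""Hierarchical Bernoulli-logit and Gaussian log-posteriors with gradients.

Both outcome models share a linear predictor

    eta_i = x_i' beta + C[center(i)],          C_j ~ Normal(0, sigma_c)

with weakly-informative priors beta_j ~ Normal(0, prior_sd_beta) and
half-Normal(0, prior_sd_scales) on the scale parameters sigma_c (and, for
the Gaussian model, the residual SD sigma). The binary risky-drinking
outcome is Bernoulli(inv_logit(eta)); AUDIT scores are Normal(eta, sigma).

Sampling runs on an unconstrained parameter vector

    theta = (beta[p], c[k], log sigma_c, [log sigma])

with the log-transform Jacobian included in the density. Center effects
use the non-centered parameterization C = sigma_c * c_raw by default
(k = 5 groups with a weakly identified scale is the classic funnel case);
the centered form is available and induces the same posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import EncodedDesign
from .errors import ShapeError

__all__ = [
    "ModelSpec",
    "log_posterior",
    "grad_log_posterior",
    "constrain",
    "constrained_names",
    "TrialOutcomeModel",
]


@dataclass(frozen=True)
class ModelSpec:
    """Likelihood kind, data and prior scales for one outcome model."""

    kind: str  # "bernoulli_logit" | "gaussian"
    X: np.ndarray
    y: np.ndarray
    center_index: np.ndarray | None = None  # 0-based, or None for no intercepts
    k: int = 0
    prior_sd_beta: float = 1.0
    prior_sd_scales: float = 1.0
    parameterization: str = "noncentered"
    colnames: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("bernoulli_logit", "gaussian"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.parameterization not in ("noncentered", "centered"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        if self.prior_sd_beta <= 0 or self.prior_sd_scales <= 0:
            raise ValueError("prior SDs must be positive")
        if (self.center_index is None) != (self.k == 0):
            raise ValueError("center_index and k must be provided together")

    @classmethod
    def from_design(cls, design: EncodedDesign, **kwargs) -> "ModelSpec":
        kind = "bernoulli_logit" if design.outcome == "risk" else "gaussian"
        return cls(
            kind=kind,
            X=design.X,
            y=design.y,
            center_index=design.center_index - 1,  # to 0-based
            k=design.k,
            colnames=list(design.colnames),
            **kwargs,
        )

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def dim(self) -> int:
        """Unconstrained dimension: p + k (+ log sigma_c) (+ log sigma)."""
        d = self.p + self.k + (1 if self.k else 0)
        if self.kind == "gaussian":
            d += 1
        return d

    def unpack(self, theta: np.ndarray):
        theta = np.asarray(theta, float)
        if theta.shape != (self.dim,):
            raise ShapeError(
                f"theta has shape {theta.shape}, model needs ({self.dim},)"
            )
        p, k = self.p, self.k
        beta = theta[:p]
        c = theta[p:p + k]
        pos = p + k
        log_sigma_c = theta[pos] if k else None
        pos += 1 if k else 0
        log_sigma = theta[pos] if self.kind == "gaussian" else None
        return beta, c, log_sigma_c, log_sigma


def _linear_predictor(spec: ModelSpec, beta, c, sigma_c):
    eta = spec.X @ beta
    if spec.k:
        C = sigma_c * c if spec.parameterization == "noncentered" else c
        eta = eta + C[spec.center_index]
    return eta


def log_posterior(spec: ModelSpec, theta: np.ndarray) -> float:
    """Log joint density (up to a constant) on the unconstrained scale."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _log_posterior(spec, theta)


def _log_posterior(spec: ModelSpec, theta: np.ndarray) -> float:
    beta, c, log_sigma_c, log_sigma = spec.unpack(theta)
    sigma_c = np.exp(log_sigma_c) if spec.k else 0.0
    eta = _linear_predictor(spec, beta, c, sigma_c)

    if spec.kind == "bernoulli_logit":
        ll = float(spec.y @ eta - np.logaddexp(0.0, eta).sum())
    else:
        sigma = np.exp(log_sigma)
        r = spec.y - eta
        ll = float(-len(spec.y) * log_sigma - 0.5 * (r @ r) / sigma**2)

    lp = -0.5 * float(beta @ beta) / spec.prior_sd_beta**2
    ss2 = spec.prior_sd_scales**2
    if spec.k:
        if spec.parameterization == "noncentered":
            lp += -0.5 * float(c @ c)
        else:
            lp += -spec.k * log_sigma_c - 0.5 * float(c @ c) / sigma_c**2
        # half-normal prior on sigma_c plus log-transform Jacobian
        lp += -0.5 * sigma_c**2 / ss2 + log_sigma_c
    if spec.kind == "gaussian":
        sigma = np.exp(log_sigma)
        lp += -0.5 * sigma**2 / ss2 + log_sigma
    return ll + lp


def grad_log_posterior(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Analytic gradient of :func:`log_posterior` in the same coordinates."""
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        return _grad_log_posterior(spec, theta)


def _grad_log_posterior(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    beta, c, log_sigma_c, log_sigma = spec.unpack(theta)
    sigma_c = np.exp(log_sigma_c) if spec.k else 0.0
    eta = _linear_predictor(spec, beta, c, sigma_c)
    ss2 = spec.prior_sd_scales**2

    if spec.kind == "bernoulli_logit":
        d_eta = spec.y - 1.0 / (1.0 + np.exp(-eta))
    else:
        sigma = np.exp(log_sigma)
        r = spec.y - eta
        d_eta = r / sigma**2

    g = np.empty(spec.dim)
    p, k = spec.p, spec.k
    g[:p] = spec.X.T @ d_eta - beta / spec.prior_sd_beta**2
    if k:
        per_center = np.bincount(spec.center_index, weights=d_eta, minlength=k)
        if spec.parameterization == "noncentered":
            g[p:p + k] = sigma_c * per_center - c
            g[p + k] = sigma_c * float(c @ per_center) - sigma_c**2 / ss2 + 1.0
        else:
            g[p:p + k] = per_center - c / sigma_c**2
            g[p + k] = -k + float(c @ c) / sigma_c**2 - sigma_c**2 / ss2 + 1.0
    if spec.kind == "gaussian":
        sigma = np.exp(log_sigma)
        g[-1] = -len(spec.y) + float(r @ r) / sigma**2 - sigma**2 / ss2 + 1.0
    return g


def constrained_names(spec: ModelSpec) -> list[str]:
    """Column names of the constrained draw matrix."""
    base = spec.colnames or [f"x{j}" for j in range(spec.p)]
    names = [f"beta_{name}" for name in base]
    names += [f"C_{j + 1}" for j in range(spec.k)]
    if spec.k:
        names.append("sigma_c")
    if spec.kind == "gaussian":
        names.append("sigma")
    return names


def constrain(spec: ModelSpec, theta_draws: np.ndarray) -> np.ndarray:
    """Map unconstrained draws (rows) to the constrained reporting scale.

    Center effects are reported as C_j (already multiplied by sigma_c in
    the non-centered case) and scales as sigma_c, sigma.
    """
    theta_draws = np.atleast_2d(theta_draws)
    p, k = spec.p, spec.k
    out = [theta_draws[:, :p]]
    if k:
        sigma_c = np.exp(theta_draws[:, p + k])
        c = theta_draws[:, p:p + k]
        C = c * sigma_c[:, None] if spec.parameterization == "noncentered" else c
        out += [C, sigma_c[:, None]]
    if spec.kind == "gaussian":
        out.append(np.exp(theta_draws[:, -1])[:, None])
    return np.hstack(out)


class TrialOutcomeModel:
    """Bayesian outcome model for a two-arm clustered trial.

    Construct from an :class:`~bintrial.data.EncodedDesign` (or via
    :meth:`from_table` / :meth:`from_csv`), then call :meth:`fit` to draw
    posterior samples with Hamiltonian Monte Carlo; the returned
    :class:`~bintrial.results.TrialPosterior` carries draws, convergence
    diagnostics and the effect-probability summaries.
    """

    def __init__(self, design: EncodedDesign, prior_sd_beta: float = 1.0,
                 prior_sd_scales: float = 1.0,
                 parameterization: str = "noncentered"):
        self.design = design
        self.spec = ModelSpec.from_design(
            design,
            prior_sd_beta=prior_sd_beta,
            prior_sd_scales=prior_sd_scales,
            parameterization=parameterization,
        )

    @classmethod
    def from_table(cls, table, outcome: str = "risk", **kwargs) -> "TrialOutcomeModel":
        from .data import encode
        return cls(encode(table, outcome), **kwargs)

    @classmethod
    def from_csv(cls, path, outcome: str = "risk", mapping=None, **kwargs):
        from .data import read_trial_csv
        return cls.from_table(read_trial_csv(path, mapping), outcome, **kwargs)

    def fit(self, config=None, **kwargs):
        """Sample the posterior; returns a results object.

        ``config`` is a :class:`~bintrial.hmc.SamplerConfig`; keyword
        arguments override its fields (``n_chains``, ``n_iter``,
        ``warmup``, ``seed``, ...).
        """
        from .hmc import SamplerConfig, sample
        from .results import TrialPosterior

        if config is None:
            config = SamplerConfig(**kwargs)
        elif kwargs:
            from dataclasses import replace
            config = replace(config, **kwargs)
        draws = sample(self.spec, config)
        return TrialPosterior(model=self, draws=draws)
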